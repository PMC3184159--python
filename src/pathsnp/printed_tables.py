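"""Bundled published result tables (plain-TSV package data).

These are the printed per-SNP association table (genotype-class counts,
chosen models, ORs, bootstrap pass counts), the cumulative-risk category
table, the haplotype association table, the terminal-node table of the
interaction tree, and the cohort composition facts.  They serve as inputs
for arithmetic reproduction checks and as a realistic template for the
synthetic-cohort defaults.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table"]

_FILES = {
    "snp_associations": "table1.tsv",
    "cumulative": "table2.tsv",
    "haplotypes": "table4.tsv",
    "cart_nodes": "table5.tsv",
    "cohort_facts": "cohort_facts.tsv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load a bundled printed table by name.

    Names: ``snp_associations``, ``cumulative``, ``haplotypes``,
    ``cart_nodes``, ``cohort_facts``.
    """
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown bundled table {name!r}; "
                       f"choose from {sorted(_FILES)}") from None
    ref = resources.files("pathsnp").joinpath("data", fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
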