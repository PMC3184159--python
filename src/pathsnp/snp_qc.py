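"""Per-SNP summary statistics and Hardy-Weinberg equilibrium screening.

HWE is tested with the chi-square goodness-of-fit test (df = 1: three
genotype classes minus one minus one estimated allele frequency), comparing
observed genotype counts with the p^2 / 2pq / q^2 expectation, conventionally
in controls.  Screening results are reported, not used to drop SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GenotypeMatrix, SubjectTable

__all__ = ["HweResult", "variant_allele_freq", "hwe_test", "qc_report"]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float


def _check_counts(counts) -> tuple[int, int, int]:
    n_ww, n_wv, n_vv = (int(c) for c in counts)
    if min(n_ww, n_wv, n_vv) < 0:
        raise ValueError("negative genotype count")
    if n_ww + n_wv + n_vv == 0:
        raise ValueError("zero total genotype count")
    return n_ww, n_wv, n_vv


def variant_allele_freq(counts) -> float:
    """Variant-allele frequency from (n_WW, n_WV, n_VV)."""
    n_ww, n_wv, n_vv = _check_counts(counts)
    total = n_ww + n_wv + n_vv
    return (n_wv + 2 * n_vv) / (2 * total)


def hwe_test(counts) -> HweResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Monomorphic SNPs (estimated variant frequency 0 or 1) fit HWE exactly
    by construction and return chi2 = 0, p = 1.  No continuity correction.
    """
    n_ww, n_wv, n_vv = _check_counts(counts)
    total = n_ww + n_wv + n_vv
    q = variant_allele_freq(counts)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1.0)
    expected = np.array([p * p, 2 * p * q, q * q]) * total
    observed = np.array([n_ww, n_wv, n_vv], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def qc_report(gm: GenotypeMatrix, subjects: SubjectTable) -> pd.DataFrame:
    """Per-SNP, per-group genotype counts, variant frequency, and HWE."""
    subjects = subjects.align_to(gm)
    case = subjects.y == 1
    rows = []
    for snp in gm.snps:
        for group, mask in (("case", case), ("control", ~case)):
            counts = gm.genotype_counts(snp, mask=mask)
            if sum(counts) == 0:
                rows.append({"snp": snp, "group": group,
                             "n_ww": 0, "n_wv": 0, "n_vv": 0,
                             "maf": np.nan, "hwe_chi2": np.nan,
                             "hwe_p": np.nan})
                continue
            hwe = hwe_test(counts)
            rows.append({"snp": snp, "group": group,
                         "n_ww": counts[0], "n_wv": counts[1],
                         "n_vv": counts[2],
                         "maf": variant_allele_freq(counts),
                         "hwe_chi2": hwe.chi2, "hwe_p": hwe.p})
    return pd.DataFrame(rows)
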