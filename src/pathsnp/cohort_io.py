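"""Readers, writers, and core containers for case-control SNP cohorts.

Genotypes are coded by variant-allele count: 0 = homozygous wild-type (WW),
1 = heterozygous (WV), 2 = homozygous variant (VV); missing genotypes are
NaN.  The variant allele is defined structurally (VCF ALT, or the table
dialect's V allele) regardless of sample frequency; "minor allele frequency"
is a derived report field.

Two tabular genotype dialects are supported alongside VCF:

* a *wide* per-subject table (rows = subjects, columns = SNPs, values
  0/1/2/NA), which round-trips a :class:`GenotypeMatrix` exactly; and
* a *count* table holding per-SNP genotype-class counts split case/control
  ("107/82"-style cells), the form in which association studies print their
  results.  Count tables expand deterministically to pseudo-subjects (cases
  first, WW then WV then VV within each status) so printed tables are
  directly loadable and their per-class counts are reproduced exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SubjectTable",
    "read_genotypes",
    "read_subjects",
    "read_annotation",
    "write_genotypes",
    "write_count_table",
    "write_results",
]


class CohortIOError(ValueError):
    """Malformed or inconsistent cohort input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """N subjects x M biallelic SNPs, coded 0/1/2 with NaN for missing."""

    subjects: list[str]
    snps: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.snps = [str(s) for s in self.snps]
        self.codes = np.asarray(self.codes, dtype=float)
        n, m = len(self.subjects), len(self.snps)
        if self.codes.shape != (n, m):
            raise CohortIOError(
                f"codes shape {self.codes.shape} does not match "
                f"{n} subjects x {m} SNPs"
            )
        if len(set(self.snps)) != m:
            raise CohortIOError("duplicate SNP identifiers")
        if len(set(self.subjects)) != n:
            raise CohortIOError("duplicate subject identifiers")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortIOError(
                f"invalid genotype code {self.codes[i, j]!r} for subject "
                f"{self.subjects[i]!r}, SNP {self.snps[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp: str) -> int:
        try:
            return self.snps.index(snp)
        except ValueError:
            raise KeyError(f"SNP {snp!r} not in matrix") from None

    def column(self, snp: str) -> np.ndarray:
        return self.codes[:, self.snp_index(snp)]

    def subset(self, snps) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snps]
        return GenotypeMatrix(list(self.subjects), [self.snps[i] for i in idx],
                              self.codes[:, idx].copy())

    def genotype_counts(self, snp: str, mask: np.ndarray | None = None):
        """(n_WW, n_WV, n_VV) over non-missing subjects (optionally masked)."""
        col = self.column(snp)
        if mask is not None:
            col = col[np.asarray(mask, dtype=bool)]
        col = col[~np.isnan(col)]
        return (int((col == 0).sum()), int((col == 1).sum()),
                int((col == 2).sum()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=pd.Index(self.subjects, name="subject"),
                            columns=self.snps)


@dataclass
class SubjectTable:
    """Case/control labels plus adjustment covariates (age, ethnicity).

    Age or ethnicity may be absent (NaN) for pseudo-subjects expanded from
    printed count tables; models then fit without those covariates.
    """

    frame: pd.DataFrame

    REQUIRED = ("subject", "status")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise CohortIOError(f"subject table lacks column {col!r}")
        for col in ("age", "ethnicity"):
            if col not in df.columns:
                df[col] = np.nan
        df["subject"] = df["subject"].astype(str)
        if df["subject"].duplicated().any():
            dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
            raise CohortIOError(f"duplicate subject id {dup!r}")
        status = df["status"].astype(str).str.strip().str.lower()
        norm = status.map({"case": "case", "control": "control",
                           "1": "case", "0": "control"})
        if norm.isna().any():
            bad = status[norm.isna()].iloc[0]
            raise CohortIOError(f"unknown status token {bad!r}")
        df["status"] = norm
        age = pd.to_numeric(df["age"], errors="coerce")
        bad_age = age.isna() & df["age"].notna()
        if bad_age.any():
            row = int(np.argwhere(bad_age.to_numpy())[0][0])
            raise CohortIOError(
                f"non-numeric age {df['age'].iloc[row]!r} in row {row + 1}")
        if (age <= 0).any():
            raise CohortIOError("ages must be positive")
        df["age"] = age
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return self.frame["subject"].tolist()

    @property
    def y(self) -> np.ndarray:
        """1 = case, 0 = control."""
        return (self.frame["status"] == "case").to_numpy(dtype=float)

    def covariate_design(self):
        """Adjustment design matrix: age (continuous) + ethnicity indicators.

        The largest ethnicity stratum is the reference level.  Covariates
        with any missing value are dropped entirely (complete columns only).
        Returns ``(X, names)``; X has shape (n, k) and may have k = 0.
        """
        cols, names = [], []
        age = self.frame["age"]
        if age.notna().all():
            cols.append(age.to_numpy(dtype=float))
            names.append("age")
        eth = self.frame["ethnicity"]
        if eth.notna().all() and eth.nunique() > 1:
            counts = eth.value_counts()
            ref = counts.index[0]
            for level in sorted(x for x in counts.index if x != ref):
                cols.append((eth == level).to_numpy(dtype=float))
                names.append(f"ethnicity[{level}]")
        X = np.column_stack(cols) if cols else np.empty((len(self.frame), 0))
        return X, names

    def align_to(self, gm: GenotypeMatrix) -> "SubjectTable":
        """Reorder rows to match a genotype matrix; error on mismatch."""
        order = {s: i for i, s in enumerate(self.frame["subject"])}
        missing = [s for s in gm.subjects if s not in order]
        if missing:
            raise CohortIOError(f"subjects missing from table: {missing[:3]}")
        idx = [order[s] for s in gm.subjects]
        return SubjectTable(self.frame.iloc[idx].reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the tabular dialect.

    ``format="table"`` auto-detects the wide per-subject form versus the
    count form (cells like ``"107/82"``).  Count tables expand to
    pseudo-subjects named ``case_0001``...; recover their status with
    :func:`read_subjects` on the same file via :func:`count_table_subjects`.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "table":
        return _read_table(path)
    raise CohortIOError(f"unknown genotype format {format!r}")


def _read_vcf(path, multiallelic: str = "error") -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps, columns = [], []
    for var in vcf:
        alts = [a for a in var.ALT if a not in (None, ".")]
        if len(alts) != 1:
            if multiallelic == "error":
                raise CohortIOError(
                    f"non-biallelic record at {var.CHROM}:{var.POS}; "
                    "no split policy configured")
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        col = np.full(len(subjects), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                col[i] = float(sum(1 for a in alleles if a > 0))
        snps.append(vid)
        columns.append(col)
    if not snps:
        raise CohortIOError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(subjects, snps, np.column_stack(columns))


def _sniff_table(text: str) -> str:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise CohortIOError("genotype table has no data rows")
    if "/" in lines[1].split("\t", 2)[-1]:
        return "counts"
    return "wide"


def _read_table(path) -> GenotypeMatrix:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise CohortIOError(f"empty genotype table {path}")
    if _sniff_table(text) == "counts":
        gm, _ = expand_count_table(io.StringIO(text))
        return gm
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    codes = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(codes) & df.notna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortIOError(
            f"unparseable genotype {df.iat[i, j]!r} at line {i + 2}, "
            f"column {df.columns[j]!r}")
    return GenotypeMatrix(list(df.index), list(df.columns), codes)


def expand_count_table(path_or_buf) -> tuple[GenotypeMatrix, SubjectTable]:
    """Expand a per-SNP count table ("107/82" cells) to pseudo-subjects.

    Expected columns: ``snp`` (optionally ``gene``), then ``ww``, ``wv``,
    ``vv`` with ``case/control`` counts.  Expansion is deterministic: cases
    precede controls, and within each status subjects are assigned WW first,
    then WV, then VV in subject order.  SNPs typed on fewer subjects than
    the cohort maximum leave trailing subjects missing.
    """
    df = pd.read_csv(path_or_buf, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("snp", "ww", "wv", "vv"):
        if col not in df.columns:
            raise CohortIOError(f"count table lacks column {col!r}")

    def split(cell, line, col):
        try:
            a, b = str(cell).split("/")
            return int(a), int(b)
        except Exception:
            raise CohortIOError(
                f"bad case/control cell {cell!r} at line {line}, column {col}"
            ) from None

    counts = {}
    for i, row in df.iterrows():
        cc = {g: split(row[g], i + 2, g) for g in ("ww", "wv", "vv")}
        counts[str(row["snp"])] = cc
    n_case = max(sum(v[0] for v in cc.values()) for cc in counts.values())
    n_control = max(sum(v[1] for v in cc.values()) for cc in counts.values())
    width = len(str(max(n_case, n_control)))
    subjects = [f"case_{i + 1:0{width}d}" for i in range(n_case)]
    subjects += [f"control_{i + 1:0{width}d}" for i in range(n_control)]
    codes = np.full((len(subjects), len(counts)), np.nan)
    for j, (_, cc) in enumerate(counts.items()):
        for status, off, _n in (("case", 0, n_case), ("control", n_case, n_control)):
            k = 0 if status == "case" else 1
            pos = off
            for code, g in enumerate(("ww", "wv", "vv")):
                n = cc[g][k]
                codes[pos:pos + n, j] = code
                pos += n
    gm = GenotypeMatrix(subjects, list(counts), codes)
    subj = SubjectTable(pd.DataFrame({
        "subject": subjects,
        "status": ["case"] * n_case + ["control"] * n_control,
    }))
    return gm, subj


def read_subjects(path) -> SubjectTable:
    """Read a subject table (TSV with subject/id, status, age, ethnicity)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortIOError(f"empty subject table {path}") from None
    if df.empty:
        raise CohortIOError(f"subject table {path} has no rows")
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" in df.columns and "subject" not in df.columns:
        df = df.rename(columns={"id": "subject"})
    return SubjectTable(df)


def read_annotation(path) -> pd.DataFrame:
    """Read SNP annotation: snp (rsID), gene, ref/var alleles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("snp", "gene"):
        if col not in df.columns:
            raise CohortIOError(f"annotation lacks column {col!r}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise CohortIOError(f"duplicate annotation for SNP {dup!r}")
    if (df["gene"].isna() | (df["gene"].str.strip() == "")).any():
        raise CohortIOError("empty gene symbol in annotation")
    return df.reset_index(drop=True)


def check_annotation(gm: GenotypeMatrix, annotation: pd.DataFrame) -> None:
    missing = set(gm.snps) - set(annotation["snp"])
    if missing:
        raise CohortIOError(f"SNPs without annotation: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt_code(x: float) -> str:
    return "NA" if np.isnan(x) else str(int(x))


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the wide per-subject dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(gm.snps) + "\n")
        for i, subj in enumerate(gm.subjects):
            fh.write(subj + "\t" +
                     "\t".join(_fmt_code(x) for x in gm.codes[i]) + "\n")


def write_count_table(gm: GenotypeMatrix, subjects: SubjectTable, path,
                      annotation: pd.DataFrame | None = None) -> None:
    """Write the per-SNP count dialect (cells ``n_case/n_control``)."""
    subjects = subjects.align_to(gm)
    case = subjects.y == 1
    gene = {}
    if annotation is not None:
        gene = dict(zip(annotation["snp"], annotation["gene"]))
    with open(path, "w") as fh:
        fh.write("snp\tgene\tww\twv\tvv\n")
        for snp in gm.snps:
            ca = gm.genotype_counts(snp, mask=case)
            co = gm.genotype_counts(snp, mask=~case)
            cells = "\t".join(f"{a}/{b}" for a, b in zip(ca, co))
            fh.write(f"{snp}\t{gene.get(snp, '.')}\t{cells}\n")


def write_results(results, path, sort: bool = True) -> None:
    """Write a stage result table as deterministic TSV.

    Rows are ordered by (gene, snp) when those columns exist, else by a
    ``node`` column, else kept as given; identical inputs produce
    byte-identical files.
    """
    if results is None or len(results) == 0:
        raise CohortIOError("refusing to write an empty result table")
    df = pd.DataFrame(results).copy()
    if sort:
        if {"gene", "snp"} <= set(df.columns):
            df = df.sort_values(["gene", "snp"], kind="mergesort")
        elif "node" in df.columns:
            df = df.sort_values("node", kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              na_rep="NA", lineterminator="\n")
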