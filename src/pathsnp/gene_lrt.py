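"""Gene-level global association via likelihood-ratio tests.

A gene's SNPs enter a single logistic model together (under a dominant or
additive coding); the likelihood-ratio statistic compares that full model
against the covariates-only null, 2*(ll_full - ll_null), referred to a
chi-square with df equal to the number of SNP terms retained.  Exactly
collinear SNP columns (perfectly correlated tags) are pruned greedily
before fitting, and the degrees of freedom shrink to match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .association_models import code_exposure
from .cohort_io import GenotypeMatrix, SubjectTable

__all__ = ["GeneTestResult", "prune_collinear", "gene_global_test",
           "gene_scan"]

_CODING_MAP = {"dominant": "DOM", "additive": "ADD", "DOM": "DOM",
               "ADD": "ADD", "recessive": "REC", "REC": "REC"}


@dataclass
class GeneTestResult:
    gene: str
    coding: str
    n_snps: int
    df: int
    statistic: float
    p: float
    converged: bool = True


def prune_collinear(base: np.ndarray, candidates: np.ndarray,
                    tol: float = 1e-8) -> list[int]:
    """Greedy selection of candidate columns not (near-)dependent on the
    running design.  ``base`` columns are always kept; returns retained
    candidate indices in order."""
    kept: list[int] = []
    work = base.copy()
    for j in range(candidates.shape[1]):
        col = candidates[:, j:j + 1]
        trial = np.hstack([work, col])
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] > tol * s[0]:
            kept.append(j)
            work = trial
    return kept


def gene_global_test(gene_codes: np.ndarray, status: np.ndarray,
                     covariates: np.ndarray | None, coding: str,
                     gene: str = ".", snps: list[str] | None = None,
                     tol: float = 1e-8) -> GeneTestResult:
    """Likelihood-ratio test of all of one gene's SNPs jointly.

    ``gene_codes`` is the (n, k) genotype-code slice for the gene; subjects
    missing any of the gene's genotypes are dropped (complete-case per
    gene).  An empty retained term set yields statistic 0, p = 1.
    """
    model = _CODING_MAP[coding]
    gene_codes = np.asarray(gene_codes, dtype=float)
    if gene_codes.ndim == 1:
        gene_codes = gene_codes[:, None]
    status = np.asarray(status, dtype=float)
    cov = (np.asarray(covariates, dtype=float)
           if covariates is not None and np.size(covariates)
           else np.empty((len(status), 0)))
    ok = ~np.isnan(gene_codes).any(axis=1)
    if cov.size:
        ok &= ~np.isnan(cov).any(axis=1)
    G, y, C = gene_codes[ok], status[ok], cov[ok]
    n_snps = G.shape[1]

    exposures = np.column_stack([code_exposure(G[:, j], model)
                                 for j in range(n_snps)])
    # constant columns carry no term; then prune exact linear dependence
    varying = [j for j in range(n_snps) if np.ptp(exposures[:, j]) > 0]
    base = np.column_stack([np.ones(len(y))] + ([C] if C.size else []))
    kept = [varying[j] for j in
            prune_collinear(base, exposures[:, varying], tol)] if varying else []
    df = len(kept)
    if df == 0:
        return GeneTestResult(gene, model, n_snps, 0, 0.0, 1.0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.Logit(y, base).fit(disp=0, maxiter=200, method="newton",
                                         tol=1e-10)
            full = sm.Logit(y, np.hstack([base, exposures[:, kept]])).fit(
                disp=0, maxiter=200, method="bfgs", gtol=1e-8)
        if not (null.mle_retvals.get("converged", False)
                and full.mle_retvals.get("converged", False)):
            raise RuntimeError("no convergence")
    except Exception:
        return GeneTestResult(gene, model, n_snps, df, np.nan, np.nan,
                              converged=False)
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    return GeneTestResult(gene, model, n_snps, df, float(stat),
                          float(stats.chi2.sf(stat, df)))


def gene_scan(gm: GenotypeMatrix, subjects: SubjectTable,
              annotation: pd.DataFrame, adjust: bool = True,
              codings=("dominant", "additive")) -> pd.DataFrame:
    """Per-gene global tests under each coding, sorted by best P."""
    subjects = subjects.align_to(gm)
    y = subjects.y
    X, _ = subjects.covariate_design() if adjust else (np.empty((len(y), 0)), [])
    ann = annotation[annotation["snp"].isin(gm.snps)]
    rows = []
    for gene, grp in ann.groupby("gene", sort=True):
        snps = [s for s in gm.snps if s in set(grp["snp"])]
        slab = gm.subset(snps)
        row = {"gene": gene, "n_snps": len(snps)}
        for coding in codings:
            res = gene_global_test(slab.codes, y, X, coding, gene=gene,
                                   snps=snps)
            key = _CODING_MAP[coding].lower()
            row[f"p_{key}"] = res.p
            row[f"df_{key}"] = res.df
        rows.append(row)
    df = pd.DataFrame(rows)
    pcols = [c for c in df.columns if c.startswith("p_")]
    df["p_min"] = df[pcols].min(axis=1)
    return df.sort_values(["p_min", "gene"], kind="mergesort").reset_index(drop=True)
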