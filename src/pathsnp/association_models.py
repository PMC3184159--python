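"""Per-SNP logistic association under three genetic models, best-model
selection, and bootstrap internal validation.

Each SNP is tested under dominant (WW vs WV+VV), recessive (WW+WV vs VV),
and additive (variant-allele count 0/1/2) codings by unconditional logistic
regression adjusted for age and ethnicity.  The best-fitting model is the
one with the smallest Wald P; when the homozygous-variant share falls below
a threshold (default 5% of cases or of controls) only the dominant model is
considered, since the recessive and additive contrasts are then underpowered.
Internal validation refits the chosen model on bootstrap resamples and
counts how many of B = 100 resamples reach P < 0.05; SNPs significant in at
least 80 resamples are considered validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort_io import GenotypeMatrix, SubjectTable
from .snp_qc import variant_allele_freq

__all__ = [
    "CODINGS",
    "FitResult",
    "fit_logistic",
    "best_model_select",
    "bootstrap_validate",
    "analyze_snps",
    "validated_subset",
]

# genotype code (variant-allele count) -> model exposure
CODINGS: dict[str, np.ndarray] = {
    "DOM": np.array([0.0, 1.0, 1.0]),
    "REC": np.array([0.0, 0.0, 1.0]),
    "ADD": np.array([0.0, 1.0, 2.0]),
}

MODEL_PRECEDENCE = ("DOM", "REC", "ADD")  # tie-break order on exact P ties

_WALD_Z = 1.96  # 95% Wald interval multiplier


@dataclass
class FitResult:
    or_: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    converged: bool
    reason: str = ""

    @classmethod
    def failure(cls, reason: str) -> "FitResult":
        return cls(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                   False, reason)


def code_exposure(codes: np.ndarray, model: str) -> np.ndarray:
    """Map 0/1/2 genotype codes to the model's exposure (NaN passes through)."""
    table = CODINGS[model]
    out = np.full(len(codes), np.nan)
    ok = ~np.isnan(codes)
    out[ok] = table[codes[ok].astype(int)]
    return out


def fit_logistic(exposure: np.ndarray, status: np.ndarray,
                 covariates: np.ndarray | None = None,
                 maxiter: int = 100) -> FitResult:
    """Maximum-likelihood logistic fit of status on one exposure term.

    Fitting is by iteratively reweighted least squares (Newton scoring).
    Returns the exposure odds ratio with its 95% Wald interval
    ``exp(beta +/- 1.96*SE)`` and Wald P.  Perfect separation or
    non-convergence yields a flagged :class:`FitResult`, not an exception,
    so batch scans survive degenerate SNPs.
    """
    exposure = np.asarray(exposure, dtype=float)
    status = np.asarray(status, dtype=float)
    ok = ~np.isnan(exposure)
    if covariates is not None and covariates.size:
        ok &= ~np.isnan(covariates).any(axis=1)
    x, y = exposure[ok], status[ok]
    if len(np.unique(y)) < 2:
        return FitResult.failure("single status class")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant: model not identifiable")
    cols = [np.ones(len(x)), x]
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, dtype=float)[ok].T)
    X = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, method="newton",
                                     tol=1e-10)
    except Exception as exc:  # separation, singular Hessian, ...
        return FitResult.failure(type(exc).__name__)
    if not res.mle_retvals.get("converged", False):
        return FitResult.failure("no convergence")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 50:
        return FitResult.failure("unstable standard error")
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return FitResult(np.exp(beta), np.exp(beta - _WALD_Z * se),
                     np.exp(beta + _WALD_Z * se), p, beta, se, True)


def best_model_select(counts_case, counts_control, fits: dict[str, FitResult],
                      vv_threshold: float = 0.05,
                      threshold_rule: str = "fraction") -> str | None:
    """Choose the best-fitting genetic model for one SNP.

    The candidate set collapses to {DOM} when the homozygous-variant class
    is rare — below ``vv_threshold`` as a fraction of cases or of controls
    (``threshold_rule="fraction"``), or below an absolute count
    (``threshold_rule="count"``).  Among candidates with converged fits the
    smallest P wins; exact ties break by DOM > REC > ADD.  Returns None when
    every candidate fit failed.
    """
    candidates = list(MODEL_PRECEDENCE)
    for counts in (counts_case, counts_control):
        total = sum(counts)
        if total == 0:
            continue
        rare = (counts[2] < vv_threshold * total if threshold_rule == "fraction"
                else counts[2] < vv_threshold)
        if rare:
            candidates = ["DOM"]
            break
    best, best_p = None, np.inf
    for model in candidates:  # precedence order: first strict winner kept
        fit = fits.get(model)
        if fit is None or not fit.converged or not np.isfinite(fit.p):
            continue
        if fit.p < best_p:
            best, best_p = model, fit.p
    return best


def bootstrap_validate(codes: np.ndarray, status: np.ndarray,
                       covariates: np.ndarray | None, model: str,
                       rng: np.random.Generator, B: int = 100,
                       alpha: float = 0.05, pass_threshold: int = 80,
                       stratified: bool = True,
                       reselect_model: bool = False,
                       counts_case=None, counts_control=None):
    """Bootstrap internal validation of one SNP's chosen model.

    Draws ``B`` resamples of subjects with replacement (stratified within
    case/control by default, preserving the matched design), refits the
    chosen model, and counts resamples with P < ``alpha``.  Resamples that
    fail to fit (single status class, separation) count as non-significant.
    With ``reselect_model`` the best model is re-chosen inside each resample.
    Returns ``(pass_count, pass_flag)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    status = np.asarray(status, dtype=float)
    n = len(status)
    idx_case = np.flatnonzero(status == 1)
    idx_ctrl = np.flatnonzero(status == 0)
    hits = 0
    for _ in range(B):
        if stratified:
            take = np.concatenate([
                rng.choice(idx_case, size=len(idx_case), replace=True),
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True)])
        else:
            take = rng.integers(0, n, size=n)
        c = codes[take]
        y = status[take]
        cov = covariates[take] if covariates is not None and covariates.size else None
        use = model
        if reselect_model:
            fits = {m: _safe_fit(code_exposure(c, m), y, cov)
                    for m in MODEL_PRECEDENCE}
            ca = _class_counts(c[y == 1])
            co = _class_counts(c[y == 0])
            use = best_model_select(ca, co, fits)
            if use is None:
                continue
            fit = fits[use]
        else:
            fit = _safe_fit(code_exposure(c, use), y, cov)
        if fit.converged and np.isfinite(fit.p) and fit.p < alpha:
            hits += 1
    return hits, hits >= pass_threshold


def _safe_fit(exposure, status, covariates) -> FitResult:
    try:
        return fit_logistic(exposure, status, covariates)
    except ValueError:
        return FitResult.failure("constant exposure")


def _class_counts(codes: np.ndarray):
    codes = codes[~np.isnan(codes)]
    return (int((codes == 0).sum()), int((codes == 1).sum()),
            int((codes == 2).sum()))


def analyze_snps(gm: GenotypeMatrix, subjects: SubjectTable,
                 annotation: pd.DataFrame | None = None,
                 adjust: bool = True,
                 vv_threshold: float = 0.05,
                 threshold_rule: str = "fraction",
                 bootstrap_B: int = 100,
                 bootstrap_alpha: float = 0.05,
                 bootstrap_pass: int = 80,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Scan every SNP: three-model fits, best-model choice, bootstrap count.

    Missing genotypes are handled complete-case per SNP.  Returns one row
    per SNP with genotype counts, per-group variant frequencies, the chosen
    model's OR / 95% CI / P, and the bootstrap pass count out of B.
    """
    subjects = subjects.align_to(gm)
    y = subjects.y
    X, _ = subjects.covariate_design() if adjust else (np.empty((len(y), 0)), [])
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    gene = {}
    if annotation is not None:
        gene = dict(zip(annotation["snp"], annotation["gene"]))
    rows = []
    for snp in gm.snps:
        codes = gm.column(snp)
        ca = gm.genotype_counts(snp, mask=y == 1)
        co = gm.genotype_counts(snp, mask=y == 0)
        row = {"snp": snp, "gene": gene.get(snp, "."),
               "ww_case": ca[0], "ww_control": co[0],
               "wv_case": ca[1], "wv_control": co[1],
               "vv_case": ca[2], "vv_control": co[2],
               "maf_case": variant_allele_freq(ca) if sum(ca) else np.nan,
               "maf_control": variant_allele_freq(co) if sum(co) else np.nan}
        fits = {m: _safe_fit(code_exposure(codes, m), y, X)
                for m in CODINGS}
        model = best_model_select(ca, co, fits, vv_threshold, threshold_rule)
        if model is None:
            row.update({"model": "NA", "or": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": np.nan,
                        "bootstrap": 0, "validated": False})
        else:
            fit = fits[model]
            count, flag = bootstrap_validate(
                codes, y, X, model, rng, B=bootstrap_B,
                alpha=bootstrap_alpha, pass_threshold=bootstrap_pass)
            row.update({"model": model, "or": fit.or_, "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high, "p": fit.p,
                        "bootstrap": count, "validated": flag})
        rows.append(row)
    return pd.DataFrame(rows)


def validated_subset(results: pd.DataFrame, pass_threshold: int = 80,
                     alpha: float = 0.05) -> pd.DataFrame:
    """SNPs significant at ``alpha`` and passing the bootstrap threshold."""
    keep = (results["p"] < alpha) & (results["bootstrap"] >= pass_threshold)
    return results.loc[keep].reset_index(drop=True)
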