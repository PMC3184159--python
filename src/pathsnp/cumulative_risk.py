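"""Cumulative unfavorable-genotype risk scoring and dose-response analysis.

For each validated SNP the *unfavorable* genotype group is the risk-raising
side of its best-fitting model: the exposed genotype set when the fitted
OR exceeds 1, and its complement when the OR is below 1 (for additive-model
SNPs, the dominant grouping of the risk-raising allele).  A subject's score
counts how many of their genotypes fall in an unfavorable set; scores are
binned into ordered categories, each category's odds ratio is estimated
against the lowest-score reference category by covariate-adjusted logistic
regression, and a dose-response trend P comes from a logistic fit on the
ordinal category index.  Percentile bootstrap CIs over subject resamples
are available for the category ORs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_models import FitResult, fit_logistic
from .cohort_io import GenotypeMatrix

__all__ = [
    "UnfavorableRule",
    "derive_unfavorable",
    "score_subjects",
    "default_breaks",
    "category_analysis",
]

_EXPOSED = {"DOM": frozenset({1, 2}), "REC": frozenset({2}),
            "ADD": frozenset({1, 2})}
_ALL = frozenset({0, 1, 2})


@dataclass(frozen=True)
class UnfavorableRule:
    snp: str
    codes: frozenset

    def __post_init__(self) -> None:
        if not self.codes or self.codes >= _ALL:
            raise ValueError("unfavorable set must be a non-empty proper "
                             "subset of {0,1,2}")


def derive_unfavorable(results: pd.DataFrame) -> list[UnfavorableRule]:
    """Derive unfavorable-genotype rules from per-SNP association results.

    ``results`` needs columns snp, model, or.  SNPs with OR exactly 1 carry
    no direction and are skipped with a warning.  Protective additive SNPs
    take the dominant grouping of the wild-type (risk-raising) allele,
    i.e. {WW, WV}; published reports sometimes label the variant-carrier
    group as unfavorable even for protective SNPs, so a note is emitted
    whenever the complement rule fires.
    """
    rules = []
    for _, row in results.iterrows():
        or_, model = float(row["or"]), str(row["model"])
        if model not in _EXPOSED or not np.isfinite(or_):
            warnings.warn(f"{row['snp']}: no usable model fit; skipped")
            continue
        if or_ == 1.0:
            warnings.warn(f"{row['snp']}: OR exactly 1, no risk direction; "
                          "skipped")
            continue
        exposed = _EXPOSED[model]
        if or_ > 1.0:
            codes = exposed
        else:
            if model == "ADD":
                codes = frozenset({0, 1})  # carriers of the wild-type allele
            else:
                codes = _ALL - exposed
            warnings.warn(
                f"{row['snp']}: protective under {model} (OR {or_:.2f}); "
                "unfavorable group taken as the complement (risk-raising) "
                "side, which may differ from variant-carrier labels in "
                "published tables")
        rules.append(UnfavorableRule(str(row["snp"]), frozenset(codes)))
    return rules


def score_subjects(rules: list[UnfavorableRule], gm: GenotypeMatrix):
    """Count unfavorable genotypes per subject.

    Missing genotypes contribute 0 to the score; returns ``(scores,
    completeness)`` where completeness is the number of non-missing rule
    SNPs per subject (out of ``len(rules)``).
    """
    if not rules:
        raise ValueError("no unfavorable rules supplied")
    n = gm.n_subjects
    scores = np.zeros(n, dtype=int)
    complete = np.zeros(n, dtype=int)
    for rule in rules:
        col = gm.column(rule.snp)
        ok = ~np.isnan(col)
        complete += ok.astype(int)
        hit = np.zeros(n, dtype=bool)
        hit[ok] = np.isin(col[ok].astype(int), list(rule.codes))
        scores += hit.astype(int)
    return scores, complete


def default_breaks(scores: np.ndarray, n_categories: int = 4) -> list[int]:
    """Quartile-style upper break points over the observed score range."""
    qs = np.quantile(scores, np.linspace(0, 1, n_categories + 1)[1:-1])
    breaks = sorted(set(int(np.floor(q)) for q in qs))
    return [b for b in breaks if scores.min() <= b < scores.max()]


def _categorize(scores: np.ndarray, breaks: list[int]):
    edges = sorted(breaks)
    cat = np.digitize(scores, [e + 0.5 for e in edges])
    labels = []
    lo = int(scores.min())
    for e in edges + [int(scores.max())]:
        labels.append(f"{lo}-{e}" if e > lo else f"{lo}")
        lo = e + 1
    return cat, labels


def category_analysis(scores: np.ndarray, status: np.ndarray,
                      covariates: np.ndarray | None = None,
                      breaks: list[int] | None = None,
                      boot_B: int = 0, alpha_z: float = 1.96,
                      rng: np.random.Generator | None = None):
    """Category odds ratios against the lowest-score category, plus trend P.

    ``breaks`` are inclusive upper edges of all but the last category
    (e.g. ``[4, 7, 10]`` gives 0-4 / 5-7 / 8-10 / 11-max); default breaks
    are quartile-based.  Every category must contain subjects; a category
    with only cases or only controls gets a flagged (NaN) OR.  With
    ``boot_B`` > 0, percentile bootstrap 95% CIs over subject resamples are
    added.  Returns ``(DataFrame, trend_p)``.
    """
    scores = np.asarray(scores)
    status = np.asarray(status, dtype=float)
    if breaks is None:
        breaks = default_breaks(scores)
    cat, labels = _categorize(scores, breaks)
    k = len(labels)
    occupied = [np.sum(cat == i) > 0 for i in range(k)]
    if sum(occupied) < 2:
        raise ValueError("need at least two non-empty score categories")

    fits = _fit_categories(cat, k, status, covariates)
    trend = fit_logistic(cat.astype(float), status, covariates)

    boot = None
    if boot_B > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        boot = _bootstrap_categories(cat, k, status, covariates, boot_B, rng)

    rows = []
    for i in range(k):
        n_case = int(np.sum((cat == i) & (status == 1)))
        n_ctrl = int(np.sum((cat == i) & (status == 0)))
        row = {"category": labels[i], "n_case": n_case, "n_control": n_ctrl}
        if i == 0:
            row.update({"or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan})
        else:
            fit = fits[i]
            row.update({"or": fit.or_, "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high, "p": fit.p})
        if boot is not None:
            lo, hi = boot[i]
            row.update({"boot_ci_low": lo, "boot_ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows), float(trend.p)


def _fit_categories(cat, k, status, covariates) -> dict[int, FitResult]:
    """One joint logistic fit with k-1 category indicators vs reference 0."""
    import statsmodels.api as sm
    from scipy import stats as sps

    cols = [np.ones(len(cat))]
    for i in range(1, k):
        cols.append((cat == i).astype(float))
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, dtype=float).T)
    X = np.column_stack(cols)
    out = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(status, X).fit(disp=0, maxiter=100,
                                          method="newton", tol=1e-10)
        converged = res.mle_retvals.get("converged", False)
    except Exception:
        converged = False
        res = None
    for i in range(1, k):
        if not converged:
            out[i] = FitResult.failure("category fit failed")
            continue
        beta, se = float(res.params[i]), float(res.bse[i])
        if not np.isfinite(se) or se > 50:
            out[i] = FitResult.failure("separated category")
            continue
        p = float(2 * sps.norm.sf(abs(beta / se)))
        out[i] = FitResult(np.exp(beta), np.exp(beta - 1.96 * se),
                           np.exp(beta + 1.96 * se), p, beta, se, True)
    return out


def _bootstrap_categories(cat, k, status, covariates, B, rng):
    n = len(cat)
    idx_case = np.flatnonzero(status == 1)
    idx_ctrl = np.flatnonzero(status == 0)
    draws = {i: [] for i in range(1, k)}
    for _ in range(B):
        take = np.concatenate([
            rng.choice(idx_case, size=len(idx_case), replace=True),
            rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True)])
        cov = (np.asarray(covariates)[take]
               if covariates is not None and np.size(covariates) else None)
        fits = _fit_categories(cat[take], k, status[take], cov)
        for i in range(1, k):
            if fits[i].converged:
                draws[i].append(fits[i].or_)
    out = {0: (np.nan, np.nan)}
    for i in range(1, k):
        vals = np.array(draws[i])
        if len(vals) < max(20, B // 10):
            out[i] = (np.nan, np.nan)
        else:
            out[i] = (float(np.percentile(vals, 2.5)),
                      float(np.percentile(vals, 97.5)))
    return out
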