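"""EM haplotype frequency estimation, pairwise LD, Gabriel-style block
partition, and haplotype-level association.

Phase is unobserved: for a block of k biallelic SNPs the population
haplotype frequencies are estimated by expectation-maximization over each
subject's compatible phase pairs (E-step weights proportional to the
product of current haplotype frequencies; M-step re-estimates frequencies
from expected haplotype counts).  Pairwise LD is summarized by D' and r^2,
with a one-sided 95% CI on |D'| from the normalized likelihood profile over
D' — the construction behind the Gabriel block rules: a pair is in *strong
LD* when the CI is [>=0.70, >=0.98], shows *strong recombination* when the
upper bound is < 0.90, and a run of SNPs is a block when at least 95% of
its informative pairs are strong LD.  Haplotype association uses each
subject's expected haplotype dosage (0-2 copies from the EM posterior) in
a covariate-adjusted logistic model against the most common haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_models import FitResult, fit_logistic
from .cohort_io import GenotypeMatrix

__all__ = [
    "HaplotypeSet",
    "LdPair",
    "GabrielParams",
    "em_haplotype_freqs",
    "ld_stats",
    "ld_pair_from_genotypes",
    "ld_matrix",
    "gabriel_blocks",
    "haplotype_association",
]

MAX_BLOCK_SNPS = 8  # 2^k haplotype space; EM is exact but exponential in k


def hap_label(code: int, k: int) -> str:
    """Allele string for a haplotype bitmask, e.g. ``W_V_W`` (W = wild)."""
    return "_".join("V" if (code >> s) & 1 else "W" for s in range(k))


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype frequencies for one SNP block."""

    snps: list[str]
    hap_codes: np.ndarray        # bitmask per haplotype, ascending
    freqs: np.ndarray            # aligned with hap_codes, sums to 1
    loglik: float
    subject_idx: np.ndarray      # rows of the source matrix used (complete)
    dosages: np.ndarray          # (n_subjects_used, n_haps) expected copies
    n_iter: int = 0
    loglik_history: list = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        k = len(self.snps)
        return [hap_label(c, k) for c in self.hap_codes]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"haplotype": self.labels,
                             "frequency": self.freqs})


def _compatible_pairs(geno: tuple[int, ...]):
    """Unordered phase pairs (h1, h2, multiplicity) compatible with one
    multilocus genotype (codes 0/1/2 per SNP)."""
    base = 0
    hets = []
    for s, g in enumerate(geno):
        if g == 2:
            base |= 1 << s
        elif g == 1:
            hets.append(s)
    if not hets:
        return [(base, base, 1)]
    first, rest = hets[0], hets[1:]
    pairs = []
    for bits in range(1 << len(rest)):
        add = 0
        for t, s in enumerate(rest):
            if (bits >> t) & 1:
                add |= 1 << s
        h1 = base | add
        h2 = base | ((1 << first) | sum(1 << s for s in rest)) ^ add
        pairs.append((h1, h2, 2))
    return pairs


def _em_run(pair_sets, weights, f0, max_iter, tol):
    """EM on grouped genotypes; returns (freqs, loglik, iterations).

    pair_sets: list of (i_idx, j_idx, mult) arrays per unique genotype;
    weights: subject count per unique genotype.  Frequencies live on the
    support index space used by those arrays.
    """
    f = f0.copy()
    n_chrom = 2.0 * weights.sum()
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros_like(f)
        ll = 0.0
        for (ii, jj, mult), w in zip(pair_sets, weights):
            pw = mult * f[ii] * f[jj]
            tot = pw.sum()
            if tot <= 0:
                return f, -np.inf, it, history
            ll += w * np.log(tot)
            share = pw * (w / tot)
            np.add.at(counts, ii, share)
            np.add.at(counts, jj, share)
        history.append(ll)
        f_new = counts / n_chrom
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    return f, history[-1] if history else -np.inf, it, history


def em_haplotype_freqs(gm_or_codes, snps: list[str] | None = None,
                       max_iter: int = 1000, tol: float = 1e-8,
                       restarts: int = 5,
                       seed: int | np.random.Generator = 0) -> HaplotypeSet:
    """Estimate haplotype frequencies for one block by multi-start EM.

    Accepts a :class:`~pathsnp.cohort_io.GenotypeMatrix` plus SNP names, or
    a raw (n, k) code array.  Subjects with any missing genotype in the
    block are excluded.  Starts: a counting-based start (compatible pairs
    weighted uniformly) plus ``restarts`` random Dirichlet starts; the run
    with the best final log-likelihood wins.
    """
    if isinstance(gm_or_codes, GenotypeMatrix):
        if snps is None:
            snps = list(gm_or_codes.snps)
        codes = gm_or_codes.subset(snps).codes
    else:
        codes = np.asarray(gm_or_codes, dtype=float)
        if codes.ndim == 1:
            codes = codes[:, None]
        if snps is None:
            snps = [f"snp{j + 1}" for j in range(codes.shape[1])]
    k = codes.shape[1]
    if k == 0:
        raise ValueError("empty SNP block")
    if k > MAX_BLOCK_SNPS:
        raise ValueError(f"block of {k} SNPs exceeds the EM cap of "
                         f"{MAX_BLOCK_SNPS}")
    complete = ~np.isnan(codes).any(axis=1)
    subject_idx = np.flatnonzero(complete)
    if len(subject_idx) == 0:
        raise ValueError("no subjects with complete block genotypes")
    rows = codes[complete].astype(int)

    uniq, inverse, counts = np.unique(rows, axis=0, return_inverse=True,
                                      return_counts=True)
    raw_pairs = [_compatible_pairs(tuple(g)) for g in uniq]
    support = sorted({h for prs in raw_pairs for p in prs for h in p[:2]})
    pos = {h: i for i, h in enumerate(support)}
    pair_sets = []
    for prs in raw_pairs:
        ii = np.array([pos[a] for a, _b, _m in prs])
        jj = np.array([pos[b] for _a, b, _m in prs])
        mult = np.array([m for _a, _b, m in prs], dtype=float)
        pair_sets.append((ii, jj, mult))
    H = len(support)
    weights = counts.astype(float)

    # counting-based start: each compatible pair contributes equally
    f_count = np.zeros(H)
    for (ii, jj, _m), w in zip(pair_sets, weights):
        share = w / len(ii)
        np.add.at(f_count, ii, share)
        np.add.at(f_count, jj, share)
    f_count /= f_count.sum()

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    starts = [f_count] + [rng.dirichlet(np.ones(H)) for _ in range(restarts)]
    best = None
    for f0 in starts:
        f, ll, it, hist = _em_run(pair_sets, weights, f0, max_iter, tol)
        if best is None or ll > best[1] + 1e-12:
            best = (f, ll, it, hist)
    f, ll, it, hist = best

    # per-subject expected haplotype dosages under the final frequencies
    dos_uniq = np.zeros((len(uniq), H))
    for u, (ii, jj, mult) in enumerate(pair_sets):
        pw = mult * f[ii] * f[jj]
        tot = pw.sum()
        w = pw / tot if tot > 0 else np.full(len(ii), 1.0 / len(ii))
        np.add.at(dos_uniq[u], ii, w)
        np.add.at(dos_uniq[u], jj, w)
    dosages = dos_uniq[inverse]

    return HaplotypeSet(list(snps), np.array(support), f, float(ll),
                        subject_idx, dosages, n_iter=it, loglik_history=hist)


# ---------------------------------------------------------------------------
# pairwise LD and blocks
# ---------------------------------------------------------------------------

@dataclass
class LdPair:
    snp_i: str
    snp_j: str
    d: float
    d_prime: float
    r2: float
    ci_low: float = np.nan
    ci_high: float = np.nan

    @property
    def informative(self) -> bool:
        return np.isfinite(self.d_prime)


def ld_stats(freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from two-SNP haplotype frequencies.

    ``freqs`` is a 2x2 array, ``freqs[a, b]`` = frequency of the haplotype
    carrying allele ``a`` at the first SNP and ``b`` at the second.
    """
    p = np.asarray(freqs, dtype=float)
    if p.shape != (2, 2) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("need a 2x2 haplotype frequency table summing to 1")
    pa, pb = p[1].sum(), p[:, 1].sum()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")
    d = p[1, 1] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(d), float(d_prime), float(r2)


def _pair_loglik_grid(n33: np.ndarray, pa: float, pb: float, sign: int,
                      grid: np.ndarray) -> np.ndarray:
    """Log-likelihood of a 3x3 genotype count table along a |D'| grid."""
    if sign >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        d = grid * dmax
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        d = -grid * dmax
    p11 = np.clip(pa * pb + d, 0.0, 1.0)
    p10 = np.clip(pa * (1 - pb) - d, 0.0, 1.0)
    p01 = np.clip((1 - pa) * pb - d, 0.0, 1.0)
    p00 = np.clip((1 - pa) * (1 - pb) + d, 0.0, 1.0)
    # genotype-combination probabilities under random pairing of haplotypes
    probs = np.empty((len(grid), 3, 3))
    probs[:, 0, 0] = p00 ** 2
    probs[:, 0, 1] = 2 * p00 * p01
    probs[:, 0, 2] = p01 ** 2
    probs[:, 1, 0] = 2 * p00 * p10
    probs[:, 1, 1] = 2 * p11 * p00 + 2 * p10 * p01
    probs[:, 1, 2] = 2 * p01 * p11
    probs[:, 2, 0] = p10 ** 2
    probs[:, 2, 1] = 2 * p10 * p11
    probs[:, 2, 2] = p11 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(n33 > 0, np.log(np.maximum(probs, 1e-300)) * n33, 0.0)
    return lp.sum(axis=(1, 2))


def ld_pair_from_genotypes(col_i: np.ndarray, col_j: np.ndarray,
                           name_i: str = "snp_i", name_j: str = "snp_j",
                           grid_step: float = 0.001) -> LdPair:
    """Pairwise LD with the likelihood-profile CI on |D'|.

    Haplotype frequencies come from a two-SNP EM; the one-sided 95% CI on
    |D'| takes the 5th and 95th percentiles of the normalized likelihood
    profile over a |D'| grid with allele frequencies held at their sample
    estimates.  Monomorphic SNPs yield an uninformative (NaN) pair.
    """
    ok = ~(np.isnan(col_i) | np.isnan(col_j))
    gi, gj = col_i[ok].astype(int), col_j[ok].astype(int)
    pa = gi.mean() / 2.0
    pb = gj.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LdPair(name_i, name_j, np.nan, np.nan, np.nan)
    hs = em_haplotype_freqs(np.column_stack([gi, gj]).astype(float),
                            snps=[name_i, name_j], restarts=2, seed=0)
    table = np.zeros((2, 2))
    for code, freq in zip(hs.hap_codes, hs.freqs):
        table[code & 1, (code >> 1) & 1] = freq
    d, d_prime, r2 = ld_stats(table)

    n33 = np.zeros((3, 3))
    np.add.at(n33, (gi, gj), 1.0)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = _pair_loglik_grid(n33, pa, pb, 1 if d >= 0 else -1, grid)
    like = np.exp(ll - ll.max())
    cum = np.cumsum(like) / like.sum()
    lo = float(grid[np.searchsorted(cum, 0.05)])
    hi = float(grid[np.searchsorted(cum, 0.95)])
    return LdPair(name_i, name_j, d, d_prime, r2, lo, hi)


def ld_matrix(gm: GenotypeMatrix, snps: list[str] | None = None) -> list[LdPair]:
    """All ordered pairwise LD statistics (i < j in SNP order)."""
    snps = list(snps or gm.snps)
    cols = {s: gm.column(s) for s in snps}
    pairs = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            pairs.append(ld_pair_from_genotypes(cols[snps[i]], cols[snps[j]],
                                                snps[i], snps[j]))
    return pairs


def ld_pairs_frame(pairs: list[LdPair]) -> pd.DataFrame:
    return pd.DataFrame([{"snp_i": p.snp_i, "snp_j": p.snp_j, "d": p.d,
                          "d_prime": p.d_prime, "r2": p.r2,
                          "ci_low": p.ci_low, "ci_high": p.ci_high}
                         for p in pairs])


@dataclass(frozen=True)
class GabrielParams:
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    min_strong_fraction: float = 0.95


def gabriel_blocks(gm: GenotypeMatrix, snps: list[str] | None = None,
                   params: GabrielParams = GabrielParams(),
                   pairs: list[LdPair] | None = None) -> list[tuple[int, int]]:
    """Partition ordered SNPs into LD blocks by the D'-CI criteria.

    A pair is strong LD when its |D'| CI lower bound >= ``strong_ci_low``
    and upper bound >= ``strong_ci_high``; strong recombination when the
    upper bound < ``recomb_ci_high``.  An interval is a candidate block
    when at least ``min_strong_fraction`` of its informative pairs are
    strong LD (and it has at least one informative pair); maximal
    non-overlapping candidates are chosen greedily from the longest spans
    (leftmost first on ties).  Returns inclusive index intervals.
    """
    snps = list(snps or gm.snps)
    m = len(snps)
    if m < 2:
        return []
    if pairs is None:
        pairs = ld_matrix(gm, snps)
    idx = {s: i for i, s in enumerate(snps)}
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for p in pairs:
        i, j = idx[p.snp_i], idx[p.snp_j]
        if not np.isfinite(p.ci_high):
            continue
        s = (p.ci_low >= params.strong_ci_low
             and p.ci_high >= params.strong_ci_high)
        r = p.ci_high < params.recomb_ci_high
        strong[i, j] = strong[j, i] = s
        informative[i, j] = informative[j, i] = s or r

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            sub = slice(i, j + 1)
            tri = np.triu_indices(j - i + 1, k=1)
            inf = informative[sub, sub][tri]
            if inf.sum() == 0:
                continue
            if strong[sub, sub][tri].sum() / inf.sum() >= params.min_strong_fraction:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    blocks, taken = [], np.zeros(m, dtype=bool)
    for i, j in candidates:
        if not taken[i:j + 1].any():
            blocks.append((i, j))
            taken[i:j + 1] = True
    return sorted(blocks)


# ---------------------------------------------------------------------------
# haplotype association
# ---------------------------------------------------------------------------

def haplotype_association(hapset: HaplotypeSet, status: np.ndarray,
                          covariates: np.ndarray | None = None,
                          min_freq: float = 0.03) -> pd.DataFrame:
    """Per-haplotype association against the most common haplotype.

    Each subject contributes the expected dosage (0-2 copies) of each
    haplotype; haplotypes rarer than ``min_freq`` pool into ``other``.  For
    every non-reference haplotype a logistic model of status on its dosage
    plus covariates is fitted; the reference (highest pooled frequency,
    lexicographically lowest label on ties) is reported with OR 1.  The
    table also carries expected case/control copy counts and row
    percentages.
    """
    status = np.asarray(status, dtype=float)[hapset.subject_idx]
    cov = None
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)[hapset.subject_idx]
    labels = hapset.labels
    freqs = hapset.freqs
    order = np.argsort([-f for f in freqs], kind="mergesort")
    top = [i for i in order if freqs[i] == freqs[order[0]]]
    if len(top) > 1:
        warnings.warn("reference haplotype frequency tied; lowest "
                      "lexicographic label used")
        ref = min(top, key=lambda i: labels[i])
    else:
        ref = order[0]

    groups: list[tuple[str, np.ndarray, float]] = []
    other_dos = np.zeros(len(status))
    other_freq = 0.0
    for i in np.argsort(labels):
        if i == ref:
            continue
        if freqs[i] < min_freq:
            other_dos += hapset.dosages[:, i]
            other_freq += freqs[i]
            continue
        groups.append((labels[i], hapset.dosages[:, i], freqs[i]))
    rows = [_hap_row("H0:" + labels[ref], hapset.dosages[:, ref],
                     freqs[ref], status, None)]
    for n, (label, dos, fr) in enumerate(
            sorted(groups, key=lambda g: -g[2]), start=1):
        fit = fit_logistic(dos, status, cov) if np.ptp(dos) > 0 \
            else FitResult.failure("constant dosage")
        rows.append(_hap_row(f"H{n}:{label}", dos, fr, status, fit))
    if other_freq > 0:
        fit = fit_logistic(other_dos, status, cov) if np.ptp(other_dos) > 0 \
            else FitResult.failure("constant dosage")
        rows.append(_hap_row("other", other_dos, other_freq, status, fit))
    df = pd.DataFrame(rows)
    total = df["case_copies"] + df["control_copies"]
    df["control_pct"] = 100.0 * df["control_copies"] / total
    df["case_pct"] = 100.0 * df["case_copies"] / total
    return df


def _hap_row(label, dosage, freq, status, fit):
    row = {"haplotype": label, "frequency": freq,
           "control_copies": float(dosage[status == 0].sum()),
           "case_copies": float(dosage[status == 1].sum())}
    if fit is None:
        row.update({"or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                    "p": np.nan})
    else:
        row.update({"or": fit.or_, "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high, "p": fit.p})
    return row
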