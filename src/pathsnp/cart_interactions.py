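"""Recursive-partitioning (CART-style) search for SNP-SNP interaction
strata with terminal-node odds ratios.

At each node every candidate SNP and every admissible genotype bipartition
of its observed codes ({WW} vs {WV,VV}, {WW,WV} vs {VV}, {WW} vs {WV}, ...)
is scored by the Pearson chi-square P of the induced 2x2 case-control
table; the smallest P wins (ties break deterministically by SNP order then
partition order).  Splitting stops on purity, minimum leaf size, maximum
depth, or when no split reaches the alpha threshold — pre-pruning in place
of cost-complexity pruning, since a single grown tree is the reported
object.  A Gini-impurity criterion is available as an alternative.

Terminal nodes are numbered by ascending case fraction; the lowest-risk
leaf is the reference for the per-leaf logistic odds ratios, with an
ordinal trend test across leaves and percentile bootstrap CIs (tree held
fixed, subjects resampled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association_models import FitResult
from .cohort_io import GenotypeMatrix, SubjectTable

__all__ = ["CartParams", "TreeNode", "RiskTree", "grow_tree",
           "node_risk_table"]


@dataclass(frozen=True)
class CartParams:
    min_leaf: int = 20
    max_depth: int = 4
    alpha: float = 0.05
    criterion: str = "chi2"  # or "gini"


@dataclass
class TreeNode:
    index: int
    depth: int
    n_case: int
    n_control: int
    snp: str | None = None           # split SNP (None for a leaf)
    left_codes: frozenset = frozenset()
    split_p: float = np.nan
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.snp is None


@dataclass
class RiskTree:
    root: TreeNode
    snps: list[str]
    params: CartParams

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)
        walk(self.root)
        return out

    def assign(self, gm_or_codes) -> np.ndarray:
        """Leaf node index per subject."""
        codes = (gm_or_codes.subset(self.snps).codes
                 if isinstance(gm_or_codes, GenotypeMatrix)
                 else np.asarray(gm_or_codes, dtype=float))
        pos = {s: i for i, s in enumerate(self.snps)}
        leaf = np.empty(codes.shape[0], dtype=int)
        for i in range(codes.shape[0]):
            node = self.root
            while not node.is_leaf:
                g = codes[i, pos[node.snp]]
                if np.isnan(g):
                    node = (node.left if node.left.n_case + node.left.n_control
                            >= node.right.n_case + node.right.n_control
                            else node.right)
                else:
                    node = node.left if int(g) in node.left_codes else node.right
            leaf[i] = node.index
        return leaf

    def to_text(self) -> str:
        lines = []

        def walk(node, indent, tag):
            size = node.n_case + node.n_control
            if node.is_leaf:
                lines.append(f"{'  ' * indent}{tag}leaf#{node.index} "
                             f"[case {node.n_case} / control {node.n_control}]")
            else:
                grp = "".join("012"[c] for c in sorted(node.left_codes))
                lines.append(f"{'  ' * indent}{tag}{node.snp} in {{{grp}}} "
                             f"(p={node.split_p:.3g}, n={size})")
                walk(node.left, indent + 1, "yes: ")
                walk(node.right, indent + 1, "no:  ")
        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_newick(self) -> str:
        def walk(node):
            if node.is_leaf:
                return f"leaf{node.index}_{node.n_case}c_{node.n_control}n"
            grp = "".join("012"[c] for c in sorted(node.left_codes))
            return (f"({walk(node.left)},{walk(node.right)})"
                    f"{node.snp}_{grp}")
        return walk(self.root) + ";"


def _pearson_p(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square P (df=1, no correction) for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(chi2, 1))


def _bipartitions(observed: list[int]):
    """All unordered bipartitions of the observed codes into two non-empty
    sides; the side containing the smallest code is 'left' (deterministic)."""
    obs = sorted(observed)
    if len(obs) < 2:
        return []
    if len(obs) == 2:
        return [(frozenset({obs[0]}), frozenset({obs[1]}))]
    a, b, c = obs
    return [(frozenset({a}), frozenset({b, c})),
            (frozenset({a, b}), frozenset({c})),
            (frozenset({a, c}), frozenset({b}))]


def _gini_score(a, b, c, d):
    """Negative weighted Gini impurity (larger is better); mapped onto the
    same 'smaller wins' axis as P values by negation of the decrease."""
    n1, n2 = a + b, c + d
    n = n1 + n2

    def gini(case, tot):
        if tot == 0:
            return 0.0
        p = case / tot
        return 2 * p * (1 - p)
    child = (n1 * gini(a, n1) + n2 * gini(c, n2)) / n
    parent = gini(a + c, n)
    return -(parent - child)


def best_split(codes: np.ndarray, status: np.ndarray, idx: np.ndarray,
               params: CartParams):
    """Best admissible split at one node, or None.

    Returns ``(score, snp_col, left_codes, left_idx, right_idx)``; score is
    the chi-square P (or negative Gini decrease).  Subjects with a missing
    genotype at the split SNP are routed with the larger side.
    """
    y = status[idx]
    best = None
    for j in range(codes.shape[1]):
        col = codes[idx, j]
        ok = ~np.isnan(col)
        observed = sorted(set(col[ok].astype(int)))
        for part_no, (left_codes, _right) in enumerate(_bipartitions(observed)):
            go_left = np.zeros(len(idx), dtype=bool)
            go_left[ok] = np.isin(col[ok].astype(int), list(left_codes))
            # missing codes follow the larger non-missing side
            if (~ok).any():
                if go_left[ok].sum() >= (ok.sum() - go_left[ok].sum()):
                    go_left[~ok] = True
            nl, nr = int(go_left.sum()), int(len(idx) - go_left.sum())
            if nl < params.min_leaf or nr < params.min_leaf:
                continue
            a = int(y[go_left].sum())
            c = int(y[~go_left].sum())
            if params.criterion == "gini":
                score = _gini_score(a, nl - a, c, nr - c)
            else:
                score = _pearson_p(a, nl - a, c, nr - c)
            key = (score, j, part_no)
            if best is None or key < best[0]:
                best = (key, j, left_codes, idx[go_left], idx[~go_left])
    if best is None:
        return None
    (score, _j, _pn), j, left_codes, li, ri = best
    return score, j, left_codes, li, ri


def grow_tree(gm_or_codes, status: np.ndarray,
              snps: list[str] | None = None,
              params: CartParams = CartParams()) -> RiskTree:
    """Grow a classification tree over candidate SNPs.

    Deterministic: identical data and parameters give identical trees, and
    subject order does not matter (split scores depend only on counts).
    A root with no admissible split yields a single-leaf tree with a
    warning.
    """
    if isinstance(gm_or_codes, GenotypeMatrix):
        snps = list(snps or gm_or_codes.snps)
        codes = gm_or_codes.subset(snps).codes
    else:
        codes = np.asarray(gm_or_codes, dtype=float)
        snps = list(snps or [f"snp{j + 1}" for j in range(codes.shape[1])])
    if codes.shape[1] < 2:
        raise ValueError("need at least two candidate SNPs")
    status = np.asarray(status, dtype=float)
    counter = {"n": 0}

    def build(idx, depth):
        counter["n"] += 1
        node = TreeNode(counter["n"], depth,
                        int(status[idx].sum()),
                        int(len(idx) - status[idx].sum()))
        n_case, n_ctrl = node.n_case, node.n_control
        if (depth >= params.max_depth or n_case == 0 or n_ctrl == 0
                or len(idx) < 2 * params.min_leaf):
            return node
        found = best_split(codes, status, idx, params)
        if found is None:
            return node
        score, j, left_codes, li, ri = found
        if params.criterion == "chi2" and score >= params.alpha:
            return node
        if params.criterion == "gini" and score >= 0:
            return node
        node.snp = snps[j]
        node.left_codes = left_codes
        node.split_p = score if params.criterion == "chi2" else np.nan
        node.left = build(li, depth + 1)
        node.right = build(ri, depth + 1)
        return node

    root = build(np.arange(codes.shape[0]), 0)
    if root.is_leaf:
        warnings.warn("no admissible split at the root; single-leaf tree")
    return RiskTree(root, snps, params)


def node_risk_table(tree: RiskTree, gm_or_codes, status: np.ndarray,
                    covariates: np.ndarray | None = None,
                    boot_B: int = 0,
                    rng: np.random.Generator | None = None):
    """Per-leaf odds ratios against the lowest-risk leaf, plus trend P.

    Leaves are ordered by ascending case fraction and labelled node 1..k;
    leaf 1 is the reference.  ORs, Wald CIs and P values come from one
    logistic fit of status on leaf indicators plus covariates; the trend P
    from a fit on the ordinal leaf index.  With ``boot_B`` > 0, percentile
    bootstrap 95% CIs resample subjects with the tree held fixed.
    Returns ``(DataFrame, trend_p)``.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("tree has fewer than two leaves")
    assign = tree.assign(gm_or_codes)
    status = np.asarray(status, dtype=float)
    frac = {lf.index: (lf.n_case / (lf.n_case + lf.n_control)) for lf in leaves}
    order = sorted(leaves, key=lambda lf: (frac[lf.index], lf.index))
    rank = {lf.index: r for r, lf in enumerate(order)}  # 0 = reference
    cat = np.array([rank[i] for i in assign])
    k = len(order)

    from .cumulative_risk import _bootstrap_categories, _fit_categories
    from .association_models import fit_logistic

    fits = _fit_categories(cat, k, status, covariates)
    trend = fit_logistic(cat.astype(float), status, covariates)
    boot = None
    if boot_B > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        boot = _bootstrap_categories(cat, k, status, covariates, boot_B, rng)

    rows = []
    for r, lf in enumerate(order):
        n_case = int(np.sum((cat == r) & (status == 1)))
        n_ctrl = int(np.sum((cat == r) & (status == 0)))
        row = {"node": r + 1, "leaf_index": lf.index,
               "n_case": n_case, "n_control": n_ctrl,
               "case_pct": 100.0 * n_case / max(n_case + n_ctrl, 1)}
        fit = fits.get(r) if r > 0 else None
        if r == 0:
            row.update({"or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan})
        elif fit is not None and fit.converged:
            row.update({"or": fit.or_, "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high, "p": fit.p})
        else:
            row.update({"or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan})
        if boot is not None:
            lo, hi = boot[r]
            row.update({"boot_ci_low": lo, "boot_ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows), float(trend.p)
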