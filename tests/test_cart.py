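"""Recursive partitioning: split search, determinism, node risk tables."""

import itertools

import numpy as np
import pytest
from scipy import stats

import pathsnp as ps
from pathsnp.cart_interactions import CartParams, best_split


def brute_force_root_split(codes, y, min_leaf):
    """Independent enumeration of every SNP x bipartition split, scored by
    the Pearson chi-square P of the 2x2 table (no correction)."""
    best = None
    for j in range(codes.shape[1]):
        col = codes[:, j]
        observed = sorted(set(col.astype(int)))
        parts = []
        if len(observed) == 2:
            parts = [frozenset({observed[0]})]
        elif len(observed) == 3:
            a, b, c = observed
            parts = [frozenset({a}), frozenset({a, b}), frozenset({a, c})]
        for pn, left in enumerate(parts):
            mask = np.isin(col.astype(int), list(left))
            nl, nr = mask.sum(), (~mask).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            tab = np.array([[y[mask].sum(), nl - y[mask].sum()],
                            [y[~mask].sum(), nr - y[~mask].sum()]])
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                p = 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
            key = (p, j, pn)
            if best is None or key < best[0]:
                best = (key, j, left)
    return best


class TestGrowTree:
    def test_pure_node_becomes_leaf(self):
        codes = np.column_stack([np.r_[np.zeros(30), np.ones(30)],
                                 np.r_[np.ones(30), np.zeros(30)]])
        y = np.ones(60)  # all cases: nothing to separate
        tree = ps.grow_tree(codes, y, params=CartParams(min_leaf=5))
        assert tree.root.is_leaf

    def test_deterministic_and_order_invariant(self, study_cohort, rng):
        _design, gm, subjects, _truth = study_cohort
        snps = gm.snps[:6]
        t1 = ps.grow_tree(gm, subjects.y, snps=snps)
        t2 = ps.grow_tree(gm, subjects.y, snps=snps)
        assert t1.to_newick() == t2.to_newick()
        perm = rng.permutation(gm.n_subjects)
        gm_perm = ps.GenotypeMatrix([gm.subjects[i] for i in perm], gm.snps,
                                    gm.codes[perm])
        t3 = ps.grow_tree(gm_perm, subjects.y[perm], snps=snps)
        assert t1.to_newick() == t3.to_newick()

    @pytest.mark.parametrize("inst", range(10))
    def test_root_split_matches_exhaustive_oracle(self, inst):
        rng = np.random.default_rng(900 + inst)
        n = int(rng.integers(30, 61))
        m = int(rng.integers(2, 4))
        codes = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.integers(0, 2, size=n).astype(float)
        params = CartParams(min_leaf=5, alpha=1.1)  # alpha>1: always split
        oracle = brute_force_root_split(codes, y, params.min_leaf)
        found = best_split(codes, y, np.arange(n), params)
        if oracle is None:
            assert found is None
        else:
            _, j, left = oracle
            assert found is not None
            assert (found[1], found[2]) == (j, left)

    def test_planted_strong_snp_wins_root(self):
        hits, reps = 0, 30
        design = ps.SimulationDesign(
            n_cases=300, n_controls=300,
            blocks=[ps.single_snp_block("signal", 0.3)]
            + [ps.single_snp_block(f"null{i}", 0.3) for i in range(5)],
            effects=[ps.Effect("signal", "DOM", 3.0)], seed=0)
        for r in range(reps):
            gm, subjects, _ = ps.simulate_cohort(design, seed=7000 + r)
            tree = ps.grow_tree(gm, subjects.y)
            hits += (not tree.root.is_leaf) and tree.root.snp == "signal"
        assert hits >= 0.9 * reps

    def test_no_admissible_split_warns_single_leaf(self):
        codes = np.zeros((50, 2))
        codes[:, 1] = np.r_[np.zeros(25), np.ones(25)]
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.warns(UserWarning, match="single-leaf"):
            tree = ps.grow_tree(codes, y, params=CartParams(min_leaf=30))
        assert tree.root.is_leaf


class TestNodeRiskTable:
    def test_identical_leaves_give_or_one(self):
        half = np.r_[np.zeros(100), np.ones(100)]
        codes = np.column_stack([half, half])
        y = np.tile([1.0, 0.0], 100)  # same case fraction in both halves
        # alpha > 1 forces the (uninformative) split so both leaves exist
        tree = ps.grow_tree(codes, y, params=CartParams(min_leaf=5,
                                                        max_depth=1,
                                                        alpha=1.1))
        assert not tree.root.is_leaf
        table, _ = ps.node_risk_table(tree, codes, y)
        assert table.iloc[1]["or"] == pytest.approx(1.0, abs=1e-9)

    def test_printed_node_counts_reproduce_cross_product(self):
        """Top-vs-reference crude OR from the printed terminal-node counts
        equals the 2x2 cross product (6.36)."""
        t5 = ps.load_table("cart_nodes")
        top = t5.iloc[-1]
        ref = t5.iloc[0]
        expected = (top["case_n"] * ref["control_n"]) / \
            (top["control_n"] * ref["case_n"])
        assert expected == pytest.approx(6.36, abs=0.005)
        # the same arithmetic through the category fit machinery
        cat = np.repeat(np.arange(4),
                        (t5["case_n"] + t5["control_n"]).to_numpy())
        status = np.concatenate([
            np.r_[np.ones(int(c)), np.zeros(int(n))]
            for c, n in zip(t5["case_n"], t5["control_n"])])
        from pathsnp.cumulative_risk import _fit_categories
        fits = _fit_categories(cat, 4, status, None)
        assert fits[3].or_ == pytest.approx(expected, rel=1e-6)

    def test_leaves_ordered_by_case_fraction(self, study_cohort):
        _design, gm, subjects, _truth = study_cohort
        tree = ps.grow_tree(gm, subjects.y, snps=gm.snps[:8])
        if len(tree.leaves()) < 2:
            pytest.skip("tree did not split")
        table, trend_p = ps.node_risk_table(tree, gm, subjects.y)
        fracs = table["case_pct"].to_numpy()
        assert (np.diff(fracs) >= -1e-9).all()
        assert 0 <= trend_p <= 1

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(400, 3)).astype(float)
        y = (rng.random(400) < 0.3 + 0.3 * (codes[:, 0] > 0)).astype(float)
        tree = ps.grow_tree(codes, y, params=CartParams(min_leaf=30,
                                                        max_depth=2))
        if len(tree.leaves()) < 2:
            pytest.skip("tree did not split")
        table, _ = ps.node_risk_table(tree, codes, y, boot_B=200,
                                      rng=np.random.default_rng(6))
        for _, row in table.iloc[1:].iterrows():
            if np.isfinite(row["boot_ci_low"]):
                assert row["boot_ci_low"] <= row["or"] <= row["boot_ci_high"]

    def test_single_leaf_rejected(self):
        codes = np.zeros((50, 2))
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.warns(UserWarning):
            tree = ps.grow_tree(codes, y)
        with pytest.raises(ValueError):
            ps.node_risk_table(tree, codes, y)
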