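"""EM haplotype estimation, LD statistics, block partition, association."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

import pathsnp as ps
from pathsnp.haplotype_em import hap_label


def brute_force_hap_mle(rows, n_starts=8, seed=0):
    """Independent phase-unknown MLE: enumerate every ordered haplotype
    pair, maximize the multinomial likelihood on a softmax-parameterized
    simplex from multiple starts.  Returns (freqs over all 2^k haplotypes
    in bitmask order, loglik)."""
    k = rows.shape[1]
    haps = np.array([[(h >> s) & 1 for s in range(k)] for h in range(2 ** k)])
    geno_of_pair = haps[:, None, :] + haps[None, :, :]
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    masks = [(geno_of_pair == g).all(axis=2) for g in uniq]

    def negll(theta):
        w = np.exp(theta - theta.max())
        f = w / w.sum()
        P = np.outer(f, f)
        ll = 0.0
        for m, c in zip(masks, counts):
            pg = P[m].sum()
            if pg <= 0:
                return 1e9
            ll += c * np.log(pg)
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.zeros(2 ** k) if s == 0 else rng.normal(0, 1, 2 ** k)
        r = minimize(negll, x0, method="L-BFGS-B")
        if best is None or r.fun < best.fun:
            best = r
    w = np.exp(best.x - best.x.max())
    return w / w.sum(), -best.fun


def _em_freq_vector(hapset, k):
    out = np.zeros(2 ** k)
    for code, f in zip(hapset.hap_codes, hapset.freqs):
        out[code] = f
    return out


class TestEmHaplotypeFreqs:
    def test_double_het_symmetric_fixed_point(self):
        # the counting start is the symmetric saddle; with no restarts the
        # EM stays there: all four haplotypes at 0.25
        hs = ps.em_haplotype_freqs(np.array([[1.0, 1.0]]), restarts=0)
        np.testing.assert_allclose(np.sort(hs.freqs), [0.25] * 4, atol=1e-9)

    def test_unambiguous_subjects_reduce_to_counting(self, rng):
        # at most one heterozygous site per subject: phase is known
        rows = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2], [0, 0]],
                        dtype=float)
        hs = ps.em_haplotype_freqs(rows, restarts=3, seed=1)
        counts = np.zeros(4)
        for g1, g2 in rows.astype(int):
            for copy in range(2):
                a1 = 1 if g1 == 2 or (g1 == 1 and copy == 0) else 0
                a2 = 1 if g2 == 2 or (g2 == 1 and copy == 0) else 0
                counts[a1 + 2 * a2] += 1
        np.testing.assert_allclose(_em_freq_vector(hs, 2), counts / 12,
                                   atol=1e-7)

    @pytest.mark.parametrize("inst", range(6))
    def test_em_matches_brute_force_mle(self, inst):
        rng = np.random.default_rng(500 + inst)
        rows = rng.integers(0, 3, size=(12, 3))
        f_oracle, _ll = brute_force_hap_mle(rows, seed=inst)
        hs = ps.em_haplotype_freqs(rows.astype(float), restarts=16, seed=inst)
        assert np.abs(_em_freq_vector(hs, 3) - f_oracle).max() < 1e-4

    def test_loglik_monotone_and_freqs_normalized(self, study_cohort):
        _design, gm, _subjects, _truth = study_cohort
        hs = ps.em_haplotype_freqs(gm, ["hap1_1", "hap1_2", "hap1_3"],
                                   restarts=3, seed=2)
        diffs = np.diff(hs.loglik_history)
        assert (diffs >= -1e-9).all()
        assert abs(hs.freqs.sum() - 1.0) < 1e-9
        assert (hs.freqs >= 0).all()

    def test_block_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            ps.em_haplotype_freqs(np.zeros((4, 9)))

    def test_empty_block_errors(self):
        with pytest.raises(ValueError):
            ps.em_haplotype_freqs(np.full((3, 2), np.nan))


class TestLdStats:
    def test_complete_ld(self):
        d, dp, r2 = ps.ld_stats(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independence(self):
        p = np.outer([0.7, 0.3], [0.6, 0.4])
        d, dp, r2 = ps.ld_stats(p)
        assert dp == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_intermediate_case(self):
        # p(ww)=0.4, p(wv)=0.1, p(vw)=0.1, p(vv)=0.4
        d, dp, r2 = ps.ld_stats(np.array([[0.4, 0.1], [0.1, 0.4]]))
        assert d == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)
        assert dp == pytest.approx(0.6)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ps.ld_stats(np.array([[0.6, 0.4], [0.0, 0.0]]))


class TestGabrielBlocks:
    def test_single_snp_no_blocks(self, ld_cohort):
        _design, gm, _subjects = ld_cohort
        assert ps.gabriel_blocks(gm, snps=gm.snps[:1]) == []

    def test_recovers_planted_five_blocks(self, ld_cohort):
        design, gm, _subjects = ld_cohort
        blocks = ps.gabriel_blocks(gm)
        sizes = [len(b.snps) for b in design.blocks]
        expected, start = [], 0
        for k in sizes:
            expected.append((start, start + k - 1))
            start += k
        assert blocks == expected

    def test_unlinked_snps_give_no_blocks(self):
        design = ps.SimulationDesign(
            n_cases=300, n_controls=300,
            blocks=[ps.single_snp_block(f"s{i}", 0.4) for i in range(5)],
            seed=23)
        gm, _subjects, _ = ps.simulate_cohort(design)
        assert ps.gabriel_blocks(gm) == []


class TestHaplotypeAssociation:
    def test_phased_data_gives_integer_dosages_and_count_or(self, ld_cohort):
        _design, gm, subjects = ld_cohort
        hs = ps.em_haplotype_freqs(gm, ["blk1_1", "blk1_2"], restarts=3,
                                   seed=3)
        # ladder haplotypes leave no phase ambiguity with positive frequency
        assert np.abs(hs.dosages - np.round(hs.dosages)).max() < 1e-6
        table = ps.haplotype_association(hs, subjects.y)
        ref = table.iloc[0]
        assert ref["or"] == 1.0
        row = table.iloc[1]
        y = subjects.y[hs.subject_idx]
        dos = np.round(hs.dosages[:, [l == row["haplotype"].split(":")[1]
                                      for l in hs.labels]].ravel())
        fit = ps.fit_logistic(dos, y)
        assert row["or"] == pytest.approx(fit.or_, rel=1e-6)

    def test_row_percentages_sum_to_100(self, ld_cohort):
        _design, gm, subjects = ld_cohort
        hs = ps.em_haplotype_freqs(gm, ["blk2_1", "blk2_2"], restarts=2,
                                   seed=4)
        table = ps.haplotype_association(hs, subjects.y)
        np.testing.assert_allclose(table["control_pct"] + table["case_pct"],
                                   100.0)

    def test_reference_tie_warns_and_uses_lexicographic(self):
        rows = np.array([[1.0, 1.0]] * 40)  # perfectly symmetric block
        hs = ps.em_haplotype_freqs(rows, restarts=0)
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.warns(UserWarning, match="tied"):
            table = ps.haplotype_association(hs, y)
        assert table.iloc[0]["haplotype"].endswith(sorted(hs.labels)[0])
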