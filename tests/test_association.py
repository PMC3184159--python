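"""Logistic association engine: codings, model selection, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathsnp as ps
from pathsnp.association_models import (FitResult, code_exposure,
                                        bootstrap_validate)


def _two_by_two(exposed_case, unexposed_case, exposed_ctrl, unexposed_ctrl):
    exposure = np.r_[np.ones(exposed_case), np.zeros(unexposed_case),
                     np.ones(exposed_ctrl), np.zeros(unexposed_ctrl)]
    y = np.r_[np.ones(exposed_case + unexposed_case),
              np.zeros(exposed_ctrl + unexposed_ctrl)]
    return exposure, y


class TestFitLogistic:
    def test_printed_dominant_table_matches_cross_product(self):
        # dominant 2x2 from the printed genotype classes of rs7588807
        exposure, y = _two_by_two(310, 107, 335, 82)
        fit = ps.fit_logistic(exposure, y)
        assert fit.or_ == pytest.approx((310 * 82) / (335 * 107), rel=1e-6)
        assert fit.or_ == pytest.approx(0.709, abs=5e-4)

    @given(st.tuples(*[st.integers(5, 400)] * 4))
    @settings(max_examples=30)
    def test_cross_product_oracle(self, cells):
        a, b, c, d = cells
        exposure, y = _two_by_two(a, b, c, d)
        fit = ps.fit_logistic(exposure, y)
        assert fit.or_ == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_constant_exposure_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ps.fit_logistic(np.ones(40), np.r_[np.ones(20), np.zeros(20)])

    def test_single_status_class_flagged(self):
        fit = ps.fit_logistic(np.r_[np.zeros(10), np.ones(10)], np.ones(20))
        assert not fit.converged

    def test_simulation_recovery_dominant_or2(self):
        design = ps.SimulationDesign(
            n_cases=1000, n_controls=1000,
            blocks=[ps.single_snp_block("snp", 0.3)],
            effects=[ps.Effect("snp", "DOM", 2.0)], seed=21)
        gm, subjects, _ = ps.simulate_cohort(design)
        fit = ps.fit_logistic(code_exposure(gm.column("snp"), "DOM"),
                              subjects.y)
        assert abs(fit.beta - np.log(2.0)) < 3 * fit.se

    def test_ci_brackets_or(self):
        exposure, y = _two_by_two(80, 40, 60, 70)
        fit = ps.fit_logistic(exposure, y)
        assert fit.ci_low <= fit.or_ <= fit.ci_high


class TestBestModelSelect:
    def _fits(self, p_dom, p_rec, p_add):
        return {m: FitResult(1.5, 1.1, 2.0, p, np.log(1.5), 0.1, True)
                for m, p in zip(("DOM", "REC", "ADD"), (p_dom, p_rec, p_add))}

    def test_rare_homozygous_variant_forces_dominant(self):
        # VV in 4/417 cases and 5/417 controls: below the 5% threshold
        fits = self._fits(0.02, 0.001, 0.01)
        assert ps.best_model_select((313, 100, 4), (343, 69, 5), fits) == "DOM"

    def test_common_homozygous_variant_opens_all_models(self):
        # VV classes 83/417 and 72/417: all three models compete
        fits = self._fits(0.02, 0.001, 0.01)
        assert ps.best_model_select((131, 203, 83), (171, 174, 72),
                                    fits) == "REC"

    def test_exact_tie_breaks_by_precedence(self):
        fits = self._fits(0.01, 0.01, 0.01)
        assert ps.best_model_select((100, 200, 100), (100, 200, 100),
                                    fits) == "DOM"

    def test_count_rule_switch(self):
        fits = self._fits(0.5, 0.001, 0.2)
        chosen = ps.best_model_select((300, 100, 17), (300, 100, 17), fits,
                                      vv_threshold=5, threshold_rule="count")
        assert chosen == "REC"  # 17 VV >= 5, so the recessive fit competes

    def test_all_failed_returns_none(self):
        fits = {m: FitResult.failure("x") for m in ("DOM", "REC", "ADD")}
        assert ps.best_model_select((10, 10, 10), (10, 10, 10), fits) is None


class TestBootstrapValidate:
    def test_zero_resamples_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_validate(np.zeros(10), np.r_[np.ones(5), np.zeros(5)],
                               None, "DOM", rng, B=0)

    def test_planted_effect_usually_passes(self, rng):
        design = ps.SimulationDesign(
            n_cases=417, n_controls=417,
            blocks=[ps.single_snp_block("snp", 0.09)],
            effects=[ps.Effect("snp", "DOM", 1.6)], seed=3)
        passes = 0
        for r in range(10):
            gm, subjects, _ = ps.simulate_cohort(design, seed=100 + r)
            count, flag = bootstrap_validate(gm.column("snp"), subjects.y,
                                             None, "DOM", rng, B=100)
            passes += flag
        assert passes >= 5  # strong planted effect validates most of the time

    def test_null_snp_rarely_passes(self, rng):
        design = ps.SimulationDesign(
            n_cases=300, n_controls=300,
            blocks=[ps.single_snp_block("snp", 0.3)], effects=[], seed=4)
        passes = 0
        for r in range(20):
            gm, subjects, _ = ps.simulate_cohort(design, seed=200 + r)
            _count, flag = bootstrap_validate(gm.column("snp"), subjects.y,
                                              None, "DOM", rng, B=50,
                                              pass_threshold=40)
            passes += flag
        assert passes <= 2


class TestScanAndFilter:
    def test_validated_filter_reproduces_published_set(self, table1):
        validated = table1[table1["bootstrap"] >= 80]
        assert len(validated) == 13
        assert validated["gene"].nunique() == 8

    def test_analyze_snps_schema(self, study_cohort):
        design, gm, subjects, _truth = study_cohort
        small = gm.subset(gm.snps[:3])
        res = ps.analyze_snps(small, subjects, design.annotation(),
                              bootstrap_B=10, bootstrap_pass=8, seed=0)
        assert list(res["snp"]) == small.snps
        assert res["model"].isin(["DOM", "REC", "ADD", "NA"]).all()
        assert ((res["ci_low"] <= res["or"]) & (res["or"] <= res["ci_high"])).all()
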