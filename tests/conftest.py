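import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathsnp as ps

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_cohort():
    """One simulated study-like cohort shared across read-only tests."""
    design = ps.default_design(seed=11)
    gm, subjects, truth = ps.simulate_cohort(design)
    return design, gm, subjects, truth


@pytest.fixture(scope="session")
def ld_cohort():
    """Null cohort whose 29 SNPs form five strong-LD blocks."""
    design = ps.ld_panel_design(seed=7)
    gm, subjects, _ = ps.simulate_cohort(design)
    return design, gm, subjects


@pytest.fixture(scope="session")
def table1():
    return ps.load_table("snp_associations")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
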