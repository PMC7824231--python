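import numpy as np
import pandas as pd
import pytest

import deltamethyl as dm


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with injected per-CpG and global effects."""
    cfg = dm.SimConfig(
        n_subjects=80,
        n_cpgs=400,
        n_effect_cpgs_per_mode=20,
        effect_size_m=1.2,
        global_shift_eff=-0.05,
        noise_sd_m=0.4,
        seed=11,
    )
    return cfg, *dm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_delta(small_cohort):
    _, mb, m10, sheet, _ = small_cohort
    return dm.delta_pipeline(mb, m10, sheet)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sheet(n, seed=0):
    """Sample sheet with covariates but no methylation, for design tests."""
    cfg = dm.SimConfig(n_subjects=n, n_cpgs=4, n_effect_cpgs_per_mode=0, seed=seed)
    _, _, sheet, _ = dm.simulate_cohort(cfg)
    return sheet
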