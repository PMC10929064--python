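import warnings

import pytest

import morphonorm as mn

FIVE_MEASURES = [
    "lh_bankssts_thickness",
    "rh_precentral_thickness",
    "lh_superiorfrontal_area",
    "Left-Thalamus",
    "Right-Hippocampus",
]


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure multisite cohort, 5 measures, 400 subjects/sex."""
    cfg = mn.SyntheticConfig(n_per_sex=400, measures=FIVE_MEASURES, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = mn.generate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Single-site cohort without outliers or coupling: residuals are pure
    heteroscedastic noise around the generative trajectory."""
    cfg = mn.SyntheticConfig(
        n_per_sex=600,
        measures=FIVE_MEASURES,
        site_count=1,
        site_offset_sd=0.0,
        site_scale_sd=0.0,
        global_coupling=0.0,
        outlier_rate=0.0,
        seed=19,
    )
    table, truth = mn.generate_cohort(cfg)
    return table, truth
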