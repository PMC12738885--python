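import warnings

import pytest

from degbrin import RegionalDGE, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-region cohort with planted effects, shared across read-only tests."""
    config = SyntheticConfig(
        n_genes=500,
        n_regions=3,
        subjects_per_group={"CON": 20, "MCI": 20, "AD": 20},
        deg_per_region=30,
        seed=7,
    )
    expr, samples, truth = generate_cohort(config)
    return config, expr, samples, truth


@pytest.fixture(scope="session")
def small_cohort_degs(small_cohort):
    _config, expr, samples, _truth = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RegionalDGE(expr, samples).fit()


@pytest.fixture(scope="session")
def planted_cohort():
    """Full 19-region cohort at the ablation study conditions (30 per group)."""
    config = SyntheticConfig(
        subjects_per_group={"CON": 30, "MCI": 30, "AD": 30}, seed=0
    )
    expr, samples, truth = generate_cohort(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = RegionalDGE(expr, samples).fit()
    return expr, samples, truth, results.region_sets
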