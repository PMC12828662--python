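import numpy as np
import pytest

import strokeconn as sc


@pytest.fixture(scope="session")
def seven():
    return sc.build_scheme("seven")


@pytest.fixture(scope="session")
def seventeen():
    return sc.build_scheme("seventeen")


@pytest.fixture(scope="session")
def null_cohort(seven):
    """Small two-group cohort with no planted effects."""
    return sc.generate_cohort(seven, n_stroke=12, n_control=12, T=100, seed=11)


@pytest.fixture(scope="session")
def effect_cohort(seven):
    """Cohort with the planted stroke direction pattern at |dr| = 0.25."""
    return sc.generate_cohort(
        seven, n_stroke=30, n_control=30, T=200,
        effect=sc.figure_pattern_effect(0.25), seed=21,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
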