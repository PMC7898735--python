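import numpy as np
import pytest

from enorms.cohort import StratumSpec, simulate_mixed_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_series(rng):
    """The canonical validation input: 1,000 draws from N(20, 1.5)."""
    return rng.normal(20, 1.5, 1000)


@pytest.fixture
def toy_cohort():
    """12 hand-placed records spanning all 8 (sex, age-bin) strata."""
    specs = [
        StratumSpec(sex=sex, age_low=lo, age_high=hi, n=n,
                    healthy_mean=25.0, healthy_sd=2.0, contamination_fraction=0.0)
        for (sex, lo, hi, n) in [
            ("male", 17, 49, 2), ("male", 50, 69, 2),
            ("male", 70, 79, 1), ("male", 80, 98, 1),
            ("female", 17, 49, 2), ("female", 50, 69, 2),
            ("female", 70, 79, 1), ("female", 80, 98, 1),
        ]
    ]
    return simulate_mixed_cohort(specs, seed=7)
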