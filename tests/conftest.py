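import numpy as np
import pytest

from dfcstates import build_windowed_fc, example_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 2-group cohort with 4 planted states, windowed at 30 s."""
    spec = example_cohort_spec(
        n_per_group=(8, 8),
        group_labels=("A", "B"),
        self_stay=(0.995, 0.98),
        stationary=(0.3, 0.25, 0.25, 0.2),
        n_regions=12,
        n_timepoints=150,
        seed=7,
    )
    subjects, truth = generate_cohort(spec)
    windowed = [build_windowed_fc(s, window_seconds=30) for s in subjects]
    return subjects, windowed, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
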