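import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def time_design():
    from bisectlab import build_design

    return build_design("time")


@pytest.fixture
def standard_observer():
    from bisectlab import ObserverParams

    return ObserverParams(alpha=633.0, beta=0.012)


@pytest.fixture
def design_counts(time_design):
    """Per-level test-phase trial counts for one full session (3 blocks)."""
    d = time_design
    anchors = d.anchor_reps_per_block * d.n_blocks
    middles = d.middle_reps_per_block * d.n_blocks
    return np.array([anchors, middles, middles, middles, middles, anchors], dtype=float)


@pytest.fixture
def expected_summary(time_design, standard_observer, design_counts):
    """Expected-proportion (fractional-count) data exactly on the true PF."""
    from bisectlab import ResponseSummary, psi_logistic

    levels = np.array(time_design.levels)
    p = psi_logistic(levels, standard_observer.alpha, standard_observer.beta)
    return ResponseSummary(levels, design_counts, design_counts * p)
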