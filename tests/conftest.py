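import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from infradian import Cohort, CycleSeries, SimulationParams, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: iid-noise study conditions: no oscillation, no persistence, no jumps.
NULL_PARAMS = SimulationParams(
    mu=29.3, sigma=2.0, osc_amplitude=0.0, ar1=0.0, jump_prob=0.0, n_cycles=20
)


@pytest.fixture
def small_cohort() -> Cohort:
    """Three hand-written women with known lengths and dates."""
    return Cohort(
        series=(
            CycleSeries("A", dt.date(2000, 1, 1), (28, 30, 26, 28)),
            CycleSeries("B", dt.date(2001, 6, 15), (29, 29, 29)),
            CycleSeries("C", dt.date(1999, 12, 31), (31, 25, 30, 27, 28)),
        ),
        label="hand-made",
    )


@pytest.fixture
def null_cohort() -> Cohort:
    """100 women x 20 iid cycles — the exchangeable null."""
    return generate_cohort(100, NULL_PARAMS, seed=42)
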