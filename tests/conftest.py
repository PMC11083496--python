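import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uromir

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: one shared seed for all deterministic fixtures
SEED = 7


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down planted cohort: fast enough to preprocess in seconds."""
    return uromir.SimulationConfig(n_features=300, seed=SEED)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return uromir.generate_cohort_signals(small_cfg)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    signals, meta, truth = small_cohort
    expr, log = uromir.preprocess(signals)
    return expr, log, meta, truth


@pytest.fixture(scope="session")
def null_expr():
    """No planted effects: every feature is null by construction."""
    cfg = uromir.SimulationConfig(
        n_features=800, n_planted_up=0, n_planted_down=0, frac_undetectable=0.1,
        seed=SEED,
    )
    signals, meta, _ = uromir.generate_cohort_signals(cfg)
    expr, _ = uromir.preprocess(signals)
    return expr, meta
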