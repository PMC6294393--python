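import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from antforage import ColonyConfig, FNParams, StimulusParams, run_closed_loop

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fn_defaults() -> FNParams:
    return FNParams()


@pytest.fixture(scope="session")
def stim_defaults() -> StimulusParams:
    return StimulusParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20180815)


@pytest.fixture(scope="session")
def short_colony_record():
    """A 30-minute closed-loop run at moderate volatility, shared by tests
    that only need *a* valid record (serialization, bookkeeping checks)."""
    cfg = ColonyConfig(c_u=3.0, c_i=2.0, N=200, D=3.0, duration=1800.0, seed=42)
    return run_closed_loop(cfg)
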