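import numpy as np
import pytest

from stbrproc.process_data import PassageRecord
from stbrproc.simulator import SimulationParams, simulate_passage


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def default_passage(default_params):
    """One noiseless passage at generator defaults (4 d, perfusion from d1)."""
    return simulate_passage(default_params)


@pytest.fixture(scope="session")
def default_record(default_params, default_passage) -> PassageRecord:
    return PassageRecord(
        label="p1",
        volume=default_params.volume,
        inoc_density=default_params.inoc_density,
        duration=default_params.duration,
        samples=default_passage.samples,
        schedule=default_params.resolved_schedule(),
    )


@pytest.fixture(scope="session")
def batch_params() -> SimulationParams:
    """Pure batch exponential growth: no lag, no decline, no perfusion.

    Metabolite pools are scaled so glucose never starves over 4 days.
    """
    from stbrproc.process_data import PerfusionSchedule

    return SimulationParams(
        mu_max=1.0, mu_min=1.0, t_growth_start=0.0, t_decline_start=10.0,
        glc_init=400.0, schedule=PerfusionSchedule.empty())


@pytest.fixture(scope="session")
def batch_passage(batch_params):
    return simulate_passage(batch_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
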