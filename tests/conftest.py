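import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chorus_effort import (
    DetectionRecord,
    SimulationConfig,
    default_community,
    simulate_detections,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_records() -> list[DetectionRecord]:
    """Two plots, two days, a handful of species across both phases."""
    return [
        DetectionRecord("P01", 1, -60, "ERIRUB"),
        DetectionRecord("P01", 1, -30, "TURMER"),
        DetectionRecord("P01", 1, 180, "FRICOE"),
        DetectionRecord("P01", 2, -60, "ERIRUB"),
        DetectionRecord("P02", 1, -60, "ERIRUB"),
        DetectionRecord("P02", 1, 195, "PERATE"),
        DetectionRecord("P02", 2, 237, "FRICOE"),
    ]


@pytest.fixture(scope="session")
def sim_community():
    return default_community(50, seed=11)


@pytest.fixture(scope="session")
def sim_dataset(sim_community):
    """Default-design simulation: 17 plots x 4 days, full base grid."""
    config = SimulationConfig(n_plots=17, n_days=4, seed=11)
    records, truth = simulate_detections(sim_community, config)
    return records, truth, config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
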