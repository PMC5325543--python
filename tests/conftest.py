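import numpy as np
import pytest

from phototrace.geometry import ChamberGeometry
from phototrace.protocol import Schedule, dark
from phototrace.scenario import AdaptationScenario, SCENARIOS
from phototrace.simulate import SimulationConfig, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return ChamberGeometry()


def pure_scenario(type_index: int) -> AdaptationScenario:
    """A stationary scenario where every cell has one photophobic type."""
    p = [0.0] * 4
    p[type_index] = 1.0
    return AdaptationScenario(name=f"pure_{type_index}", p0=tuple(p), p_inf=tuple(p))


def dark_config(n_cells=10, seed=0, duration=60.0, **kw) -> SimulationConfig:
    kw.setdefault("scenario", SCENARIOS["standard"])
    return SimulationConfig(schedule=Schedule(((dark(duration), 1),)),
                            n_cells=n_cells, seed=seed, **kw)
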