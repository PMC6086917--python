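import numpy as np
import pytest

from flywind import geometry as geo
from flywind.grid import build_grid, uniform_grid


@pytest.fixture(scope="session")
def planform():
    return geo.default_planform()


@pytest.fixture(scope="session")
def clipped_planform(planform):
    return geo.clip_trailing_edge(planform, geo.default_clip_curve(planform))


@pytest.fixture(scope="session")
def fly(planform):
    return geo.make_fly_geometry(planform, resolution=16)


@pytest.fixture
def small_windtunnel_grid():
    return build_grid(
        domain=((-2.0, 4.0), (-2.0, 2.0)),
        box=((-1.0, 1.0), (-1.0, 1.0)),
        delta=0.1,
        stretch_ratio=1.15,
    )


@pytest.fixture
def periodic_grid_64():
    return uniform_grid(((0, 2 * np.pi), (0, 2 * np.pi)), (64, 64), periodic=True)


# -- expensive shared runs (session scope: ~5 minutes total) ----------------

SWEEP_KS = (0.33, 0.65, 1.30)
DESK_DELTA = 0.035
DESK_CYCLES = 3


@pytest.fixture(scope="session")
def desk_sweep():
    """Three-run reduced-frequency sweep at the desk trend resolution."""
    from flywind.experiments import DeskCase, frequency_sweep

    base = DeskCase(cycles=DESK_CYCLES, delta=DESK_DELTA)
    result = frequency_sweep(base, SWEEP_KS)
    assert not result.failures, result.failures
    return result


@pytest.fixture(scope="session")
def desk_clipped_065():
    """Clipped-wing partner of the sweep's k=0.65 row (matched settings)."""
    from flywind.experiments import DeskCase, run_desk_case

    return run_desk_case(
        DeskCase(k=0.65, cycles=DESK_CYCLES, delta=DESK_DELTA, clipped=True)
    )


def taylor_green_init(sim):
    sim.initialize(
        [
            lambda x, y: np.cos(x) * np.sin(y),
            lambda x, y: -np.sin(x) * np.cos(y),
        ],
        pressure_func=lambda x, y: -0.25 * (np.cos(2 * x) + np.cos(2 * y)),
    )


@pytest.fixture
def tg_init():
    return taylor_green_init
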