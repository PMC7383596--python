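import pytest

from phasegrid import grid_model as gm
from phasegrid import signals as sg


@pytest.fixture(scope="session")
def traj1d():
    return sg.gen_trajectory_1d(120.0, seed=101)


@pytest.fixture(scope="session")
def traj2d():
    return sg.gen_trajectory_2d(300.0, box_cm=100.0, seed=102)


@pytest.fixture(scope="session")
def phase8(traj2d):
    """Constant 8 Hz baseline covering the 2D session."""
    lfp = sg.gen_broadband_lfp(traj2d.duration + 1.1, 512.0, 8.0, 8.0)
    return sg.preprocess_lfp(lfp)


@pytest.fixture(scope="session")
def phase_bb(traj2d):
    """Arrhythmic broadband 2-20 Hz baseline covering the 2D session."""
    lfp = sg.gen_broadband_lfp(traj2d.duration + 1.1, 512.0, 2.0, 20.0, seed=103)
    return sg.preprocess_lfp(lfp)


@pytest.fixture(scope="session")
def cells40(traj2d):
    """40-cell population (8 per module) on the 2D session."""
    cfg = gm.PopulationConfig(n_cells=40, n_modules=5)
    return gm.build_population(cfg, traj2d, seed=104)


@pytest.fixture(scope="session")
def trains40(traj2d, phase_bb, cells40):
    """Precession-mode spike trains for the 40-cell population."""
    return gm.simulate_population(traj2d, phase_bb, cells40, seed=105)


@pytest.fixture(scope="session")
def cells40_locking(traj2d):
    cfg = gm.PopulationConfig(n_cells=40, n_modules=5, phase_mode="locking")
    return gm.build_population(cfg, traj2d, seed=104)


@pytest.fixture(scope="session")
def trains40_locking(traj2d, phase_bb, cells40_locking):
    return gm.simulate_population(traj2d, phase_bb, cells40_locking, seed=105)
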