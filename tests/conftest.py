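import numpy as np
import pytest

from adsorbkit import synthetic
from adsorbkit.io_formats import SurfaceModel


@pytest.fixture(scope="session")
def surface():
    return SurfaceModel(planes=[0.0])


@pytest.fixture(scope="session")
def small_sheet():
    """4-chain beta-sheet over 20 ns at 50 ps frames, default-style schedule."""
    script = synthetic.default_beta_sheet_script(n_chains=4, t_end=20.0,
                                                 frame_interval=0.05)
    topo, traj, ledger = synthetic.make_beta_sheet_system(n_chains=4, script=script,
                                                          seed=11)
    return topo, traj, ledger


@pytest.fixture(scope="session")
def two_domain():
    """Two rigid domains, 40-degree hinge at 35 ns, 100 ns at 100 ps frames."""
    return synthetic.make_two_domain_protein(hinge_time=35.0, hinge_angle=40.0,
                                             t_end=100.0, frame_interval=0.1, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
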