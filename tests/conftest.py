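import numpy as np
import pytest

from nanoret.bem import BEMSolver
from nanoret.dielectric import make_drude, make_silver_bb
from nanoret.meshing import build_sphere, build_tip_a, combine


@pytest.fixture(scope="session")
def sphere_solver():
    """Unit sphere, level 3 (1280 curved tesserae)."""
    return BEMSolver(build_sphere(1.0, 3))


@pytest.fixture(scope="session")
def sphere2_solver():
    """Radius-2 sphere, level 3, used by the near-field rate tests."""
    return BEMSolver(build_sphere(2.0, 3))


@pytest.fixture(scope="session")
def silver():
    return make_silver_bb()


@pytest.fixture(scope="session")
def drude9():
    """Drude silver-like model: wp = 9 eV, gamma = 0.05 wp."""
    return make_drude(9.0, 0.45)


@pytest.fixture(scope="session")
def junction_solver():
    """The STML-style tip + substrate junction at default (reduced) meshing."""
    tip, sub = build_tip_a()
    return BEMSolver(combine(tip, sub, label="tip_a+substrate"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240215)
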