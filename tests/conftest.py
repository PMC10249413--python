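import pytest
from hypothesis import settings

from chargereg import SaltBath, SurfaceModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def silica_model() -> SurfaceModel:
    """The reference silica-like surface: l_B = 0.714 nm, 4.8 sites/nm^2,
    pKa 7.7, d_is 0.35 nm, d_ii 0.4 nm, zeta 0.75, xi2 1."""
    return SurfaceModel()


@pytest.fixture
def molar_1_1() -> SaltBath:
    """1000 mM symmetric 1:1 salt."""
    return SaltBath.z_one(1, 1.0)


@pytest.fixture
def molar_2_1() -> SaltBath:
    """1000 mM 2:1 salt (divalent cation, monovalent anion)."""
    return SaltBath.z_one(2, 1.0)
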