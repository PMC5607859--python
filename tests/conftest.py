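import numpy as np
import pytest

from cspkit.crystal_core import (
    CrystalStructure, Placement, RigidMolecule, SpaceGroupSetting,
    UnitCell, quat_canonical,
)
from cspkit.energy import ForceField, optimize
from cspkit.structure_generation import SearchConfig, run_random_search
from cspkit.synthetic_data import (
    coumarin_model, diatomic_model, planar_ring_model, toy_forcefield,
)


@pytest.fixture(scope="session")
def diatomic():
    return diatomic_model()


@pytest.fixture(scope="session")
def ring():
    return planar_ring_model()


@pytest.fixture(scope="session")
def coumarin():
    return coumarin_model()


@pytest.fixture(scope="session")
def toy_ff():
    return toy_forcefield()


@pytest.fixture(scope="session")
def p21_toy(diatomic, toy_ff):
    """A deterministic, optimized P2(1) diatomic crystal used across
    the suite (the best of a tiny seeded search)."""
    cfg = SearchConfig(space_groups=("P21",), z_prime=1, n_samples=8,
                       seed=31, density_window=(1.0, 2.2))
    best = run_random_search(cfg, diatomic, toy_ff).best()
    assert best is not None
    return best.structure


@pytest.fixture(scope="session")
def unoptimized_p21(diatomic):
    """A hand-placed (not optimized) P2(1) diatomic structure."""
    rng = np.random.default_rng(3)
    q = quat_canonical(rng.normal(size=4))
    return CrystalStructure(
        cell=UnitCell(4.2, 4.8, 5.5, 90, 95, 90),
        group=SpaceGroupSetting.from_symbol("P21"),
        molecule=diatomic,
        placements=(Placement(position=np.array([0.13, 0.22, 0.41]),
                              orientation=q),))
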