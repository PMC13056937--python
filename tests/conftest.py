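import numpy as np
import pytest

import nmadiel as nd
from nmadiel.constants import ATOMIC_MASS, ELEMENTARY_CHARGE
from nmadiel.modes import AtomSet
from nmadiel.synthetic import HarmonicSystem, _pairwise_hessian


def make_diatomic(m1_amu=12.0, m2_amu=16.0, k=0.1, q1_e=0.3, q2_e=-0.3):
    """Two atoms on the x axis joined by one spring."""
    coords = np.array([[0.0, 0.0, 0.0], [0.15, 0.0, 0.0]])
    springs = np.array([[0, 1, k, 0.15]])
    atoms = AtomSet(
        masses=np.array([m1_amu, m2_amu]) * ATOMIC_MASS,
        charges=np.array([q1_e, q2_e]) * ELEMENTARY_CHARGE,
        component_labels=np.array(["protein", "protein"], dtype=object),
        residue_indices=np.array([0, 1]),
        coordinates=coords,
    )
    return HarmonicSystem(
        atoms=atoms, springs=springs, hessian=_pairwise_hessian(coords, springs)
    )


@pytest.fixture
def diatomic():
    return make_diatomic()


@pytest.fixture
def random_system():
    return nd.build_harmonic_system(
        "random", 10, charges_e=0.3 * (-1.0) ** np.arange(10), seed=1
    )


@pytest.fixture
def random_modes(random_system):
    return nd.select_vibrational_modes(nd.solve_modes(random_system))


@pytest.fixture
def hydrated_pair(random_system):
    """(bare ModeSet, hydrated ModeSet) with a stiff shell."""
    hydrated = nd.synth_hydrated_variant(
        random_system, 4, attach_stiffness=5.0, seed=101
    )
    return (
        nd.select_vibrational_modes(nd.solve_modes(random_system)),
        nd.select_vibrational_modes(nd.solve_modes(hydrated)),
    )


@pytest.fixture
def small_ensemble():
    return nd.synth_mode_ensemble(2, topology="random", n_atoms=10, seed=42)
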