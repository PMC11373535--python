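import numpy as np
import pytest

from csens import synthdata
from csens.structio import Conformer, make_atom


@pytest.fixture(scope="session")
def small_spec():
    return synthdata.SyntheticSpec(n_residues=6, seed=11, replica_noise=0.05)


@pytest.fixture(scope="session")
def small_groups(small_spec):
    return synthdata.make_conformer_groups(small_spec)


@pytest.fixture(scope="session")
def small_shift_tables(small_spec, small_groups):
    group_s, _ = small_groups
    plants = {(3, "CA"): 8.0, (4, "N"): 8.0}
    spec = synthdata.SyntheticSpec(
        n_residues=small_spec.n_residues,
        seed=small_spec.seed,
        planted_sensitivities=plants,
        n_methods=3,
    )
    return synthdata.make_shift_tables(spec, group_s.central)


def bare_chain(n_residues: int, phi: float = -135.0, psi: float = 135.0) -> Conformer:
    """Uncapped n-residue chain (cap groups stripped), residues renumbered 1..n."""
    atoms = [
        a
        for a in synthdata.build_backbone("A" * n_residues, phi, psi)
        if not a.is_cap
    ]
    for a in atoms:
        a.residue_number -= 1
    return Conformer("bare", atoms)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def toy_conformer(coords, names=None, elements=None, resnums=None) -> Conformer:
    """Ad-hoc conformer from raw coordinates for geometry tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    resnums = resnums or list(range(1, n + 1))
    atoms = [
        make_atom(names[i], elements[i], "ALA", resnums[i], coords[i]) for i in range(n)
    ]
    return Conformer("toy", atoms)
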