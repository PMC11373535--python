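"""Structure model, PDB I/O and geometry primitives.

Conformers are ordered atom lists read from (multi-model) PDB files.  The
geometric operations here — mass-weighted radius of gyration, Kabsch
superposition, backbone dihedrals and per-atom alignability — are the inputs
to frame selection, the dihedral-change features and the alignability
feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from csens.errors import SelectionError, StructureMismatchError

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "T3P"}
CAP_RESNAMES = {"ACE", "NME", "NMA", "NAC"}

#: atom names considered part of the peptide backbone (incl. backbone H)
BACKBONE_ATOM_NAMES = {
    "N", "CA", "C", "O", "OXT",
    "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3",
}
BACKBONE_HEAVY_NAMES = ("N", "CA", "C", "O")

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}


def guess_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("SE", "CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class AtomRecord:
    """One atom of a conformer (PDB conventions, coordinates in Å)."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    coordinates: np.ndarray
    is_backbone: bool = False
    is_cap: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


def make_atom(
    atom_name: str,
    element: str,
    residue_name: str,
    residue_number: int,
    coordinates,
) -> AtomRecord:
    """Build an AtomRecord, deriving the backbone/cap/water flags from names."""
    resname = residue_name.strip().upper()
    return AtomRecord(
        atom_name=atom_name.strip(),
        element=element.strip().capitalize(),
        residue_name=resname,
        residue_number=int(residue_number),
        coordinates=coordinates,
        is_backbone=atom_name.strip() in BACKBONE_ATOM_NAMES,
        is_cap=resname in CAP_RESNAMES,
        is_water=resname in WATER_RESNAMES,
    )


@dataclass
class Conformer:
    """A single configuration of the system: an ordered sequence of atoms."""

    conformer_id: str
    atoms: list[AtomRecord]
    group: str = "unassigned"
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array; cached, do not mutate in place."""
        if self._coords is None:
            self._coords = np.array([a.coordinates for a in self.atoms])
        return self._coords

    def with_coords(self, coords: np.ndarray, conformer_id: str | None = None) -> "Conformer":
        """Copy of this conformer with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coordinates=c.copy()) for a, c in zip(self.atoms, coords)]
        return Conformer(conformer_id or self.conformer_id, atoms, group=self.group)

    def backbone_heavy_indices(self) -> np.ndarray:
        idx = [
            i for i, a in enumerate(self.atoms)
            if not a.is_water and not a.is_cap
            and a.atom_name in BACKBONE_HEAVY_NAMES and a.element != "H"
        ]
        return np.asarray(idx, dtype=int)

    def atom_signature(self) -> tuple:
        return tuple((a.atom_name, a.residue_name, a.residue_number) for a in self.atoms)


@dataclass
class ConformerGroup:
    """A set of conformers regarded as replicas of one conformation."""

    label: str
    members: list[Conformer]
    central: Conformer

    def __post_init__(self) -> None:
        if not any(m is self.central for m in self.members):
            raise ValueError("central conformer must be a group member")
        sig = self.members[0].atom_signature()
        for m in self.members[1:]:
            if m.atom_signature() != sig:
                raise StructureMismatchError(
                    "group members do not share the atom ordering"
                )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_conformers(pdb_source) -> list[Conformer]:
    """Read a (multi-model) PDB file into one Conformer per MODEL.

    Water residues (HOH/WAT/SOL/...) are flagged; ACE/NME residues are
    flagged as caps.  Raises StructureMismatchError when models differ in
    atom count.
    """
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(pdb_source))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureMismatchError(
            f"inconsistent models in {pdb_source}: {exc}"
        ) from exc

    conformers = []
    n_models = stack.stack_depth()
    for m in range(n_models):
        arr = stack[m]
        atoms = []
        for i in range(arr.array_length()):
            element = arr.element[i] if arr.element[i] else guess_element(arr.atom_name[i])
            atoms.append(
                make_atom(
                    atom_name=arr.atom_name[i],
                    element=element,
                    residue_name=arr.res_name[i],
                    residue_number=int(arr.res_id[i]),
                    coordinates=arr.coord[i],
                )
            )
        conformers.append(Conformer(conformer_id=f"model-{m + 1}", atoms=atoms))
    return conformers


def write_conformers(path, conformers: Sequence[Conformer]) -> None:
    """Write conformers as a multi-model PDB file (one MODEL per conformer)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if not conformers:
        raise ValueError("nothing to write")
    sig = conformers[0].atom_signature()
    for c in conformers[1:]:
        if c.atom_signature() != sig:
            raise StructureMismatchError("conformers do not share the atom ordering")
    template = conformers[0]
    n = len(template.atoms)
    stack = struc.AtomArrayStack(len(conformers), n)
    stack.coord = np.stack([c.coords for c in conformers])
    stack.atom_name = np.array([a.atom_name for a in template.atoms])
    stack.res_name = np.array([a.residue_name for a in template.atoms])
    stack.res_id = np.array([a.residue_number for a in template.atoms])
    stack.element = np.array([a.element.upper() for a in template.atoms])
    stack.chain_id = np.array(["A"] * n)
    stack.set_annotation("hetero", np.array([a.is_water for a in template.atoms]))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def radius_of_gyration(conformer: Conformer, selection: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration over a selection (default backbone heavy)."""
    if selection is None:
        selection = conformer.backbone_heavy_indices()
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("empty selection for radius of gyration")
    if selection.size == 1:
        return 0.0
    coords = conformer.coords[selection]
    masses = np.array([conformer.atoms[i].mass for i in selection])
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(math.sqrt(np.average(sq, weights=masses)))


def superpose(
    mobile: Conformer,
    reference: Conformer,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch-optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference frame, with the minimal RMSD over the selection.
    """
    if selection is None:
        selection = mobile.backbone_heavy_indices()
    selection = np.asarray(selection, dtype=int)
    mob = mobile.coords[selection]
    ref = reference.coords[selection]
    if mob.shape != ref.shape:
        raise SelectionError("selected atom counts differ between conformers")
    n = mob.shape[0]
    if n < 3:
        raise SelectionError("need at least 3 atoms for superposition")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise SelectionError("selection is collinear; superposition underdetermined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    fitted = mob @ rotation.T + translation
    rmsd = float(math.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def superposed_rmsd(
    mobile: Conformer, reference: Conformer, selection: np.ndarray | None = None
) -> float:
    return superpose(mobile, reference, selection)[2]


def select_extreme_frames(conformers: Sequence[Conformer]) -> tuple[int, int]:
    """Indices of the max- and min-RGYR frames (backbone heavy atoms).

    Ties are broken by the lowest frame index.
    """
    if len(conformers) < 2:
        raise SelectionError("need at least 2 conformers")
    rgyr = np.array([radius_of_gyration(c) for c in conformers])
    return int(np.argmax(rgyr)), int(np.argmin(rgyr))


def select_neighbors(
    conformers: Sequence[Conformer],
    center: Conformer,
    k: int,
    label: str = "unassigned",
) -> ConformerGroup:
    """Group the ``k`` conformers most similar to ``center`` with it.

    Similarity is backbone heavy-atom RMSD after Kabsch superposition; ties
    are broken by frame index.  ``k = 0`` yields a group of just the center.
    """
    if k < 0:
        raise SelectionError("k must be non-negative")
    pool = [(i, c) for i, c in enumerate(conformers) if c is not center]
    if k > len(pool):
        raise SelectionError(f"k={k} exceeds available pool of {len(pool)}")
    ranked = sorted(
        ((superposed_rmsd(c, center), i, c) for i, c in pool),
        key=lambda t: (t[0], t[1]),
    )
    members = [center] + [c for _, _, c in ranked[:k]]
    return ConformerGroup(label=label, members=members, central=center)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return wrap_angle(ang)


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = ((angle + 180.0) % 360.0) - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def _peptide_units(conformer: Conformer) -> list[tuple[int, str, dict[str, np.ndarray]]]:
    """Ordered non-water units as (residue_number, residue_name, {atom: coord})."""
    units: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for atom in conformer.atoms:
        if atom.is_water:
            continue
        if not units or units[-1][0] != atom.residue_number:
            units.append((atom.residue_number, atom.residue_name, {}))
        units[-1][2].setdefault(atom.atom_name, atom.coordinates)
    return units


def backbone_dihedrals(conformer: Conformer) -> dict[int, tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; terminal/missing angles are None.

    Cap groups (ACE/NME) provide the flanking C/N atoms but do not get
    entries of their own.
    """
    units = _peptide_units(conformer)
    result: dict[int, tuple[float | None, float | None]] = {}
    for i, (resnum, resname, atoms) in enumerate(units):
        if resname in CAP_RESNAMES:
            continue
        phi = psi = None
        n, ca, c = atoms.get("N"), atoms.get("CA"), atoms.get("C")
        if n is not None and ca is not None and c is not None:
            if i > 0:
                c_prev = units[i - 1][2].get("C")
                if c_prev is not None:
                    phi = dihedral(c_prev, n, ca, c)
            if i + 1 < len(units):
                n_next = units[i + 1][2].get("N")
                if n_next is not None:
                    psi = dihedral(n, ca, c, n_next)
        result[resnum] = (phi, psi)
    return result


def delta_dihedral(angle_globular: float | None, angle_stretched: float | None) -> float | None:
    """Stretched minus globular, wrapped to (-180, 180]; None propagates."""
    if angle_globular is None or angle_stretched is None:
        return None
    return wrap_angle(angle_stretched - angle_globular)


def per_atom_alignability(
    group: ConformerGroup, selection: np.ndarray | None = None
) -> np.ndarray:
    """Mean inter-copy distance per atom after superposing members onto central.

    All members are rigidly fitted (default: backbone heavy atoms) onto the
    group's central member; per atom the mean over all unordered member
    pairs of the distance between its copies is returned.
    """
    if len(group.members) < 2:
        raise SelectionError("alignability needs at least 2 members")
    aligned = []
    for m in group.members:
        if m is group.central:
            aligned.append(m.coords)
        else:
            rot, trans, _ = superpose(m, group.central, selection=selection)
            aligned.append(m.coords @ rot.T + trans)
    stack = np.stack(aligned)  # (n_members, n_atoms, 3)
    n = stack.shape[0]
    total = np.zeros(stack.shape[1])
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.linalg.norm(stack[i] - stack[j], axis=1)
            n_pairs += 1
    return total / n_pairs
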