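"""Per-residue QM-input fragment construction.

Each fragment holds one central unit (an amino acid or a terminal cap
group), every unit with at least one atom within a distance cutoff of the
central unit, ACE/NME caps sealing the chain breaks that the selection
introduces, and optionally the first solvation shell of water molecules.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from csens.errors import CappingError, SelectionError
from csens.structio import AtomRecord, Conformer, make_atom

#: geometry for constructed methyl hydrogens
_METHYL_CH = 1.09
_TETRAHEDRAL = math.degrees(math.acos(-1.0 / 3.0))  # 109.47...


@dataclass
class CapRecord:
    """A constructed ACE or NME cap sealing one chain break."""

    cap_type: str                 # "ACE" | "NME"
    attachment_residue: int       # selected residue the cap is bonded to
    side: str                     # "N-side" | "C-side"
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if self.cap_type == "ACE" and self.side != "N-side":
            raise CappingError("ACE caps only seal N-side breaks")
        if self.cap_type == "NME" and self.side != "C-side":
            raise CappingError("NME caps only seal C-side breaks")


@dataclass
class SolvationShell:
    """Whole water molecules within a cutoff of the central unit."""

    cutoff: float
    waters: list[int]             # water residue numbers, source order


@dataclass
class Fragment:
    central_unit: int
    member_units: set[int]
    caps: list[CapRecord]
    waters: list[int] = field(default_factory=list)
    atoms: list[AtomRecord] = field(default_factory=list)
    #: fragment atom index -> source atom index (None for constructed cap atoms)
    atom_map: list[int | None] = field(default_factory=list)


# ---------------------------------------------------------------------------
# unit bookkeeping
# ---------------------------------------------------------------------------

def chain_units(conformer: Conformer) -> list[tuple[int, str, list[int]]]:
    """Ordered non-water units: (residue_number, residue_name, atom indices)."""
    units: list[tuple[int, str, list[int]]] = []
    for i, atom in enumerate(conformer.atoms):
        if atom.is_water:
            continue
        if not units or units[-1][0] != atom.residue_number:
            units.append((atom.residue_number, atom.residue_name, []))
        units[-1][2].append(i)
    return units


def _unit_index(units, residue_number: int) -> int:
    for pos, (num, _, _) in enumerate(units):
        if num == residue_number:
            return pos
    raise SelectionError(f"unknown residue {residue_number}")


# ---------------------------------------------------------------------------
# environment selection
# ---------------------------------------------------------------------------

def select_environment(conformer: Conformer, central_unit: int, cutoff: float) -> set[int]:
    """Residue numbers of all units with any atom within ``cutoff`` of the central unit.

    The distance test is all-atom (hydrogens included) and inclusive
    (d <= cutoff).  The central unit is always a member.
    """
    if cutoff <= 0:
        raise SelectionError("cutoff must be positive")
    units = chain_units(conformer)
    pos = _unit_index(units, central_unit)
    coords = conformer.coords
    tree = cKDTree(coords[units[pos][2]])
    members = {central_unit}
    for num, _, idx in units:
        if num == central_unit:
            continue
        d, _ = tree.query(coords[idx])
        if np.min(d) <= cutoff:
            members.add(num)
    return members


# ---------------------------------------------------------------------------
# capping
# ---------------------------------------------------------------------------

def _methyl_hydrogens(c_methyl: np.ndarray, attached: np.ndarray) -> list[np.ndarray]:
    """Three H positions for a methyl carbon, ideal tetrahedral geometry."""
    u = c_methyl - attached
    u = u / np.linalg.norm(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    cos_a = math.cos(math.radians(180.0 - _TETRAHEDRAL))
    sin_a = math.sin(math.radians(180.0 - _TETRAHEDRAL))
    positions = []
    for k in range(3):
        theta = 2.0 * math.pi * k / 3.0
        direction = cos_a * u + sin_a * (math.cos(theta) * v + math.sin(theta) * w)
        positions.append(c_methyl + _METHYL_CH * direction)
    return positions


def _neighbor_coord(conformer, idx_list, *names) -> np.ndarray | None:
    for name in names:
        for i in idx_list:
            if conformer.atoms[i].atom_name == name:
                return conformer.atoms[i].coordinates
    return None


def _build_ace(conformer: Conformer, neighbor, attachment: int) -> CapRecord:
    """ACE built from an excluded N-side neighbor's C/O/CA backbone positions."""
    num, resname, idx = neighbor
    c = _neighbor_coord(conformer, idx, "C")
    o = _neighbor_coord(conformer, idx, "O")
    ca = _neighbor_coord(conformer, idx, "CA", "CH3")
    if c is None or o is None or ca is None:
        raise CappingError(f"residue {num} ({resname}) lacks C/O/CA atoms for an ACE cap")
    atoms = [
        make_atom("CH3", "C", "ACE", num, ca),
        make_atom("C", "C", "ACE", num, c),
        make_atom("O", "O", "ACE", num, o),
    ]
    for k, pos in enumerate(_methyl_hydrogens(ca, c), start=1):
        atoms.append(make_atom(f"HH3{k}", "H", "ACE", num, pos))
    return CapRecord("ACE", attachment_residue=attachment, side="N-side", atoms=atoms)


def _build_nme(conformer: Conformer, neighbor, attachment: int) -> CapRecord:
    """NME built from an excluded C-side neighbor's N/H/CA backbone positions."""
    num, resname, idx = neighbor
    n = _neighbor_coord(conformer, idx, "N")
    ca = _neighbor_coord(conformer, idx, "CA", "CH3")
    if n is None or ca is None:
        raise CappingError(f"residue {num} ({resname}) lacks N/CA atoms for an NME cap")
    h = _neighbor_coord(conformer, idx, "H", "HN")
    atoms = [make_atom("N", "N", "NME", num, n)]
    if h is not None:
        atoms.append(make_atom("H", "H", "NME", num, h))
    atoms.append(make_atom("CH3", "C", "NME", num, ca))
    for k, pos in enumerate(_methyl_hydrogens(ca, n), start=1):
        atoms.append(make_atom(f"HH3{k}", "H", "NME", num, pos))
    return CapRecord("NME", attachment_residue=attachment, side="C-side", atoms=atoms)


def _selection_runs(units, member_units: set[int]) -> list[tuple[int, int]]:
    """Maximal contiguous runs of selected chain positions as (start, end)."""
    selected = [pos for pos, (num, _, _) in enumerate(units) if num in member_units]
    runs = []
    for pos in selected:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return runs


def cap_breaks(conformer: Conformer, member_units: set[int]) -> list[CapRecord]:
    """ACE/NME cap records for every chain break the selection introduces.

    For each maximal contiguous run of selected units: an excluded N-side
    neighbor donates its C, O and CA positions to an ACE cap (CA becoming
    the methyl carbon); an excluded C-side neighbor donates N, H and CA to
    an NME cap.  Original termini need no cap.
    """
    if not member_units:
        raise SelectionError("member_units must not be empty")
    units = chain_units(conformer)
    caps: list[CapRecord] = []
    for start, end in _selection_runs(units, member_units):
        if start > 0:
            caps.append(_build_ace(conformer, units[start - 1], units[start][0]))
        if end + 1 < len(units):
            caps.append(_build_nme(conformer, units[end + 1], units[end][0]))
    return caps


# ---------------------------------------------------------------------------
# micro-solvation
# ---------------------------------------------------------------------------

def water_molecules(conformer: Conformer) -> list[tuple[int, list[int]]]:
    """Water molecules as (residue_number, atom indices), source order."""
    waters: list[tuple[int, list[int]]] = []
    for i, atom in enumerate(conformer.atoms):
        if not atom.is_water:
            continue
        if not waters or waters[-1][0] != atom.residue_number:
            waters.append((atom.residue_number, []))
        waters[-1][1].append(i)
    return waters


def extract_microsolvation(
    conformer: Conformer, central_unit: int, cutoff: float
) -> SolvationShell:
    """Whole waters with any atom within ``cutoff`` of the central unit."""
    if cutoff <= 0:
        raise SelectionError("cutoff must be positive")
    units = chain_units(conformer)
    pos = _unit_index(units, central_unit)
    coords = conformer.coords
    tree = cKDTree(coords[units[pos][2]])
    shell = []
    for num, idx in water_molecules(conformer):
        d, _ = tree.query(coords[idx])
        if np.min(d) <= cutoff:
            shell.append(num)
    return SolvationShell(cutoff=cutoff, waters=shell)


# ---------------------------------------------------------------------------
# fragment assembly
# ---------------------------------------------------------------------------

def build_fragment(
    conformer: Conformer,
    central_unit: int,
    cutoff: float = 4.0,
    with_solvent: bool = False,
) -> Fragment:
    """Assemble one fragment around a central unit."""
    members = select_environment(conformer, central_unit, cutoff)
    caps = cap_breaks(conformer, members)
    shell = (
        extract_microsolvation(conformer, central_unit, cutoff)
        if with_solvent
        else SolvationShell(cutoff=cutoff, waters=[])
    )
    units = chain_units(conformer)
    runs = _selection_runs(units, members)
    cap_by_key = {(c.side, c.attachment_residue): c for c in caps}

    atoms: list[AtomRecord] = []
    atom_map: list[int | None] = []

    def _append_cap(cap: CapRecord) -> None:
        for a in cap.atoms:
            atoms.append(a)
            atom_map.append(None)

    for start, end in runs:
        ace = cap_by_key.get(("N-side", units[start][0]))
        if ace is not None:
            _append_cap(ace)
        for pos in range(start, end + 1):
            for i in units[pos][2]:
                atoms.append(conformer.atoms[i])
                atom_map.append(i)
        nme = cap_by_key.get(("C-side", units[end][0]))
        if nme is not None:
            _append_cap(nme)
    if with_solvent:
        mol_by_num = dict(water_molecules(conformer))
        for num in shell.waters:
            for i in mol_by_num[num]:
                atoms.append(conformer.atoms[i])
                atom_map.append(i)

    return Fragment(
        central_unit=central_unit,
        member_units=members,
        caps=caps,
        waters=shell.waters,
        atoms=atoms,
        atom_map=atom_map,
    )


def fragment_all(
    conformer: Conformer, cutoff: float = 4.0, with_solvent: bool = False
) -> list[Fragment]:
    """One fragment per central unit; central units are every amino acid plus
    the terminal cap groups, so a fully capped n-residue peptide yields n+2
    fragments."""
    units = chain_units(conformer)
    if not units:
        raise SelectionError("conformer has no peptide units")
    return [
        build_fragment(conformer, num, cutoff=cutoff, with_solvent=with_solvent)
        for num, _, _ in units
    ]


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fragment(fragment: Fragment, path, fmt: str = "pdb") -> None:
    """Write a fragment as PDB or XYZ plus an atom-map sidecar (``.map.csv``)."""
    path = Path(path)
    if fmt == "pdb":
        frag_conf = Conformer(f"fragment-{fragment.central_unit}", list(fragment.atoms))
        from csens.structio import write_conformers

        write_conformers(path, [frag_conf])
    elif fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{len(fragment.atoms)}\n")
            fh.write(f"fragment central_unit={fragment.central_unit}\n")
            for a in fragment.atoms:
                x, y, z = a.coordinates
                fh.write(f"{a.element:<2s} {x:12.3f} {y:12.3f} {z:12.3f}\n")
    else:
        raise ValueError(f"unsupported format: {fmt!r}")

    sidecar = path.with_suffix(path.suffix + ".map.csv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["fragment_index", "source_index", "residue_number", "atom_name", "is_cap_atom"]
        )
        for fi, (src, atom) in enumerate(zip(fragment.atom_map, fragment.atoms)):
            writer.writerow(
                [fi, "" if src is None else src, atom.residue_number, atom.atom_name, int(src is None)]
            )
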