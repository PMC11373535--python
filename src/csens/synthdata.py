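"""Seeded synthetic conformers, shift tables and reference tables.

Two conformation groups of near-identical replicas are built from ideal
backbone geometry at per-group (phi, psi) targets; per-method shift tables
carry planted between-group mean separations (in pooled-sigma units) on a
known within-group spread, so the downstream statistics can be checked
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from csens.referencing import SHIFT_COLUMNS
from csens.structio import AtomRecord, Conformer, ConformerGroup, make_atom

# ideal backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
BOND_N_H = 1.010
BOND_CA_CB = 1.521
BOND_C_H = 1.090
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0
OMEGA = 180.0

_BASE_SHIFT = {"H": 4.0, "C": 50.0, "N": 120.0, "O": 0.0}

#: independent random-stream domains derived from the master seed
_STREAM_GEOMETRY = 1
_STREAM_SHIFTS = 2
_STREAM_REFERENCE = 3


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-conformation system."""

    n_residues: int = 10
    sequence: str | None = None            # one-letter codes; default poly-alanine
    group_geometry: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"stretched": (-135.0, 135.0), "globular": (-75.0, -30.0)}
    )
    replica_noise: float = 0.05            # Å coordinate jitter sd
    n_replicas: int = 5
    planted_sensitivities: Mapping[tuple[int, str], float] | None = None
    within_group_sd: float = 0.1           # ppm
    rc_offsets: Mapping[int, tuple[float, float]] | None = None  # residue -> (dCA, dCB)
    experimental_offset: float = 0.0       # relative error planted into the experiment
    n_methods: int = 9
    n_waters: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_sensitivities" in raw and raw["planted_sensitivities"]:
            raw["planted_sensitivities"] = {
                (int(k.split(":")[0]), k.split(":")[1]): float(v)
                for k, v in raw["planted_sensitivities"].items()
            }
        if "rc_offsets" in raw and raw["rc_offsets"]:
            raw["rc_offsets"] = {int(k): tuple(v) for k, v in raw["rc_offsets"].items()}
        if "group_geometry" in raw and raw["group_geometry"]:
            raw["group_geometry"] = {k: tuple(v) for k, v in raw["group_geometry"].items()}
        return cls(**raw)


THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position X with |X-c| = bond, angle(X,c,b) = angle and
    dihedral(X,c,b,a) = dihedral (degrees), standard internal-coordinate
    chain extension."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        -bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _methyl_h(center: np.ndarray, attached: np.ndarray) -> list[np.ndarray]:
    u = center - attached
    u = u / np.linalg.norm(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    tet = math.degrees(math.acos(-1.0 / 3.0))
    cos_a = math.cos(math.radians(180.0 - tet))
    sin_a = math.sin(math.radians(180.0 - tet))
    return [
        center + BOND_C_H * (cos_a * u + sin_a * (math.cos(t) * v + math.sin(t) * w))
        for t in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
    ]


def build_backbone(
    sequence: str, phi: float | list[float], psi: float | list[float]
) -> list[AtomRecord]:
    """Capped peptide from ideal geometry at the given (phi, psi) targets.

    Residue numbering: ACE = 1, amino acids 2..n+1, NME = n+2.  Each amino
    acid gets N, H, CA, HA, CB (except glycine), C, O.
    """
    n = len(sequence)
    phis = [phi] * n if np.isscalar(phi) else list(phi)
    psis = [psi] * n if np.isscalar(psi) else list(psi)
    if len(phis) != n or len(psis) != n:
        raise ValueError("phi/psi target lists must match the sequence length")

    atoms: list[AtomRecord] = []

    # ACE: CH3-C(=O)-; seed coordinates placed manually in the xy-plane
    ch3 = np.array([0.0, 0.0, 0.0])
    c_prev = np.array([1.522, 0.0, 0.0])
    n_first = place_atom(
        np.array([0.0, 0.0, 1.0]), ch3, c_prev, BOND_C_N, ANGLE_CA_C_N, 60.0
    )
    ace_o = place_atom(n_first, ch3, c_prev, BOND_C_O, ANGLE_CA_C_O, 180.0)
    atoms.append(make_atom("CH3", "C", "ACE", 1, ch3))
    for k, pos in enumerate(_methyl_h(ch3, c_prev), start=1):
        atoms.append(make_atom(f"HH3{k}", "H", "ACE", 1, pos))
    atoms.append(make_atom("C", "C", "ACE", 1, c_prev))
    atoms.append(make_atom("O", "O", "ACE", 1, ace_o))

    ca_prev = ch3          # previous-residue CA role for the omega dihedral
    n_cur = n_first
    for i, letter in enumerate(sequence):
        resnum = i + 2
        resname = THREE_LETTER[letter.upper()]
        ca = place_atom(ca_prev, c_prev, n_cur, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        h_amide = place_atom(ca_prev, c_prev, n_cur, BOND_N_H, ANGLE_C_N_H, 0.0)
        c = place_atom(c_prev, n_cur, ca, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        ha = place_atom(c_prev, n_cur, ca, BOND_C_H, 109.5, phis[i] + 118.0)
        cb = place_atom(c_prev, n_cur, ca, BOND_CA_CB, 110.5, phis[i] - 122.0)
        atoms.append(make_atom("N", "N", resname, resnum, n_cur))
        if resname != "PRO":
            atoms.append(make_atom("H", "H", resname, resnum, h_amide))
        atoms.append(make_atom("CA", "C", resname, resnum, ca))
        atoms.append(make_atom("HA", "H", resname, resnum, ha))
        if resname != "GLY":
            atoms.append(make_atom("CB", "C", resname, resnum, cb))
        # next backbone N fixes psi; O is anti-periplanar to it
        n_next = place_atom(n_cur, ca, c, BOND_C_N, ANGLE_CA_C_N, psis[i])
        o = place_atom(n_cur, ca, c, BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        atoms.append(make_atom("C", "C", resname, resnum, c))
        atoms.append(make_atom("O", "O", resname, resnum, o))
        ca_prev, c_prev, n_cur = ca, c, n_next

    # NME: -NH-CH3
    nme_num = n + 2
    ch3_nme = place_atom(ca_prev, c_prev, n_cur, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
    h_nme = place_atom(ca_prev, c_prev, n_cur, BOND_N_H, ANGLE_C_N_H, 0.0)
    atoms.append(make_atom("N", "N", "NME", nme_num, n_cur))
    atoms.append(make_atom("H", "H", "NME", nme_num, h_nme))
    atoms.append(make_atom("CH3", "C", "NME", nme_num, ch3_nme))
    for k, pos in enumerate(_methyl_h(ch3_nme, n_cur), start=1):
        atoms.append(make_atom(f"HH3{k}", "H", "NME", nme_num, pos))
    return atoms


def _add_waters(atoms: list[AtomRecord], n_waters: int, rng: np.random.Generator) -> None:
    """Scatter rigid waters 3-6 Å away from randomly chosen peptide atoms."""
    next_num = max(a.residue_number for a in atoms) + 1
    peptide_coords = np.array([a.coordinates for a in atoms])
    for w in range(n_waters):
        anchor = peptide_coords[rng.integers(0, len(peptide_coords))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        o = anchor + direction * rng.uniform(3.0, 6.0)
        h1 = o + np.array([0.9572, 0.0, 0.0])
        h2 = o + 0.9572 * np.array([math.cos(math.radians(104.5)), math.sin(math.radians(104.5)), 0.0])
        num = next_num + w
        atoms.append(make_atom("OW", "O", "HOH", num, o))
        atoms.append(make_atom("HW1", "H", "HOH", num, h1))
        atoms.append(make_atom("HW2", "H", "HOH", num, h2))


def make_conformer_groups(spec: SyntheticSpec) -> tuple[ConformerGroup, ConformerGroup]:
    """Build the two replica groups from the per-group (phi, psi) targets.

    Member 0 of each group is the exact ideal-geometry chain (the central
    member); the others carry Gaussian coordinate jitter of sd
    ``replica_noise``.
    """
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues")
    sequence = spec.sequence or "A" * spec.n_residues
    if len(sequence) != spec.n_residues:
        raise ValueError("sequence length must equal n_residues")
    rng = np.random.default_rng([spec.seed, _STREAM_GEOMETRY])
    groups = []
    for label in ("stretched", "globular"):
        phi, psi = spec.group_geometry[label]
        atoms = build_backbone(sequence, phi, psi)
        if spec.n_waters:
            _add_waters(atoms, spec.n_waters, rng)
        central = Conformer(f"{label}-0", atoms, group=label)
        members = [central]
        coords = central.coords
        for r in range(1, spec.n_replicas):
            jitter = rng.normal(scale=spec.replica_noise, size=coords.shape)
            members.append(
                central.with_coords(coords + jitter, conformer_id=f"{label}-{r}")
            )
            members[-1].group = label
        groups.append(ConformerGroup(label=label, members=members, central=central))
    return groups[0], groups[1]


# ---------------------------------------------------------------------------
# shift tables with planted separations
# ---------------------------------------------------------------------------

def make_shift_tables(
    spec: SyntheticSpec, conformer: Conformer
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-method canonical shift tables with planted sensitivities.

    For each non-water atom: globular samples ~ N(mu, sd) and stretched
    samples ~ N(mu + s_true * sd, sd) with sd = ``within_group_sd`` and
    s_true from ``planted_sensitivities`` (default 0).  In the degenerate
    sd = 0 case the planted offset is s_true ppm, so a nonzero plant still
    separates the (now point-mass) groups.  Returns the tables keyed by
    pseudo-method name plus a ground-truth table of s_true.
    """
    if spec.within_group_sd < 0:
        raise ValueError("within_group_sd must be non-negative")
    rng = np.random.default_rng([spec.seed, _STREAM_SHIFTS])
    plants = spec.planted_sensitivities or {}
    atoms = [a for a in conformer.atoms if not a.is_water]
    sd = spec.within_group_sd

    truth_rows = []
    base_mu = {}
    for a in atoms:
        key = (a.residue_number, a.atom_name)
        mu = _BASE_SHIFT.get(a.element.upper(), 50.0) + rng.uniform(-2.0, 2.0)
        base_mu[key] = mu
        truth_rows.append(
            {
                "residue_number": a.residue_number,
                "residue_name": a.residue_name,
                "atom_name": a.atom_name,
                "element": a.element,
                "s_true": float(plants.get(key, 0.0)),
            }
        )
    truth = pd.DataFrame(truth_rows)

    tables = {}
    for m in range(spec.n_methods):
        method = f"method-{m + 1}"
        rows = []
        for a in atoms:
            key = (a.residue_number, a.atom_name)
            mu = base_mu[key]
            s_true = float(plants.get(key, 0.0))
            offset = s_true * sd if sd > 0 else s_true
            for group, shift_mean in (
                ("globular", mu),
                ("stretched", mu + offset),
            ):
                samples = (
                    shift_mean + rng.normal(scale=sd, size=spec.n_replicas)
                    if sd > 0
                    else np.full(spec.n_replicas, shift_mean)
                )
                for r, value in enumerate(samples):
                    rows.append(
                        {
                            "method": method,
                            "conformer_id": f"{group}-{r}",
                            "group": group,
                            "residue_number": a.residue_number,
                            "residue_name": a.residue_name,
                            "atom_name": a.atom_name,
                            "element": a.element,
                            "value_ppm": float(value),
                        }
                    )
        tables[method] = pd.DataFrame(rows, columns=SHIFT_COLUMNS)
    return tables, truth


# ---------------------------------------------------------------------------
# experimental / random-coil reference tables
# ---------------------------------------------------------------------------

def make_reference_tables(
    spec: SyntheticSpec, shift_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Experimental and random-coil tables with controlled properties.

    The experimental value is the ensemble mean scaled so the mean relative
    error of the ensemble mean equals ``experimental_offset`` exactly; the
    random-coil value is the experimental one minus the planted
    ``rc_offsets`` (per residue: dCA on CA, dCB on CB), so secondary shifts
    are controlled exactly.
    """
    mean = (
        shift_table.groupby(
            ["residue_number", "residue_name", "atom_name", "element"], as_index=False
        )["value_ppm"].mean()
    )
    exp = mean.copy()
    exp["value_ppm"] = exp["value_ppm"] / (1.0 + spec.experimental_offset)

    rc = exp[["residue_number", "atom_name", "value_ppm"]].copy()
    offsets = spec.rc_offsets or {}
    for resnum, (d_ca, d_cb) in offsets.items():
        for name, d in (("CA", d_ca), ("CB", d_cb)):
            mask = (rc["residue_number"] == resnum) & (rc["atom_name"] == name)
            rc.loc[mask, "value_ppm"] = rc.loc[mask, "value_ppm"] - d
    return exp, rc


# ---------------------------------------------------------------------------
# convenience plant layouts
# ---------------------------------------------------------------------------

def plant_two_level(
    conformer: Conformer,
    seed: int,
    fraction_sensitive: float = 0.5,
    separation: float = 6.0,
) -> dict[tuple[int, str], float]:
    """Randomly assign each non-water atom a planted separation of 0 or
    ``separation`` sigma; used by the recovery checks."""
    rng = np.random.default_rng([seed, 0xF1])
    plants = {}
    for a in conformer.atoms:
        if a.is_water:
            continue
        s = separation if rng.random() < fraction_sensitive else 0.0
        plants[(a.residue_number, a.atom_name)] = s
    return plants
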