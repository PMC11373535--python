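"""Per-atom biophysical feature table and permutation-importance study.

Features are signed stretched-minus-globular deltas (distances, dihedrals,
per-atom SASA) plus categorical atom/residue descriptors, the per-atom
alignability and two negative controls; the label is the conformational
sensitivity.  A random-forest regressor with fixed hyperparameters is fit
repeatedly and feature importance is measured as the mean test-R² drop
under (grouped) permutation of each feature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from csens.errors import SelectionError
from csens.structio import (
    Conformer,
    ConformerGroup,
    backbone_dihedrals,
    delta_dihedral,
    per_atom_alignability,
    wrap_angle,
)

VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
PROBE_RADIUS = 1.4
SASA_POINTS = 512

#: minimum sequence separation for delta-distance targets
MIN_RESIDUE_SEPARATION = 3

CATEGORICAL_FEATURES = ["atom_category", "atom_name", "atom_element", "residue_name"]
NUMERIC_FEATURES = [
    "residue_number", "ddist_O", "ddist_N", "ddist_RES",
    "dphi", "dpsi", "dsasa", "is_sidechain", "alignability",
    "neg_control_cont", "neg_control_cat",
]

RF_PARAMS = dict(
    n_estimators=100,
    criterion="squared_error",
    min_samples_leaf=10,
    min_samples_split=15,
    max_depth=10,
)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Test points are placed on each atom's solvent-expanded sphere; a point
    is accessible if it lies outside every other atom's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = coords.shape[0]
    expanded = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    sasa = np.empty(n_atoms)
    for i in range(n_atoms):
        points = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(points - coords[j], axis=1)
            accessible &= d > expanded[j]
            if not accessible.any():
                break
        sasa[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.sum() / n_points
    return sasa


def conformer_sasa(conformer: Conformer, n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom SASA of the peptide atoms (waters excluded from the system)."""
    idx = [i for i, a in enumerate(conformer.atoms) if not a.is_water]
    coords = conformer.coords[idx]
    radii = np.array([
        VDW_RADII.get(conformer.atoms[i].element.upper().capitalize(), None)
        for i in idx
    ], dtype=object)
    if any(r is None for r in radii):
        bad = {conformer.atoms[i].element for i, r in zip(idx, radii) if r is None}
        raise SelectionError(f"no van der Waals radius for element(s) {bad}")
    values = shrake_rupley(coords, radii.astype(float), n_points=n_points)
    out = np.full(len(conformer.atoms), np.nan)
    out[idx] = values
    return out


# ---------------------------------------------------------------------------
# delta-distance features
# ---------------------------------------------------------------------------

def _min_distance_to_kind(
    conformer: Conformer, atom_index: int, kind: str
) -> float | None:
    """Minimum distance from one atom to the nearest qualifying target.

    Targets are atoms of the given element (O or N) or residue centers of
    geometry (RES), belonging to residues at least MIN_RESIDUE_SEPARATION
    apart in sequence; waters never qualify.
    """
    atom = conformer.atoms[atom_index]
    own_res = atom.residue_number
    coords = conformer.coords
    if kind in ("O", "N"):
        targets = [
            coords[j]
            for j, a in enumerate(conformer.atoms)
            if not a.is_water
            and a.element.upper() == kind
            and abs(a.residue_number - own_res) >= MIN_RESIDUE_SEPARATION
        ]
    elif kind == "RES":
        centers: dict[int, list[np.ndarray]] = {}
        for j, a in enumerate(conformer.atoms):
            if a.is_water:
                continue
            if abs(a.residue_number - own_res) >= MIN_RESIDUE_SEPARATION:
                centers.setdefault(a.residue_number, []).append(coords[j])
        targets = [np.mean(v, axis=0) for v in centers.values()]
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    if not targets:
        return None
    d = np.linalg.norm(np.asarray(targets) - coords[atom_index], axis=1)
    return float(d.min())


def delta_distance_feature(
    group_s: ConformerGroup,
    group_g: ConformerGroup,
    residue_number: int,
    atom_name: str,
    target_kind: str,
) -> float | None:
    """Signed change (stretched - globular) of the group-mean minimum distance
    from the atom to the nearest qualifying target of the given kind."""
    def group_value(group: ConformerGroup) -> float | None:
        vals = []
        for member in group.members:
            idx = _find_atom(member, residue_number, atom_name)
            d = _min_distance_to_kind(member, idx, target_kind)
            if d is None:
                return None
            vals.append(d)
        return float(np.mean(vals))

    vs = group_value(group_s)
    vg = group_value(group_g)
    if vs is None or vg is None:
        return None
    return vs - vg


def delta_sasa(
    group_s: ConformerGroup,
    group_g: ConformerGroup,
    residue_number: int,
    atom_name: str,
    n_points: int = SASA_POINTS,
) -> float:
    """Signed change (stretched - globular) of the group-mean per-atom SASA."""
    def group_value(group: ConformerGroup) -> float:
        vals = []
        for member in group.members:
            idx = _find_atom(member, residue_number, atom_name)
            vals.append(conformer_sasa(member, n_points=n_points)[idx])
        return float(np.mean(vals))

    return group_value(group_s) - group_value(group_g)


def _find_atom(conformer: Conformer, residue_number: int, atom_name: str) -> int:
    for i, a in enumerate(conformer.atoms):
        if a.residue_number == residue_number and a.atom_name == atom_name:
            return i
    raise SelectionError(f"atom {atom_name} of residue {residue_number} not found")


# ---------------------------------------------------------------------------
# feature-table assembly
# ---------------------------------------------------------------------------

def _circular_mean_deg(angles: list[float]) -> float:
    rad = np.radians(angles)
    return wrap_angle(math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _group_dihedrals(group: ConformerGroup) -> dict[int, tuple[float | None, float | None]]:
    per_member = [backbone_dihedrals(m) for m in group.members]
    out = {}
    for resnum in per_member[0]:
        phis = [d[resnum][0] for d in per_member]
        psis = [d[resnum][1] for d in per_member]
        phi = _circular_mean_deg(phis) if all(p is not None for p in phis) else None
        psi = _circular_mean_deg(psis) if all(p is not None for p in psis) else None
        out[resnum] = (phi, psi)
    return out


def build_feature_table(
    group_s: ConformerGroup,
    group_g: ConformerGroup,
    sensitivity_records: pd.DataFrame,
    seed: int = 0,
    sasa_points: int = SASA_POINTS,
) -> pd.DataFrame:
    """One row per retained atom with the full feature set and the label.

    ``sensitivity_records`` is the output of
    :func:`csens.sensitivity.compute_sensitivity` after atom filtering; the
    negative controls are drawn from ``seed`` independently of everything
    else.
    """
    rng = np.random.default_rng([int(seed), 0xC0])
    dih_s = _group_dihedrals(group_s)
    dih_g = _group_dihedrals(group_g)
    align_s = per_atom_alignability(group_s)
    align_g = per_atom_alignability(group_g)
    # group-mean per-atom SASA (computed once per member, then indexed)
    sasa_s = np.nanmean([conformer_sasa(m, sasa_points) for m in group_s.members], axis=0)
    sasa_g = np.nanmean([conformer_sasa(m, sasa_points) for m in group_g.members], axis=0)

    template = group_s.central
    rows = []
    for rec in sensitivity_records.itertuples():
        idx = _find_atom(template, rec.residue_number, rec.atom_name)
        atom = template.atoms[idx]
        dphi = dpsi = None
        if rec.residue_number in dih_s and rec.residue_number in dih_g:
            dphi = delta_dihedral(dih_g[rec.residue_number][0], dih_s[rec.residue_number][0])
            dpsi = delta_dihedral(dih_g[rec.residue_number][1], dih_s[rec.residue_number][1])
        rows.append(
            {
                "residue_number": rec.residue_number,
                "atom_name": rec.atom_name,
                "atom_element": rec.element,
                "atom_category": rec.category,
                "residue_name": rec.residue_name,
                "ddist_O": delta_distance_feature(group_s, group_g, rec.residue_number, rec.atom_name, "O"),
                "ddist_N": delta_distance_feature(group_s, group_g, rec.residue_number, rec.atom_name, "N"),
                "ddist_RES": delta_distance_feature(group_s, group_g, rec.residue_number, rec.atom_name, "RES"),
                "dphi": dphi,
                "dpsi": dpsi,
                "dsasa": float(sasa_s[idx] - sasa_g[idx]),
                "is_sidechain": int(not atom.is_backbone),
                "alignability": float(0.5 * (align_s[idx] + align_g[idx])),
                "neg_control_cont": float(rng.uniform(0.0, 20.0)),
                "neg_control_cat": int(rng.integers(0, 7)),
                "sensitivity": rec.sensitivity,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode(
    table: pd.DataFrame, scheme: str = "one-hot"
) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[str]]]:
    """Encode the feature table into a numeric matrix.

    Returns (X, y, column_map) where column_map maps each original feature
    to the encoded columns it occupies — one-hot expands categoricals into
    indicator blocks, ordinal assigns stable sorted-level codes.
    """
    if scheme not in ("one-hot", "ordinal"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    y = table["sensitivity"].to_numpy(dtype=float)
    feature_cols = [c for c in CATEGORICAL_FEATURES + NUMERIC_FEATURES if c in table.columns]
    parts = []
    column_map: dict[str, list[str]] = {}
    for col in feature_cols:
        if col in CATEGORICAL_FEATURES:
            levels = sorted(table[col].astype(str).unique())
            if scheme == "one-hot":
                block = pd.DataFrame(
                    {f"{col}={lvl}": (table[col].astype(str) == lvl).astype(float) for lvl in levels}
                )
                parts.append(block)
                column_map[col] = list(block.columns)
            else:
                codes = table[col].astype(str).map({lvl: i for i, lvl in enumerate(levels)})
                parts.append(codes.rename(col).astype(float).to_frame())
                column_map[col] = [col]
        else:
            series = pd.to_numeric(table[col]).astype(float)
            parts.append(series.rename(col).to_frame())
            column_map[col] = [col]
    X = pd.concat(parts, axis=1)
    # RF cannot ingest NaNs; impute with column medians, keeping the row
    X = X.fillna(X.median(numeric_only=True))
    return X, y, column_map


def ordinal_decode(codes, levels: list[str]) -> list[str]:
    """Recover categorical labels from sorted-level ordinal codes."""
    return [levels[int(c)] for c in codes]


# ---------------------------------------------------------------------------
# random-forest permutation importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    importance_mean: dict[str, float]
    importance_sd: dict[str, float]
    train_scores: list[float] = field(default_factory=list)
    test_scores: list[float] = field(default_factory=list)
    n_retained: int = 0
    n_total: int = 0
    per_seed: list[dict[str, float]] = field(default_factory=list)

    def ranking(self) -> list[str]:
        return sorted(self.importance_mean, key=self.importance_mean.get, reverse=True)

    def standard_error(self, feature: str) -> float:
        if self.n_retained < 2:
            return float("inf")
        return self.importance_sd[feature] / math.sqrt(self.n_retained)


def fit_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    column_map: dict[str, list[str]],
    seeds=range(50),
    n_permutations: int = 10,
    test_fraction: float = 0.2,
    rf_params: dict | None = None,
) -> ImportanceReport:
    """Repeated 80/20 random-forest fits with grouped permutation importance.

    Per seed: split, fit, score; repeats with negative test R² are dropped.
    Importance of a feature is the mean drop in test R² when its encoded
    column block is jointly shuffled.
    """
    if len(X) < 30:
        raise SelectionError("need at least 30 rows for the split/leaf constraints")
    params = dict(RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    per_seed_importances: list[dict[str, float]] = []
    train_scores, test_scores = [], []
    n_total = 0
    for seed in seeds:
        n_total += 1
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, random_state=seed
        )
        model = RandomForestRegressor(random_state=seed, **params)
        model.fit(X_tr, y_tr)
        base = r2_score(y_te, model.predict(X_te))
        if base < 0:
            continue
        rng = np.random.default_rng(seed)
        imp = {}
        for feature, cols in column_map.items():
            drops = []
            for _ in range(n_permutations):
                X_perm = X_te.copy()
                perm = rng.permutation(len(X_te))
                X_perm[cols] = X_te[cols].to_numpy()[perm]
                drops.append(base - r2_score(y_te, model.predict(X_perm)))
            imp[feature] = float(np.mean(drops))
        per_seed_importances.append(imp)
        train_scores.append(float(r2_score(y_tr, model.predict(X_tr))))
        test_scores.append(float(base))
    if not per_seed_importances:
        warnings.warn("all repeats yielded negative test R²; nothing retained")
        return ImportanceReport({}, {}, train_scores, test_scores, 0, n_total)
    features = list(per_seed_importances[0])
    stacked = {f: np.array([d[f] for d in per_seed_importances]) for f in features}
    return ImportanceReport(
        importance_mean={f: float(v.mean()) for f, v in stacked.items()},
        importance_sd={f: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for f, v in stacked.items()},
        train_scores=train_scores,
        test_scores=test_scores,
        n_retained=len(per_seed_importances),
        n_total=n_total,
        per_seed=per_seed_importances,
    )
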