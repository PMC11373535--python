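"""Conformational-sensitivity statistic and cross-method agreement.

For each atom, the two conformation groups supply two small samples of a
predicted chemical shift.  The separation of the two sample means in
multiples of the pooled standard deviation is the sensitivity; an atom is
flagged sensitive when the overlap of the two implied equal-width Gaussians
drops below 10%, i.e. when the separation exceeds 3.29 pooled sigma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from csens.errors import JoinError, SelectionError
from csens.structio import CAP_RESNAMES

logger = logging.getLogger(__name__)

SENSITIVITY_THRESHOLD = 3.29
VOTE_THRESHOLD = 4

CATEGORIES = (
    "Calpha", "Ccarbonyl", "Hamide", "Namide",
    "Cbeta", "Cother", "Hother", "Nother",
)

_AMIDE_H_NAMES = {"H", "HN"}


@dataclass
class SensitivityRecord:
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    category: str
    mean_stretched: float
    mean_globular: float
    sd_stretched: float
    sd_globular: float
    pooled_sd: float
    sensitivity: float
    is_sensitive: bool


def pooled_std(samples_a, samples_b) -> float:
    """Classical two-sample pooled standard deviation ((n-1)-weighted)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SelectionError("pooled_std needs at least 2 samples per group")
    var_a = np.var(a, ddof=1)
    var_b = np.var(b, ddof=1)
    pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / (a.size + b.size - 2)
    return float(math.sqrt(pooled))


def gaussian_overlap(separation: float) -> float:
    """Overlap area of two equal-sigma normal densities separated by d sigma.

    Equals 2*Phi(-d/2); 1 at zero separation, strictly decreasing.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    return float(2.0 * norm.cdf(-separation / 2.0))


def separation_for_overlap(overlap: float) -> float:
    """Inverse of gaussian_overlap: separation (in sigma) for a target overlap."""
    if not 0.0 < overlap <= 1.0:
        raise ValueError("overlap must be in (0, 1]")
    if overlap == 1.0:
        return 0.0
    return float(brentq(lambda d: gaussian_overlap(d) - overlap, 0.0, 100.0, xtol=1e-12))


def sensitivity_sigma(samples_stretched, samples_globular) -> dict:
    """Two-group comparison: means, SDs, pooled SD and sensitivity in sigma units.

    With a vanishing pooled SD the sensitivity is 0 for equal means and
    +inf otherwise.
    """
    s = np.asarray(samples_stretched, dtype=float)
    g = np.asarray(samples_globular, dtype=float)
    pooled = pooled_std(s, g)
    mean_s, mean_g = float(np.mean(s)), float(np.mean(g))
    diff = abs(mean_s - mean_g)
    if pooled == 0.0:
        sens = 0.0 if diff == 0.0 else math.inf
    else:
        sens = diff / pooled
    return {
        "mean_stretched": mean_s,
        "mean_globular": mean_g,
        "sd_stretched": float(np.std(s, ddof=1)),
        "sd_globular": float(np.std(g, ddof=1)),
        "pooled_sd": pooled,
        "sensitivity": sens,
    }


def classify_sensitive(sensitivity: float, threshold: float = SENSITIVITY_THRESHOLD) -> bool:
    """Strictly greater than the threshold (overlap strictly below 10%)."""
    if sensitivity < 0:
        raise ValueError("sensitivity must be non-negative")
    return sensitivity > threshold


def categorize_atom(atom_name: str, element: str) -> str:
    """Map an atom to one of the eight sensitivity categories.

    Oxygen (and any other element outside H/C/N) must be filtered out
    beforehand and raises here.
    """
    element = element.strip().capitalize()
    name = atom_name.strip().upper()
    if element not in ("H", "C", "N"):
        raise SelectionError(
            f"atom {atom_name!r} with element {element!r} has no category; "
            "filter oxygens/cap atoms first"
        )
    if element == "C":
        if name == "CA":
            return "Calpha"
        if name == "C":
            return "Ccarbonyl"
        if name == "CB":
            return "Cbeta"
        return "Cother"
    if element == "N":
        return "Namide" if name == "N" else "Nother"
    return "Hamide" if name in _AMIDE_H_NAMES else "Hother"


def filter_atoms(shift_table: pd.DataFrame) -> pd.DataFrame:
    """Drop cap-group rows and oxygen rows; the removal count is logged."""
    is_cap = shift_table["residue_name"].str.upper().isin(CAP_RESNAMES)
    is_oxygen = shift_table["element"].str.capitalize() == "O"
    removed = int((is_cap | is_oxygen).sum())
    if removed:
        logger.info("filter_atoms: removed %d cap/oxygen rows", removed)
    return shift_table[~(is_cap | is_oxygen)].reset_index(drop=True)


def compute_sensitivity(
    shift_table: pd.DataFrame, threshold: float = SENSITIVITY_THRESHOLD
) -> pd.DataFrame:
    """Per-atom sensitivity records from a canonical (filtered) shift table.

    Atoms are matched across conformers by (residue_number, atom_name); the
    ``group`` column must contain exactly 'stretched' and 'globular'.
    """
    groups = set(shift_table["group"].unique())
    if not {"stretched", "globular"} <= groups:
        raise SelectionError(
            f"shift table must contain both conformation groups, got {sorted(groups)}"
        )
    records = []
    keys = ["residue_number", "residue_name", "atom_name", "element"]
    for (resnum, resname, aname, element), sub in shift_table.groupby(keys, sort=True):
        s = sub.loc[sub["group"] == "stretched", "value_ppm"].to_numpy()
        g = sub.loc[sub["group"] == "globular", "value_ppm"].to_numpy()
        stats = sensitivity_sigma(s, g)
        records.append(
            SensitivityRecord(
                residue_number=int(resnum),
                residue_name=resname,
                atom_name=aname,
                element=element,
                category=categorize_atom(aname, element),
                is_sensitive=classify_sensitive(stats["sensitivity"], threshold),
                **stats,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


BACKBONE_PLUS_CB = {"Calpha", "Ccarbonyl", "Hamide", "Namide", "Cbeta"}


def residue_sensitivity(records: pd.DataFrame, mode: str = "mean") -> float | None:
    """Aggregate one residue's atom sensitivities to a per-residue value.

    mode 'mean': arithmetic mean over backbone atoms plus Cbeta;
    mode 'single:<atom_name>': that atom's sensitivity alone.
    Returns None when no qualifying atom exists.
    """
    if mode == "mean":
        sub = records[records["category"].isin(BACKBONE_PLUS_CB)]
    elif mode.startswith("single:"):
        sub = records[records["atom_name"] == mode.split(":", 1)[1]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if sub.empty:
        return None
    return float(sub["sensitivity"].mean())


def agreement_matrix(
    per_method_flags: pd.DataFrame, vote_threshold: int = VOTE_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series, list[tuple[int, str]]]:
    """Cross-method agreement on per-atom sensitivity.

    ``per_method_flags`` needs columns method, residue_number, atom_name,
    is_sensitive.  Returns the atoms-by-methods matrix (True/False/NaN for
    not-computed), the per-atom vote counts, and the list of atoms whose
    sensitive votes reach the threshold.
    """
    required = {"method", "residue_number", "atom_name", "is_sensitive"}
    if not required <= set(per_method_flags.columns):
        raise JoinError(f"flags table needs columns {sorted(required)}")
    dup = per_method_flags.duplicated(["method", "residue_number", "atom_name"])
    if dup.any():
        raise JoinError("conflicting duplicate atom identities within a method")
    matrix = per_method_flags.pivot(
        index=["residue_number", "atom_name"], columns="method", values="is_sensitive"
    )
    votes = matrix.apply(lambda row: int((row == True).sum()), axis=1)  # noqa: E712
    flagged = [tuple(ix) for ix in votes[votes >= vote_threshold].index]
    return matrix, votes, flagged
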