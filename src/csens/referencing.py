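"""Shielding-to-shift referencing and per-fragment shift assembly.

1H/13C shieldings are referenced against a method-matched computed TMS
shielding; 15N shieldings use a secondary-standard scheme through
methylamine, anchored to the literature absolute shieldings of liquid
ammonia (244.6 ppm) and methylamine (249.5 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from csens.errors import CoverageError, ReferencingError

#: canonical long-format shift table schema consumed by all downstream modules
SHIFT_COLUMNS = [
    "method",
    "conformer_id",
    "group",
    "residue_number",
    "residue_name",
    "atom_name",
    "element",
    "value_ppm",
]

SIGMA_NH3_LIT = 244.6
SIGMA_CH3NH2_LIT = 249.5


@dataclass(frozen=True)
class ReferenceConstants:
    """Method-matched computed reference shieldings plus literature anchors (ppm)."""

    sigma_tms_h: float
    sigma_tms_c: float
    sigma_ch3nh2_calc: float
    sigma_nh3_lit: float = SIGMA_NH3_LIT
    sigma_ch3nh2_lit: float = SIGMA_CH3NH2_LIT


def shift_from_shielding_hc(sigma_x: float, sigma_tms_calc: float) -> float:
    """delta = sigma_TMS(calc) - sigma_X, for 1H and 13C nuclei."""
    return sigma_tms_calc - sigma_x


def shift_from_shielding_n(sigma_x: float, constants: ReferenceConstants) -> float:
    """15N referencing via the methylamine secondary standard.

    The computed methylamine shielding plays the role of the reference,
    shifted onto the liquid-ammonia scale by the fixed literature offset
    (sigma_NH3_lit - sigma_CH3NH2_lit = -4.9 ppm with the default anchors):

        delta = sigma_CH3NH2(calc) - sigma_X + (sigma_NH3_lit - sigma_CH3NH2_lit)
    """
    offset = constants.sigma_nh3_lit - constants.sigma_ch3nh2_lit
    return constants.sigma_ch3nh2_calc - sigma_x + offset


def shift_from_shielding(sigma_x: float, element: str, constants: ReferenceConstants) -> float:
    """Dispatch referencing by element (H, C via TMS; N via methylamine)."""
    element = element.strip().capitalize()
    if element == "H":
        return shift_from_shielding_hc(sigma_x, constants.sigma_tms_h)
    if element == "C":
        return shift_from_shielding_hc(sigma_x, constants.sigma_tms_c)
    if element == "N":
        return shift_from_shielding_n(sigma_x, constants)
    raise ReferencingError(f"no referencing scheme for element {element!r}")


def reference_table(shielding_df: pd.DataFrame, constants: ReferenceConstants) -> pd.DataFrame:
    """Convert a shielding table (canonical schema, value_ppm = sigma) to shifts.

    Rows whose element has no referencing scheme (e.g. oxygen) are dropped;
    they are excluded from all downstream analysis anyway.
    """
    supported = shielding_df["element"].str.capitalize().isin(["H", "C", "N"])
    df = shielding_df[supported].copy()
    df["value_ppm"] = [
        shift_from_shielding(sigma, el, constants)
        for sigma, el in zip(df["value_ppm"], df["element"])
    ]
    return df


# ---------------------------------------------------------------------------
# assembly of per-fragment central-residue shifts
# ---------------------------------------------------------------------------

def assemble_peptide_shifts(
    fragment_tables: Sequence[tuple[int, pd.DataFrame]]
) -> pd.DataFrame:
    """Combine per-fragment shift tables, keeping each atom's value from the
    fragment in which its residue was central.

    ``fragment_tables`` is a sequence of (central_unit, table) pairs; every
    residue appearing in the output must be central in exactly one fragment.
    """
    seen: dict[int, pd.DataFrame] = {}
    for central, table in fragment_tables:
        if central in seen:
            raise CoverageError(f"residue {central} is central in more than one fragment")
        seen[central] = table
    parts = []
    for central, table in sorted(seen.items()):
        rows = table[table["residue_number"] == central]
        if rows.empty:
            raise CoverageError(
                f"fragment with central residue {central} carries no rows for it"
            )
        parts.append(rows)
    out = pd.concat(parts, ignore_index=True)
    keys = out[["conformer_id", "residue_number", "atom_name"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise CoverageError("duplicate (conformer, atom) keys after assembly")
    return out.sort_values(
        ["conformer_id", "residue_number", "atom_name"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# canonical CSV I/O
# ---------------------------------------------------------------------------

def read_shift_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing columns: {missing}")
    df["residue_number"] = df["residue_number"].astype(int)
    return df


def write_shift_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in SHIFT_COLUMNS if c in df.columns])


def read_reference_constants(path, method: str | None = None) -> ReferenceConstants:
    """Read a per-method reference-constants CSV.

    Expected columns: method, sigma_tms_h, sigma_tms_c, sigma_ch3nh2_calc
    and optionally sigma_nh3_lit / sigma_ch3nh2_lit overrides.
    """
    df = pd.read_csv(path)
    if method is not None:
        df = df[df["method"] == method]
    if df.empty:
        raise ReferencingError(f"no reference constants for method {method!r}")
    row = df.iloc[0]
    kwargs = dict(
        sigma_tms_h=float(row["sigma_tms_h"]),
        sigma_tms_c=float(row["sigma_tms_c"]),
        sigma_ch3nh2_calc=float(row["sigma_ch3nh2_calc"]),
    )
    for opt in ("sigma_nh3_lit", "sigma_ch3nh2_lit"):
        if opt in df.columns and not pd.isna(row[opt]):
            kwargs[opt] = float(row[opt])
    return ReferenceConstants(**kwargs)
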