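"""Validation against experiment and secondary-chemical-shift analysis."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from csens.errors import JoinError

#: |delta-delta| beyond which a residue is called alpha/beta rather than coil
IDENTIFIER_THRESHOLD = 1.0

ATOM_KEY = ["residue_number", "atom_name"]


def ensemble_mean(shift_table: pd.DataFrame) -> pd.DataFrame:
    """Per-atom mean shift over all conformers in a canonical shift table."""
    return (
        shift_table.groupby(ATOM_KEY, as_index=False)["value_ppm"]
        .mean()
        .rename(columns={"value_ppm": "value_sim_mean"})
    )


def mean_relative_error(exp_table: pd.DataFrame, shift_table: pd.DataFrame) -> float:
    """Mean over joined atoms of |sim_mean - exp| / |exp|.

    The simulated value is the mean over the conformers supplied.  Atoms
    with a zero experimental shift are excluded with a warning.
    """
    sim = ensemble_mean(shift_table)
    exp = exp_table.rename(columns={"value_ppm": "value_exp"})
    joined = exp.merge(sim, on=ATOM_KEY, how="inner")
    if joined.empty:
        raise JoinError("experimental and simulated tables share no atoms")
    zero = joined["value_exp"] == 0.0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} atoms with zero experimental shift")
        joined = joined[~zero]
    rel = np.abs(joined["value_sim_mean"] - joined["value_exp"]) / np.abs(joined["value_exp"])
    return float(rel.mean())


def mean_relative_error_by_element(
    exp_table: pd.DataFrame, shift_table: pd.DataFrame
) -> dict[str, float]:
    """Per-element MRE breakdown (1H shifts near 0 ppm inflate the pooled number)."""
    out = {}
    for element, sub in exp_table.groupby("element"):
        atoms = sub[ATOM_KEY]
        sim_sub = shift_table.merge(atoms, on=ATOM_KEY)
        if sim_sub.empty:
            continue
        out[element] = mean_relative_error(sub, sim_sub)
    return out


def secondary_shift(delta_obs: float | None, delta_rc: float | None) -> float | None:
    """Secondary chemical shift: observed minus random-coil value."""
    if delta_obs is None or delta_rc is None:
        return None
    return delta_obs - delta_rc


def secondary_structure_identifier(
    dd_ca: float | None,
    dd_cb: float | None,
    threshold: float = IDENTIFIER_THRESHOLD,
) -> tuple[float | None, str | None]:
    """Identifier dd_Ca - dd_Cb and its alpha/beta/coil call.

    Positive values beyond the threshold indicate alpha structure, negative
    ones beta; glycine (no Cbeta) yields (None, None).
    """
    if dd_ca is None or dd_cb is None:
        return None, None
    ident = dd_ca - dd_cb
    if ident > threshold:
        call = "alpha-indication"
    elif ident < -threshold:
        call = "beta-indication"
    else:
        call = "random-coil"
    return ident, call


def secondary_shift_table(
    obs_table: pd.DataFrame,
    rc_table: pd.DataFrame,
    threshold: float = IDENTIFIER_THRESHOLD,
) -> pd.DataFrame:
    """Per-residue secondary shifts and structure calls.

    ``obs_table``: canonical shift table (or any table with residue_number,
    atom_name, value_ppm) — multiple conformers are averaged.  ``rc_table``:
    random-coil values with residue_number, atom_name, value_ppm.
    """
    obs = (
        obs_table.groupby(ATOM_KEY, as_index=False)["value_ppm"].mean()
        if "conformer_id" in obs_table.columns
        else obs_table[ATOM_KEY + ["value_ppm"]]
    )
    rc = rc_table.rename(columns={"value_ppm": "value_rc"})
    joined = obs.merge(rc[ATOM_KEY + ["value_rc"]], on=ATOM_KEY, how="inner")
    joined["delta"] = joined["value_ppm"] - joined["value_rc"]

    rows = []
    for resnum, sub in joined.groupby("residue_number"):
        by_name = dict(zip(sub["atom_name"], sub["delta"]))
        dd_ca = by_name.get("CA")
        dd_cb = by_name.get("CB")
        ident, call = secondary_structure_identifier(dd_ca, dd_cb, threshold)
        rows.append(
            {
                "residue_number": int(resnum),
                "delta_ca": dd_ca,
                "delta_cb": dd_cb,
                "identifier": ident,
                "call": call,
            }
        )
    return pd.DataFrame(rows)
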