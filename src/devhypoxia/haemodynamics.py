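"""Haemodynamic derivations for a single-ventricle (chelonian) circulation.

From 5-min-window channel means — one flow probe on the right-aorta
bundle (right aorta + both subclavians + right carotid), separate probes
on the left aorta, left carotid and left pulmonary artery, plus
ventricular pressure — the derived variables are:

* systemic flow   Q_sys = right bundle + left aorta + left carotid
* pulmonary flow  Q_pul = 2 x left pulmonary (left/right assumed equal)
* total flow      Q_tot = Q_sys + Q_pul
* stroke volumes  V_s = Q / fH                           (per circuit)
* net shunt       Q_shunt = Q_pul - Q_sys  (negative = right-to-left)
* shunt ratio     Q_frac = Q_pul / Q_sys
* mean ventricular pressure  P_vent = (P_sys + 2 P_dia) / 3
* cardiac power output       PO = Q_tot * (P_sys - P_dia) / heart mass,
  with Q_tot in mL s^-1 and pressures in kPa so PO is in mW g^-1.

Flows are mL min^-1, heart rate beats min^-1, pressures kPa, heart mass g.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CHANNEL_COLUMNS = (
    "heart_rate",
    "q_right_aorta_bundle",
    "q_left_aorta",
    "q_left_carotid",
    "q_left_pulmonary",
    "p_systolic",
    "p_diastolic",
)

DERIVED_COLUMNS = (
    "q_sys", "q_pul", "q_tot",
    "vs_sys", "vs_pul", "vs_tot",
    "q_shunt", "q_fractional",
    "p_vent", "delta_p", "power_output",
)


def derive_state(channels: pd.DataFrame, heart_mass: float) -> pd.DataFrame:
    """Derive haemodynamic variables from per-window channel means.

    Rows with heart rate <= 0 get undefined stroke volumes and rows with
    zero systemic flow get an undefined shunt ratio; both are flagged in
    boolean ``undefined_*`` columns rather than raising.
    """
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise ValueError(f"missing channel columns: {missing}")
    if heart_mass <= 0:
        raise ValueError("heart mass must be positive")
    if (channels["p_systolic"] < channels["p_diastolic"]).any():
        raise ValueError("systolic pressure below diastolic pressure")

    out = channels.copy()
    out["q_sys"] = (
        out["q_right_aorta_bundle"] + out["q_left_aorta"] + out["q_left_carotid"]
    )
    out["q_pul"] = 2.0 * out["q_left_pulmonary"]
    out["q_tot"] = out["q_sys"] + out["q_pul"]

    fh = out["heart_rate"].to_numpy(dtype=float)
    fh_ok = fh > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for circuit in ("sys", "pul", "tot"):
            out[f"vs_{circuit}"] = np.where(
                fh_ok, out[f"q_{circuit}"] / np.where(fh_ok, fh, 1.0), np.nan
            )
    out["undefined_stroke_volume"] = ~fh_ok

    out["q_shunt"] = out["q_pul"] - out["q_sys"]
    qs = out["q_sys"].to_numpy(dtype=float)
    qs_ok = qs != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["q_fractional"] = np.where(qs_ok, out["q_pul"] / np.where(qs_ok, qs, 1.0), np.nan)
    out["undefined_shunt_fraction"] = ~qs_ok

    out["p_vent"] = (out["p_systolic"] + 2.0 * out["p_diastolic"]) / 3.0
    out["delta_p"] = out["p_systolic"] - out["p_diastolic"]
    # mL min^-1 -> mL s^-1; kPa * mL s^-1 = mW
    out["power_output"] = (out["q_tot"] / 60.0) * out["delta_p"] / heart_mass
    return out


def percent_change_from_baseline(
    states: pd.DataFrame,
    baseline_window,
    variables=DERIVED_COLUMNS + ("heart_rate",),
    animal_col: str = "animal",
    window_col: str = "window",
    group_col: str | None = "group",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-animal percent change of each variable relative to a baseline
    window, with group mean +/- SEM summaries.

    Returns (per-animal long table, group summary or None).  Variables
    with zero baseline are left undefined (NaN) and flagged.
    """
    variables = [v for v in variables if v in states.columns]
    base = states[states[window_col] == baseline_window].set_index(animal_col)
    if base.empty:
        raise ValueError(f"no rows for baseline window {baseline_window!r}")
    rows = []
    for _, r in states.iterrows():
        animal = r[animal_col]
        for v in variables:
            b = base.loc[animal, v]
            ok = np.isfinite(b) and b != 0
            pct = 100.0 * (r[v] - b) / b if ok else np.nan
            rows.append(
                {
                    animal_col: animal,
                    window_col: r[window_col],
                    **({group_col: r[group_col]} if group_col and group_col in states else {}),
                    "variable": v,
                    "pct_change": pct,
                    "undefined_baseline": not ok,
                }
            )
    long = pd.DataFrame(rows)
    summary = None
    if group_col and group_col in long.columns:
        g = long.groupby([group_col, window_col, "variable"])["pct_change"]
        summary = g.agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(x.notna().sum()) if x.notna().sum() > 1 else np.nan,
            n="count",
        ).reset_index()
    return long, summary


def heart_body_ratio(heart_mass_g: float, body_mass_g: float) -> float:
    """Heart-to-body-mass ratio as a percentage, to 2 decimals."""
    if heart_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("masses must be positive")
    return round(100.0 * heart_mass_g / body_mass_g, 2)
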