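"""Differential-sensitivity compound ranking and viability screen processing.

Given predicted pIC50 values for two cell lines over a compound library, the
prioritisation score is Δ = pIC50(line A) − pIC50(line B): Δ = 2 means a
100-fold predicted potency preference for line A.  Calls are categorical —
|Δ| > 2 preferential, |Δ| < 1 none, the band between indeterminate — and
candidate sets pair the strongest preferential compounds with no-preference
controls for validation screens.

Plate-reader post-processing uses percent-of-control viability:
%V = (sample − mean positive control) / (mean negative control − mean
positive control) × 100, where the positive control is fully killed and the
negative control is vehicle only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRONG_CUT = 2.0
NONE_CUT = 1.0

PLATE_ROLES = ("sample", "pos_ctrl", "neg_ctrl", "vehicle")


@dataclass
class PreferenceCall:
    """Per-drug differential-sensitivity call between two cell lines."""

    drug_id: str
    delta: float
    category: str  # A_preferential | B_preferential | none | indeterminate
    strong_cut: float = STRONG_CUT
    none_cut: float = NONE_CUT


def differential_activity(pred_a: dict[str, float], pred_b: dict[str, float]
                          ) -> pd.Series:
    """Δ = pIC50(A) − pIC50(B) per drug, sorted descending.

    Drugs missing from either prediction set are excluded with a warning.
    """
    common = [d for d in pred_a if d in pred_b]
    dropped = (set(pred_a) | set(pred_b)) - set(common)
    if dropped:
        warnings.warn(f"{len(dropped)} drugs missing in one line; excluded: "
                      f"{sorted(dropped)[:5]}...")
    if not common:
        raise ValueError("no drugs shared between the two prediction sets")
    s = pd.Series({d: float(pred_a[d]) - float(pred_b[d]) for d in common})
    return s.sort_values(ascending=False, kind="stable")


def categorize_preference(delta: float, drug_id: str = "",
                          strong_cut: float = STRONG_CUT,
                          none_cut: float = NONE_CUT) -> PreferenceCall:
    """Categorise a differential-activity value.

    |Δ| > strong_cut → preferential toward the more sensitive line;
    |Δ| < none_cut → no preference; the band in between → indeterminate.
    """
    delta = float(delta)
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    if abs(delta) > strong_cut:
        cat = "A_preferential" if delta > 0 else "B_preferential"
    elif abs(delta) < none_cut:
        cat = "none"
    else:
        cat = "indeterminate"
    return PreferenceCall(str(drug_id), delta, cat, strong_cut, none_cut)


def select_for_validation(calls: list[PreferenceCall], n_top: int = 4,
                          n_controls: int = 2) -> list[PreferenceCall]:
    """Validation candidates: strongest differential compounds plus controls.

    Top ``n_top`` by Δ (descending, id tie-break) plus ``n_controls`` drawn
    from the "none" category, lowest |Δ| first.  If too few "none" calls
    exist, the remainder fills from the lowest-|Δ| leftover calls with a
    warning.
    """
    if len(calls) < n_top + n_controls:
        raise ValueError(f"need at least {n_top + n_controls} calls")
    ranked = sorted(calls, key=lambda c: (-c.delta, c.drug_id))
    top = ranked[:n_top]
    rest = [c for c in calls if c not in top]
    nones = sorted((c for c in rest if c.category == "none"),
                   key=lambda c: (abs(c.delta), c.drug_id))
    controls = nones[:n_controls]
    if len(controls) < n_controls:
        warnings.warn(f"only {len(controls)} 'none' calls available for "
                      f"{n_controls} controls; filling from lowest |delta|")
        filler = sorted((c for c in rest if c not in controls),
                        key=lambda c: (abs(c.delta), c.drug_id))
        controls += filler[:n_controls - len(controls)]
    return top + controls


def percent_viability(sample_rlu: float, pos_ctrl_mean: float,
                      neg_ctrl_mean: float) -> float:
    """Percent viability from raw luminescence.

    100 at the negative (vehicle) control mean, 0 at the positive (kill)
    control mean; values outside [0, 100] are legitimate.
    """
    if neg_ctrl_mean == pos_ctrl_mean:
        raise ValueError("control means are equal: viability undefined")
    return float((sample_rlu - pos_ctrl_mean)
                 / (neg_ctrl_mean - pos_ctrl_mean) * 100.0)


def screen_summary(plate: pd.DataFrame,
                   randomisation_map: dict[str, str] | None = None,
                   ic50_viability_cut: float = 50.0) -> pd.DataFrame:
    """Per-drug concentration–viability table from a plate-reader long table.

    ``plate`` columns: well, drug_id, concentration_micromolar, rlu, role
    (sample | pos_ctrl | neg_ctrl | vehicle).  ``randomisation_map`` maps
    physical well -> logical well and is applied first (de-randomisation).
    Output: one row per (drug, concentration) with mean viability, plus a
    per-drug flag ``ic50_reached`` — true when any tested concentration drops
    mean viability to or below ``ic50_viability_cut``.
    """
    required = {"well", "drug_id", "concentration_micromolar", "rlu", "role"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    plate = plate.copy()
    if randomisation_map:
        plate["well"] = plate["well"].map(lambda w: randomisation_map.get(w, w))
    bad = set(plate["role"]) - set(PLATE_ROLES)
    if bad:
        raise ValueError(f"unknown plate roles: {sorted(bad)}")
    pos = plate.loc[plate["role"] == "pos_ctrl", "rlu"]
    neg_role = "neg_ctrl" if (plate["role"] == "neg_ctrl").any() else "vehicle"
    neg = plate.loc[plate["role"] == neg_role, "rlu"]
    if pos.empty or neg.empty:
        raise ValueError("plate must contain positive and negative/vehicle "
                         "control wells")
    pos_mean, neg_mean = float(pos.mean()), float(neg.mean())

    samples = plate[plate["role"] == "sample"]
    rows = []
    for (drug, conc), grp in samples.groupby(["drug_id", "concentration_micromolar"]):
        if len(samples[samples["drug_id"] == drug]["concentration_micromolar"].unique()) < 2:
            raise ValueError(f"drug {drug!r} tested at fewer than 2 concentrations")
        via = [percent_viability(r, pos_mean, neg_mean) for r in grp["rlu"]]
        rows.append({"drug_id": drug, "concentration_micromolar": float(conc),
                     "viability_pct": float(np.mean(via)), "n_wells": len(via)})
    out = pd.DataFrame(rows).sort_values(
        ["drug_id", "concentration_micromolar"]).reset_index(drop=True)
    reached = out.groupby("drug_id")["viability_pct"].min() <= ic50_viability_cut
    out["ic50_reached"] = out["drug_id"].map(reached)
    return out
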