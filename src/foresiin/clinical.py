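"""Deterministic clinical formulas and comparator stroke-risk scores.

Implements the MDRD estimated glomerular filtration rate, Devereux left
ventricular mass (and its body-surface-area index), and the two point-based
stroke-risk scores used as comparators in AF cohorts: CHA2DS2-VASc and ATRIA.
Score component definitions follow the original publications (Lip et al. 2010
for CHA2DS2-VASc; Singer et al. 2013 for ATRIA).  All functions are
vectorized over numpy arrays / pandas columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "egfr_mdrd",
    "lvm_devereux",
    "lvm_index",
    "cha2ds2_vasc",
    "atria_score",
    "scores_from_baseline",
]


def _positive(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError(f"{name} must be positive")
    return value


def egfr_mdrd(creatinine, age, female, race_black=False):
    """MDRD eGFR in mL/min/1.73 m2.

    eGFR = 175 * Cr^-1.154 * age^-0.203 * 1.212 (if black) * 0.742 (if female),
    with serum creatinine in mg/dL and age in years.
    """
    cr = _positive("creatinine", creatinine)
    age = _positive("age", age)
    female = np.asarray(female, dtype=bool)
    race_black = np.asarray(race_black, dtype=bool)
    out = 175.0 * cr**-1.154 * age**-0.203
    out = out * np.where(race_black, 1.212, 1.0) * np.where(female, 0.742, 1.0)
    return out if out.ndim else float(out)


def lvm_devereux(lvedd, ivsd, pwd):
    """Devereux left ventricular mass in grams from M-mode dimensions (cm).

    LVM = 0.8 * 1.04 * ((LVEDD + IVSd + PWd)^3 - LVEDD^3) + 0.6
    """
    lvedd = _positive("LVEDD", lvedd)
    ivsd = np.asarray(ivsd, dtype=float)
    pwd = np.asarray(pwd, dtype=float)
    if np.any(ivsd < 0) or np.any(pwd < 0):
        raise ValueError("wall thicknesses must be non-negative")
    out = 0.8 * 1.04 * ((lvedd + ivsd + pwd) ** 3 - lvedd**3) + 0.6
    return out if out.ndim else float(out)


def lvm_index(lvm, bsa):
    """LVM indexed to body surface area (g/m2)."""
    lvm = np.asarray(lvm, dtype=float)
    bsa = _positive("BSA", bsa)
    out = lvm / bsa
    return out if out.ndim else float(out)


_REQUIRED_CHADSVASC = (
    "age", "sex_male", "heart_failure", "hypertension",
    "diabetes", "prior_stroke_tia", "cad", "paod",
)
_REQUIRED_ATRIA = (
    "age", "sex_male", "heart_failure", "hypertension",
    "diabetes", "prior_stroke_tia", "proteinuria", "egfr", "esrd",
)


def _require(baseline: pd.DataFrame, fields) -> None:
    missing = [f for f in fields if f not in baseline.columns]
    if missing:
        raise KeyError(f"baseline table is missing required field(s): {missing}")


def cha2ds2_vasc(baseline: pd.DataFrame) -> np.ndarray:
    """CHA2DS2-VASc score (0-9) per patient.

    Components: CHF 1, hypertension 1, age >= 75 y 2, diabetes 1, prior
    stroke/TIA 2, vascular disease (CAD or PAOD) 1, age 65-74 y 1, female 1.
    The two age categories are mutually exclusive.
    """
    _require(baseline, _REQUIRED_CHADSVASC)
    age = baseline["age"].to_numpy(dtype=float)
    score = (
        baseline["heart_failure"].to_numpy(dtype=int)
        + baseline["hypertension"].to_numpy(dtype=int)
        + 2 * (age >= 75)
        + 1 * ((age >= 65) & (age < 75))
        + baseline["diabetes"].to_numpy(dtype=int)
        + 2 * baseline["prior_stroke_tia"].to_numpy(dtype=int)
        + ((baseline["cad"].to_numpy(dtype=int) | baseline["paod"].to_numpy(dtype=int)))
        + (1 - baseline["sex_male"].to_numpy(dtype=int))
    )
    return score.astype(int)


# ATRIA age points: (lower age bound, points without prior stroke, with prior stroke)
_ATRIA_AGE = [(85, 6, 9), (75, 5, 7), (65, 3, 7), (0, 0, 8)]


def atria_score(baseline: pd.DataFrame) -> np.ndarray:
    """ATRIA stroke-risk score (0-15) per patient.

    Age points depend on prior-stroke status (without / with prior stroke:
    <65 y: 0/8, 65-74: 3/7, 75-84: 5/7, >=85: 6/9); plus 1 point each for
    female sex, diabetes, CHF, hypertension, proteinuria, and
    eGFR < 45 mL/min/1.73 m2 or ESRD.
    """
    _require(baseline, _REQUIRED_ATRIA)
    age = baseline["age"].to_numpy(dtype=float)
    stroke = baseline["prior_stroke_tia"].to_numpy(dtype=int).astype(bool)
    age_pts = np.zeros(len(age), dtype=int)
    assigned = np.zeros(len(age), dtype=bool)
    for lower, pts_no, pts_yes in _ATRIA_AGE:
        sel = (age >= lower) & ~assigned
        age_pts[sel] = np.where(stroke[sel], pts_yes, pts_no)
        assigned |= sel
    renal = (baseline["egfr"].to_numpy(dtype=float) < 45) | (
        baseline["esrd"].to_numpy(dtype=int).astype(bool)
    )
    score = (
        age_pts
        + (1 - baseline["sex_male"].to_numpy(dtype=int))
        + baseline["diabetes"].to_numpy(dtype=int)
        + baseline["heart_failure"].to_numpy(dtype=int)
        + baseline["hypertension"].to_numpy(dtype=int)
        + baseline["proteinuria"].to_numpy(dtype=int)
        + renal.astype(int)
    )
    return score.astype(int)


def scores_from_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Both comparator scores for a baseline table (used as ranking statistics)."""
    return pd.DataFrame(
        {
            "patient_id": baseline["patient_id"],
            "cha2ds2_vasc": cha2ds2_vasc(baseline),
            "atria": atria_score(baseline),
        }
    )
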