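"""Analysis covariates derived from raw participant fields.

Five continuous biomarkers act as markers of underlying (often unrecorded)
comorbidity: estimated glomerular filtration rate (renal impairment), body
mass index (obesity), the FIB-4 index (liver fibrosis), haemoglobin
(anaemia), and mid blood pressure (hypertension).  Age enters the interaction
models scaled to 15-year increments, close to its SD in most trials.

All functions are vectorised over numpy arrays / pandas Series and validate
their physiological preconditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import ValidationError

__all__ = [
    "mid_bp",
    "egfr_mdrd",
    "fib4",
    "bmi",
    "age_units",
    "creatinine_from_umol",
    "derive_biomarkers",
]

#: mg/dL per umol/L for creatinine unit conversion.
_CREAT_UMOL_PER_MGDL = 88.42


def _require_positive(**named) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError(f"{name} must be strictly positive and finite")


def mid_bp(sbp, dbp):
    """Mid blood pressure, 0.5 * (systolic + diastolic), in mmHg."""
    _require_positive(sbp=sbp, dbp=dbp)
    s, d = np.asarray(sbp, dtype=float), np.asarray(dbp, dtype=float)
    if np.any(d > s):
        raise ValidationError("diastolic blood pressure exceeds systolic")
    out = 0.5 * (s + d)
    return float(out) if out.ndim == 0 else out


def egfr_mdrd(creatinine, age, female, black, constant: float = 175.0):
    """Estimated GFR (mL/min/1.73m^2) by the 4-variable MDRD equation.

    ``constant=175`` is the IDMS-traceable recalibration (the original assay
    used 186); the constant is exposed because source trials may predate the
    recalibration.  ``female``/``black`` are 0/1 indicators.
    """
    _require_positive(creatinine=creatinine, age=age)
    cr = np.asarray(creatinine, dtype=float)
    a = np.asarray(age, dtype=float)
    f = np.asarray(female, dtype=float)
    b = np.asarray(black, dtype=float)
    out = (
        constant
        * cr ** (-1.154)
        * a ** (-0.203)
        * np.where(f > 0, 0.742, 1.0)
        * np.where(b > 0, 1.212, 1.0)
    )
    return float(out) if out.ndim == 0 else out


def fib4(age, ast, alt, platelets):
    """FIB-4 liver-fibrosis index: age * AST / (platelets * sqrt(ALT)).

    AST and ALT in U/L, platelets in 10^9/L (the Sterling formulation).
    """
    _require_positive(age=age, ast=ast, alt=alt, platelets=platelets)
    out = (
        np.asarray(age, dtype=float)
        * np.asarray(ast, dtype=float)
        / (np.asarray(platelets, dtype=float) * np.sqrt(np.asarray(alt, dtype=float)))
    )
    return float(out) if out.ndim == 0 else out


def bmi(weight, height):
    """Body mass index, weight (kg) / height (m) squared."""
    _require_positive(weight=weight, height=height)
    out = np.asarray(weight, dtype=float) / np.asarray(height, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def age_units(age, width: float = 15.0, center: float | None = None):
    """Age scaled to ``width``-year increments about ``center``.

    The default width of 15 years matches the typical trial age SD; centering
    (default: the mean of the ages passed in) only shifts the intercept of a
    linear model — interaction slopes are invariant to it.
    """
    if width <= 0:
        raise ValidationError(f"width must be > 0, got {width}")
    a = np.asarray(age, dtype=float)
    if center is None:
        center = float(np.mean(a))
    out = (a - center) / width
    return float(out) if out.ndim == 0 else out


def creatinine_from_umol(creatinine_umol):
    """Convert creatinine from umol/L to mg/dL (divide by 88.42)."""
    _require_positive(creatinine_umol=creatinine_umol)
    out = np.asarray(creatinine_umol, dtype=float) / _CREAT_UMOL_PER_MGDL
    return float(out) if out.ndim == 0 else out


def derive_biomarkers(
    table: pd.DataFrame,
    creatinine_unit: str = "mg/dL",
    mdrd_constant: float = 175.0,
) -> pd.DataFrame:
    """Augment a participant table with derivable biomarker columns.

    Columns are only computed where absent and the required raw fields are
    present: ``egfr`` from creatinine/age/sex/race, ``bmi`` from
    height/weight, ``fib4`` from age/AST/ALT/platelets, and ``mid_bp`` from
    systolic/diastolic pressure.  ``haemoglobin`` is a passthrough
    measurement and is never computed.
    """
    if creatinine_unit not in ("mg/dL", "umol/L"):
        raise ValidationError(f"unknown creatinine unit {creatinine_unit!r}")
    out = table.copy()
    cols = set(out.columns)
    if "egfr" not in cols and {"creatinine", "age", "male"} <= cols:
        cr = out["creatinine"]
        if creatinine_unit == "umol/L":
            cr = creatinine_from_umol(cr)
        black = out["black"] if "black" in cols else np.zeros(len(out))
        out["egfr"] = egfr_mdrd(cr, out["age"], 1 - out["male"], black, mdrd_constant)
    if "bmi" not in cols and {"weight", "height"} <= cols:
        out["bmi"] = bmi(out["weight"], out["height"])
    if "fib4" not in cols and {"age", "ast", "alt", "platelets"} <= cols:
        out["fib4"] = fib4(out["age"], out["ast"], out["alt"], out["platelets"])
    if "mid_bp" not in cols and {"sbp", "dbp"} <= cols:
        out["mid_bp"] = mid_bp(out["sbp"], out["dbp"])
    return out
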