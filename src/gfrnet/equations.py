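"""Traditional creatinine-based GFR estimating equations and CKD staging.

Implements the four serum-creatinine equations routinely used in adult
nephrology — Cockcroft–Gault (1976), the six- and four-variable MDRD
equations (1999), and CKD-EPI (2009) — together with body-surface-area
formulas, unit conversions, and KDOQI CKD staging.  All equations return
GFR in ml/min/1.73 m²; Cockcroft–Gault (which natively estimates raw
creatinine clearance in ml/min) is standardized to 1.73 m² of body
surface.

Every function accepts scalars or numpy arrays (broadcasting applies) and
validates its clinical domain, raising :class:`DomainError` on physically
impossible inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DomainError",
    "PatientRecord",
    "CkdStage",
    "compute_bsa",
    "cockcroft_gault",
    "mdrd6",
    "mdrd4",
    "ckd_epi",
    "ckd_stage",
    "stage_vector",
    "convert_units",
]


class DomainError(ValueError):
    """Raised when an input lies outside its clinically meaningful domain."""


def _is_female(sex) -> np.ndarray:
    """Map sex labels to a boolean female indicator.

    Accepts 'M'/'F', 'male'/'female' (any case), or 0/1 numeric coding
    where male = 1 and female = 0 (the network's dummy coding).
    """
    arr = np.asarray(sex)
    if arr.dtype.kind in "ifb":
        return np.asarray(arr == 0)
    s = np.char.upper(np.asarray(arr, dtype=str))
    female = np.isin(s, ("F", "FEMALE"))
    male = np.isin(s, ("M", "MALE"))
    if not np.all(female | male):
        bad = np.asarray(arr)[~(female | male)]
        raise DomainError(f"unrecognized sex label(s): {np.unique(bad)!r}")
    return female


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be finite and strictly positive")
    return arr


@dataclass
class PatientRecord:
    """One subject's covariates plus optional reference GFR.

    Units: age in years, height in cm, weight in kg, sc (serum creatinine)
    in mg/dL, sun (serum urea nitrogen) in mg/dL, alb (serum albumin) in
    g/dL, sgfr (reference GFR) in ml/min/1.73 m².
    """

    age: float
    sex: str
    height: float
    weight: float
    sc: float
    sun: float
    alb: Optional[float] = None
    sgfr: Optional[float] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise DomainError(f"age must be >= 18 years, got {self.age}")
        for name in ("age", "height", "weight", "sc", "sun"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and positive, got {v}")
        if self.alb is not None and (not np.isfinite(self.alb) or self.alb <= 0):
            raise DomainError(f"alb must be finite and positive, got {self.alb}")
        if self.sgfr is not None and not (0 < self.sgfr < 200):
            raise DomainError(f"sgfr must lie in (0, 200), got {self.sgfr}")
        _is_female(self.sex)  # validates the label


@dataclass(frozen=True)
class CkdStage:
    """KDOQI CKD stage (1-5) with the combined label used for sparse tails."""

    stage: int
    combined_label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4, 5):
            raise DomainError(f"stage must be 1-5, got {self.stage}")
        label = {1: "1-2", 2: "1-2", 3: "3", 4: "4-5", 5: "4-5"}[self.stage]
        object.__setattr__(self, "combined_label", label)


def compute_bsa(height, weight, formula: str = "dubois"):
    """Body-surface area in m².

    Du Bois & Du Bois (default): 0.007184 · H^0.725 · W^0.425 with H in cm
    and W in kg.  Mosteller: sqrt(H·W/3600).
    """
    h = np.asarray(height, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(~np.isfinite(h)) or np.any((h <= 50) | (h >= 250)):
        raise DomainError("height must lie in (50, 250) cm")
    if np.any(~np.isfinite(w)) or np.any((w <= 20) | (w >= 250)):
        raise DomainError("weight must lie in (20, 250) kg")
    if formula == "dubois":
        out = 0.007184 * h**0.725 * w**0.425
    elif formula == "mosteller":
        out = np.sqrt(h * w / 3600.0)
    else:
        raise ValueError(f"unknown BSA formula {formula!r}")
    return out if out.ndim else float(out)


def cockcroft_gault(age, weight, sc, sex, bsa=None, *, standardize: bool = True):
    """Cockcroft–Gault creatinine clearance, standardized to 1.73 m² BSA.

    (140 − age) · weight / (72 · SC), ×0.85 if female; when ``standardize``
    the raw ml/min value is scaled by 1.73/BSA so that all estimators share
    the ml/min/1.73 m² scale.  ``bsa`` is required when standardizing.
    """
    a = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 18):
        raise DomainError("age must be finite and >= 18")
    if np.any(a >= 140):
        raise DomainError("age must be < 140 years (Cockcroft-Gault numerator)")
    w = _require_positive("weight", weight)
    scr = _require_positive("sc", sc)
    female = _is_female(sex)
    out = (140.0 - a) * w / (72.0 * scr)
    out = np.where(female, 0.85 * out, out)
    if standardize:
        if bsa is None:
            raise DomainError("bsa is required to standardize Cockcroft-Gault output")
        b = _require_positive("bsa", bsa)
        out = out * 1.73 / b
    return out if np.ndim(out) else float(out)


def mdrd6(sc, age, sex, sun, alb, *, black: bool = False):
    """Six-variable MDRD equation (original 1999 coefficients).

    170 · SC^−0.999 · age^−0.176 · SUN^−0.170 · Alb^0.318, ×0.762 if
    female, ×1.180 if black (off by default; cohorts here are Chinese).
    """
    scr = _require_positive("sc", sc)
    a = _require_positive("age", age)
    u = _require_positive("sun", sun)
    al = _require_positive("alb", alb)
    female = _is_female(sex)
    out = 170.0 * scr**-0.999 * a**-0.176 * u**-0.170 * al**0.318
    out = np.where(female, 0.762 * out, out)
    if black:
        out = out * 1.180
    return out if np.ndim(out) else float(out)


def mdrd4(sc, age, sex, *, dialect: str = "original", black: bool = False):
    """Four-variable MDRD equation.

    ``dialect='original'`` (default): 186 · SC^−1.154 · age^−0.203, ×0.742
    if female, ×1.212 if black.  ``dialect='idms'`` substitutes the 175
    coefficient re-expressed for IDMS-traceable creatinine assays.
    """
    coeff = {"original": 186.0, "idms": 175.0}.get(dialect)
    if coeff is None:
        raise ValueError(f"unknown MDRD dialect {dialect!r} (use 'original' or 'idms')")
    scr = _require_positive("sc", sc)
    a = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 18):
        raise DomainError("age must be finite and >= 18")
    female = _is_female(sex)
    out = coeff * scr**-1.154 * a**-0.203
    out = np.where(female, 0.742 * out, out)
    if black:
        out = out * 1.212
    return out if np.ndim(out) else float(out)


def ckd_epi(sc, age, sex, *, black: bool = False):
    """CKD-EPI 2009 creatinine equation.

    141 · min(SC/κ, 1)^α · max(SC/κ, 1)^−1.209 · 0.993^age, ×1.018 if
    female (×1.159 if black, default off), with κ = 0.7 (F) / 0.9 (M) and
    α = −0.329 (F) / −0.411 (M).  Continuous in SC at the κ breakpoint.
    """
    scr = _require_positive("sc", sc)
    a = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 18):
        raise DomainError("age must be finite and >= 18")
    female = _is_female(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**a
    )
    out = np.where(female, 1.018 * out, out)
    if black:
        out = out * 1.159
    return out if np.ndim(out) else float(out)


# KDOQI stage bands, lower-inclusive so that the <60 and <15 diagnostic
# thresholds are exact complements of stages {1,2} and {1..4}.
_STAGE_EDGES = (90.0, 60.0, 30.0, 15.0)


def ckd_stage(gfr) -> CkdStage:
    """KDOQI CKD stage for one GFR value (ml/min/1.73 m²)."""
    g = float(gfr)
    if not np.isfinite(g) or g < 0:
        raise DomainError(f"gfr must be finite and >= 0, got {gfr}")
    return CkdStage(int(stage_vector(g)))


def stage_vector(gfr) -> np.ndarray:
    """Vectorized stage numbers (1-5) for an array of GFR values."""
    g = np.asarray(gfr, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g < 0):
        raise DomainError("gfr values must be finite and >= 0")
    stage = np.full(g.shape, 5, dtype=int)
    stage[g >= _STAGE_EDGES[3]] = 4
    stage[g >= _STAGE_EDGES[2]] = 3
    stage[g >= _STAGE_EDGES[1]] = 2
    stage[g >= _STAGE_EDGES[0]] = 1
    return stage


# Conversion factors to mg/dL from the conventional SI units:
# creatinine 113.12 g/mol (µmol/L -> mg/dL divides by 88.4);
# urea carries 2 N of 14.007 g/mol, so 1 mmol/L urea = 2.8014 mg/dL SUN.
_CONVERSIONS = {"creatinine": 1.0 / 88.4, "urea_nitrogen": 2.8014}


def convert_units(value, quantity: str, direction: str = "to_mg_dl"):
    """Convert creatinine (µmol/L) or urea nitrogen (mmol/L urea) to/from mg/dL.

    ``direction`` is ``'to_mg_dl'`` or ``'from_mg_dl'``; round-trips are
    exact to floating-point.
    """
    if quantity not in _CONVERSIONS:
        raise ValueError(
            f"unknown quantity {quantity!r}; expected one of {sorted(_CONVERSIONS)}"
        )
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise DomainError(f"{quantity} concentration must be >= 0")
    factor = _CONVERSIONS[quantity]
    if direction == "to_mg_dl":
        out = v * factor
    elif direction == "from_mg_dl":
        out = v / factor
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out if np.ndim(out) else float(out)
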