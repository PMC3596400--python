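"""Variable encoding, min-max normalization, and cohort splitting.

Raw covariates live on incommensurate scales (creatinine in units of
mg/dL, height in cm, ...), so every network input and the GFR target are
min-max scaled into [0, 1] before training; gender is dummy-coded
(male = 1, female = 0) and pinned to the (0, 1) range.  Normalization
ranges are fit on the development cohort with a configurable padding
margin and stored inside every saved model, so a deployed estimator is
self-contained.  All stored minima are floored at 0 — negative
concentrations, ages or GFRs are physically meaningless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .equations import _is_female
from .io import OUTPUT_VARIABLE, variable_column

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationSpec",
    "OutOfRangeWarning",
    "fit_normalization",
    "normalize_frame",
    "denormalize_output",
    "split_cohort",
]


class OutOfRangeWarning(UserWarning):
    """A prediction-time value fell outside the fitted range and was clamped."""


@dataclass
class NormalizationSpec:
    """Per-variable (min, max) ranges mapping raw values onto [0, 1]."""

    variables: List[str]
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo < 0:
                raise ValueError(f"normalization minimum for {name} is negative ({lo})")
            if not hi > lo:
                raise ValueError(f"degenerate range for {name}: max ({hi}) must exceed min ({lo})")
        missing = [v for v in self.variables if v not in self.ranges]
        if missing:
            raise ValueError(f"spec lacks ranges for variables: {missing}")

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "ranges": {k: [float(lo), float(hi)] for k, (lo, hi) in self.ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(
            variables=list(d["variables"]),
            ranges={k: (float(v[0]), float(v[1])) for k, v in d["ranges"].items()},
        )


def fit_normalization(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    padding_fraction: float = 0.1,
) -> NormalizationSpec:
    """Fit per-variable min-max ranges on a cohort.

    Ranges are widened by ``padding_fraction`` on each side (min scaled by
    1−p, max by 1+p) so moderate distribution shift at prediction time
    stays inside the scale; minima are floored at 0.  Gender is fixed to
    (0, 1).  A variable constant across the cohort has no usable range and
    raises ``ValueError``.
    """
    if len(cohort) == 0:
        raise ValueError("cannot fit normalization on an empty cohort")
    if padding_fraction < 0:
        raise ValueError("padding_fraction must be >= 0")
    ranges: Dict[str, Tuple[float, float]] = {}
    for var in variables:
        if var == "gender":
            ranges[var] = (0.0, 1.0)
            continue
        col = variable_column(var)
        if col not in cohort.columns:
            raise ValueError(f"variable {var!r} (column {col!r}) absent from cohort")
        values = np.asarray(cohort[col], dtype=float)
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi == lo:
            raise ValueError(f"variable {var!r} is constant ({lo}); degenerate range")
        ranges[var] = (max(0.0, lo * (1.0 - padding_fraction)), hi * (1.0 + padding_fraction))
    return NormalizationSpec(variables=list(variables), ranges=ranges)


def _scale(values: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    scaled = (values - lo) / (hi - lo)
    out = np.clip(scaled, 0.0, 1.0)
    n_out = int(np.sum((scaled < 0) | (scaled > 1)))
    if n_out:
        warnings.warn(
            f"{n_out} value(s) of {what} outside fitted range [{lo:g}, {hi:g}]; clamped",
            OutOfRangeWarning,
            stacklevel=3,
        )
        logger.warning("clamped %d out-of-range value(s) for %s", n_out, what)
    return out


def normalize_frame(
    cohort: pd.DataFrame,
    spec: NormalizationSpec,
    variables: Sequence[str] | None = None,
) -> np.ndarray:
    """Encode a cohort as an (n, d) feature matrix of [0, 1] values.

    Gender maps M→1, F→0; other variables are min-max scaled with
    clamping (and a logged :class:`OutOfRangeWarning`) outside the fitted
    range.
    """
    variables = list(variables) if variables is not None else list(spec.variables)
    missing = [v for v in variables if v not in spec.ranges]
    if missing:
        raise ValueError(f"normalization spec does not cover: {missing}")
    cols = []
    for var in variables:
        col = variable_column(var)
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks column {col!r} for variable {var!r}")
        raw = cohort[col]
        if raw.isna().any():
            bad = cohort.loc[raw.isna(), "id"].tolist() if "id" in cohort else list(raw[raw.isna()].index)
            raise ValueError(f"missing {var!r} for record(s) {bad[:5]}")
        if var == "gender":
            cols.append((~_is_female(raw.to_numpy())).astype(float))
        else:
            lo, hi = spec.ranges[var]
            cols.append(_scale(np.asarray(raw, dtype=float), lo, hi, var))
    return np.column_stack(cols)


def normalize_target(cohort: pd.DataFrame, spec: NormalizationSpec) -> np.ndarray:
    """Scale the reference GFR column onto [0, 1] using the output range."""
    lo, hi = spec.ranges[OUTPUT_VARIABLE]
    return _scale(np.asarray(cohort[OUTPUT_VARIABLE], dtype=float), lo, hi, OUTPUT_VARIABLE)


def denormalize_output(y_scaled, spec: NormalizationSpec):
    """Map scaled network output back to ml/min/1.73 m² (inverse of normalize)."""
    if OUTPUT_VARIABLE not in spec.ranges:
        raise ValueError("spec does not contain the output variable range")
    lo, hi = spec.ranges[OUTPUT_VARIABLE]
    out = np.asarray(y_scaled, dtype=float) * (hi - lo) + lo
    return out if np.ndim(out) else float(out)


def split_cohort(
    cohort: pd.DataFrame, n_development: int, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition a cohort into development and internal-validation sets.

    Deterministic for a fixed seed and independent of the input row order
    (rows are ranked by a per-id hash-free permutation of the sorted ids).
    """
    n = len(cohort)
    if not 0 < n_development < n:
        raise ValueError(f"n_development must be in (0, {n}), got {n_development}")
    order = np.argsort(np.asarray(cohort["id"], dtype=str), kind="stable")
    perm = np.random.default_rng(seed).permutation(n)
    dev_pos = order[perm[:n_development]]
    val_pos = order[perm[n_development:]]
    dev = cohort.iloc[np.sort(dev_pos)].reset_index(drop=True)
    val = cohort.iloc[np.sort(val_pos)].reset_index(drop=True)
    return dev, val
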