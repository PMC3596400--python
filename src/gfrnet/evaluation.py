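"""Method-comparison statistics for GFR estimators.

Everything needed to compare an estimator against the reference GFR and
against another estimator: Bland–Altman limits of agreement with the
difference-on-average regression, tolerance accuracy (P15/P30/P50),
CKD-staging concordance, and the paired tests (Wilcoxon signed-rank,
continuity-corrected McNemar, ANCOVA-style slope/intercept comparison).

Conventions: the difference is always estimate minus reference
(d = eGFR − sGFR); percent deviation is relative to the reference;
precision is the width between the 95% limits of agreement
(3.92 · SD of d), with 60 ml/min/1.73 m² as the prior acceptable
tolerance; percentiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .equations import stage_vector

__all__ = [
    "AgreementSummary",
    "AccuracySummary",
    "ConcordanceSummary",
    "bland_altman",
    "accuracy_summary",
    "staging_concordance",
    "compare_models",
    "metrics_table",
]

PRECISION_TOLERANCE = 60.0  # ml/min/1.73 m², prior acceptable precision
_LOA_MULTIPLIER = 1.96


def _validate_pair(egfr, sgfr, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    e = np.asarray(egfr, dtype=float).ravel()
    s = np.asarray(sgfr, dtype=float).ravel()
    if e.size != s.size:
        raise ValueError("eGFR and sGFR vectors must have equal length")
    if e.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations, got {e.size}")
    if np.any(~np.isfinite(e)) or np.any(~np.isfinite(s)):
        raise ValueError("eGFR and sGFR must be finite")
    if np.any(s <= 0):
        raise ValueError("reference GFR values must be strictly positive")
    return e, s


@dataclass
class AgreementSummary:
    """Bland–Altman agreement of one estimator against the reference."""

    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    precision: float
    precision_acceptable: bool
    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    intercept_ci: Tuple[float, float]
    residual_loa: Tuple[float, float]


def bland_altman(egfr, sgfr) -> AgreementSummary:
    """Limits of agreement and the difference-on-average regression.

    d = eGFR − sGFR; LoA = mean(d) ± 1.96·SD(d) (sample SD); precision is
    the LoA width.  d is regressed on (eGFR + sGFR)/2 by OLS with t-based
    95% CIs; the residual limits of agreement describe scatter about the
    regression line (residual SD uses n−2 df).
    """
    e, s = _validate_pair(egfr, sgfr)
    d = e - s
    avg = (e + s) / 2.0
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    loa = (mean_d - _LOA_MULTIPLIER * sd_d, mean_d + _LOA_MULTIPLIER * sd_d)
    precision = loa[1] - loa[0]

    X = sm.add_constant(avg)
    fit = sm.OLS(d, X).fit()
    ci = fit.conf_int(alpha=0.05)
    resid_sd = float(np.sqrt(fit.ssr / fit.df_resid))
    return AgreementSummary(
        n=e.size,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_lower=loa[0],
        loa_upper=loa[1],
        precision=precision,
        precision_acceptable=bool(precision <= PRECISION_TOLERANCE),
        slope=float(fit.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        residual_loa=(
            -_LOA_MULTIPLIER * resid_sd,
            _LOA_MULTIPLIER * resid_sd,
        ),
    )


@dataclass
class AccuracySummary:
    """Tolerance accuracy of one estimator against the reference."""

    n: int
    median_difference: float
    difference_iqr: Tuple[float, float]
    median_pct_absolute_difference: float
    pct_absolute_difference_iqr: Tuple[float, float]
    p15: float
    p30: float
    p50: float


def accuracy_summary(egfr, sgfr) -> AccuracySummary:
    """Median difference, median % absolute difference, and P15/P30/P50.

    P_p is the percentage of estimates within p% of the reference:
    100 · mean(|e − s| / s ≤ p/100).  Quartiles use linear interpolation.
    """
    e, s = _validate_pair(egfr, sgfr)
    d = e - s
    rel = np.abs(d) / s
    pct_abs = 100.0 * rel
    return AccuracySummary(
        n=e.size,
        median_difference=float(np.median(d)),
        difference_iqr=(float(np.percentile(d, 25)), float(np.percentile(d, 75))),
        median_pct_absolute_difference=float(np.median(pct_abs)),
        pct_absolute_difference_iqr=(
            float(np.percentile(pct_abs, 25)),
            float(np.percentile(pct_abs, 75)),
        ),
        p15=float(100.0 * np.mean(rel <= 0.15)),
        p30=float(100.0 * np.mean(rel <= 0.30)),
        p50=float(100.0 * np.mean(rel <= 0.50)),
    )


@dataclass
class ConcordanceSummary:
    """CKD-staging agreement between estimated and reference GFR."""

    n: int
    cross_table: np.ndarray  # (5, 5), rows = reference stage, cols = estimated
    misclassification_rate: float
    per_stage_correct_ratio: Dict[int, float]  # conditioned on estimated stage
    misclassification_below_60: float
    misclassification_below_15: float


def staging_concordance(egfr, sgfr) -> ConcordanceSummary:
    """Stage cross-table, misclassification rates, and threshold errors.

    The overall rate is the fraction of records whose estimated stage
    differs from the reference stage.  Binary misclassification at a
    threshold T counts disagreement of the indicators eGFR < T vs
    sGFR < T in either direction.  Per-stage correct-classification
    ratios condition on the *estimated* stage (among records an
    estimator places in stage s, the fraction truly in stage s).
    """
    e, s = _validate_pair(egfr, sgfr)
    est = stage_vector(e)
    ref = stage_vector(s)
    table = np.zeros((5, 5), dtype=int)
    for r, c in zip(ref, est):
        table[r - 1, c - 1] += 1
    per_stage = {}
    for stage in range(1, 6):
        placed = table[:, stage - 1].sum()
        per_stage[stage] = float(table[stage - 1, stage - 1] / placed) if placed else float("nan")
    return ConcordanceSummary(
        n=e.size,
        cross_table=table,
        misclassification_rate=float(np.mean(est != ref)),
        per_stage_correct_ratio=per_stage,
        misclassification_below_60=float(np.mean((e < 60) != (s < 60))),
        misclassification_below_15=float(np.mean((e < 15) != (s < 15))),
    )


def compare_models(egfr_a, egfr_b, sgfr, tolerance: float = 0.30) -> Dict[str, dict]:
    """Paired comparison of two estimators on the same subjects.

    * Wilcoxon signed-rank on the paired absolute percent errors.
    * Continuity-corrected McNemar on paired within-``tolerance`` hits.
    * ANCOVA-style regression comparison: the two difference-on-average
      regressions are pooled with a method indicator; the slope contrast
      is the average×method interaction, and the intercept contrast is
      the method main effect in the equal-slopes model.

    Degenerate inputs (all ties, no discordant pairs) skip the affected
    test with a notice instead of raising.
    """
    a, s = _validate_pair(egfr_a, sgfr)
    b, _ = _validate_pair(egfr_b, sgfr)
    if a.size != b.size:
        raise ValueError("both estimators must cover the same subjects")
    report: Dict[str, dict] = {}

    err_a = np.abs(a - s) / s
    err_b = np.abs(b - s) / s
    diffs = err_a - err_b
    if np.allclose(diffs, 0.0):
        report["wilcoxon"] = {"skipped": True, "reason": "all paired errors tied"}
    else:
        stat, p = stats.wilcoxon(err_a, err_b)
        report["wilcoxon"] = {"skipped": False, "statistic": float(stat), "p_value": float(p)}

    hit_a = err_a <= tolerance
    hit_b = err_b <= tolerance
    n01 = int(np.sum(hit_a & ~hit_b))  # discordant: A hit, B miss
    n10 = int(np.sum(~hit_a & hit_b))
    if n01 + n10 == 0:
        report["mcnemar"] = {
            "skipped": True,
            "reason": "no discordant pairs",
            "b": n01,
            "c": n10,
        }
    else:
        table = [
            [int(np.sum(hit_a & hit_b)), n01],
            [n10, int(np.sum(~hit_a & ~hit_b))],
        ]
        res = _sm_mcnemar(table, exact=False, correction=True)
        report["mcnemar"] = {
            "skipped": False,
            "b": n01,
            "c": n10,
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
        }

    d = np.concatenate([a - s, b - s])
    avg = np.concatenate([(a + s) / 2.0, (b + s) / 2.0])
    method = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    X_int = sm.add_constant(np.column_stack([avg, method, avg * method]))
    fit_int = sm.OLS(d, X_int).fit()
    X_eq = sm.add_constant(np.column_stack([avg, method]))
    fit_eq = sm.OLS(d, X_eq).fit()
    report["regression"] = {
        "slope_difference": float(fit_int.params[3]),
        "slope_p_value": float(fit_int.pvalues[3]),
        "intercept_difference": float(fit_eq.params[2]),
        "intercept_p_value": float(fit_eq.pvalues[2]),
    }
    return report


def bland_altman_plot(egfr, sgfr, path, title: Optional[str] = None) -> None:
    """Save a Bland–Altman plot: mean-difference line, 95% limits of
    agreement, difference-on-average regression with 95% CI band, and the
    residual limits of agreement about the regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e, s = _validate_pair(egfr, sgfr)
    summary = bland_altman(e, s)
    d = e - s
    avg = (e + s) / 2.0

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(avg, d, s=12, alpha=0.5, color="0.3", edgecolors="none")
    ax.axhline(summary.mean_difference, color="tab:blue", label="mean difference")
    for loa in (summary.loa_lower, summary.loa_upper):
        ax.axhline(loa, color="tab:brown", linestyle="--", label="95% limits of agreement" if loa == summary.loa_lower else None)
    grid = np.linspace(avg.min(), avg.max(), 100)
    line = summary.intercept + summary.slope * grid
    ax.plot(grid, line, color="tab:red", label="difference-on-average regression")
    lo_ci = summary.intercept_ci[0] + summary.slope_ci[0] * grid
    hi_ci = summary.intercept_ci[1] + summary.slope_ci[1] * grid
    ax.plot(grid, lo_ci, color="tab:green", linestyle=":", label="95% CI of regression")
    ax.plot(grid, hi_ci, color="tab:green", linestyle=":")
    for r in summary.residual_loa:
        ax.plot(grid, line + r, color="tab:purple", linestyle="--", label="95% LoA of regression" if r == summary.residual_loa[0] else None)
    ax.set_xlabel("average of eGFR and sGFR (ml/min/1.73 m²)")
    ax.set_ylabel("eGFR − sGFR (ml/min/1.73 m²)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def metrics_table(estimates: Dict[str, np.ndarray], sgfr) -> pd.DataFrame:
    """One row of agreement/accuracy/staging metrics per estimator."""
    rows = []
    for name, egfr in estimates.items():
        agree = bland_altman(egfr, sgfr)
        acc = accuracy_summary(egfr, sgfr)
        conc = staging_concordance(egfr, sgfr)
        rows.append(
            {
                "estimator": name,
                "n": agree.n,
                "mean_difference": agree.mean_difference,
                "loa_lower": agree.loa_lower,
                "loa_upper": agree.loa_upper,
                "precision": agree.precision,
                "slope": agree.slope,
                "intercept": agree.intercept,
                "median_difference": acc.median_difference,
                "median_pct_abs_difference": acc.median_pct_absolute_difference,
                "p15": acc.p15,
                "p30": acc.p30,
                "p50": acc.p50,
                "stage_misclassification": conc.misclassification_rate,
                "misclassification_below_60": conc.misclassification_below_60,
                "misclassification_below_15": conc.misclassification_below_15,
            }
        )
    return pd.DataFrame(rows)
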