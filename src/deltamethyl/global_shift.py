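"""Epigenome-wide methylation-shift statistics.

Two complementary summaries of whether methylation change from birth to age
10 differs by feeding mode *globally*, over all CpGs rather than one at a
time:

1. Per-subject mean of the delta residuals, regressed on feeding mode (EFF
   and Mixed dummies, EBF reference) plus the confounder set.
2. The quartile-percentage statistic: per subject, the percentage of CpGs
   whose delta falls below the population median of per-subject first
   quartiles (pronounced declines), and above the median of third quartiles
   (pronounced rises); each percentage regressed on feeding mode the same
   way. Percentages are on a 0-100 scale.

A negative mean-delta coefficient for EFF together with a positive below-Q1
percentage coefficient is the signature of a global downward methylation
shift in exclusively formula-fed children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import confounder_design
from .preprocess import DeltaMatrix

__all__ = [
    "GlobalShiftResult",
    "per_subject_mean_delta",
    "quartile_percentages",
    "regress_global",
    "check_normality",
    "run_global_shift",
]


@dataclass
class GlobalShiftResult:
    """Coefficients of the three global regressions plus intermediates."""

    mean_delta: pd.DataFrame  # rows: EFF, Mixed; cols: coeff, se, p
    pct_below_q1: pd.DataFrame
    pct_above_q3: pd.DataFrame
    per_subject: pd.DataFrame  # mean_delta, pct_below, pct_above per subject
    normality: dict


def per_subject_mean_delta(delta: DeltaMatrix) -> pd.Series:
    """Mean delta residual per subject over all CpGs."""
    return delta.values.mean(axis=0).rename("mean_delta")


def quartile_percentages(delta: DeltaMatrix) -> pd.DataFrame:
    """Per-subject percentages of CpGs below the median Q1 / above the median Q3.

    Per subject, Q1 and Q3 are the 25th and 75th percentiles (linear
    interpolation) of that subject's delta values. The population medians of
    these Q1s and Q3s define two fixed cutoffs; each subject's percentages
    count CpGs strictly below the Q1-median and strictly above the
    Q3-median, on a 0-100 scale.
    """
    V = delta.values.to_numpy()
    p, n = V.shape
    if n < 2 or p < 4:
        raise ValueError("need at least 2 subjects and 4 CpGs")
    q1 = np.percentile(V, 25, axis=0)
    q3 = np.percentile(V, 75, axis=0)
    m1 = float(np.median(q1))
    m3 = float(np.median(q3))
    if np.all(V == V.flat[0]):
        import warnings

        warnings.warn("degenerate delta matrix (all values equal); percentages are 0")
    pct_below = 100.0 * (V < m1).sum(axis=0) / p
    pct_above = 100.0 * (V > m3).sum(axis=0) / p
    return pd.DataFrame(
        {"pct_below": pct_below, "pct_above": pct_above}, index=delta.subject_ids
    )


def regress_global(
    per_subject_stat: pd.Series,
    sheet: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of a per-subject statistic on feeding-mode dummies + confounders.

    Feeding enters as EFF and Mixed indicators against the EBF reference.
    Returns one row per non-reference mode with coefficient, standard error
    and two-sided p-value.
    """
    subjects = per_subject_stat.index
    sub = sheet.loc[subjects]
    conf = confounder_design(sub)
    modes = sub["feeding_mode"]
    X = pd.DataFrame(index=subjects)
    X["intercept"] = 1.0
    X["EFF"] = (modes == "EFF").astype(float)
    X["Mixed"] = (modes == "Mixed").astype(float)
    X = pd.concat([X, conf], axis=1)
    Xa = X.to_numpy()
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient global regression design")
    y = per_subject_stat.to_numpy(dtype=float)
    n, k = Xa.shape
    XtX_inv = np.linalg.inv(Xa.T @ Xa)
    beta = XtX_inv @ Xa.T @ y
    resid = y - Xa @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), n - k)
    out = pd.DataFrame({"coeff": beta, "se": se, "p": pvals}, index=X.columns)
    return out.loc[["EFF", "Mixed"]]


def check_normality(outcomes: pd.DataFrame | pd.Series) -> dict:
    """Normality diagnostics for the global-regression outcomes (report-only).

    Shapiro-Wilk per outcome plus Mardia-style multivariate skewness and
    kurtosis across the outcome columns. Never gates the pipeline.
    """
    if isinstance(outcomes, pd.Series):
        outcomes = outcomes.to_frame()
    report: dict = {"per_outcome": {}, "mardia": None}
    cols = []
    for name, col in outcomes.items():
        x = col.to_numpy(dtype=float)
        if np.all(x == x[0]):
            report["per_outcome"][name] = {"degenerate": True}
            continue
        if len(x) < 8:
            report["per_outcome"][name] = {"degenerate": True, "reason": "n < 8"}
            continue
        stat, p = stats.shapiro(x)
        report["per_outcome"][name] = {"shapiro_w": float(stat), "shapiro_p": float(p)}
        cols.append(name)
    if len(cols) >= 2:
        Xc = outcomes[cols].to_numpy(dtype=float)
        n = Xc.shape[0]
        Xc = Xc - Xc.mean(axis=0)
        S = Xc.T @ Xc / n
        Sinv = np.linalg.pinv(S)
        D = Xc @ Sinv @ Xc.T
        b1 = float((D**3).sum() / n**2)  # multivariate skewness
        b2 = float(np.mean(np.diag(D) ** 2))  # multivariate kurtosis
        report["mardia"] = {"skewness": b1, "kurtosis": b2}
    return report


def run_global_shift(delta: DeltaMatrix, sheet: pd.DataFrame) -> GlobalShiftResult:
    """All three global regressions plus intermediates and diagnostics."""
    means = per_subject_mean_delta(delta)
    pcts = quartile_percentages(delta)
    per_subject = pd.concat([means, pcts], axis=1)
    return GlobalShiftResult(
        mean_delta=regress_global(means, sheet),
        pct_below_q1=regress_global(pcts["pct_below"], sheet),
        pct_above_q3=regress_global(pcts["pct_above"], sheet),
        per_subject=per_subject,
        normality=check_normality(per_subject),
    )
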