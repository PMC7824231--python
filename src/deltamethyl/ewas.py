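"""Confounder-adjusted per-CpG inference on screened CpGs, with FDR control.

For every CpG that survives screening, the delta residual is regressed on
the feeding indicator together with the full confounder set: infant sex,
cell compositions and season of blood collection at both ages, maternal age
at delivery, maternal smoking during pregnancy, mode of delivery,
birthweight, birth order, and family socioeconomic status. A positive
coefficient means methylation rose from birth to age 10 in the exposed
group relative to the rest; a negative coefficient means it declined.
Within each feeding mode's screened set, p-values are adjusted by the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import CELL_TYPES, SEASONS, DeltaMatrix

__all__ = [
    "confounder_design",
    "fit_adjusted",
    "fit_adjusted_all",
    "run_ewas",
    "bh_fdr",
    "direction_summary",
]


def confounder_design(sheet: pd.DataFrame) -> pd.DataFrame:
    """Confounder design matrix (no intercept column; callers add it).

    Continuous: maternal age, birthweight, the five non-granulocyte cell
    fractions at each age. Dummies: sex (male=1), maternal smoking,
    caesarean delivery, season at each age (winter reference), birth order
    (reference first-born), SES (reference high).
    """
    X = pd.DataFrame(index=sheet.index)
    X["sex_male"] = (sheet["sex"] == "male").astype(float)
    X["maternal_smoking"] = sheet["maternal_smoking"].astype(float)
    X["maternal_age"] = sheet["maternal_age"].astype(float)
    X["birthweight"] = sheet["birthweight"].astype(float)
    X["caesarean"] = sheet["caesarean"].astype(float)
    for tp in ("birth", "age10"):
        for ct in CELL_TYPES[:-1]:
            X[f"{ct}_{tp}"] = sheet[f"{ct}_{tp}"].astype(float)
        for s in SEASONS[1:]:
            X[f"season_{tp}_{s}"] = (sheet[f"season_{tp}"] == s).astype(float)
    for level in ("2", "3+"):
        X[f"birth_order_{level}"] = (sheet["birth_order"].astype(str) == level).astype(float)
    for level in ("medium", "low"):
        X[f"ses_{level}"] = (sheet["ses"] == level).astype(float)
    return X


def _design_with_exposure(
    feeding: np.ndarray, confounders: pd.DataFrame
) -> np.ndarray:
    n = len(feeding)
    X = np.column_stack([np.ones(n), np.asarray(feeding, dtype=float), confounders.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by dropping one at a time
        names = ["intercept", "feeding", *confounders.columns]
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")
    return X


def fit_adjusted(
    delta_row: np.ndarray | pd.Series,
    feeding: np.ndarray | pd.Series,
    confounders: pd.DataFrame,
) -> tuple[float, float]:
    """OLS coefficient and two-sided p for the feeding term at one CpG."""
    y = np.asarray(delta_row, dtype=float)
    X = _design_with_exposure(np.asarray(feeding), confounders)
    coef, p = _ols_column(X, y[None, :])
    return float(coef[0]), float(p[0])


def _ols_column(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched OLS of rows of Y on X; coefficient/p for X's second column."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = np.einsum("mn,mn->m", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals[se == 0] = 1.0
    return beta[:, 1], pvals


def fit_adjusted_all(
    delta: DeltaMatrix,
    feeding: np.ndarray | pd.Series,
    confounders: pd.DataFrame,
    cpg_ids=None,
) -> pd.DataFrame:
    """Adjusted coefficients and raw p-values for a set of CpGs at once."""
    ids = delta.cpg_ids if cpg_ids is None else pd.Index(cpg_ids)
    Y = delta.values.loc[ids].to_numpy()
    X = _design_with_exposure(np.asarray(feeding), confounders)
    coef, p = _ols_column(X, Y)
    return pd.DataFrame({"coeff": coef, "p_raw": p}, index=ids)


def bh_fdr(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (empty in, empty out)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ewas(
    delta: DeltaMatrix,
    sheet: pd.DataFrame,
    screened: dict[str, pd.Index],
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adjusted EWAS over the screened CpGs of each feeding mode.

    FDR adjustment is applied within each mode's screened set separately
    (three separate EWAS). Returns one row per (mode, CpG): coefficient,
    raw p, FDR p, and direction sign.
    """
    conf = confounder_design(sheet.loc[delta.subject_ids])
    modes_col = sheet.loc[delta.subject_ids, "feeding_mode"]
    out = []
    for mode, cpgs in screened.items():
        if len(cpgs) == 0:
            continue
        feeding = (modes_col == mode).to_numpy().astype(float)
        fit = fit_adjusted_all(delta, feeding, conf, cpg_ids=cpgs)
        fit["p_fdr"] = bh_fdr(fit["p_raw"].to_numpy())
        fit["mode"] = mode
        fit["direction"] = np.sign(fit["coeff"]).astype(int)
        out.append(fit.reset_index().rename(columns={"index": "cpg_id"}))
    if not out:
        return pd.DataFrame(columns=["cpg_id", "mode", "coeff", "p_raw", "p_fdr", "direction"])
    table = pd.concat(out, ignore_index=True)[
        ["cpg_id", "mode", "coeff", "p_raw", "p_fdr", "direction"]
    ]
    if annotation is not None:
        ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
        table = table.join(ann, on="cpg_id")
    return table


def direction_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Counts of positive/negative/zero coefficients per feeding mode.

    Also emits the volcano-plot coordinates (coefficient, -log10 raw p) as
    columns of the input for downstream plotting.
    """
    if rows.empty:
        raise ValueError("no EWAS rows to summarize")
    rows = rows.copy()
    rows["neg_log10_p"] = -np.log10(rows["p_raw"])
    counts = (
        rows.groupby("mode")["direction"]
        .agg(
            positive=lambda d: int((d > 0).sum()),
            negative=lambda d: int((d < 0).sum()),
            zero=lambda d: int((d == 0).sum()),
        )
        .reset_index()
    )
    counts.attrs["volcano"] = rows[["cpg_id", "mode", "coeff", "neg_log10_p"]]
    return counts
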