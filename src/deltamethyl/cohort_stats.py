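"""Cohort representativeness tests, location enrichment, and stability checks.

Representativeness compares the analytical sample (subjects with paired
methylation data) against the full birth cohort: one-sample proportion
tests for binary variables, goodness-of-fit chi-square for multi-category
variables, and one-sample t-tests for continuous variables. The temporal
stability of discovered CpGs between ages 10 and 18 is assessed per CpG by
a linear mixed model with a subject random intercept; a CpG is called
dynamic when the age effect has p < 0.1 (deliberately liberal, no
multiplicity adjustment, so that only clearly stable CpGs are promoted as
candidate biomarkers).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MethylationMatrix

__all__ = [
    "one_sample_prop_test",
    "gof_chisq",
    "one_sample_t",
    "representativeness_report",
    "location_enrichment",
    "stability_classify",
    "outcome_by_feeding_regression",
]

#: Gene-location labels recognised by location_enrichment.
LOCATION_LABELS = {"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"}
TSS_GROUP = {"TSS200", "TSS1500"}
BODY_GROUP = {"Body", "1stExon"}


def one_sample_prop_test(
    x: int, n: int, p0: float, continuity: bool = False
) -> tuple[float, float]:
    """One-sample z-test of a proportion against a population value.

    z = (x/n - p0) / sqrt(p0 (1 - p0) / n); two-sided p from the normal.
    No continuity correction by default (``continuity=True`` applies the
    Yates half-count correction to the numerator).
    """
    if n <= 0 or not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n with n > 0")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    diff = x / n - p0
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5 / n, 0.0)
    z = diff / np.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def gof_chisq(
    observed, population_props
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square of sample counts vs cohort proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(population_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and proportions must have equal length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("population proportions must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be positive")
    expected = total * props
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def one_sample_t(
    sample_mean: float, sample_sd: float, n: int, mu0: float
) -> tuple[float, float]:
    """One-sample t-test from summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sample_sd <= 0:
        raise ValueError("degenerate input: sd must be positive")
    t = (sample_mean - mu0) / (sample_sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def representativeness_report(margins: pd.DataFrame) -> pd.DataFrame:
    """Run the Table-1-style tests from a margins table.

    ``margins`` needs columns: variable, test ('prop_z', 'chisq_gof' or
    't_one_sample'), and per test either (x, n, X, N) counts, count vectors
    encoded as ';'-separated category rows sharing a variable name, or
    (mean, sd, n, mu0). One output row per variable with statistic and p.
    """
    rows = []
    for var, grp in margins.groupby("variable", sort=False):
        test = grp["test"].iloc[0]
        if test == "prop_z":
            r = grp.iloc[0]
            z, p = one_sample_prop_test(int(r["x"]), int(r["n"]), r["X"] / r["N"])
            rows.append({"variable": var, "test": test, "statistic": z, "p": p})
        elif test == "chisq_gof":
            obs = grp["x"].to_numpy(dtype=float)
            props = grp["X"].to_numpy(dtype=float) / grp["N"].iloc[0]
            chi2, df, p = gof_chisq(obs, props)
            rows.append({"variable": var, "test": test, "statistic": chi2, "df": df, "p": p})
        elif test == "t_one_sample":
            r = grp.iloc[0]
            t, p = one_sample_t(r["mean"], r["sd"], int(r["n"]), r["mu0"])
            rows.append({"variable": var, "test": test, "statistic": t, "p": p})
        else:
            raise ValueError(f"unknown test {test!r} for variable {var!r}")
    return pd.DataFrame(rows)


def _parse_locations(label) -> set[str]:
    if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
        return set()
    parts = {p.strip() for p in str(label).replace(",", ";").split(";") if p.strip()}
    unknown = parts - LOCATION_LABELS
    if unknown:
        raise ValueError(f"unknown gene-location labels: {sorted(unknown)}")
    return parts


def location_enrichment(
    cpg_lists: dict[str, list[str]],
    annotation: pd.DataFrame,
) -> dict:
    """Gene-location contingency tables across feeding modes (report-only).

    Multi-label locations count toward every group they belong to. Builds a
    2 x k table for TSS membership (TSS200/TSS1500) and one for gene-body
    membership (Body/1stExon), with a Pearson chi-square each. Requires at
    least two modes.
    """
    if len(cpg_lists) < 2:
        raise ValueError("need CpG lists for at least two feeding modes")
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    tables = {}
    for name, group in (("tss", TSS_GROUP), ("body", BODY_GROUP)):
        counts = {}
        for mode, cpgs in cpg_lists.items():
            in_grp = 0
            for cpg in cpgs:
                if cpg not in ann.index:
                    raise KeyError(f"no annotation for {cpg!r}")
                locs = _parse_locations(ann.loc[cpg, "location"])
                if locs & group:
                    in_grp += 1
            counts[mode] = (in_grp, len(cpgs) - in_grp)
        table = np.array(list(counts.values())).T  # 2 x k
        if table.sum() == 0 or np.any(table.sum(axis=0) == 0):
            raise ValueError("empty mode in contingency table")
        # all-in-one-category tables have expected zeros; chi-square is 0, p 1
        if np.any(table.sum(axis=1) == 0):
            chi2, p, df = 0.0, 1.0, (table.shape[1] - 1)
        else:
            chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        tables[name] = {
            "counts": pd.DataFrame(table, index=["in", "out"], columns=list(counts)),
            "chi2": float(chi2),
            "df": int(df),
            "p": float(p),
        }
    return tables


def stability_classify(
    m10: MethylationMatrix,
    m18: MethylationMatrix,
    cpg_ids=None,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Stable/dynamic calls for CpGs between ages 10 and 18.

    Per CpG, a linear mixed model of the M-value on an age indicator with a
    subject random intercept is fitted by restricted maximum likelihood; the
    CpG is called dynamic when the age-effect p-value is below ``threshold``
    (no multiplicity adjustment). For this balanced paired design the REML
    solution is closed-form: the age effect is the mean within-subject
    difference, the residual variance is half the REML variance of the
    differences, and the Wald test reduces to a t-test with n-1 degrees of
    freedom on the paired differences. Returns cpg_id, p, call.
    """
    subjects = m10.sample_ids.intersection(m18.sample_ids)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects paired at 10 and 18 years")
    ids = m10.cpg_ids.intersection(m18.cpg_ids) if cpg_ids is None else pd.Index(cpg_ids)
    D = (
        m18.values.loc[ids, subjects].to_numpy()
        - m10.values.loc[ids, subjects].to_numpy()
    )  # CpG x subject within-subject differences
    effect = D.mean(axis=1)
    sd = D.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, effect / (sd / np.sqrt(n)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p[sd == 0] = 1.0
    return pd.DataFrame(
        {
            "cpg_id": ids,
            "effect": effect,
            "p": p,
            "call": np.where(p < threshold, "dynamic", "stable"),
        }
    ).reset_index(drop=True)


def outcome_by_feeding_regression(
    delta_cpg: pd.Series,
    outcome: pd.Series,
    modes: pd.Series,
    min_group: int = 3,
) -> pd.DataFrame:
    """Separate OLS line of a health outcome on one CpG's delta, per feeding group.

    Emits a plot-ready table with slope, intercept and group size; groups
    with fewer than ``min_group`` subjects are skipped with a warning.
    """
    rows = []
    for mode, idx in modes.groupby(modes).groups.items():
        x = delta_cpg.loc[idx].to_numpy(dtype=float)
        y = outcome.loc[idx].to_numpy(dtype=float)
        if len(x) < min_group:
            warnings.warn(f"feeding group {mode!r} has fewer than {min_group} subjects; skipped")
            continue
        if np.allclose(x, x[0]):
            slope, intercept = 0.0, float(np.mean(y))
        else:
            slope, intercept = np.polyfit(x, y, 1)
        rows.append({"mode": mode, "slope": float(slope), "intercept": float(intercept), "n": len(x)})
    return pd.DataFrame(rows)
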