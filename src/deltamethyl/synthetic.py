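"""Synthetic paired-timepoint methylation cohorts with known feeding effects.

The generator emulates the statistical structure the downstream pipeline
assumes: beta values bounded in (0, 1); additive cell-composition, season,
and age effects on the M scale; a subject-level baseline carried across both
ages; feeding-mode effects injected on the birth-to-age-10 change at a known
CpG subset; and a small global shift applied to exclusively formula-fed
subjects at age 10. The injected truth is returned alongside the data so
parameter-recovery and calibration tests have ground truth to score against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CELL_TYPES, SEASONS, MethylationMatrix, covariates_for, m_to_beta  # noqa: F401

__all__ = [
    "FEEDING_MODES",
    "SimConfig",
    "SimTruth",
    "derive_feeding_mode",
    "simulate_cohort",
    "write_cohort",
]

FEEDING_MODES = ("EBF", "EFF", "Mixed")

#: Exclusivity cutoff, in weeks, separating exclusive from mixed feeding.
EXCLUSIVITY_WEEKS = 13

# Dirichlet concentrations for leukocyte fractions (CD8T, CD4T, NK, Bcell,
# Mono, Gran). Neonatal blood is granulocyte-dominated; by age 10 the
# lymphocyte share is larger.
_CELL_ALPHA_BIRTH = np.array([1.5, 3.5, 1.0, 1.5, 1.5, 11.0])
_CELL_ALPHA_AGE10 = np.array([2.5, 5.0, 1.5, 2.0, 1.5, 7.5])


class FeedingClassificationError(ValueError):
    """Raised when no feeding information is available for a subject."""


@dataclass
class SimConfig:
    """Generator settings.

    Defaults mirror the study conditions: 201 subjects, feeding prevalences
    of roughly 23% exclusively breastfed (EBF), 9% exclusively formula-fed
    (EFF) and 68% mixed, a global downward M-value shift of -0.03 for EFF
    subjects at age 10, and per-CpG feeding effects of 0.4 M-units at 30
    CpGs per mode. The CpG count is a desk-scale stand-in for a filtered
    array.

    Attributes
    ----------
    effect_size_m
        Difference in birth-to-age-10 M-value change between subjects of a
        mode and everyone else, applied at that mode's effect CpGs.
    global_shift_eff
        Mean M-value shift added to every CpG of EFF subjects at age 10.
    noise_sd_m
        SD of i.i.d. measurement noise added on the M scale at each
        timepoint independently.
    cell_coef_sd, season_coef_sd, age_effect_sd, subject_baseline_sd
        Scales of the per-CpG covariate coefficients, the shared
        birth-to-age-10 drift, and the subject-level baseline deviation.
    """

    n_subjects: int = 201
    n_cpgs: int = 10_000
    n_effect_cpgs_per_mode: int = 30
    effect_size_m: float = 0.4
    global_shift_eff: float = -0.03
    feeding_probs: tuple[float, float, float] = (0.229, 0.089, 0.682)
    cell_type_count: int = 6
    season_levels: tuple[str, ...] = SEASONS
    noise_sd_m: float = 0.5
    baseline_beta_params: tuple[float, float] = (2.0, 8.0)
    cell_coef_sd: float = 1.0
    season_coef_sd: float = 0.1
    age_effect_sd: float = 0.2
    subject_baseline_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.feeding_probs) - 1.0) > 1e-12:
            raise ValueError("feeding_probs must sum to 1")
        if min(self.n_subjects, self.n_cpgs) <= 0 or self.n_effect_cpgs_per_mode < 0:
            raise ValueError("counts must be positive")
        if 3 * self.n_effect_cpgs_per_mode > self.n_cpgs:
            raise ValueError("n_effect_cpgs_per_mode too large for n_cpgs")
        if self.cell_type_count != len(CELL_TYPES):
            raise ValueError(f"cell_type_count must be {len(CELL_TYPES)}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: what was injected and where."""

    effect_cpg_ids: dict[str, list[str]]
    effect_size_m: float
    global_shift_eff: float
    cell_props_birth: pd.DataFrame
    cell_props_age10: pd.DataFrame
    seasons_birth: pd.Series
    seasons_age10: pd.Series

    def __post_init__(self) -> None:
        ids = [set(v) for v in self.effect_cpg_ids.values()]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ids[i] & ids[j]:
                    raise ValueError("effect CpG lists must be disjoint")
        for props in (self.cell_props_birth, self.cell_props_age10):
            if np.any(np.abs(props.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("cell proportions must sum to 1 per sample")


def derive_feeding_mode(
    bf_weeks: float | None,
    formula_intro_week: float | None,
    solids_intro_week: float | None,
) -> str:
    """Classify a feeding history as EBF, EFF, or Mixed (13-week cutoff).

    EBF: only breastmilk for at least 13 weeks before formula or solids were
    introduced. EFF: only formula (no breastfeeding at all) for at least 13
    weeks before solids. Mixed: a mixture of sources occurs before 13 weeks.
    Exactly 13 weeks qualifies as "at least 13 weeks".
    """
    if bf_weeks is None and formula_intro_week is None and solids_intro_week is None:
        raise FeedingClassificationError("no feeding information supplied")
    bf = 0.0 if bf_weeks is None else float(bf_weeks)
    formula = np.inf if formula_intro_week is None else float(formula_intro_week)
    solids = np.inf if solids_intro_week is None else float(solids_intro_week)
    if min(bf, 0.0) < 0 or formula < 0 or solids < 0:
        raise ValueError("durations must be non-negative")
    if bf > 0:
        if bf >= EXCLUSIVITY_WEEKS and min(formula, solids) >= EXCLUSIVITY_WEEKS:
            return "EBF"
        return "Mixed"
    # never breastfed
    if np.isfinite(formula) and solids >= EXCLUSIVITY_WEEKS:
        return "EFF"
    return "Mixed"


def _draw_durations(mode: str, rng: np.random.Generator) -> tuple[float, float, float]:
    """Feeding durations (bf weeks, formula intro, solids intro) consistent with a mode."""
    if mode == "EBF":
        bf = float(EXCLUSIVITY_WEEKS + rng.integers(0, 27))
        formula = bf + float(rng.integers(0, 8))
        solids = float(EXCLUSIVITY_WEEKS + rng.integers(0, 13))
        return bf, formula, solids
    if mode == "EFF":
        solids = float(EXCLUSIVITY_WEEKS + rng.integers(0, 13))
        return 0.0, 0.0, solids
    bf = float(rng.integers(1, 26))
    formula = float(rng.integers(0, EXCLUSIVITY_WEEKS))
    solids = float(rng.integers(8, 26))
    return bf, formula, solids


def _draw_confounders(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Birth-cohort-like confounders (prevalences typical of a UK birth cohort)."""
    return pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], size=n, p=[0.513, 0.487]),
            "maternal_smoking": rng.random(n) < 0.25,
            "maternal_age": np.round(rng.normal(29.2, 5.5, size=n), 1),
            "birthweight": np.round(rng.normal(3.4, 0.5, size=n), 2),
            "birth_order": rng.choice(["1", "2", "3+"], size=n, p=[0.426, 0.342, 0.232]),
            "ses": rng.choice(["high", "medium", "low"], size=n, p=[0.08, 0.77, 0.15]),
            "caesarean": rng.random(n) < 0.093,
            "maternal_asthma": rng.random(n) < 0.109,
        }
    )


def simulate_cohort(
    config: SimConfig,
) -> tuple[MethylationMatrix, MethylationMatrix, pd.DataFrame, SimTruth]:
    """Generate a paired-timepoint cohort with known injected effects.

    Generative model on the M scale, for CpG i, subject j, timepoint t:

        M_ij(t) = mu_i + u_ij + sum_k gamma_ik * cellprop_jk(t)
                  + season effect_i(t) + d_i * 1[t = age10]
                  + effect_size_m * 1[t = age10, i in mode(j)'s effect set]
                  + global_shift_eff * 1[t = age10, mode(j) = EFF]
                  + noise_ij(t)

    where mu_i is a bimodal baseline (hypo/hyper-methylated CpGs drawn on
    the beta scale, transformed to M), u_ij a subject-level deviation
    carried across ages, gamma_ik per-CpG cell coefficients, and d_i a
    shared birth-to-age-10 drift. M values are returned as beta matrices.

    Returns (birth matrix, age-10 matrix, sample sheet, truth); identical
    config (incl. seed) reproduces the output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_cpgs
    subjects = pd.Index([f"S{j:04d}" for j in range(n)], name="subject_id")
    cpgs = pd.Index([f"cg{i:08d}" for i in range(p)], name="cpg_id")

    # feeding modes and consistent durations
    modes = rng.choice(FEEDING_MODES, size=n, p=list(config.feeding_probs))
    durations = np.array([_draw_durations(m, rng) for m in modes])

    # baseline: bimodal beta mixture -> M scale
    a, b = config.baseline_beta_params
    hyper = rng.random(p) < 0.5
    base_beta = np.where(hyper, rng.beta(b, a, size=p), rng.beta(a, b, size=p))
    base_beta = np.clip(base_beta, 0.01, 0.99)
    mu = np.log2(base_beta / (1.0 - base_beta))

    u = rng.normal(0.0, config.subject_baseline_sd, size=(p, n))
    gamma = rng.normal(0.0, config.cell_coef_sd, size=(p, len(CELL_TYPES)))
    season_coef = np.concatenate(
        [np.zeros((p, 1)), rng.normal(0.0, config.season_coef_sd, size=(p, 3))], axis=1
    )
    drift = rng.normal(0.0, config.age_effect_sd, size=p)

    cells_birth = rng.dirichlet(_CELL_ALPHA_BIRTH, size=n)
    cells_age10 = rng.dirichlet(_CELL_ALPHA_AGE10, size=n)
    season_idx_birth = rng.integers(0, 4, size=n)
    season_idx_age10 = rng.integers(0, 4, size=n)

    # disjoint effect CpG sets per mode
    effect_idx = rng.choice(p, size=3 * config.n_effect_cpgs_per_mode, replace=False)
    effect_sets = {
        mode: sorted(effect_idx[k * config.n_effect_cpgs_per_mode : (k + 1) * config.n_effect_cpgs_per_mode])
        for k, mode in enumerate(FEEDING_MODES)
    }

    # scale=0 yields exact zeros, so the degenerate noiseless case falls out
    M_birth = (
        mu[:, None]
        + u
        + gamma @ cells_birth.T
        + season_coef[:, season_idx_birth]
        + rng.normal(0.0, config.noise_sd_m, size=(p, n))
    )
    M_age10 = (
        mu[:, None]
        + u
        + gamma @ cells_age10.T
        + season_coef[:, season_idx_age10]
        + drift[:, None]
        + rng.normal(0.0, config.noise_sd_m, size=(p, n))
    )
    for mode in FEEDING_MODES:
        idx = effect_sets[mode]
        in_mode = modes == mode
        if len(idx) and in_mode.any():
            M_age10[np.ix_(idx, np.flatnonzero(in_mode))] += config.effect_size_m
    M_age10[:, modes == "EFF"] += config.global_shift_eff

    beta_birth = m_to_beta(M_birth)
    beta_age10 = m_to_beta(M_age10)

    sheet = _draw_confounders(n, rng)
    sheet.index = subjects
    for k, ct in enumerate(CELL_TYPES):
        sheet[f"{ct}_birth"] = cells_birth[:, k]
        sheet[f"{ct}_age10"] = cells_age10[:, k]
    sheet["season_birth"] = np.array(SEASONS)[season_idx_birth]
    sheet["season_age10"] = np.array(SEASONS)[season_idx_age10]
    sheet["bf_weeks"] = durations[:, 0]
    sheet["formula_intro_week"] = durations[:, 1]
    sheet["solids_intro_week"] = durations[:, 2]
    sheet["feeding_mode"] = modes

    truth = SimTruth(
        effect_cpg_ids={m: [cpgs[i] for i in effect_sets[m]] for m in FEEDING_MODES},
        effect_size_m=config.effect_size_m,
        global_shift_eff=config.global_shift_eff,
        cell_props_birth=pd.DataFrame(cells_birth, index=subjects, columns=CELL_TYPES),
        cell_props_age10=pd.DataFrame(cells_age10, index=subjects, columns=CELL_TYPES),
        seasons_birth=pd.Series(np.array(SEASONS)[season_idx_birth], index=subjects),
        seasons_age10=pd.Series(np.array(SEASONS)[season_idx_age10], index=subjects),
    )
    mm_birth = MethylationMatrix(pd.DataFrame(beta_birth, index=cpgs, columns=subjects), "beta")
    mm_age10 = MethylationMatrix(pd.DataFrame(beta_age10, index=cpgs, columns=subjects), "beta")
    return mm_birth, mm_age10, sheet, truth


def write_cohort(
    out_dir,
    mm_birth: MethylationMatrix,
    mm_age10: MethylationMatrix,
    sheet: pd.DataFrame,
    truth: SimTruth,
) -> None:
    """Write a simulated cohort to disk (TSV matrices, CSV sheet and truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mm_birth.to_tsv(out / "beta_birth.tsv")
    mm_age10.to_tsv(out / "beta_age10.tsv")
    sheet.to_csv(out / "sample_sheet.csv", index_label="subject_id")
    rows = [
        {"mode": mode, "cpg_id": cpg, "effect_size_m": truth.effect_size_m}
        for mode, ids in truth.effect_cpg_ids.items()
        for cpg in ids
    ]
    pd.DataFrame(rows, columns=["mode", "cpg_id", "effect_size_m"]).to_csv(
        out / "truth_effects.csv", index=False
    )
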