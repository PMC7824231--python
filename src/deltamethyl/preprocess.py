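"""Probe QC, beta/M transformation, residualization, and delta-residual construction.

The methylation outcome used throughout the package is the *delta residual*:
per CpG and per subject, the residual of the M-value (logit2 of the beta
value) after regressing out leukocyte cell-type proportions and season of
blood collection at each age separately, differenced as age-10 minus birth.
A positive delta means methylation rose from birth to age 10 relative to
what cell composition and season predict; a negative delta means it fell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "SEASONS",
    "MethylationMatrix",
    "DeltaMatrix",
    "AlignmentError",
    "beta_from_intensities",
    "beta_to_m",
    "m_to_beta",
    "detection_filter",
    "snp_probe_filter",
    "intersect_timepoints",
    "covariates_for",
    "delta_pipeline",
    "celltype_season_design",
    "residualize",
    "delta_residuals",
]

#: Houseman-style leukocyte fractions estimated per sample; they live on the
#: simplex, so regression designs drop the granulocyte column.
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Season of blood collection; winter is the reference level.
SEASONS = ("winter", "spring", "summer", "fall")

#: Default clipping bound applied to beta values before the logit transform.
BETA_CLIP = 1e-6


class AlignmentError(ValueError):
    """Raised when matrices or sheets disagree on CpG/sample identifiers."""


@dataclass
class MethylationMatrix:
    """CpG-by-sample methylation values at a single timepoint.

    Parameters
    ----------
    values
        DataFrame with CpG identifiers as the index and sample identifiers
        as columns.
    scale
        One of ``"beta"`` (bounded in (0, 1)), ``"M"`` (logit2 of beta), or
        ``"residual"`` (M-scale residuals after covariate adjustment).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M", "residual"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate CpG identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            if np.any(vals <= 0) or np.any(vals >= 1):
                raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_m(self, clip: float = BETA_CLIP) -> "MethylationMatrix":
        """Return the matrix on the M scale (logit2 transform)."""
        if self.scale == "M":
            return self
        if self.scale != "beta":
            raise ValueError("only beta matrices can be logit-transformed")
        m = beta_to_m(self.values.to_numpy(), clip=clip)
        return MethylationMatrix(
            pd.DataFrame(m, index=self.cpg_ids, columns=self.sample_ids),
            scale="M",
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="cpg_id")

    @classmethod
    def from_tsv(cls, path, scale: str = "beta") -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)


@dataclass
class DeltaMatrix:
    """Per-CpG, per-subject residual methylation change (age 10 minus birth)."""

    values: pd.DataFrame  # CpG x subject, M-scale residual difference

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("delta residuals must be finite")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="cpg_id")

    @classmethod
    def from_tsv(cls, path) -> "DeltaMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# Scale transforms
# ---------------------------------------------------------------------------

def beta_from_intensities(methylated, unmethylated, c: float = 100.0):
    """Beta value from methylated/unmethylated intensities: M / (c + M + U).

    The offset ``c`` guards against zero denominators on failed probes; the
    Illumina convention is 100. Inputs may be scalars or arrays.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0) or c < 0:
        raise ValueError("intensities and offset must be non-negative")
    denom = c + m + u
    if np.any(denom == 0):
        raise ValueError("undefined beta: c + M + U = 0")
    out = m / denom
    return out.item() if out.ndim == 0 else out


def beta_to_m(beta, clip: float = BETA_CLIP):
    """M-value from beta: log2(beta / (1 - beta)), after clipping to (0, 1).

    Values are clipped to ``[clip, 1 - clip]`` so the logit stays finite at
    the array's numerical extremes.
    """
    b = np.clip(np.asarray(beta, dtype=float), clip, 1.0 - clip)
    if np.any(b <= 0) or np.any(b >= 1):
        raise ValueError("beta values outside (0, 1) after clipping")
    out = np.log2(b / (1.0 - b))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse logit2: beta = 2**m / (1 + 2**m), numerically stable."""
    m = np.asarray(m, dtype=float)
    # expit form avoids overflow for large |m|
    out = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Probe QC
# ---------------------------------------------------------------------------

def detection_filter(
    detection_p: pd.DataFrame,
    threshold: float = 1e-16,
    min_frac: float = 0.95,
) -> pd.Index:
    """CpGs whose detection p-value beats ``threshold`` in >= ``min_frac`` of samples.

    A probe is retained iff the fraction of samples with detection p below
    the threshold is at least ``min_frac`` (boundary inclusive).
    """
    passing = (detection_p.to_numpy() < threshold).mean(axis=1)
    return detection_p.index[passing >= min_frac]


_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def snp_probe_filter(
    annotation: pd.DataFrame,
    cpg_ids: Iterable[str] | None = None,
    snp_distance_bp: float = 10,
    maf_cutoff: float = 0.07,
    missing_policy: str = "strict",
) -> pd.Index:
    """Drop SNP-confounded and non-autosomal probes.

    A CpG is excluded when a probe SNP lies within ``snp_distance_bp`` bases
    AND its minor allele frequency exceeds ``maf_cutoff``, or when the probe
    is not autosomal. ``annotation`` must carry columns ``chromosome``,
    ``snp_distance`` and ``maf`` indexed by (or containing) ``cpg_id``;
    missing snp_distance/maf means no nearby SNP.

    ``missing_policy``: ``"strict"`` raises if a queried CpG has no
    annotation row; ``"keep"`` retains it with no SNP information.
    """
    ann = annotation
    if "cpg_id" in ann.columns:
        ann = ann.set_index("cpg_id")
    if cpg_ids is None:
        query = ann.index
    else:
        query = pd.Index(cpg_ids)
        missing = query.difference(ann.index)
        if len(missing) and missing_policy == "strict":
            raise KeyError(f"no annotation for {len(missing)} CpGs, e.g. {missing[0]!r}")

    kept = []
    for cpg in query:
        if cpg not in ann.index:
            kept.append(cpg)  # missing_policy == "keep"
            continue
        row = ann.loc[cpg]
        chrom = str(row["chromosome"])
        if chrom not in _AUTOSOMES:
            continue
        dist = row.get("snp_distance", np.nan)
        maf = row.get("maf", np.nan)
        if pd.notna(dist) and pd.notna(maf) and dist <= snp_distance_bp and maf > maf_cutoff:
            continue
        kept.append(cpg)
    return pd.Index(kept)


def intersect_timepoints(
    matrix_birth: MethylationMatrix,
    matrix_age10: MethylationMatrix,
) -> tuple[MethylationMatrix, MethylationMatrix, pd.Index]:
    """Restrict both matrices to the shared CpG set and shared subjects.

    Sample identifiers are treated as subject identifiers (one sample per
    subject per timepoint); the returned matrices share an identical ordered
    CpG index and subject columns.
    """
    cpgs = matrix_birth.cpg_ids.intersection(matrix_age10.cpg_ids)
    subjects = matrix_birth.sample_ids.intersection(matrix_age10.sample_ids)
    if len(cpgs) == 0 or len(subjects) == 0:
        raise AlignmentError("no CpGs or subjects present at both timepoints")
    mb = MethylationMatrix(matrix_birth.values.loc[cpgs, subjects], matrix_birth.scale)
    m10 = MethylationMatrix(matrix_age10.values.loc[cpgs, subjects], matrix_age10.scale)
    return mb, m10, subjects


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

def celltype_season_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for one timepoint: intercept, 5 cell fractions, 3 season dummies.

    ``covariates`` carries the six cell-type fraction columns of
    :data:`CELL_TYPES` and a ``season`` column. Granulocytes are dropped to
    break the simplex constraint; winter is the season reference.
    """
    missing = [c for c in CELL_TYPES if c not in covariates.columns]
    if missing or "season" not in covariates.columns:
        raise KeyError(f"covariates missing columns: {missing + ['season'] if missing else ['season']}")
    bad = set(covariates["season"]) - set(SEASONS)
    if bad:
        raise ValueError(f"unknown season levels: {sorted(bad)}")
    X = pd.DataFrame(index=covariates.index)
    X["intercept"] = 1.0
    for ct in CELL_TYPES[:-1]:  # drop granulocytes
        X[ct] = covariates[ct].astype(float)
    for s in SEASONS[1:]:  # winter reference
        X[f"season_{s}"] = (covariates["season"] == s).astype(float)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name a set of collinear columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(arr)
        small = [X.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"suspect columns: {small or list(X.columns)}"
        )


def residualize(
    m_matrix: MethylationMatrix,
    covariates: pd.DataFrame,
) -> MethylationMatrix:
    """Residuals of per-CpG OLS of M-values on cell proportions and season.

    The same design applies to every CpG at a given timepoint, so the
    projection is computed once and applied to the whole matrix. Subjects
    with any missing covariate are dropped (complete-case). Covariate
    columns constant across the retained samples carry no information beyond
    the intercept and are dropped before the rank check (so, e.g., a cohort
    sampled in a single season still residualizes cleanly).
    """
    if m_matrix.scale not in ("M", "residual"):
        raise ValueError("residualize expects an M-scale matrix; call .to_m() first")
    cov = covariates.loc[covariates.notna().all(axis=1)]
    samples = m_matrix.sample_ids.intersection(cov.index)
    if len(samples) == 0:
        raise AlignmentError("no samples shared between matrix and covariates")
    X = celltype_season_design(cov.loc[samples])
    constant = [c for c in X.columns if c != "intercept" and X[c].nunique() == 1]
    X = X.drop(columns=constant)
    _check_full_rank(X)
    V = m_matrix.values[samples].to_numpy()  # CpG x n
    Xa = X.to_numpy()
    coef, *_ = np.linalg.lstsq(Xa, V.T, rcond=None)
    resid = V - (Xa @ coef).T
    return MethylationMatrix(
        pd.DataFrame(resid, index=m_matrix.cpg_ids, columns=samples),
        scale="residual",
    )


def covariates_for(sheet: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Extract the cell-fraction + season covariate frame for one timepoint.

    The sample sheet stores per-timepoint columns suffixed ``_birth`` /
    ``_age10`` (e.g. ``CD4T_birth``, ``season_age10``).
    """
    if timepoint not in ("birth", "age10"):
        raise ValueError("timepoint must be 'birth' or 'age10'")
    cov = pd.DataFrame(index=sheet.index)
    for ct in CELL_TYPES:
        cov[ct] = sheet[f"{ct}_{timepoint}"]
    cov["season"] = sheet[f"season_{timepoint}"]
    return cov


def delta_pipeline(
    matrix_birth: MethylationMatrix,
    matrix_age10: MethylationMatrix,
    sheet: pd.DataFrame,
) -> DeltaMatrix:
    """Beta matrices at two ages -> delta residuals, in one call.

    Intersects CpGs/subjects, logit-transforms, residualizes each timepoint
    on its cell proportions and season, and differences the residuals.
    """
    mb, m10, _ = intersect_timepoints(matrix_birth, matrix_age10)
    resid_b = residualize(mb.to_m(), covariates_for(sheet, "birth"))
    resid_10 = residualize(m10.to_m(), covariates_for(sheet, "age10"))
    return delta_residuals(resid_10, resid_b)


def delta_residuals(
    resid_age10: MethylationMatrix,
    resid_birth: MethylationMatrix,
) -> DeltaMatrix:
    """Delta residuals: residual M at age 10 minus residual M at birth.

    A negative entry means methylation at that CpG declined from birth to
    age 10 (after cell-type/season adjustment) for that subject.
    """
    if not resid_age10.cpg_ids.equals(resid_birth.cpg_ids) or not resid_age10.sample_ids.equals(
        resid_birth.sample_ids
    ):
        raise AlignmentError("residual matrices are not aligned; run intersect_timepoints first")
    return DeltaMatrix(resid_age10.values - resid_birth.values)
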