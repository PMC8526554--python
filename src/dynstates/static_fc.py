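"""Static functional connectivity over the whole time course.

Edges are bivariate Pearson correlations between region time courses.
Covariates known to shift connectivity (age, gender, pre-treatment motor
severity on medication, in-scanner motion) are removed edge-wise across
subjects by least-squares residualization before the group matrix is formed.
The overall-FC scalar (mean of positive edges) later serves as the control
covariate for graph-metric associations, because proportional thresholding
leaves graphs sensitive to overall connectivity differences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ComputationError, InputError
from .io import PhenotypeRecord, SubjectTimeSeries

COVARIATE_NAMES = ("age_years", "gender", "updrs3_on_preop", "mean_framewise_displacement")


def static_fc(ts: SubjectTimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the full time course (diagonal zeroed)."""
    x = ts.data
    if x.shape[0] < 3:
        raise InputError(f"{ts.subject_id}: need at least 3 time points for correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        region = ts.region_labels[int(np.argmin(sd))]
        raise ComputationError(f"{ts.subject_id}: zero-variance region '{region}'")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return r


def fisher_z(r: np.ndarray, clip: float = 0.999999) -> np.ndarray:
    """Fisher's variance-stabilizing transform, z = atanh(r), clipped near |r|=1."""
    return np.arctanh(np.clip(r, -clip, clip))


def covariate_design(phenotypes: Sequence[PhenotypeRecord]) -> np.ndarray:
    """Design matrix [1, age, gender, UPDRS-III ON, mean FD] across subjects."""
    rows = [
        [1.0] + [float(getattr(p, name)) for name in COVARIATE_NAMES]
        for p in phenotypes
    ]
    return np.asarray(rows)


def adjust_for_covariates(
    matrices: Sequence[np.ndarray],
    design: np.ndarray | None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Residualize every edge across subjects against the covariate design
    (with intercept), re-add the cohort mean, and average into a group matrix.

    ``design`` of shape (n_subjects, 1 + n_covariates); ``None`` or an
    intercept-only design leaves the matrices unchanged.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    n = len(mats)
    if n == 0:
        raise InputError("no matrices to adjust")
    r = mats[0].shape[0]
    stacked = np.stack(mats)                       # subjects x R x R
    if design is None:
        adjusted = stacked.copy()
    else:
        design = np.asarray(design, dtype=float)
        if design.shape[0] != n:
            raise InputError("design rows must match number of subjects")
        q = design.shape[1]
        n_covariates = q - 1  # design includes the intercept column
        if n < n_covariates + 2:
            raise InputError(
                f"need at least {n_covariates + 2} subjects for "
                f"{n_covariates} covariates")
        if np.linalg.matrix_rank(design) < q:
            raise ComputationError("rank-deficient covariate design")
        iu, ju = np.triu_indices(r, k=1)
        y = stacked[:, iu, ju]                     # subjects x edges
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        adj_edges = resid + y.mean(axis=0)         # re-add cohort mean per edge
        adjusted = np.zeros_like(stacked)
        adjusted[:, iu, ju] = adj_edges
        adjusted[:, ju, iu] = adj_edges
    group = adjusted.mean(axis=0)
    np.fill_diagonal(group, 0.0)
    return [adjusted[i] for i in range(n)], group


def overall_fc(matrix: np.ndarray) -> float:
    """Mean of the strictly positive upper-triangle values."""
    m = np.asarray(matrix, dtype=float)
    iu, ju = np.triu_indices(m.shape[0], k=1)
    vals = m[iu, ju]
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ComputationError("no positive connectivity values; subject flagged")
    return float(pos.mean())


def edgewise_variance(matrices: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    """Per-edge cross-subject sample variance (n-1 denominator) and its mean
    over upper-triangle edges."""
    if len(matrices) < 2:
        raise InputError("edgewise variance needs at least 2 matrices")
    stacked = np.stack([np.asarray(m, dtype=float) for m in matrices])
    var = stacked.var(axis=0, ddof=1)
    np.fill_diagonal(var, 0.0)
    iu, ju = np.triu_indices(var.shape[0], k=1)
    return var, float(var[iu, ju].mean())
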