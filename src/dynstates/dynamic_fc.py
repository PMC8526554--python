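"""Sliding-window dynamic functional connectivity with L1 regularization.

Each subject's time course is cut into tapered windows (default 22 TRs =
59.4 s at TR 2.7 s, stepped by 1 TR). Because 22 samples is short for a
25-region covariance, the precision matrix in each window is estimated by
graphical lasso; the penalty is chosen per subject by held-out Gaussian
log-likelihood over random train/test splits of the windows. Windowed
matrices are reported on the correlation scale, like static FC.

Window-count convention: floor((T - W) / step) windows, starting at
0, step, 2*step, ... — the final taper position is dropped. With T = 253,
W = 22, step = 1 this yields 231 windows.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .config import RunConfig
from .errors import ComputationError, InputError
from .io import SubjectTimeSeries


@dataclasses.dataclass
class WindowSpec:
    """Sliding-window geometry: length W, Gaussian taper sigma, step (in TRs)."""

    length_tr: int = 22
    taper_sigma_tr: float = 3.0
    step_tr: int = 1
    tr_seconds: float = 2.7

    def __post_init__(self) -> None:
        if self.length_tr < 2:
            raise InputError("window length must be >= 2 TRs")
        if self.taper_sigma_tr <= 0:
            raise InputError("taper sigma must be > 0")
        if self.step_tr < 1:
            raise InputError("step must be >= 1 TR")
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.length_tr * self.tr_seconds

    @classmethod
    def from_config(cls, config: RunConfig) -> "WindowSpec":
        return cls(
            length_tr=config.window_length_tr,
            taper_sigma_tr=config.taper_sigma_tr,
            step_tr=config.step_tr,
            tr_seconds=config.tr_seconds,
        )


@dataclasses.dataclass
class WindowedSeries:
    """Per-window correlation matrices for one subject."""

    subject_id: str
    matrices: list[np.ndarray]
    window_start_indices: np.ndarray
    lambda_used: float
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return len(self.matrices)


def n_windows(t: int, spec: WindowSpec) -> int:
    """Number of sliding windows: floor((T - W) / step); requires T > W."""
    if t <= spec.length_tr:
        raise InputError(
            f"time series length {t} must exceed window length {spec.length_tr}"
        )
    return (t - spec.length_tr) // spec.step_tr


def window_starts(t: int, spec: WindowSpec) -> np.ndarray:
    return np.arange(n_windows(t, spec)) * spec.step_tr


def taper_weights(spec: WindowSpec) -> np.ndarray:
    """Rectangle of length W convolved with a unit-mass Gaussian (sd = sigma,
    support +/- ceil(3 sigma)), central W samples kept, renormalized to sum 1.

    The result is symmetric and strictly positive.
    """
    w = spec.length_tr
    sigma = spec.taper_sigma_tr
    half = int(np.ceil(3 * sigma))
    support = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (support / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(w), kernel, mode="full")  # length w + 2*half
    central = full[half : half + w]
    return central / central.sum()


def _weighted_cov(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Covariance with normalized observation weights, weighted mean removed."""
    mu = weights @ x
    xc = x - mu
    return (xc * weights[:, None]).T @ xc


def window_covariances(ts: SubjectTimeSeries, spec: WindowSpec) -> list[np.ndarray]:
    """Raw taper-weighted covariance per window (input to penalized fits)."""
    weights = taper_weights(spec)
    starts = window_starts(ts.n_timepoints, spec)
    return [_weighted_cov(ts.data[s : s + spec.length_tr], weights) for s in starts]


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return corr


def penalized_correlation(cov: np.ndarray, lam: float, window_index: int = -1) -> np.ndarray:
    """Graphical-lasso estimate at penalty ``lam``, returned on the correlation
    scale with a zeroed diagonal. ``lam = 0`` reduces to the sample correlation.

    A window of W samples over R > W regions has a rank-deficient covariance,
    so a small diagonal ridge (1e-2 of the mean variance, escalated up to
    1e-1 on solver failure) stabilizes the solver; the L1 penalty itself does
    the statistical regularization.
    """
    if lam < 0:
        raise InputError("penalty must be >= 0")
    if lam == 0:
        return _cov_to_corr(cov)
    scale = float(np.mean(np.diag(cov)))
    last_err: Exception | None = None
    for ridge in (1e-2, 3e-2, 1e-1):
        s = cov + ridge * scale * np.eye(cov.shape[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                cov_est, _ = _sk_graphical_lasso(
                    s, alpha=lam * scale, tol=1e-3, max_iter=100)
            return _cov_to_corr(cov_est)
        except FloatingPointError as e:
            last_err = e
    raise ComputationError(
        f"graphical lasso failed to converge at window {window_index}: {last_err}"
    ) from last_err


def windowed_fc(ts: SubjectTimeSeries, spec: WindowSpec, lam: float) -> WindowedSeries:
    """Tapered, L1-regularized FC matrix for every sliding window."""
    if lam < 0:
        raise InputError("penalty must be >= 0")
    covs = window_covariances(ts, spec)
    mats = [penalized_correlation(c, lam, i) for i, c in enumerate(covs)]
    return WindowedSeries(
        subject_id=ts.subject_id,
        matrices=mats,
        window_start_indices=window_starts(ts.n_timepoints, spec),
        lambda_used=lam,
        spec=spec,
    )


def _gaussian_loglik(test_cov: np.ndarray, precision: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(test_cov @ precision))


def select_lambda(
    covariances: Sequence[np.ndarray],
    grid: Sequence[float],
    n_reps: int = 10,
    seed: int = 0,
    return_scores: bool = False,
):
    """Pick the penalty maximizing mean held-out Gaussian log-likelihood.

    For each repetition the windows are split into random train/test halves;
    a penalized precision is fit to the pooled (averaged) train covariance at
    each grid value and scored by the average log-likelihood it assigns to
    the test-window covariances. Deterministic given ``seed``.
    """
    grid = list(grid)
    if not grid:
        raise InputError("lambda grid must be non-empty")
    if any(l < 0 for l in grid):
        raise InputError("penalties must be >= 0")
    if len(grid) == 1 and not return_scores:
        return float(grid[0])
    covs = [np.asarray(c) for c in covariances]
    n = len(covs)
    if n < 4:
        raise InputError("lambda selection needs at least 4 windows")
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_reps, len(grid)))
    for rep in range(n_reps):
        perm = rng.permutation(n)
        train, test = perm[: n // 2], perm[n // 2 :]
        pooled = np.mean([covs[i] for i in train], axis=0)
        for gi, lam in enumerate(grid):
            if lam == 0:
                prec = np.linalg.pinv(pooled)
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        _, prec = _sk_graphical_lasso(
                            pooled, alpha=lam * float(np.mean(np.diag(pooled))),
                            max_iter=500)
                except FloatingPointError:
                    scores[rep, gi] = -np.inf
                    continue
            scores[rep, gi] = float(
                np.mean([_gaussian_loglik(covs[i], prec) for i in test])
            )
    mean_scores = scores.mean(axis=0)
    best = float(grid[int(np.argmax(mean_scores))])
    if return_scores:
        return best, dict(zip(grid, mean_scores))
    return best
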