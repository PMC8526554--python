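"""Covariate-controlled association between network measures and DBS response.

The clinical outcome is the percent improvement of the UPDRS-III motor score
from stimulation-OFF to stimulation-ON (both on medication) one year after
surgery. Associations are Pearson partial correlations: graph-metric AUCs
and FC edges control for the subject's overall FC (proportional thresholding
leaves graphs sensitive to it); temporal state statistics are tested without
an additional covariate. Age, gender, pre-treatment severity and motion are
not re-entered here — they were already removed edge-wise during static FC
adjustment. Multiple testing is corrected per family (one family per local
metric per state across nodes; one per state across FC edges) with
Benjamini-Hochberg; global-metric tests are reported uncorrected.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, InputError


def dbs_response(onoff: float, onon: float) -> float:
    """Percent improvement from stimulation-OFF to stimulation-ON:
    100 * (onoff - onon) / onoff."""
    if onoff <= 0:
        raise InputError("ON-OFF score must be positive to define response")
    if onon < 0:
        raise InputError("ON-ON score must be >= 0")
    return 100.0 * (onoff - onon) / onoff


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> tuple[float, float, tuple[float, float]]:
    """Pearson partial correlation of ``x`` and ``y`` given covariates ``z``.

    Both variables are residualized (with intercept) against the covariate
    columns and the residuals correlated. p comes from the t statistic with
    n - 2 - q degrees of freedom; the 95% CI from Fisher's z with variance
    1 / (n - 3 - q). With no covariates this is the plain product-moment
    correlation. Returns (r, p, (ci_low, ci_high)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise InputError("x and y must have equal length")
    if z is None or (hasattr(z, "size") and np.asarray(z).size == 0):
        zmat = np.ones((n, 1))
        q = 0
    else:
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise InputError("covariate rows must match x")
        zmat = np.column_stack([np.ones(n), z])
        q = z.shape[1]
        if np.linalg.matrix_rank(zmat) < zmat.shape[1]:
            raise ComputationError("rank-deficient covariate design")
    if n <= q + 2:
        raise InputError(f"need more than {q + 2} observations for {q} covariates")
    beta_x, *_ = np.linalg.lstsq(zmat, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(zmat, y, rcond=None)
    rx = x - zmat @ beta_x
    ry = y - zmat @ beta_y
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ComputationError("zero residual variance; correlation undefined")
    r = float(np.clip(np.mean(rx * ry) / (sx * sy), -1.0, 1.0))
    dof = n - 2 - q
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2 * sp_stats.t.sf(abs(t), dof))
    if n - 3 - q > 0 and abs(r) < 1.0:
        zr = np.arctanh(r)
        half = sp_stats.norm.ppf(0.975) / np.sqrt(n - 3 - q)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (r, r)
    return r, max(p, np.finfo(float).tiny), ci


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


@dataclasses.dataclass
class AssociationResult:
    """One association test between a network measure and DBS response."""

    metric_name: str
    state: str                 # "static", "1", "2", ...
    node: str | None
    family: str
    r_partial: float
    ci95: tuple[float, float]
    p_value: float
    p_fdr: float
    n_used: int
    covariates_used: tuple[str, ...]


def _run_family(targets, y_by_subject, covar_by_subject, family, state,
                covariate_names, corrected=True, min_n=8):
    """targets: list of (metric_name, node, {subject_id: value})."""
    rows = []
    for metric_name, node, values in targets:
        ids = [s for s, v in values.items()
               if np.isfinite(v) and s in y_by_subject]
        if len(ids) < min_n:
            continue
        x = np.array([values[s] for s in ids])
        y = np.array([y_by_subject[s] for s in ids])
        z = (np.array([covar_by_subject[s] for s in ids])
             if covar_by_subject is not None else None)
        try:
            r, p, ci = partial_correlation(x, y, z)
        except ComputationError:
            continue
        rows.append(AssociationResult(
            metric_name=metric_name, state=state, node=node, family=family,
            r_partial=r, ci95=ci, p_value=p, p_fdr=p, n_used=len(ids),
            covariates_used=covariate_names,
        ))
    if corrected and rows:
        adj = fdr_bh([row.p_value for row in rows])
        for row, a in zip(rows, adj):
            row.p_fdr = float(a)
    return rows


def associate(
    auc_tables: dict,
    fc_matrices: dict,
    temporal: Sequence,
    response: dict,
    overall_fc_by_subject: dict,
    region_labels: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """All association tests against DBS response.

    Parameters
    ----------
    auc_tables
        ``{condition: {subject_id: GraphMetricProfile-like auc dict}}`` with
        conditions "static", "1", "2", ... (missing states simply absent).
    fc_matrices
        ``{condition: {subject_id: R x R matrix or None}}``.
    temporal
        ``TemporalStats`` per subject (empty for static-only runs).
    response
        ``{subject_id: percent improvement}``.
    overall_fc_by_subject
        ``{subject_id: overall-FC scalar}`` — the control covariate for
        graph-metric and edge tests.
    """
    y = {s: float(v) for s, v in response.items()}
    if len(set(np.round(list(y.values()), 12))) < 2:
        raise ComputationError("response has zero variance across subjects")
    covar = {s: np.array([overall_fc_by_subject[s]])
             for s in overall_fc_by_subject}
    results: list[AssociationResult] = []

    for condition, by_subject in auc_tables.items():
        # global metrics: uncorrected, overall-FC controlled
        for metric in ("global_efficiency", "assortativity"):
            values = {
                s: float(auc[metric])
                for s, auc in by_subject.items() if metric in auc
            }
            results += _run_family(
                [(metric + "_auc", None, values)], y, covar,
                family=f"global/{condition}", state=condition,
                covariate_names=("overall_fc",), corrected=False,
            )
        # local metrics: one FDR family per metric per condition, across nodes
        for metric in ("clustering_coeff", "betweenness"):
            targets = []
            any_subject = next(iter(by_subject.values()), None)
            if any_subject is None or metric not in any_subject:
                continue
            n_nodes = len(any_subject[metric])
            for j in range(n_nodes):
                label = (region_labels[j] if region_labels is not None
                         else f"R{j + 1}")
                values = {
                    s: float(auc[metric][j])
                    for s, auc in by_subject.items() if metric in auc
                }
                targets.append((metric + "_auc", label, values))
            results += _run_family(
                targets, y, covar,
                family=f"local/{metric}/{condition}", state=condition,
                covariate_names=("overall_fc",), corrected=True,
            )

    # FC edges: one FDR family per condition
    for condition, by_subject in fc_matrices.items():
        mats = {s: m for s, m in by_subject.items() if m is not None}
        if not mats:
            continue
        r_dim = next(iter(mats.values())).shape[0]
        iu, ju = np.triu_indices(r_dim, k=1)
        targets = []
        for i, j in zip(iu, ju):
            li = region_labels[i] if region_labels is not None else f"R{i + 1}"
            lj = region_labels[j] if region_labels is not None else f"R{j + 1}"
            values = {s: float(m[i, j]) for s, m in mats.items()}
            targets.append(("fc_edge", f"{li}--{lj}", values))
        results += _run_family(
            targets, y, covar,
            family=f"edges/{condition}", state=condition,
            covariate_names=("overall_fc",), corrected=True,
        )

    # temporal statistics: no extra covariate, uncorrected
    if temporal:
        k = len(temporal[0].fraction_time)
        for s_idx in range(k):
            frac = {t.subject_id: float(t.fraction_time[s_idx]) for t in temporal}
            dwell = {t.subject_id: float(t.mean_dwell_minutes[s_idx]) for t in temporal}
            results += _run_family(
                [("fraction_time", None, frac)], y, None,
                family="temporal", state=str(s_idx + 1),
                covariate_names=(), corrected=False,
            )
            results += _run_family(
                [("mean_dwell", None, dwell)], y, None,
                family="temporal", state=str(s_idx + 1),
                covariate_names=(), corrected=False,
            )
        trans = {t.subject_id: float(t.n_transitions) for t in temporal}
        results += _run_family(
            [("n_transitions", None, trans)], y, None,
            family="temporal", state="all",
            covariate_names=(), corrected=False,
        )
    return results


_RESULT_COLUMNS = ("metric", "state", "node", "family", "r_partial",
                   "ci95_low", "ci95_high", "p_value", "p_fdr", "n_used",
                   "covariates")


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy one-row-per-test results table (schema kept even when empty)."""
    if not results:
        return pd.DataFrame(columns=list(_RESULT_COLUMNS))
    return pd.DataFrame([
        {
            "metric": r.metric_name,
            "state": r.state,
            "node": r.node if r.node is not None else "",
            "family": r.family,
            "r_partial": r.r_partial,
            "ci95_low": r.ci95[0],
            "ci95_high": r.ci95[1],
            "p_value": r.p_value,
            "p_fdr": r.p_fdr,
            "n_used": r.n_used,
            "covariates": "+".join(r.covariates_used),
        }
        for r in results
    ])
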