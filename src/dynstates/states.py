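"""Brain-state decomposition of windowed FC by k-means clustering.

All windows from all subjects are pooled (states must be common to the
cohort), embedded as Fisher-z upper-triangle vectors, and clustered with
k-means over a range of candidate k. The number of states is chosen by mean
silhouette and validated with a spherical-Gaussian BIC. States are then
relabeled so that state 1 is the most connected (highest mean centroid
connectivity) — in a two-state solution, state 1 is the hyperconnected and
state 2 the hypoconnected state. Per subject and state, an element-wise
median matrix summarizes the windows, and run-length temporal statistics
(fraction time, mean dwell in minutes, transition count) are derived from
the label sequence.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .dynamic_fc import WindowSpec, WindowedSeries
from .errors import ComputationError, InputError
from .static_fc import fisher_z


@dataclasses.dataclass
class TemporalStats:
    """Per-subject temporal properties of the state label sequence."""

    subject_id: str
    fraction_time: np.ndarray       # per state, sums to 1
    mean_dwell_minutes: np.ndarray  # per state, NaN for unvisited states
    n_transitions: int


@dataclasses.dataclass
class StateDecomposition:
    """Cohort-level clustering result plus per-subject summaries."""

    k: int
    centroids: np.ndarray                       # k x n_edges, Fisher-z scale
    labels: dict                                # subject_id -> window labels (1-based)
    state_matrices: dict                        # subject_id -> list of R x R medians or None
    cohort_state_matrices: list                 # per state, cohort-level median matrix
    temporal: list                              # TemporalStats per subject
    silhouette_by_k: dict
    bic_by_k: dict
    n_regions: int


def matrices_to_features(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Fisher-z upper-triangle edge vectors, one row per window."""
    r = np.asarray(matrices[0]).shape[0]
    iu, ju = np.triu_indices(r, k=1)
    feats = np.stack([np.asarray(m)[iu, ju] for m in matrices])
    return fisher_z(feats)


def silhouette_mean(features: np.ndarray, labels: np.ndarray,
                    distance: str = "euclidean") -> float:
    """Mean silhouette (b - a) / max(a, b); singleton clusters contribute 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("silhouette needs at least 2 clusters")
    metric = "cityblock" if distance == "cityblock" else "euclidean"
    return float(np.mean(silhouette_samples(features, labels, metric=metric)))


def bic_for_k(features: np.ndarray, labels: np.ndarray,
              centroids: np.ndarray) -> float:
    """Spherical-Gaussian BIC: n*d*ln(WSS/(n*d)) + k*(d+1)*ln(n).

    WSS is the total within-cluster squared Euclidean distance. Degenerate
    (WSS = 0) clusterings are rejected.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n, d = features.shape
    k = centroids.shape[0]
    wss = 0.0
    for c in range(k):
        members = features[labels == c]
        if members.size:
            wss += float(np.sum((members - centroids[c]) ** 2))
    if wss <= 0:
        raise ComputationError("degenerate clustering: zero within-cluster dispersion")
    return n * d * np.log(wss / (n * d)) + k * (d + 1) * np.log(n)


def _kmedians_cityblock(features: np.ndarray, k: int, reps: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd-style k-medians under city-block distance, best of ``reps`` restarts."""
    n = features.shape[0]
    best_cost, best = np.inf, None
    for _ in range(reps):
        centroids = features[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(300):
            dist = np.abs(features[:, None, :] - centroids[None]).sum(axis=2)
            new_labels = dist.argmin(axis=1)
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for c in range(k):
                members = features[labels == c]
                if members.size:
                    centroids[c] = np.median(members, axis=0)
        cost = float(np.abs(features - centroids[labels]).sum())
        if cost < best_cost:
            best_cost, best = cost, (labels.copy(), centroids.copy())
    return best


def _fit_kmeans(features: np.ndarray, k: int, reps: int, seed: int,
                distance: str) -> tuple[np.ndarray, np.ndarray]:
    if distance == "cityblock":
        rng = np.random.default_rng(seed)
        return _kmedians_cityblock(features, k, reps, rng)
    km = KMeans(n_clusters=k, init="random", n_init=reps,
                random_state=seed % (2**32), algorithm="lloyd")
    labels = km.fit_predict(features)
    return labels, km.cluster_centers_


def cluster_states(
    windowed: Sequence[WindowedSeries],
    k_range: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    distance: str = "euclidean",
) -> StateDecomposition:
    """Pool all subjects' windows, select k by mean silhouette, and relabel
    states by descending centroid mean connectivity (state 1 = most connected).

    Deterministic given ``seed``. Raises when the largest candidate k is not
    below the number of distinct feature vectors.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or min(k_range) < 2:
        raise InputError("k candidates must be integers >= 2")
    all_mats, owners = [], []
    for ws in windowed:
        all_mats.extend(ws.matrices)
        owners.extend([ws.subject_id] * ws.n_windows)
    if not all_mats:
        raise InputError("no windows to cluster")
    r = all_mats[0].shape[0]
    if any(m.shape[0] != r for m in all_mats):
        raise InputError("all windowed matrices must share the region count")
    features = matrices_to_features(all_mats)
    n_distinct = np.unique(features, axis=0).shape[0]
    if max(k_range) >= n_distinct:
        raise InputError(
            f"largest k ({max(k_range)}) must be below the number of distinct "
            f"windows ({n_distinct})"
        )
    sil_by_k, bic_by_k, fits = {}, {}, {}
    for ki, k in enumerate(k_range):
        labels, centroids = _fit_kmeans(features, k, reps, seed + 1000 * ki, distance)
        sil_by_k[k] = silhouette_mean(features, labels, distance)
        bic_by_k[k] = bic_for_k(features, labels, centroids)
        fits[k] = (labels, centroids)
    best_k = max(sil_by_k, key=lambda k: (sil_by_k[k], -k))
    labels, centroids = fits[best_k]
    # relabel: state 1 = highest mean connectivity centroid (on the r scale)
    order = np.argsort(-np.tanh(centroids).mean(axis=1), kind="stable")
    remap = np.empty(best_k, dtype=int)
    remap[order] = np.arange(1, best_k + 1)
    labels_1based = remap[labels]
    centroids_ordered = centroids[order]

    per_subject_labels: dict[str, np.ndarray] = {}
    pos = 0
    for ws in windowed:
        per_subject_labels[ws.subject_id] = labels_1based[pos : pos + ws.n_windows]
        pos += ws.n_windows

    state_matrices = {
        ws.subject_id: state_medians(ws.matrices, per_subject_labels[ws.subject_id], best_k)
        for ws in windowed
    }
    cohort_meds = []
    for s in range(1, best_k + 1):
        pool = [m for m, lab in zip(all_mats, labels_1based) if lab == s]
        cohort_meds.append(np.median(np.stack(pool), axis=0) if pool else None)
    temporal = [
        temporal_stats(per_subject_labels[ws.subject_id], ws.spec, best_k, ws.subject_id)
        for ws in windowed
    ]
    return StateDecomposition(
        k=best_k,
        centroids=centroids_ordered,
        labels=per_subject_labels,
        state_matrices=state_matrices,
        cohort_state_matrices=cohort_meds,
        temporal=temporal,
        silhouette_by_k=sil_by_k,
        bic_by_k=bic_by_k,
        n_regions=r,
    )


def state_medians(matrices: Sequence[np.ndarray], labels: np.ndarray,
                  k: int) -> list:
    """Element-wise median matrix per state; ``None`` for unvisited states."""
    labels = np.asarray(labels)
    if len(labels) != len(matrices):
        raise InputError("labels must align with windows")
    out = []
    for s in range(1, k + 1):
        members = [m for m, lab in zip(matrices, labels) if lab == s]
        out.append(np.median(np.stack(members), axis=0) if members else None)
    return out


def temporal_stats(labels: np.ndarray, spec: WindowSpec, k: int,
                   subject_id: str = "") -> TemporalStats:
    """Fraction time, mean dwell (minutes), and transition count from the
    per-window state labels. Dwell converts run length in windows to minutes
    via step * TR / 60."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InputError("empty label sequence")
    n = labels.size
    fraction = np.array([np.mean(labels == s) for s in range(1, k + 1)])
    # maximal runs
    change = np.flatnonzero(np.diff(labels) != 0)
    run_ends = np.append(change, n - 1)
    run_starts = np.insert(change + 1, 0, 0)
    run_states = labels[run_starts]
    run_lengths = run_ends - run_starts + 1
    minutes_per_window = spec.step_tr * spec.tr_seconds / 60.0
    dwell = np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = run_states == s
        if mask.any():
            dwell[s - 1] = run_lengths[mask].mean() * minutes_per_window
    return TemporalStats(
        subject_id=subject_id,
        fraction_time=fraction,
        mean_dwell_minutes=dwell,
        n_transitions=int(len(change)),
    )
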