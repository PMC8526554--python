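"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a resting-state DBS cohort: 25
post-ICA region time courses in 8 canonical networks, 253 volumes at
TR = 2.7 s, and two latent connectivity states alternating under a
first-order Markov chain — a hyperconnected state (strong within- and
between-network coupling) and a hypoconnected state in which strong
connections survive only inside portions of the sensorimotor, default-mode
and visual networks. Observations are drawn from the active state's
covariance, AR(1)-smoothed, and column-standardized.

Each subject carries a latent "resilience" that rewires the hypoconnected
state's weight template by interpolating between two edge-disjoint
topologies: an assortative design (a strong clique plus a second-tier
clique, so connected nodes have matching degrees) and a disassortative
star forest (few hubs wired to many degree-one leaves). Resilient subjects
lie near the clique end and yield assortative thresholded graphs; fragile
subjects near the star end yield disassortative ones. The clinical
response variable is an affine function of the resulting true
hypoconnected-state assortativity AUC plus Gaussian noise, calibrated so the
population correlation equals ``planted_response_correlation`` (default
-0.7, matching the association the pipeline is designed to detect).
Occupancy, dwell time and transition counts are controlled by the per-state
stay probabilities, whose defaults target roughly 2:1 occupancy in favour of
the hypoconnected state and about four transitions per scan.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ComputationError, InputError
from .graphs import assortativity_auc
from .io import PhenotypeRecord, SubjectTimeSeries
from .stats import dbs_response

#: Region -> network assignment for the default 25-region layout
#: (counts follow the 8-network decomposition: 1 Sa, 7 DMN, 7 FPN, 4 SM,
#: 2 Ce, 2 Vi, 1 Au, 1 La).
DEFAULT_NETWORKS: tuple[str, ...] = (
    ("Sa",) * 1 + ("DMN",) * 7 + ("FPN",) * 7 + ("SM",) * 4
    + ("Ce",) * 2 + ("Vi",) * 2 + ("Au",) * 1 + ("La",) * 1
)

#: Networks that keep strong internal coupling in the hypoconnected state.
ACTIVE_NETWORKS = ("SM", "DMN", "Vi")


@dataclasses.dataclass
class CohortSpec:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects: int = 18
    n_timepoints: int = 253
    tr_seconds: float = 2.7
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    stay_probs: tuple[float, float] = (0.970, 0.988)
    ar_coefficient: float = 0.3
    planted_response_correlation: float = -0.7
    # hyperconnected-state template
    hyper_within: float = 0.60
    hyper_between: float = 0.25
    # hypoconnected-state template
    hypo_strong_max: float = 0.62       # top weight of clique and star edges
    hypo_grade: float = 0.004           # per-rank decrement within an edge class
    hypo_tier2_max: float = 0.46        # top weight of the second-tier clique
    hypo_background: float = 0.05
    hypo_background_jitter: float = 0.02
    # clinical response scale (percent improvement)
    response_mean: float = 53.5
    response_sd: float = 16.7

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise InputError("cohort needs at least 4 subjects")
        if self.n_timepoints < 2:
            raise InputError("need at least 2 time points")
        if abs(self.planted_response_correlation) >= 1:
            raise InputError("planted correlation must have |r| < 1")
        for p in self.stay_probs:
            if not 0 < p <= 1:
                raise InputError("stay probabilities must lie in (0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.networks)


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: CohortSpec
    seed: int
    subject_ids: list
    state_sequences: dict            # subject_id -> per-TR state labels (1/2)
    state1_covariance: np.ndarray    # shared hyperconnected correlation matrix
    state2_covariances: dict         # subject_id -> hypoconnected matrix
    resilience: dict                 # subject_id -> latent scalar in [-1, 1]
    state2_assortativity_auc: dict   # subject_id -> true AUC (threshold sweep)
    response_pct: dict               # subject_id -> percent improvement
    region_labels: tuple
    network_labels: tuple

    def occupancy(self, subject_id: str, state: int) -> float:
        seq = self.state_sequences[subject_id]
        return float(np.mean(seq == state))

    def window_labels(self, subject_id: str, window_length: int,
                      step: int = 1) -> np.ndarray:
        """Majority state per sliding window (ground truth for clustering)."""
        seq = self.state_sequences[subject_id]
        n = (len(seq) - window_length) // step
        out = np.empty(n, dtype=int)
        for i in range(n):
            win = seq[i * step : i * step + window_length]
            out[i] = 1 if np.mean(win == 1) > 0.5 else 2
        return out


def planted_state_sequence(
    t: int,
    stay_probs: Sequence[float],
    seed: int,
    start_state: int | None = None,
) -> np.ndarray:
    """First-order Markov realization of 1-based state labels.

    ``stay_probs[s-1]`` is the probability of remaining in state ``s`` at
    each step. The start state is drawn from the stationary distribution of
    the two-state chain unless given explicitly (required when both states
    are absorbing).
    """
    if t < 1:
        raise InputError("sequence length must be >= 1")
    stay = [float(p) for p in stay_probs]
    if len(stay) != 2:
        raise InputError("exactly two states are supported")
    for p in stay:
        if not 0 <= p <= 1:
            raise InputError(f"stay probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    leave = [1 - p for p in stay]
    if start_state is None:
        denom = leave[0] + leave[1]
        if denom == 0:
            raise InputError(
                "both states absorbing: supply start_state explicitly"
            )
        pi1 = leave[1] / denom
        state = 1 if rng.random() < pi1 else 2
    else:
        if start_state not in (1, 2):
            raise InputError("start_state must be 1 or 2")
        state = start_state
    seq = np.empty(t, dtype=int)
    seq[0] = state
    for i in range(1, t):
        if rng.random() < stay[state - 1]:
            pass
        else:
            state = 3 - state
        seq[i] = state
    return seq


def _nearest_corr(c: np.ndarray, min_eig: float = 0.05) -> np.ndarray:
    """Uniform-shrink PD repair: C <- (C + a*I) / (1 + a). This preserves the
    rank order of off-diagonal entries exactly, so thresholded graphs (and
    hence assortativity) are unchanged."""
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    lam = np.linalg.eigvalsh(c).min()
    if lam < min_eig:
        a = min_eig - lam
        c = (c + a * np.eye(c.shape[0])) / (1 + a)
        np.fill_diagonal(c, 1.0)
    return c


def hyperconnected_template(spec: CohortSpec) -> np.ndarray:
    """Shared state-1 correlation matrix: strong within-network blocks over a
    moderate global background."""
    nets = np.asarray(spec.networks)
    same = nets[:, None] == nets[None, :]
    c = np.where(same, spec.hyper_within, spec.hyper_between).astype(float)
    return _nearest_corr(c)


def _hypo_edge_classes(spec: CohortSpec):
    """Edge lists of the two resilience-extreme topologies.

    Active regions (SM, DMN, Vi) are split into a primary clique (first 8)
    and a second tier (the rest). The assortative design wires both tiers as
    cliques; the disassortative design wires up to three second-tier nodes
    as star hubs onto degree-one leaves drawn from the primary clique and
    the inactive regions. The three edge sets are pairwise disjoint, so
    interpolating their weights moves graph composition continuously.
    """
    nets = np.asarray(spec.networks)
    active = [i for i in range(len(nets)) if nets[i] in ACTIVE_NETWORKS]
    inactive = [i for i in range(len(nets)) if nets[i] not in ACTIVE_NETWORKS]
    if len(active) < 10:
        raise InputError("hypoconnected template needs >= 10 active regions")
    clique = active[:8]
    tier2 = active[8:]
    hubs = tier2[: min(3, len(tier2))]
    clique_edges = [(a, b) for ai, a in enumerate(clique) for b in clique[ai + 1:]]
    tier2_edges = [(a, b) for ai, a in enumerate(tier2) for b in tier2[ai + 1:]]
    # star leaves: clique nodes first, then inactive nodes, dealt round-robin
    pool = clique + inactive
    star_edges = []
    per_hub = min(7, len(pool) // max(1, len(hubs)))
    for h_idx, h in enumerate(hubs):
        for leaf in pool[h_idx * per_hub : (h_idx + 1) * per_hub]:
            star_edges.append((min(h, leaf), max(h, leaf)))
    return clique_edges, tier2_edges, star_edges


def hypoconnected_template(
    spec: CohortSpec, resilience: float, background_jitter: np.ndarray
) -> np.ndarray:
    """Subject-specific state-2 correlation matrix.

    ``resilience`` in [-1, 1] interpolates between the disassortative star
    forest (-1) and the assortative clique design (+1); weights within each
    edge class are graded by rank so the thresholded edge set shifts
    smoothly. ``background_jitter`` is a fixed symmetric matrix of small
    perturbations shared by the cohort (it breaks ties among background
    edges deterministically)."""
    n = spec.n_regions
    clique_edges, tier2_edges, star_edges = _hypo_edge_classes(spec)
    bg = spec.hypo_background
    w_a = np.full((n, n), bg)           # assortative extreme
    w_d = np.full((n, n), bg)           # disassortative extreme
    for k, (i, j) in enumerate(clique_edges):
        w_a[i, j] = w_a[j, i] = spec.hypo_strong_max - spec.hypo_grade * k
    for k, (i, j) in enumerate(tier2_edges):
        w_a[i, j] = w_a[j, i] = spec.hypo_tier2_max - spec.hypo_grade * k
    for k, (i, j) in enumerate(star_edges):
        w_d[i, j] = w_d[j, i] = spec.hypo_strong_max - spec.hypo_grade * k
    a = (1.0 + resilience) / 2.0
    c = a * w_a + (1.0 - a) * w_d + background_jitter
    c = (c + c.T) / 2.0
    return _nearest_corr(c)


def generate_subject(
    subject_id: str,
    state_sequence: np.ndarray,
    covariances: Sequence[np.ndarray],
    tr_seconds: float,
    seed: int,
    ar_coefficient: float = 0.3,
    region_labels: Sequence[str] | None = None,
    network_labels: Sequence[str] | None = None,
) -> SubjectTimeSeries:
    """Sample a subject's time series: at each TR draw from the active
    state's zero-mean Gaussian, AR(1)-smooth, and restandardize columns.
    Deterministic given ``seed``."""
    t = len(state_sequence)
    r = covariances[0].shape[0]
    chols = []
    for c in covariances:
        try:
            chols.append(np.linalg.cholesky(np.asarray(c, dtype=float)))
        except np.linalg.LinAlgError as e:
            raise ComputationError(f"state covariance not positive definite: {e}") from e
    rng = np.random.default_rng(seed)
    innovations = rng.standard_normal((t, r))
    x = np.empty((t, r))
    for i in range(t):
        sample = chols[state_sequence[i] - 1] @ innovations[i]
        x[i] = sample if i == 0 else ar_coefficient * x[i - 1] + sample
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    if region_labels is None:
        region_labels = tuple(f"IC{j + 1:02d}" for j in range(r))
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=x,
        tr_seconds=tr_seconds,
        region_labels=tuple(region_labels),
        network_labels=tuple(network_labels) if network_labels is not None else None,
    )


def truth_level_association(truth: "GroundTruth") -> tuple[float, float]:
    """Partial correlation (r, p) between the true hypoconnected-state
    assortativity AUC and the planted response, controlling each subject's
    overall FC (computed from the occupancy-weighted true state matrices).

    This is the generator-side power check: it measures the association on
    ground truth, bypassing estimation noise from windowing and clustering.
    """
    from .static_fc import overall_fc
    from .stats import partial_correlation

    ids = truth.subject_ids
    x = np.array([truth.state2_assortativity_auc[s] for s in ids])
    y = np.array([truth.response_pct[s] for s in ids])
    z = np.array([
        overall_fc(
            truth.occupancy(s, 1) * truth.state1_covariance
            + truth.occupancy(s, 2) * truth.state2_covariances[s]
        )
        for s in ids
    ])
    r, p, _ = partial_correlation(x, y, z)
    return r, p


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int = 0,
    thresholds_pct: Sequence[float] | None = None,
    timeseries: bool = True,
) -> tuple[list[SubjectTimeSeries], list[PhenotypeRecord], GroundTruth]:
    """Generate a full cohort: time series, phenotypes, and ground truth.

    ``thresholds_pct`` is the proportional-threshold grid used to compute
    each subject's true hypoconnected-state assortativity AUC (default
    10..34% by 1%). With ``timeseries=False`` only phenotypes and ground
    truth are produced (fast path for power simulations).
    """
    spec = spec or CohortSpec()
    if thresholds_pct is None:
        thresholds_pct = tuple(np.arange(10.0, 34.0 + 0.5, 1.0))
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    r = spec.n_regions
    subject_ids = [f"sub{i + 1:03d}" for i in range(n)]
    region_labels = tuple(f"IC{j + 1:02d}" for j in range(r))

    # cohort-shared structure
    state1 = hyperconnected_template(spec)
    jit = rng.uniform(-spec.hypo_background_jitter, spec.hypo_background_jitter,
                     size=(r, r))
    jit = np.triu(jit, 1)
    background_jitter = jit + jit.T

    resilience = rng.uniform(-1.0, 1.0, size=n)
    state2 = {
        sid: hypoconnected_template(spec, float(rho), background_jitter)
        for sid, rho in zip(subject_ids, resilience)
    }
    true_auc = {
        sid: assortativity_auc(state2[sid], thresholds_pct)
        for sid in subject_ids
    }

    # response: affine in the true assortativity AUC plus noise, calibrated
    # so the population correlation equals the planted value
    rho_r = spec.planted_response_correlation
    a = np.array([true_auc[sid] for sid in subject_ids])
    a_sd = a.std()
    if a_sd == 0:
        raise ComputationError("assortativity AUC degenerate across subjects")
    z_a = (a - a.mean()) / a_sd
    eps = rng.standard_normal(n)
    resp_z = rho_r * z_a + np.sqrt(1 - rho_r**2) * eps
    response = np.clip(spec.response_mean + spec.response_sd * resp_z, 0.0, 100.0)

    # clinical covariates with mild dispersion
    age = np.clip(rng.normal(55.3, 10.1, n), 40, 75)
    gender = (rng.random(n) < 14 / 18).astype(int)   # 1 = male, cohort-typical
    updrs_on = np.clip(rng.normal(13.0, 6.0, n), 1, 40)
    fd = np.clip(rng.normal(0.15, 0.05, n), 0.03, 0.4)
    onoff = np.clip(rng.normal(27.1, 10.0, n), 8, 62)
    onon = onoff * (1 - response / 100.0)

    sequences = {
        sid: planted_state_sequence(
            spec.n_timepoints, spec.stay_probs, int(rng.integers(2**31))
        )
        for sid in subject_ids
    }

    phenotypes = [
        PhenotypeRecord(
            subject_id=sid,
            age_years=float(age[i]),
            gender=int(gender[i]),
            updrs3_on_preop=float(updrs_on[i]),
            mean_framewise_displacement=float(fd[i]),
            updrs3_onoff=float(onoff[i]),
            updrs3_onon=float(onon[i]),
        )
        for i, sid in enumerate(subject_ids)
    ]
    # consistency: recorded scores reproduce the planted response exactly
    for p, resp in zip(phenotypes, response):
        assert abs(dbs_response(p.updrs3_onoff, p.updrs3_onon) - resp) < 1e-9

    cohort: list[SubjectTimeSeries] = []
    if timeseries:
        for i, sid in enumerate(subject_ids):
            cohort.append(
                generate_subject(
                    sid,
                    sequences[sid],
                    [state1, state2[sid]],
                    spec.tr_seconds,
                    seed=int(rng.integers(2**31)),
                    ar_coefficient=spec.ar_coefficient,
                    region_labels=region_labels,
                    network_labels=spec.networks,
                )
            )
    truth = GroundTruth(
        spec=spec,
        seed=seed,
        subject_ids=subject_ids,
        state_sequences=sequences,
        state1_covariance=state1,
        state2_covariances=state2,
        resilience={sid: float(rho) for sid, rho in zip(subject_ids, resilience)},
        state2_assortativity_auc=true_auc,
        response_pct={sid: float(v) for sid, v in zip(subject_ids, response)},
        region_labels=region_labels,
        network_labels=spec.networks,
    )
    return cohort, phenotypes, truth
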