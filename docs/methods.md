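# Methods

## Overview

The package estimates time-varying functional connectivity (FC) from
region-level BOLD time courses, decomposes it into recurring brain states,
characterizes each state's network topology with graph-theory metrics, and
tests those metrics against a clinical response variable. All randomness is
seeded; a single run seed is fanned out to per-stage child seeds via a
stage-name CRC so stages are stochastically independent.

## Windowed connectivity estimation

Windows are W = 22 TRs long (59.4 s at TR = 2.7 s), stepped by 1 TR. The
window count is ⌊(T − W)/step⌋ with starts 0, step, 2·step, …: the final
fully-supported start position is deliberately dropped, which is the
convention that maps 253 usable volumes to 231 windows. The taper is a
length-W rectangle convolved with a unit-mass truncated Gaussian
(σ = 3 TR, support ±⌈3σ⌉), central W samples kept and renormalized to sum
one; weighted means are removed per window before the weighted covariance
is formed.

With W = 22 samples over R = 25 regions the window covariance is rank
deficient, so the per-window estimate is a graphical lasso (L1-penalized
precision): the penalty λ is selected per subject from the grid
{0.01, 0.03, 0.1, 0.3, 0.5} by average held-out Gaussian log-likelihood
(log det Θ − tr(SΘ)) over 10 random half/half splits of the windows, with
the penalized precision fit to the pooled (averaged) train covariance.
Held-out likelihood was chosen as the selection criterion; the alternative
readings of "training repetitions" (e.g. per-window fits) change cost but
not the contract. Numerically, each per-window fit adds a diagonal ridge of
1e-2 of the mean variance (escalated ×3, ×10 on solver failure) and runs
coordinate descent at tol 1e-3 / 100 iterations; this perturbs entries by
≈1e-4, well below estimation noise at W = 22. Estimates are reported on
the correlation scale (precision inverted, standardized, diagonal zeroed).

## Brain states

All subjects' windows are pooled — states must be common to the cohort —
and embedded as Fisher-z upper-triangle vectors. k-means (random-row
initialization, squared-Euclidean distance, best of `reps` restarts by
within-cluster dispersion; a city-block/k-medians option exists in config)
is run for each candidate k; the mean silhouette selects k and a
spherical-Gaussian BIC, n·d·ln(WSS/(n·d)) + k·(d+1)·ln(n), is reported as
validation. States are relabeled by descending centroid mean connectivity,
so state 1 is always the most connected (hyperconnected) state and state 2
the hypoconnected one. Per subject and state the element-wise median of the
member windows gives the state matrix; unvisited states yield a missing
matrix and are excluded pairwise from downstream tests, with the count
logged in the run manifest. Temporal statistics come from maximal runs of
the label sequence: fraction time, mean dwell in minutes (run length ×
step × TR / 60), and the number of adjacent label changes.

## Graph analysis

Connectivity matrices are binarized by proportional thresholding: the top
round(p/100 · R(R−1)/2) upper-triangle edges by signed weight (ties broken
by lexicographic pair order; an absolute-value ranking is available in
config) for p = 10..34% in 1% steps — 25 graphs spanning the sparse-to-
moderate density range in which small-worldness peaks. Metrics: global
efficiency (mean inverse BFS shortest-path length, disconnected pairs
contribute 0), Newman degree assortativity (undefined on degree-regular
graphs; propagated as missing rather than zero-imputed, since imputation
would bias toward the null), per-node clustering coefficients (0 for
degree < 2), normalized betweenness centrality, and small-world σ against
degree-preserving double-edge-swap nulls (100 nulls, 10 swaps per edge).
Each metric is summarized by the trapezoidal AUC over the threshold grid
expressed as a fraction (0.10–0.34); sub-intervals adjacent to missing
values are excluded. Characteristic path length and degree distribution are
not exposed as metrics (they overlap efficiency and assortativity); path
length is computed internally for σ only.

## Association with response

The response variable is the percent UPDRS-III improvement from
stimulation, 100·(ON-OFF − ON-ON)/ON-OFF, computed from the phenotype
table. Tests are two-sided Pearson partial correlations on residuals
(t statistic with n − 2 − q df; CI via Fisher z with variance
1/(n − 3 − q)). Graph-metric AUCs and FC edges control for overall FC (the
mean positive edge of the subject's adjusted static matrix) because
proportional thresholding leaves graphs sensitive to overall connectivity
level; age, gender, preoperative severity and motion are already removed by
the static-stage edge-wise residualization and are not re-entered.
Temporal statistics are tested without an additional covariate.
Benjamini–Hochberg FDR is applied within families: one family per local
metric per state (across nodes) and one per state (across edges); global
metrics are reported uncorrected. Each result row records n, the covariates
used, and the family.

The static covariate adjustment itself is an edge-wise least-squares
residualization (intercept + 4 covariates, cohort mean re-added) — a
transparent, testable stand-in for multivariate covariance-model toolboxes;
covariates that are constant in a cohort (e.g. single-sex small samples)
are dropped with a manifest warning. Statistically non-significant edges
are *not* masked out of the FC matrices before analysis; a config flag
(`edge_significance_mask`) exists for the alternative convention.

## Synthetic cohort generator

The generator emulates the study conditions: 18 subjects by default, 253
volumes at TR 2.7 s, 25 regions assigned to 8 networks (1 Sa, 7 DMN,
7 FPN, 4 SM, 2 Ce, 2 Vi, 1 Au, 1 La). Each subject follows a two-state
first-order Markov chain with stay probabilities (0.970, 0.988), chosen so
that the stationary occupancy is ≈29/71% in favour of the hypoconnected
state and a scan contains about four transitions, with dwells of roughly
1.5 and 3.8 minutes — the temporal regime such studies report. At each TR
a zero-mean Gaussian draw from the active state's covariance is taken,
AR(1)-smoothed (coefficient 0.3) to mimic BOLD autocorrelation, and
columns are restandardized.

State 1 (hyperconnected) has within-network correlation 0.60 over a 0.25
between-network background. State 2 (hypoconnected) keeps strong structure
only among the SM/DMN/Vi regions, built by interpolating two edge-disjoint
weight templates as a function of a latent per-subject *resilience*
ρ ∈ [−1, 1]: at ρ = +1 an assortative design (an 8-node clique at weights
0.62 graded downward, plus a second-tier clique at 0.46) and at ρ = −1 a
disassortative star forest (three hubs wired to disjoint degree-one leaves
at 0.62 graded). Because the edge sets are disjoint and within-class
weights are rank-graded, the thresholded edge set — and hence the
assortativity AUC — shifts continuously and monotonically with ρ.
Background edges sit at 0.05 with a ±0.02 jitter pattern shared by the
cohort (it deterministically breaks rank ties). Templates are made positive
definite by uniform shrink (C + aI)/(1 + a), which preserves off-diagonal
rank order exactly, so ground-truth graph topology is unaffected.

The response is planted directly on the realized truth: with a_i the true
state-2 assortativity AUC (computed by the package's own graph stage on the
true matrices), response_z = r·z(a) + √(1−r²)·ε with ε ~ N(0,1) i.i.d. and
r the planted correlation (−0.7 by default), mapped to a percent scale
(mean 53.5, SD 16.7, clipped to [0, 100]). ON-OFF scores are drawn
(mean 27.1, SD 10) and ON-ON derived so the recorded scores reproduce the
planted response exactly. Covariates are drawn with cohort-typical
dispersion (age ≈ N(55, 10), ~78% male, UPDRS-III ON ≈ N(13, 6),
FD ≈ N(0.15, 0.05)).

What the generator does **not** emulate: hemodynamic convolution, scanner
noise and motion artifacts, spatial (voxel-level) structure, network
topology beyond the planted block/hub designs, and any coupling between
covariates and connectivity. Passing tests therefore demonstrate that the
pipeline's estimation and inference machinery recovers planted structure of
realistic size and noise — not that real acquisitions satisfy the model.

## Problem sizes used in checks

Planted-state recovery runs 18-subject default cohorts over 20 seeds with
unpenalized windowed FC and k ∈ 2..6 at 10 restarts — the planted states
are strongly separated, so this restart count is ample at this problem
size. Association power uses ground-truth matrices at n = 60 over 100
seeds (and 500 null seeds), measuring the generator-level effect without
windowing noise. The determinism check runs the full chain twice on a
9-subject, 100-volume cohort. The acceptance script's full pipeline run
uses the 18-subject default cohort with k ∈ 2..6 and 20 restarts.

## Known limitations

- λ selection on the pooled train covariance is well conditioned even when
  individual windows are not, which biases selection toward weak penalties;
  per-window regularization quality is carried by the ridge.
- The spherical-Gaussian BIC on 300-dimensional edge features decreases
  with k on realistic window counts; it is reported as validation output,
  while silhouette drives the choice of k, which is the intended role.
- Assortativity AUC on 25-node graphs is a coarse (step-like) function of
  the underlying weights; cohort-level associations are robust to this but
  single-subject AUCs have limited resolution.
- With small cohorts (n < 8 usable subjects per test) association families
  are skipped entirely rather than fitted unstably.
- In real cohorts of this kind, between-subject FC variance is reported to
  drop by an order of magnitude from static FC to the state medians,
  because static FC mixes states in subject-specific proportions. The
  generator does not reproduce that direction: its subjects share the
  state-1 covariance and differ within state 2 only through the planted
  resilience axis, so static variance is dominated by (modest) occupancy
  mixing while state-median variance is dominated by estimation noise on
  briefly-visited states plus the planted heterogeneity — and can exceed
  the static value. Emulating the real effect would require large
  between-subject heterogeneity of overall connectivity level, which is
  deliberately out of the generator's scope. The pipeline reports both
  variances; their ratio on synthetic cohorts should not be read as a
  statement about real data.
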