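# dynstates

Dynamic functional-connectivity brain states and graph-theory markers of
deep-brain-stimulation response.

## The problem

In advanced Parkinson's disease, subthalamic deep brain stimulation
(STN-DBS) helps some patients far more than others, and resting-state fMRI
collected before surgery may carry a signature of who will respond. Static
functional connectivity (FC) — one correlation matrix per scan — assumes a
single brain state for the whole acquisition. This package implements the
dynamic alternative for cohorts of region (independent-component) time
courses: FC is estimated in short sliding windows, windows are clustered
into recurring *brain states*, graph-theory metrics are computed per state
across a proportional-threshold sweep, and each network measure is tested
against the clinical response with covariate-controlled partial
correlations. The scientifically interesting phenomenon the pipeline is
built to expose: a *hypoconnected* state, invisible to static analysis, in
which network assortativity correlates negatively with DBS response.

Because patient MRI data of this kind are not publicly distributable, the
package ships a synthetic cohort generator that emulates the statistical
structure of such a study (two Markov-switching connectivity states over 25
regions in 8 networks, 253 volumes at TR = 2.7 s, a planted
assortativity-response correlation) so every stage is testable end to end
with known ground truth.

## The pipeline

For subject time series X ∈ ℝ^(T×R) (T = 253 volumes, R = 25 regions):

1. **Static FC** — Pearson correlation over the full series; edges
   residualized across subjects against age, gender, preoperative UPDRS-III
   medication-ON score, and mean framewise displacement; overall FC = mean
   of positive edges (a control covariate downstream).
2. **Dynamic FC** — sliding windows of W = 22 TRs (59.4 s), Gaussian taper
   (σ = 3 TR), step 1 TR ⇒ ⌊(T−W)/step⌋ = 231 windows; per-window sparse
   inverse covariance by graphical lasso, penalty λ chosen per subject by
   held-out log-likelihood over 10 random train/test splits; matrices
   reported on the correlation scale.
3. **Brain states** — k-means on Fisher-z edge vectors pooled over
   subjects, k ∈ 2..10 selected by mean silhouette, validated by a
   spherical-Gaussian BIC; per-subject per-state median matrices; fraction
   time, mean dwell (minutes), transition counts.
4. **Graph metrics** — binarize at the top p% of edges for p = 10..34 by 1
   (25 graphs); global efficiency E_glob, assortativity r, clustering
   coefficient C_i, betweenness centrality b_i; each summarized by its AUC
   over the sweep; small-world σ against degree-preserving rewired nulls.
5. **Association** — response = 100·(ON-OFF − ON-ON)/ON-OFF (percent
   UPDRS-III improvement from stimulation); Pearson partial correlations
   controlling overall FC for graph metrics and edges; Benjamini–Hochberg
   FDR within each local-metric and edge family.

## Worked example

```bash
dynstates all --simulate --n-subjects 12 --seed 7 --out results/run
```

or step by step, with narrative output:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_static_connectivity.py
python analysis/03_dynamic_windows.py
python analysis/04_brain_states.py
python analysis/05_graph_metrics.py
python analysis/06_associations.py
```

The run prints (step 4 and 6 excerpts):

```
silhouette selected k = 2 (by-k: {2: 0.162, 3: 0.078, 4: 0.066, 5: 0.057, 6: 0.048})
mean fraction time in hypoconnected state 2: 71.4%
mean dwell (min): state 1 = 1.76, state 2 = 4.50
mean transitions per subject: 3.2

headline: hypoconnected-state assortativity AUC vs response:
r = -0.588 [-0.878, 0.018], p = 0.0570 (n = 12; generator planted r = -0.7)
```

meaning: the two planted connectivity states were recovered, the cohort
spends about two thirds of the scan in the hypoconnected state in long
dwells, and the planted negative association between hypoconnected-state
assortativity and stimulation response is estimated near the planted value
(at n = 12 the confidence interval is wide and significance is marginal —
exactly the small-cohort behaviour such studies face; at n = 60 the power
tests recover it essentially always). Static analysis shows no
assortativity association (r ≈ 0 in the same run): the signal lives only
in the hypoconnected state.

## Layout

- `src/dynstates/` — the library: `io`, `simulate`, `static_fc`,
  `dynamic_fc`, `states`, `graphs`, `stats`, `pipeline`, `cli`
- `analysis/` — the numbered analysis drivers above
- `tests/` — pytest suite with independent brute-force oracles
- `docs/methods.md` — model, parameters, numerical choices, limitations
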