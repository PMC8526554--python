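"""Stage orchestration: simulate -> static -> dynamic -> states -> graph ->
associate, with a reproducibility manifest.

Each stage is runnable in isolation from the previous stage's on-disk
artifacts; ``run_all`` chains them in memory and writes everything. A single
run seed is fanned out to per-stage child seeds through a fixed stage-name
hash, so changing one stage's stochastic behaviour does not perturb the
others. The manifest (config echo, seed, package version, output hashes,
accumulated warnings, per-stage timing) is written even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dynamic_fc import (WindowSpec, select_lambda, taper_weights,
                         window_covariances, windowed_fc)
from .errors import ComputationError, InputError
from .graphs import profile_for_matrix
from .io import (load_cohort, write_matrix, write_phenotypes,
                 write_timeseries)
from .simulate import CohortSpec, generate_cohort
from .states import cluster_states
from .static_fc import (adjust_for_covariates, covariate_design,
                        edgewise_variance, overall_fc, static_fc)
from .stats import associate, dbs_response, results_to_frame


def stage_seed(seed: int, stage: str) -> int:
    """Child seed for a stage: mix the run seed with a stage-name CRC."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


class Manifest:
    """Accumulates config echo, hashes, warnings and timings for a run."""

    def __init__(self, config: RunConfig, out_dir: Path):
        self.data = {
            "package_version": __version__,
            "seed": config.rng_seed,
            "config": config.to_dict(),
            "stages": {},
            "warnings": [],
            "files": {},
        }
        self.out_dir = out_dir

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)

    def record_stage(self, name: str, seconds: float) -> None:
        self.data["stages"][name] = {"seconds": round(seconds, 3)}

    def hash_file(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["files"][str(path.relative_to(self.out_dir))] = digest

    def write(self) -> None:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        (self.out_dir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True)
        )


def _write_and_hash(manifest: Manifest, path: Path) -> None:
    if path.exists():
        manifest.hash_file(path)


def run_simulate(config: RunConfig, out_dir: Path,
                 cohort_spec: CohortSpec | None = None,
                 manifest: Manifest | None = None):
    """Generate and write a synthetic cohort; returns (cohort, phenotypes, truth)."""
    out_dir = Path(out_dir)
    cohort_dir = out_dir / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    spec = cohort_spec or CohortSpec(
        tr_seconds=config.tr_seconds, ar_coefficient=config.ar_coefficient
    )
    cohort, phenotypes, truth = generate_cohort(
        spec, seed=stage_seed(config.rng_seed, "simulate"),
        thresholds_pct=config.threshold_grid_pct,
    )
    for ts in cohort:
        write_timeseries(ts, cohort_dir / f"{ts.subject_id}.tsv")
    write_phenotypes(phenotypes, cohort_dir / "phenotypes.csv")
    pd.DataFrame({
        "region": truth.region_labels, "network": truth.network_labels,
    }).to_csv(cohort_dir / "networks.csv", index=False)
    gt = pd.DataFrame({
        "subject_id": truth.subject_ids,
        "resilience": [truth.resilience[s] for s in truth.subject_ids],
        "state2_assortativity_auc": [
            truth.state2_assortativity_auc[s] for s in truth.subject_ids
        ],
        "response_pct": [truth.response_pct[s] for s in truth.subject_ids],
        "occupancy_state2": [truth.occupancy(s, 2) for s in truth.subject_ids],
    })
    gt.to_csv(cohort_dir / "ground_truth.csv", index=False)
    (cohort_dir / "ground_truth.json").write_text(json.dumps({
        "seed": truth.seed,
        "stay_probs": list(truth.spec.stay_probs),
        "planted_response_correlation": truth.spec.planted_response_correlation,
        "state_sequences": {s: truth.state_sequences[s].tolist()
                            for s in truth.subject_ids},
    }))
    if manifest is not None:
        for f in sorted(cohort_dir.iterdir()):
            _write_and_hash(manifest, f)
    return cohort, phenotypes, truth


def run_static(cohort, phenotypes, out_dir: Path,
               manifest: Manifest | None = None):
    """Static FC per subject, covariate-adjusted group matrix, overall FC,
    and between-subject edge variance."""
    out_dir = Path(out_dir)
    static_dir = out_dir / "static"
    static_dir.mkdir(parents=True, exist_ok=True)
    labels = cohort[0].region_labels
    matrices, keep_phen = [], []
    for ts, ph in zip(cohort, phenotypes):
        matrices.append(static_fc(ts))
        keep_phen.append(ph)
    design = covariate_design(keep_phen)
    # constant covariate columns (e.g. single-sex small cohorts) are collinear
    # with the intercept; drop them rather than fail
    keep_cols = [0] + [
        j for j in range(1, design.shape[1]) if np.ptp(design[:, j]) > 0
    ]
    if len(keep_cols) < design.shape[1] and manifest is not None:
        from .static_fc import COVARIATE_NAMES
        dropped = [COVARIATE_NAMES[j - 1] for j in range(1, design.shape[1])
                   if j not in keep_cols]
        manifest.warn(f"constant covariates dropped from adjustment: {dropped}")
    adjusted, group = adjust_for_covariates(matrices, design[:, keep_cols])
    ofc = {}
    for ts, m in zip(cohort, adjusted):
        try:
            ofc[ts.subject_id] = overall_fc(m)
        except ComputationError:
            if manifest is not None:
                manifest.warn(f"{ts.subject_id}: no positive FC values; excluded")
    var_matrix, var_mean = edgewise_variance(adjusted)
    for ts, m in zip(cohort, adjusted):
        write_matrix(m, static_dir / f"fc_{ts.subject_id}.tsv", labels)
    write_matrix(group, static_dir / "group_fc.tsv", labels)
    write_matrix(var_matrix, static_dir / "edge_variance.tsv", labels)
    pd.DataFrame({
        "subject_id": list(ofc), "overall_fc": list(ofc.values()),
    }).to_csv(static_dir / "overall_fc.csv", index=False)
    if manifest is not None:
        for f in sorted(static_dir.iterdir()):
            _write_and_hash(manifest, f)
    return {"matrices": dict(zip([t.subject_id for t in cohort], adjusted)),
            "group": group, "overall_fc": ofc,
            "variance_matrix": var_matrix, "variance_mean": var_mean}


def run_dynamic(cohort, config: RunConfig, out_dir: Path,
                manifest: Manifest | None = None):
    """Per-subject penalty selection and windowed FC series."""
    out_dir = Path(out_dir)
    dyn_dir = out_dir / "dynamic"
    dyn_dir.mkdir(parents=True, exist_ok=True)
    spec = WindowSpec.from_config(config)
    seed0 = stage_seed(config.rng_seed, "dynamic")
    np.savetxt(dyn_dir / "taper.tsv", taper_weights(spec))
    windowed, lambdas = [], {}
    labels = cohort[0].region_labels
    iu, ju = np.triu_indices(len(labels), k=1)
    edge_names = [f"{labels[i]}--{labels[j]}" for i, j in zip(iu, ju)]
    for si, ts in enumerate(cohort):
        covs = window_covariances(ts, spec)
        lam = select_lambda(covs, config.lambda_grid, config.lambda_reps,
                            seed=seed0 + si)
        ws = windowed_fc(ts, spec, lam)
        lambdas[ts.subject_id] = lam
        windowed.append(ws)
        table = np.stack([m[iu, ju] for m in ws.matrices])
        df = pd.DataFrame(table, columns=edge_names)
        df.insert(0, "window", np.arange(len(ws.matrices)))
        df.to_csv(dyn_dir / f"windows_{ts.subject_id}.csv", index=False,
                  float_format="%.10g")
    pd.DataFrame({
        "subject_id": list(lambdas), "lambda": list(lambdas.values()),
    }).to_csv(dyn_dir / "lambda_selected.csv", index=False)
    if manifest is not None:
        for f in sorted(dyn_dir.iterdir()):
            _write_and_hash(manifest, f)
    return windowed


def run_states(windowed, config: RunConfig, out_dir: Path,
               region_labels, manifest: Manifest | None = None):
    """Cohort-level state clustering, medians, and temporal statistics."""
    out_dir = Path(out_dir)
    states_dir = out_dir / "states"
    states_dir.mkdir(parents=True, exist_ok=True)
    decomp = cluster_states(
        windowed, range(config.k_min, config.k_max + 1),
        reps=config.kmeans_reps,
        seed=stage_seed(config.rng_seed, "states"),
        distance=config.cluster_distance,
    )
    rows = []
    for sid, labs in decomp.labels.items():
        for w, lab in enumerate(labs):
            rows.append({"subject_id": sid, "window": w, "state": int(lab)})
    pd.DataFrame(rows).to_csv(states_dir / "labels.csv", index=False)
    pd.DataFrame({
        "k": list(decomp.silhouette_by_k),
        "mean_silhouette": list(decomp.silhouette_by_k.values()),
        "bic": [decomp.bic_by_k[k] for k in decomp.silhouette_by_k],
    }).to_csv(states_dir / "model_selection.csv", index=False)
    for s in range(decomp.k):
        m = decomp.cohort_state_matrices[s]
        if m is not None:
            write_matrix(m, states_dir / f"cohort_median_state{s + 1}.tsv",
                         region_labels)
    n_missing = 0
    for sid, meds in decomp.state_matrices.items():
        for s, m in enumerate(meds):
            if m is None:
                n_missing += 1
            else:
                write_matrix(m, states_dir / f"median_{sid}_state{s + 1}.tsv",
                             region_labels)
    if n_missing and manifest is not None:
        manifest.warn(f"{n_missing} subject-state median matrices missing "
                      "(state never visited)")
    pd.DataFrame([
        {"subject_id": t.subject_id,
         **{f"fraction_state{s + 1}": t.fraction_time[s] for s in range(decomp.k)},
         **{f"dwell_min_state{s + 1}": t.mean_dwell_minutes[s]
            for s in range(decomp.k)},
         "n_transitions": t.n_transitions}
        for t in decomp.temporal
    ]).to_csv(states_dir / "temporal.csv", index=False)
    if manifest is not None:
        for f in sorted(states_dir.iterdir()):
            _write_and_hash(manifest, f)
    return decomp


def run_graph(matrices_by_condition: dict, config: RunConfig, out_dir: Path,
              region_labels, manifest: Manifest | None = None,
              with_small_world: bool = False):
    """Threshold sweep + metric AUCs for every (condition, subject) matrix.

    ``matrices_by_condition``: {condition: {subject_id: matrix or None}}.
    Returns {condition: {subject_id: auc dict}} and writes the long-format
    AUC table.
    """
    out_dir = Path(out_dir)
    graph_dir = out_dir / "graph"
    graph_dir.mkdir(parents=True, exist_ok=True)
    grid = config.threshold_grid_pct
    seed0 = stage_seed(config.rng_seed, "graph")
    auc_tables: dict = {}
    rows = []
    n_undef = 0
    for condition, by_subject in matrices_by_condition.items():
        auc_tables[condition] = {}
        for sid, matrix in by_subject.items():
            if matrix is None:
                continue
            prof = profile_for_matrix(
                matrix, grid,
                n_null=config.n_null_graphs if with_small_world else 0,
                seed=seed0, rank_by_absolute=config.rank_by_absolute,
            )
            n_undef += prof.n_undefined_assortativity
            auc_tables[condition][sid] = prof.auc
            for metric in ("global_efficiency", "assortativity"):
                rows.append({"subject_id": sid, "state": condition,
                             "metric": metric, "node": "",
                             "auc": prof.auc[metric]})
            if with_small_world:
                rows.append({"subject_id": sid, "state": condition,
                             "metric": "small_worldness", "node": "",
                             "auc": prof.auc["small_worldness"]})
            for metric in ("clustering_coeff", "betweenness"):
                for j, label in enumerate(region_labels):
                    rows.append({"subject_id": sid, "state": condition,
                                 "metric": metric, "node": label,
                                 "auc": prof.auc[metric][j]})
    if n_undef and manifest is not None:
        manifest.warn(f"{n_undef} threshold points had undefined assortativity "
                      "(excluded from AUC)")
    pd.DataFrame(rows).to_csv(graph_dir / "auc.csv", index=False,
                              float_format="%.10g")
    if manifest is not None:
        _write_and_hash(manifest, graph_dir / "auc.csv")
    return auc_tables


def run_associate(auc_tables, fc_matrices, temporal, phenotypes,
                  overall_fc_by_subject, out_dir: Path, region_labels,
                  manifest: Manifest | None = None):
    """Partial-correlation associations with DBS response; writes the tidy
    results table and the headline scatter data (assortativity AUC vs
    response per condition)."""
    out_dir = Path(out_dir)
    assoc_dir = out_dir / "associate"
    assoc_dir.mkdir(parents=True, exist_ok=True)
    response = {
        p.subject_id: dbs_response(p.updrs3_onoff, p.updrs3_onon)
        for p in phenotypes
    }
    results = associate(auc_tables, fc_matrices, temporal, response,
                        overall_fc_by_subject, region_labels)
    frame = results_to_frame(results)
    frame.to_csv(assoc_dir / "associations.csv", index=False,
                 float_format="%.10g")
    scatter_rows = []
    for condition, by_subject in auc_tables.items():
        for sid, auc in by_subject.items():
            if "assortativity" in auc and sid in response:
                scatter_rows.append({
                    "subject_id": sid, "state": condition,
                    "assortativity_auc": auc["assortativity"],
                    "response_pct": response[sid],
                })
    pd.DataFrame(scatter_rows).to_csv(
        assoc_dir / "scatter_assortativity.csv", index=False,
        float_format="%.10g")
    if manifest is not None:
        for f in sorted(assoc_dir.iterdir()):
            _write_and_hash(manifest, f)
    return frame


def run_all(config: RunConfig, cohort_dir: str | Path | None = None,
            simulate: bool = False,
            cohort_spec: CohortSpec | None = None) -> pd.DataFrame:
    """Full chain; returns the association results table.

    Either ``simulate=True`` (generate a synthetic cohort under the output
    directory) or ``cohort_dir`` pointing at an existing cohort layout.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, out_dir)
    config.save(out_dir / "config.yaml")
    try:
        t0 = time.time()
        if simulate:
            cohort, phenotypes, _truth = run_simulate(
                config, out_dir, cohort_spec, manifest)
        else:
            if cohort_dir is None:
                raise InputError("either --simulate or a cohort directory is required")
            cohort_path = Path(cohort_dir)
            if not cohort_path.exists():
                raise InputError(f"cohort directory not found: {cohort_path}")
            net_file = cohort_path / "networks.csv"
            labels_map = None
            if net_file.exists():
                net_df = pd.read_csv(net_file)
                labels_map = dict(zip(net_df["region"], net_df["network"]))
            cohort, phenotypes = load_cohort(cohort_path, config.tr_seconds,
                                             labels_map)
        manifest.record_stage("cohort", time.time() - t0)

        t0 = time.time()
        static = run_static(cohort, phenotypes, out_dir, manifest)
        manifest.record_stage("static", time.time() - t0)

        t0 = time.time()
        windowed = run_dynamic(cohort, config, out_dir, manifest)
        manifest.record_stage("dynamic", time.time() - t0)

        t0 = time.time()
        region_labels = cohort[0].region_labels
        decomp = run_states(windowed, config, out_dir, region_labels, manifest)
        manifest.record_stage("states", time.time() - t0)

        t0 = time.time()
        matrices_by_condition = {"static": static["matrices"]}
        for s in range(decomp.k):
            matrices_by_condition[str(s + 1)] = {
                sid: meds[s] for sid, meds in decomp.state_matrices.items()
            }
        auc_tables = run_graph(matrices_by_condition, config, out_dir,
                               region_labels, manifest)
        manifest.record_stage("graph", time.time() - t0)

        t0 = time.time()
        frame = run_associate(
            auc_tables, matrices_by_condition, decomp.temporal, phenotypes,
            static["overall_fc"], out_dir, region_labels, manifest)
        manifest.record_stage("associate", time.time() - t0)
        return frame
    finally:
        manifest.write()
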