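"""On-disk artifacts: ROI time series (TSV), phenotypes (CSV), matrices (TSV).

Everything is plain text and human-diffable. Time-series files carry one
header row of region labels and one row per time point; connectivity
matrices are square TSVs with region labels on both axes. Imaging formats
are deliberately out of scope — the pipeline starts from post-ICA region
time courses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: The eight canonical large-scale networks region labels may map to.
NETWORKS = ("Sa", "DMN", "FPN", "SM", "Ce", "Vi", "La", "Au")

PHENOTYPE_COLUMNS = (
    "subject_id",
    "age_years",
    "gender",
    "updrs3_on_preop",
    "mean_framewise_displacement",
    "updrs3_onoff",
    "updrs3_onon",
)


@dataclasses.dataclass
class SubjectTimeSeries:
    """One subject's T x R region time-course matrix.

    Rows are time points sampled every ``tr_seconds``; columns are regions
    (independent components), each tagged with one of the eight large-scale
    networks when a network map is supplied.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    region_labels: tuple[str, ...]
    network_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError(f"{self.subject_id}: time series must be 2-D")
        t, r = self.data.shape
        if t < 2:
            raise InputError(f"{self.subject_id}: need at least 2 time points, got {t}")
        if r < 2:
            raise InputError(f"{self.subject_id}: need at least 2 regions, got {r}")
        if self.tr_seconds <= 0:
            raise InputError(f"{self.subject_id}: tr_seconds must be positive")
        if len(self.region_labels) != r:
            raise InputError(f"{self.subject_id}: {len(self.region_labels)} labels for {r} regions")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise InputError(
                f"{self.subject_id}: non-finite value at time point {bad[0]}, region {bad[1]}"
            )
        if self.network_labels is not None:
            if len(self.network_labels) != r:
                raise InputError(f"{self.subject_id}: network label count mismatch")
            unknown = set(self.network_labels) - set(NETWORKS)
            if unknown:
                raise InputError(f"{self.subject_id}: unknown networks {sorted(unknown)}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class PhenotypeRecord:
    """Clinical covariates and outcome scores for one subject."""

    subject_id: str
    age_years: float
    gender: int
    updrs3_on_preop: float
    mean_framewise_displacement: float
    updrs3_onoff: float
    updrs3_onon: float
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in (0, 1):
            raise InputError(f"{self.subject_id}: gender must be coded 0/1")
        for name in ("updrs3_on_preop", "mean_framewise_displacement",
                     "updrs3_onoff", "updrs3_onon"):
            if getattr(self, name) < 0:
                raise InputError(f"{self.subject_id}: {name} must be >= 0")


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    labels: Mapping[str, str] | None = None,
    subject_id: str | None = None,
) -> SubjectTimeSeries:
    """Read a tab-separated time-series file (header row of region labels).

    ``labels`` optionally maps region label -> network name. The subject ID
    defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"time-series file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise InputError(f"{path}: ragged or malformed TSV ({e})") from e
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least 2 region columns, got {df.shape[1]}")
    region_labels = tuple(str(c) for c in df.columns)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: non-numeric cell at data row {row}, column '{col}'"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise InputError(f"{path}: missing value at data row {row}, column '{col}'")
        values[:, j] = numeric.to_numpy()
    network_labels = None
    if labels is not None:
        missing = [r for r in region_labels if r not in labels]
        if missing:
            raise InputError(f"{path}: regions without network mapping: {missing}")
        network_labels = tuple(labels[r] for r in region_labels)
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem,
        data=values,
        tr_seconds=tr_seconds,
        region_labels=region_labels,
        network_labels=network_labels,
    )


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the cohort phenotype CSV; unknown extra columns are carried through."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"phenotype file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns: {missing}")
    ids = df["subject_id"].astype(str)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise InputError(f"{path}: duplicate subject IDs: {sorted(set(dupes))}")
    extra_cols = [c for c in df.columns if c not in PHENOTYPE_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                subject_id=str(row["subject_id"]),
                age_years=float(row["age_years"]),
                gender=int(row["gender"]),
                updrs3_on_preop=float(row["updrs3_on_preop"]),
                mean_framewise_displacement=float(row["mean_framewise_displacement"]),
                updrs3_onoff=float(row["updrs3_onoff"]),
                updrs3_onon=float(row["updrs3_onon"]),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in PHENOTYPE_COLUMNS}
        d.update(r.extra)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def write_matrix(matrix: np.ndarray, path: str | Path,
                 region_labels: Sequence[str] | None = None) -> None:
    """Write a square symmetric matrix as a labeled TSV (labels on both axes)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InputError(f"matrix must be square, got shape {matrix.shape}")
    if np.max(np.abs(matrix - matrix.T)) > 1e-10:
        raise InputError("matrix is asymmetric beyond 1e-10")
    n = matrix.shape[0]
    labels = list(region_labels) if region_labels is not None else [f"R{i+1}" for i in range(n)]
    if len(labels) != n:
        raise InputError(f"{len(labels)} labels for a {n}x{n} matrix")
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="region")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labeled square matrix TSV; returns (matrix, region labels)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise InputError(f"{path}: matrix not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise InputError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def load_cohort(
    directory: str | Path,
    tr_seconds: float,
    labels: Mapping[str, str] | None = None,
) -> tuple[list[SubjectTimeSeries], list[PhenotypeRecord]]:
    """Load a cohort directory: ``*.tsv`` per subject plus ``phenotypes.csv``.

    Rejects subjects whose region count, region order, or TR differ from the
    first subject; requires time-series and phenotype subject IDs to match.
    """
    directory = Path(directory)
    pheno_path = directory / "phenotypes.csv"
    phenotypes = read_phenotypes(pheno_path)
    ts_files = sorted(directory.glob("*.tsv"))
    if not ts_files:
        raise InputError(f"no time-series TSV files in {directory}")
    cohort = [read_timeseries(f, tr_seconds, labels) for f in ts_files]
    ref = cohort[0]
    for ts in cohort[1:]:
        if ts.region_labels != ref.region_labels:
            raise InputError(
                f"{ts.subject_id}: region labels/order differ from {ref.subject_id}"
            )
        if ts.tr_seconds != ref.tr_seconds:
            raise InputError(f"{ts.subject_id}: TR differs from {ref.subject_id}")
    ts_ids = {t.subject_id for t in cohort}
    ph_ids = {p.subject_id for p in phenotypes}
    if ts_ids != ph_ids:
        orphans = sorted(ts_ids ^ ph_ids)
        raise InputError(f"subject IDs mismatch between time series and phenotypes: {orphans}")
    order = {p.subject_id: i for i, p in enumerate(phenotypes)}
    cohort.sort(key=lambda t: order[t.subject_id])
    return cohort, phenotypes
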