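"""Run configuration: every tunable of the pipeline in one declarative object.

Defaults follow the study conditions this pipeline models: a 22-TR sliding
window (59.4 s at TR = 2.7 s) tapered by a 3-TR Gaussian, 1-TR steps,
graphical-lasso regularization selected per subject from a small grid with
10 held-out repetitions, k-means over k = 2..10 with 100 restarts, and a
proportional-threshold sweep from 10% to 34% in 1% increments (25 graphs).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import yaml

from .errors import InputError

DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 0.5)


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters with study-condition defaults."""

    window_length_tr: int = 22
    taper_sigma_tr: float = 3.0
    step_tr: int = 1
    tr_seconds: float = 2.7
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    lambda_reps: int = 10
    k_min: int = 2
    k_max: int = 10
    kmeans_reps: int = 100
    threshold_min_pct: float = 10.0
    threshold_max_pct: float = 34.0
    threshold_step_pct: float = 1.0
    n_null_graphs: int = 100
    rng_seed: int = 0
    output_dir: str = "results"
    # optional behaviour switches
    ar_coefficient: float = 0.3          # temporal smoothing in the simulator
    gender_coding: str = "0=female,1=male"
    edge_significance_mask: bool = False  # alternative reading of "(p < 0.05)"
    rank_by_absolute: bool = False        # threshold by |r| instead of signed r
    cluster_distance: str = "euclidean"   # or "cityblock"

    def __post_init__(self) -> None:
        if self.window_length_tr < 2:
            raise InputError("window_length_tr must be >= 2")
        if self.taper_sigma_tr <= 0:
            raise InputError("taper_sigma_tr must be > 0")
        if self.step_tr < 1:
            raise InputError("step_tr must be >= 1")
        if not (0 < self.threshold_min_pct <= self.threshold_max_pct < 100):
            raise InputError("threshold grid must lie within (0, 100)")
        if self.threshold_step_pct <= 0:
            raise InputError("threshold_step_pct must be > 0")
        if not self.lambda_grid:
            raise InputError("lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise InputError("lambda values must be >= 0")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise InputError("require 2 <= k_min <= k_max")
        if self.cluster_distance not in ("euclidean", "cityblock"):
            raise InputError("cluster_distance must be 'euclidean' or 'cityblock'")
        self.lambda_grid = tuple(float(l) for l in self.lambda_grid)

    @property
    def threshold_grid_pct(self) -> tuple[float, ...]:
        """The proportional-threshold sweep in percent (default 10..34 by 1)."""
        grid = []
        p = self.threshold_min_pct
        while p <= self.threshold_max_pct + 1e-9:
            grid.append(round(p, 10))
            p += self.threshold_step_pct
        return tuple(grid)

    @property
    def window_duration_seconds(self) -> float:
        return self.window_length_tr * self.tr_seconds

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "lambda_grid" in d:
            d = dict(d, lambda_grid=tuple(d["lambda_grid"]))
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON config file."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
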