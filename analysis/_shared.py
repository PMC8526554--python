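"""Shared settings for the numbered analysis steps: one output tree, one seed."""

from pathlib import Path

from dynstates.config import RunConfig

SEED = 7
OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def config() -> RunConfig:
    """Study-condition defaults, with clustering scaled to k = 2..6 and 20
    restarts (ample for the strongly separated planted states)."""
    return RunConfig(rng_seed=SEED, output_dir=str(OUT_DIR),
                     k_max=6, kmeans_reps=20)
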