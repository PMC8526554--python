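#!/usr/bin/env python
"""Step 2 — static functional connectivity.

Whole-time-course Pearson FC per subject, edge-wise residualization against
age, gender, pre-treatment UPDRS-III ON and mean framewise displacement,
the covariate-adjusted group matrix, each subject's overall-FC scalar
(the control covariate for later graph-metric tests), and the
between-subject edge variance that the dynamic states will be compared
against.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import OUT_DIR, config

from dynstates.io import load_cohort
from dynstates.pipeline import Manifest, run_static

cfg = config()
net = pd.read_csv(OUT_DIR / "cohort" / "networks.csv")
cohort, phenotypes = load_cohort(OUT_DIR / "cohort", cfg.tr_seconds,
                                 dict(zip(net.region, net.network)))
manifest = Manifest(cfg, OUT_DIR)
static = run_static(cohort, phenotypes, OUT_DIR, manifest)
manifest.write()

print(f"static FC written under {OUT_DIR / 'static'}")
print(f"group FC mean positive edge (overall FC across cohort): "
      f"{pd.Series(static['overall_fc']).mean():.3f}")
print(f"between-subject mean edge variance (static): "
      f"{static['variance_mean']:.4f}")
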