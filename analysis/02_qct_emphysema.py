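#!/usr/bin/env python
"""QCT emphysema scoring on a synthetic cross-sectional cohort.

Twelve phantom subjects span emphysema fractions 0-0.4; their airflow
obstruction (FEV_0.4:FVC) is generated to fall with emphysema burden.
Each subject runs through the full pipeline (lung segmentation, airway
removal, mask refinement, %LAA), and the per-threshold %LAA-vs-ratio
regression slope is fitted - steeper (more negative) at thresholds that
capture the emphysematous mode, which is the pattern expected when
emphysema drives the obstruction.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ferretlung import qct, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

rng = np.random.default_rng(42)
records = []
profiles = []
for i in range(12):
    f = rng.uniform(0.0, 0.4)
    spec = synthetic.PhantomSpec(
        shape=(64, 64, 64), emphysema_fraction=float(f), seed=int(rng.integers(2**31))
    )
    volume, truth = synthetic.make_ct_phantom(spec)
    _, _, profile = qct.qct_pipeline(volume, subject=f"subj{i:02d}")
    # obstruction worsens with emphysema burden (plus measurement scatter)
    ratio = float(np.clip(0.85 - 0.5 * f + rng.normal(0, 0.02), 0.3, 1.0))
    records.append((profile.subject, profile, ratio))
    df = profile.to_frame()
    df["emphysema_fraction"] = f
    df["fev_ratio"] = ratio
    profiles.append(df)

pd.concat(profiles, ignore_index=True).to_csv(RESULTS / "qct_laa_profiles.csv", index=False)
fit = qct.laa_function_slope(records)
fit.table.to_csv(RESULTS / "laa_vs_fev_slopes.csv", index=False)
print("per-threshold slope of %LAA on FEV_0.4:FVC across 12 subjects:")
print(fit.table.to_string(index=False))
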