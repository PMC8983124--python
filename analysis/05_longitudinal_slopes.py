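#!/usr/bin/env python
"""Mixed-model recovery of the genotype-specific IC/Ln age slopes.

For each genotype preset (PiMM control 0.000093, PiZZ 0.00043, AAT-KO
0.00036 mL/cm per day), 200 synthetic cohorts are generated and the
random-intercept model (sex intercept + genotype age slope, REML) is fit
to each.  The mean recovered slope sits on the generating value within
Monte-Carlo error, demonstrating unbiased recovery at the study's actual
cohort sizes.  A combined two-genotype fit also reports the slope
contrast (the progression difference between mutant and control).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ferretlung import stats, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

rows = []
for name, preset in synthetic.COHORT_PRESETS.items():
    rec = stats.simulate_slope_recovery(preset, n_reps=200, seed=1234)
    rows.append(
        {
            "genotype": name,
            "generating_slope": preset.beta_ml_cm_day,
            "mean_recovered_slope": rec["slope"].mean(),
            "mc_se": rec["slope"].std(ddof=1) / np.sqrt(len(rec)),
            "n_reps": len(rec),
            "n_animals": preset.n_animals,
            "n_visits": len(preset.visit_ages_days),
        }
    )
recovery = pd.DataFrame(rows)
recovery.to_csv(RESULTS / "cohort_slope_recovery.csv", index=False)
print(recovery.to_string(index=False))

# contrast between PiZZ and PiMM in a single joint fit
joint = pd.concat(
    [
        synthetic.make_cohort(synthetic.COHORT_PRESETS["PiZZ"], seed=77),
        synthetic.make_cohort(synthetic.COHORT_PRESETS["PiMM"], seed=78),
    ],
    ignore_index=True,
)
fit = stats.fit_longitudinal(joint)
fit.slope_contrasts.to_csv(RESULTS / "cohort_slope_contrast.csv", index=False)
print("\njoint-fit slopes:", {k: f"{v:.3g}" for k, v in fit.slopes.items()})
print(fit.slope_contrasts.to_string(index=False))
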