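#!/usr/bin/env python
"""Generate one of each synthetic input and record its ground truth.

Writes small summary tables to results/ and the (binary) phantom volume
to scratch/ for inspection.  Every downstream analysis regenerates its
own inputs from seeds, so this script is a tour of the generators rather
than a dependency of the later steps.
"""

import json
from pathlib import Path

import numpy as np

from ferretlung import io, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)

# --- CT phantom -----------------------------------------------------------
spec = synthetic.PhantomSpec(emphysema_fraction=0.25, seed=7)
volume, truth = synthetic.make_ct_phantom(spec)
io.write_volume(volume, SCRATCH / "phantom.nii.gz")
io.write_mask(truth.lung, SCRATCH / "phantom_lung.nii.gz")

# --- forced expiration ----------------------------------------------------
trace_preset = synthetic.TracePreset(fvc_ml=30.0, taus_s=(0.2,), duration_s=4.0)
trace = synthetic.make_expiration_trace(trace_preset)
io.write_flow_volume_csv(trace, SCRATCH / "trace_control.csv")

# --- PV loop, cohort, inhibition curve ------------------------------------
loop = synthetic.make_pv_loop(60, 55, 0.1, hysteresis_ml=2.0)
io.write_pv_csv(loop, SCRATCH / "pv_loop.csv")
cohort = synthetic.make_cohort(synthetic.COHORT_PRESETS["PiZZ"], seed=1)
cohort.to_csv(SCRATCH / "cohort_pizz.csv", index=False)
curve = synthetic.make_inhibition_curve([0, 1, 2, 3, 4, 5], slope_per_ul=0.2)
curve.to_csv(SCRATCH / "inhibition_control.csv", index=False)

summary = {
    "phantom": {
        "shape": spec.shape,
        "lung_voxels": truth.lung.count(),
        "airway_voxels": truth.airway.count(),
        "emphysema_fraction_requested": spec.emphysema_fraction,
        "emphysema_fraction_realised": truth.emphysema.count() / truth.lung.count(),
    },
    "trace": {
        "fvc_ml": trace_preset.fvc_ml,
        "analytic_fev_0.4_ml": synthetic.analytic_fev(trace_preset, 0.4),
    },
    "pv_loop": loop.meta,
    "cohort": {
        "n_animals": int(cohort["animal"].nunique()),
        "n_visits": len(cohort),
        "generating_slope_ml_cm_day": cohort.attrs["generating_beta_ml_cm_day"],
    },
    "inhibition_curve_auc_ul": float(np.trapezoid(curve["activity"], curve["volume_ul"])),
}
(RESULTS / "synthetic_inputs.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
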