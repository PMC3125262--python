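"""Normalize and center a simulated two-species hybridization.

Generates a small experiment (a reference species and a diverged test
species, two chips each), computes ΔG37 per probe, fits the control-probe
regression per species, and prints the calibration and the resulting
adjusted-intensity (AI) summaries.
"""

import numpy as np
import pandas as pd

from xspecnorm import SimConfig, delta_g37_many, generate_dataset, normalize_experiment

ds = generate_dataset(
    SimConfig(n_target_probes=1000, n_control_probes=300,
              divergence_per_site=0.3, seed=1)
)
dg = pd.Series(delta_g37_many(ds.probes["sequence"].tolist()),
               index=ds.probes["probe_id"])
ai, fits = normalize_experiment(ds.intensities, ds.chips, ds.probes, dg)

print("Per-species calibration (ln intensity ~ alpha + beta * dG37):")
print(fits[["species", "alpha", "beta", "resid_sd", "shift", "n_controls"]]
      .to_string(index=False))

summary = (
    ai.merge(ds.probes[["probe_id", "category"]], on="probe_id")
    .groupby(["species", "category"])["ai"].agg(["mean", "median"])
)
print("\nAdjusted intensity by species and probe category:")
print(summary.round(3))
print(
    "\nControl probes center on zero in both species by construction; "
    "reference targets sit well above zero (specific binding), while the "
    "diverged species' targets stay near zero — hybridization intensity "
    "does not fake homology after this normalization."
)
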