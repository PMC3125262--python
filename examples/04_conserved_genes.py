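"""Call conserved genes in a deeply diverged species.

Simulates a test species diverged at 0.5 substitutions/site in which 10%
of genes are evolutionarily conserved (shielded from mutation), runs the
full normalization, and tests each gene's exon probes for mean adjusted
intensity greater than zero (Bonferroni-corrected).
"""

import pandas as pd

from xspecnorm import (
    SimConfig, conserved_gene_test, delta_g37_many, generate_dataset,
    normalize_experiment,
)

cfg = SimConfig(
    n_target_probes=1000, n_control_probes=400,
    divergence_per_site=0.5, sigma_noise=0.5,
    conserved_fraction=0.1, probes_per_gene=8, seed=37,
)
ds = generate_dataset(cfg)
dg = pd.Series(delta_g37_many(ds.probes["sequence"].tolist()),
               index=ds.probes["probe_id"])
ai, _ = normalize_experiment(ds.intensities, ds.chips, ds.probes, dg)
res = conserved_gene_test(ai[ai["species"] == "test"], ds.probes)

truth = pd.Series(ds.truth.conserved)
called = set(res.loc[res["significant"], "gene_id"])
planted = set(truth[truth].index)

print(res[res["significant"]].to_string(index=False))
print(f"\nPlanted conserved genes: {len(planted)}; called: {len(called)}; "
      f"correctly recovered: {len(called & planted)}")
print("Only genes whose exon probes genuinely retain sequence identity "
      "rise above the zero-centered non-specific baseline.")
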