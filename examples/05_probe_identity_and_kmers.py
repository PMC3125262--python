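"""Score probe identity against an ortholog and count probe k-mers.

Generates an ortholog pair with a known mutation history, aligns the raw
sequences, scores each 25-mer probe position for nucleotide identity,
and counts occurrences of a few probes in a toy genome (both strands).
"""

import pandas as pd

from xspecnorm import align_orthologs, generate_ortholog_pair, kmer_frequency, probe_identity

a, b, truth_alignment = generate_ortholog_pair(
    600, divergence_per_site=0.08, indel_rate=0.01, seed=2
)
ga, gb, score = align_orthologs(a, b)
starts = list(range(0, len(a) - 25, 50))
ids = probe_identity((ga, gb), starts, probe_length=25,
                     probe_ids=[f"probe@{s}" for s in starts])

print(f"Alignment score {score:.0f} over {len(ga)} columns")
print(ids.to_string(index=False))
print("\nClass rule: 25/25 = true, 23-24 = semi-true, <23 = false — a "
      "probe needs near-perfect identity before it can bind specifically.")

genome = {"chr": a}
probes = pd.DataFrame({
    "probe_id": ["first", "repeat"],
    "sequence": [a[0:25], a[100:125]],
})
print("\nProbe occurrence counts in the reference (both strands):")
print(kmer_frequency(genome, probes).to_string(index=False))
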