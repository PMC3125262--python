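"""Compare false-positive accumulation under the two normalizations.

On a simulated cross-species dataset whose probe identity spectrum spans
<22 to 25 of 25 nucleotides, both the control-probe normalization and the
conventional quantile+scaling baseline are run; at a matched
true-positive count the mismatch-to-perfect ratio quantifies how many
non-matching probes each method would wrongly accept.
"""

from xspecnorm.experiments import specificity_contrast_study

res = specificity_contrast_study(seed=7)

print(f"Probes: {res['n_probes']}, perfect 25/25 matches: {res['n_perfect']}")
print(f"Matched true-positive count: {res['tp_count']}")
print(f"  proposed normalization: threshold {res['threshold_proposed']:.2f}, "
      f"mismatch/perfect = {res['mismatch_to_perfect_proposed']:.2f}")
print(f"  quantile baseline:      threshold {res['threshold_baseline']:.2f}, "
      f"mismatch/perfect = {res['mismatch_to_perfect_baseline']:.2f}")
fold = res["mismatch_to_perfect_baseline"] / res["mismatch_to_perfect_proposed"]
print(f"\nAt equal true-positive yield the baseline drags along {fold:.1f}× "
      "as many mismatch probes per perfect match: quantile normalization "
      "inflates non-specific heterologous signal into the range of genuine "
      "homologous binding.")
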