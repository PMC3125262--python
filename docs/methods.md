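# Methods

## The model

Probe fluorescence after hybridizing labeled genomic DNA to a short-oligo
(25-mer) tiling array is modeled as the product of a **non-specific**
component, governed by duplex thermodynamics, and a **specific**
component that requires near-perfect sequence identity between probe and
target. On the natural-log scale, for control probes — features whose
sequences come from taxa universally diverged from every hybridized
species, so their specific component is absent —

    ln(i_c,s) = α_s + β_s · ΔG37(c) + e,   e ~ N(0, σ_s²),

with one fit per species *s* (differences between species' fits are
attributed to chip-to-chip variation, since the controls are assumed
equivalently dissimilar to all of them). ΔG37 is the nearest-neighbor
free energy of the probe bound to its exact complement at 37 °C; more
negative means stickier. The fitted slope is then removed from *every*
probe and the result is centered so the median control probe sits at
zero:

    AI_p,s = ln(i_p,s) − β_s·ΔG37(p) − shift_s,
    shift_s = median_c[ ln(i_c,s) − β_s·ΔG37(c) ].

AI ≈ 0 marks the non-specific baseline; AI > 0 marks candidate specific
binding. No assumption is made about the distribution of target-probe
intensities, which is the point: a heterologous chip's target
distribution is genuinely different from a homologous chip's, and any
method that forces them to agree (quantile normalization) or to share a
mean (common-mean scaling) transfers intensity into non-binding probes.

Two centerings appear here and they are distinct: the OLS intercept
centers the *mean* residual at zero by construction, while the reported
shift centers the *median*. The median is used for the phase shift
because control populations carry occasional heavy-tailed
cross-hybridization; with an odd control count the median-zero property
is exact, with an even count it holds to floating tolerance under the
midpoint convention (mean of the two central order statistics).

### Assumptions

- Control probes bind every tested sample only non-specifically, and
  equivalently so across species.
- Non-specific binding is log-linear in ΔG37 with Gaussian error. OLS
  is the default estimator; a Theil–Sen option exists for gross
  outliers but is not default, matching the normality assumption.
- Intensities are background-subtracted and positive; the analysis is
  entirely on the natural-log scale.
- With two chips per species (biological replicates), replicate
  ln-intensities are averaged per probe *before* the per-species fit,
  since the model carries no chip index; a per-chip mode (fit and
  adjust each chip, then average AI) is available behind a flag.

## Thermodynamic parameters

The shipped table is the unified nearest-neighbor ΔG37 set at 1 M NaCl:
16 Watson–Crick stacking terms, a duplex initiation term of 1.96
kcal/mol (two G·C-terminated ends at 0.98 each), and a +0.05 kcal/mol
penalty per A·T-terminated end (so an A·T end totals the published
1.03). Initiation and terminal terms are included; note that because
ΔG37 enters the analysis only as a regression covariate, any affine
change to the table (including dropping those terms, or salt
correction) is absorbed by the fitted slope and intercept and leaves AI
unchanged. The table is package data and an alternate TSV can be
loaded. Self-folding and probe dimerization are not modeled.

## The conventional baseline

For comparison the package implements the standard aCGH-style pipeline:
quantile normalization (ties averaged over the order statistics they
span), per-array scaling to a common mean of 500 intensity units, and
positional smoothing over a 50-bp bandwidth. The smoother default is a
windowed mean over ±bandwidth/2 around each probe — chosen because it
has an exact brute-force oracle — with a Haar soft-threshold wavelet
variant available; the baseline exists to demonstrate its artifacts
(scale inflation of heterologous chips, signal bleeding into flanking
probes) and both variants exhibit them.

## Evaluation procedures

**Conserved-gene test.** Per gene, a one-sample one-sided t-test of the
exon probes' AI against zero ("greater"), Bonferroni-corrected at
family-wise 0.05. One-sided because conservation predicts signal above
baseline; genes with fewer than two exon probes are excluded, not
errors.

**Deletion scan.** The test/reference ratio per probe is
exp(AI_test − AI_ref), centered at 1.0. Within each chromosome, a
centered rolling median over 5 probes is thresholded at 0.5 and maximal
runs of ≥10 consecutive suppressed probes are reported as half-open
intervals. Defaults were chosen by simulation to recover 3-kb deletions
at 35-bp probe spacing with zero calls on matched null tracks.

**Identity and specificity.** Probe identity against an ortholog is the
number of alignment columns in the probe's span (25 positions of the
ungapped reference) where both sequences carry the same nucleotide; gap
columns count as mismatch. Classes: true = 25/25, semi-true = 23–24,
false ≤ 22 (22 is classed false; the boundary is configurable). A
global pairwise aligner (match +1, mismatch −1, gap open −5, gap extend
−1) is provided for raw ortholog pairs. The threshold-accumulation
curve counts probes of each class at or above each intensity-ratio
threshold, plus the ratio of mismatch (<25 nt) to perfect-match probes;
methods on incommensurable scales are compared at a matched
true-positive count. The matched count defaults to 75 % of the
perfect-match probes present: at very small counts both methods admit
zero mismatches and the comparison is uninformative.

**k-mer frequency.** Exact occurrence counts of each probe sequence in
a genome, both strands by default (labeled gDNA is double-stranded),
overlaps counted, reverse-complement palindromic windows counted once,
ambiguous windows skipped.

## The synthetic generator

`synth.generate_dataset` emulates a two-species tiling-array genomic
hybridization: a random reference genome (GC 0.36 by default, with an
optional higher exon GC to reproduce the GC/intensity artifact), 25-mer
probes tiled at 35-bp spacing, genes as blocks of 8 exon probes
separated by 2 intergenic probes, 500 foreign control probes, and two
chips per species. The test genome is the reference mutated by per-site
substitutions, 1-bp indels (half deletions, half 1–3-bp insertions) and
planted deletions; a configurable fraction of genes is shielded from
mutation ("conserved"). Signal follows

    ln i = α + β·ΔG37 + g(identity)·(effect + ln copies) + N(0, σ),

with α = 5, β = −0.15 log-intensity per kcal/mol, σ = 0.3 (0.5 in the
noisier gene-test scenarios), specific effect = 2.0 log units, and
g rising linearly from 0 at 20/25 identity to 1 at 25/25. Copy number
enters the specific term as ln(copies), since bound material scales
with genomic copies on the intensity scale. The identity-affinity map
g is a stated knob, not a claim — short-oligo binding is known to be
poorly predictable from identity alone, which is exactly why AI-based
screening needs the statistical testing layer.

Scenario divergences: 0.12 substitutions/site for the specificity
scenario (a candidate-gene regime whose identity spectrum spans well
below 22 up to 25 of 25) and 0.35/site for the genome-wide multi-copy
scenario (two species largely unalignable genome-wide, so heterologous
specific binding is essentially absent); deletion scans use divergence
0 (two isolates of one species). What the generator does **not**
emulate: realistic genome composition and repeat structure, optical and
scanner noise, spatial chip artifacts, probe-specific affinity beyond
ΔG37, and cross-hybridization of controls. Passing tests therefore
demonstrate correctness and statistical behavior of the procedures
under the model's own assumptions, not performance on real chips.

## Numerical choices

- Median convention: midpoint of the two central order statistics
  (even counts); the exact-zero centering invariant depends on it.
- Quantile-normalization ties: average rank, interpolated between the
  spanned order statistics.
- Degenerate inputs rejected with specifics: non-positive intensities
  (named probe), fewer than 3 distinct ΔG values, mismatched probe
  universes, unsorted positions, ambiguous bases (named position).
- All genomic intervals are 0-based half-open in every file format.
- t-tests with zero within-gene variance yield ±∞ (nonzero mean) or
  NaN (identically zero), never a significance call from NaN.
- Simulation studies derive all sub-seeds from one integer seed and
  are reproducible byte-for-byte.

## Study sizes

The bundled studies use sizes that keep every run to seconds while
leaving sampling error far from the decision boundaries: calibration
recovery at 200 replicates × 1,000 controls; deletion recovery at 50
planted + 50 null 100-kb isolates; family-wise error at 200 replicates
of a 1,000-gene global null; sensitivity on a 100-gene candidate panel
(10 planted conserved genes, 20 replicates — a screen of
candidate-gene scale, where the Bonferroni penalty leaves the one-sided
t-test with theoretical power 0.9995 at effect 2.0, σ = 0.5, 8
probes/gene); specificity and multi-copy scenarios at 2,000 target
probes.

## Known limitations

- The control-probe assumption is structural: if controls cross-react
  differentially between species, the centering is biased and nothing
  in the data flags it.
- ΔG37 captures only duplex stability; sequence-specific effects
  (self-folding, position-of-mismatch) land in the residual.
- The deletion scan is a run-length heuristic, not a segmentation
  model; overlapping or very short deletions merge or vanish.
- AI comparisons across species assume the same probe universe was
  measured on all chips.
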