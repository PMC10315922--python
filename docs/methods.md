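# Methods

## Model

All quantities live on the log2 scale, where the two multiplicative biases
of label-free MS quantification are additive:

```
log2 I(ion i, sample s) = p(protein, s) + e(i) + f(s) + ε
```

with `p` the protein's abundance profile, `e(i)` the ion's ionization
efficiency offset, `f(s)` the sample's loading/instrument factor and `ε`
measurement noise. The package estimates `f` (sample normalization) and
`p` (protein intensity estimation) by aligning *intensity traces* — rows
of the ion × sample log2 matrix in one orientation or the other — under
the model that each trace differs from the others by one additive
constant. Alignment never alters the shape of a trace, so within-sample
ion ratios and within-ion sample ratios are preserved exactly.

## The shifting engine

Pairs of traces are compared on jointly observed features only; the median
of the difference estimates the shift, the sample variance (ddof = 1) the
divergence. Merging proceeds by minimum variance (single-linkage style):
the closest pair is aligned and replaced by an average trace, and only the
matrix entries involving the new trace are recalculated. Decisions taken
where the procedure is underdetermined:

* **Variance estimator**: ddof = 1; pairs overlapping in a single feature
  get variance = ∞ so they merge last, but their median remains usable.
* **Tie-breaking**: equal minimum variances resolve to the lowest
  (row, column) position; the engine is fully deterministic and contains
  no randomness.
* **Direction**: the second member of a pair (higher current position) is
  shifted onto the first; `shift_b = median(a − b)`.
* **Averaging**: element-wise mean weighted by the number of original
  traces behind each member, which makes the average of k complete traces
  independent of merge order; where only one member is observed its value
  is taken, so averages fill in missing values.
* **Disconnected traces**: traces sharing no features with the main merge
  component keep shift 0, are flagged, and trigger a warning — never an
  error. If nothing merges at all, every trace is flagged.
* **Zero/negative/absent linear intensities** are treated as missing
  before the log2 transform.

Solutions are defined up to one global additive constant. Re-running any
shift operation on its own output returns shifts ≈ 0 (idempotence, tested
to 1e−9).

### Linear scaling and the comparison budget

With `n > nmax` traces, the `nmax` traces with the fewest missing values
(ties by input order) are merged hierarchically; all remaining traces are
then shifted independently onto the frozen average of the merged anchors,
one comparison each. We count *comparisons* (filling a new matrix cell:
initial half-matrix construction, anchor-average comparisons) separately
from *updates* (recalculating an existing cell after a merge):
comparisons are bounded by `nmax(nmax−1)/2 + (n − nmax)` exactly, updates
by `(nmax−1)(nmax−2)/2`; both are constant in `n` except the single
per-extra-trace term, so total work grows linearly with the number of
samples. Both counters are exposed on the returned solution
(`n_comparisons`, `n_updates`).

Whether beyond-anchor traces should be folded into the running average
rather than shifted against a frozen one is an open design point; the
frozen-anchor variant is used because it keeps the result independent of
the processing order of the remaining traces.

## Sample normalization

One trace per sample over the union of ions, `nmax = 50` by default.
Factors are re-centered so their median is 0 — the gauge constant is
arbitrary, and this choice keeps the dataset's overall intensity scale.
The pairwise **median** assumes a majority of unregulated ions. Two
escape hatches exist for when that fails: a housekeeping-protein subset
(traces built only from those ions, factors applied to everything), and a
kernel-density **mode** estimator (`center="mode"`), which tracks the
sharpest peak of the difference distribution instead of its median. The
mode helps when the regulated majority is *heterogeneous* (many different
fold changes smearing out, unregulated ions forming the sharpest peak); it
is noisier than the median and off by default.

### Known quantitative limit of the median

When a fraction *f* of ions is displaced to one side by much more than the
noise, the median of the difference distribution does not sit at the
unregulated peak but at its `Φ⁻¹(0.5/(1−f))` quantile — a bias of
`≈ 0.674·σ_diff` at *f* = 1/3, where `σ_diff` is the spread of the
unregulated differences. The bias vanishes as noise → 0 (and is absent
for balanced up/down regulation) but does **not** shrink with more ions.
Consequently, on simulated spike-in data with one third of ions regulated
one-sidedly at noise 0.3 log2, recovered fold changes carry a systematic
offset of ~0.17 log2 toward zero. This is a property of median-based
normalization as such, shared with every tool built on the
majority-unregulated assumption; real mixed-species benchmarks have a
smaller regulated ion fraction and correspondingly smaller offsets.

## Protein intensity estimation

Per protein: ion traces over the full ordered sample axis, aligned with
`nmax = 10`; the per-sample median of the aligned traces is the relative
log2 profile (samples with no ion evidence stay missing, never zero).
The profile is transformed back to linear space and multiplied by one
factor — total linear ion intensity over all samples divided by the total
of the back-transformed profile — so each protein's summed intensity
equals its ions' summed intensity exactly. The "total protein intensity"
in that denominator is read as the protein's own profile total; summing
over all proteins instead would break per-protein conservation and is
rejected. Proteins are processed independently; `min_ions` (default 1)
drops sparsely covered proteins. Aligned ion traces are part of the
output so every protein value can be retraced to its evidence.

## Synthetic data

`simulate_dataset` generates mixed-species spike-in designs with known
ground truth:

```
log2 I = base(protein) + ionization_offset(ion) + condition_effect
         + loading_offset(sample) + N(0, noise_sd)
```

* base intensity uniform over 18–30 log2 units (≈ 5 orders of magnitude
  linear dynamic range, typical of deep proteome measurements);
* ionization offsets N(0, 2) log2;
* condition effect = log2 of the species ratio, applied to condition-1
  samples (fold-change convention condition1 − condition2);
* noise: additive Gaussian in log2 = multiplicative log-normal in linear
  space, the standard MS intensity error model; default sd 0.3;
* missingness: records dropped with logistic probability in their log2
  intensity (left-censoring), with the midpoint calibrated by root
  finding so the marginal missing rate matches the configured fraction
  (default 15%), steepness 1/log2-unit;
* DIA mode: `fragments_per_precursor > 0` emits one MS1 trace plus that
  many fragment traces per precursor, each an independent ion.

Everything is driven by one `numpy` Generator seed. Standard designs:
`dda_spikein_config` (400 background + 200 proteins spiked 6-fold, 3 vs 3
samples, 2–6 precursors/protein), `dia_threespecies_config` (3 × 200
proteins at ratios 0.77/1/2, 2–4 precursors × (1 MS1 + 3 fragments)), and
`simulate_tissue_dataset` (three tissues with bidirectional regulation
blocks — 15% at ±2 log2, 25% at ±3 log2 — loading offsets U(−0.5, 0.5),
noise 0.15, 30% censored missingness), which reproduces the failure mode
of naive per-sample median normalization: censoring depletes each
tissue's down-regulated ions from the observed table, biasing observed
medians in a composition-dependent way that pairwise shifting on shared
ions is robust to.

What the generator does **not** model: chromatographic distortion,
co-elution interference, isotope patterns, heavy-tailed outliers, and
peptide-level shared-sequence effects. Passing tests on simulated data
therefore demonstrate the estimator's behavior under the stated additive
model, not performance on any particular real instrument output.

## Problem sizes and numerical choices

The shipped benchmark simulations use 600–1800 proteins, 6–100 samples and
10⁴–10⁵ ion records — small enough to run in seconds while leaving the
median and variance estimates well determined (per-species medians over
200 proteins have sampling error ≈ 0.01–0.02 log2). Idempotence and
exact-recovery assertions use 1e−9 tolerances; signal conservation holds
to float rounding. Duplicate (ion, sample) records are summed in linear
space at ingestion (total-signal semantics); ions mapped to multiple
protein groups are dropped with a warning, protein grouping being the
search engine's responsibility.

## Limitations

* Normalization is linear per sample; intensity-dependent (nonlinear)
  biases are out of scope.
* The median bias described above applies whenever regulation is large,
  one-sided and affects a substantial ion fraction; use the housekeeping
  subset in such designs.
* No differential-expression statistics, FDR handling, or protein-group
  inference — upstream/downstream tools own those steps.
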