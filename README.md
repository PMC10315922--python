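# tracelfq

Label-free protein quantification (LFQ) for bottom-up proteomics:
between-sample normalization and protein intensity estimation by shifting
**log2 intensity traces** on top of each other, with a hierarchical pairwise
merging algorithm that scales linearly in the number of samples.

## The problem

A shotgun proteomics experiment quantifies thousands of peptide ions
(MS1 precursors in DDA; precursors plus MS2 fragment ions in DIA) across
many runs, and two systematic multiplicative biases stand between those ion
intensities and protein abundances:

* **per-sample bias** — unequal sample loading and drifting instrument
  performance scale every ion of a run by a common factor;
* **per-ion bias** — peptide-specific ionization efficiencies offset the
  ions of one protein against each other by orders of magnitude.

In log2 space both become additive constants. `tracelfq` therefore treats
each sample (or each ion of a protein) as an *intensity trace* — a vector
of log2 intensities over a shared feature axis, with missing values as NaN
— and estimates one additive scaling factor per trace such that all traces
align.

## The algorithm

For a set of *n* traces, all pairs are compared on their jointly observed
features: the **median** of the element-wise difference estimates the
systematic shift between two traces, the **variance** (ddof = 1) their
divergence. Collecting both into half-matrices, the algorithm repeatedly

1. picks the comparable pair with the smallest variance,
2. shifts the second member onto the first by the pairwise median,
3. replaces the pair by their member-weighted average trace (missing
   entries filled from whichever member is observed), and
4. recalculates only the matrix entries involving the merged trace,

until one trace remains. Shifts applied to averaged traces propagate to all
underlying original traces. Because pairwise comparison is quadratic, at
most `nmax` traces (the most complete ones) enter this stage; every further
trace is shifted independently onto the frozen anchor average with a single
comparison — at most `nmax·(nmax−1)/2 + (n−nmax)` pairwise comparisons in
total, i.e. linear in *n*.

The pipeline uses this engine twice:

* **Sample normalization** (`nmax = 50`): one trace per sample over all
  ions; the recovered factor 2^shift rescales each sample. Valid while the
  majority of ions are unregulated; a housekeeping-protein subset or a
  KDE-mode location estimator are available when it is not.
* **Protein intensity estimation** (`nmax = 10`): per protein, one trace
  per ion over all samples; after alignment the per-sample median is the
  relative protein profile, which is transformed back to linear space and
  rescaled by one factor so that the protein's total linear intensity
  equals the total intensity of its ions (signal conservation, exact).

## Worked example

Simulate a small two-condition spike-in (30 proteins at 4-fold between
conditions on a 60-protein constant background, log2 noise 0.2, 10%
missingness), quantify it, and evaluate the recovered ratios:

```bash
tracelfq simulate --config sim.yaml --seed 7 --out table.tsv --truth truth.tsv
# wrote 1943 records for 90 proteins
tracelfq run --input table.tsv --out-dir out
tracelfq evaluate --proteins out/protein_intensities.tsv \
    --groups groups.tsv --species species.tsv --out summary.tsv
#               median        sd   n
# species
# background -0.106364  0.114078  60
# spike       1.889142  0.124961  30
```

The spiked species recovers a median log2 fold change of 1.89 (expected
log2 4 = 2), the background sits near 0; both species show a spread of
~0.12, reflecting the configured noise. `out/` additionally contains the
per-sample normalization factors (`normalization_factors.tsv`, log2 scale)
and the aligned ion traces (`aligned_ions.tsv`) from which every protein
estimate can be retraced.

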