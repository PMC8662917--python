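# beadprep

Preprocessing, simulation and reliability evaluation for Illumina
methylation BeadChip (450K/EPIC-style) data.

Illumina methylation arrays measure per-CpG methylation as a beta value
β = M/(M+U+α), where M and U are the methylated and unmethylated
fluorescence intensities and α is a small stabilizing offset.  Raw
intensities carry optical background, a systematic gain difference
between the Cy3 (green) and Cy5 (red) channels, and a compression of the
Infinium II probe beta distribution relative to Infinium I — all of which
inflate noise between technical replicates and bias the measured
methylation level.  `beadprep` implements a stepwise, model-based
preprocessing pipeline for these artifacts, three simplified comparator
pipelines, the duplicate-based statistics used to judge them, and a
synthetic two-channel array generator with known ground truth so every
stage is testable without real arrays.

## The pipeline

Stages run in order:

1. **Background correction.**  Observed intensity is modelled as
   X = S + B with background B ~ TN(μ_b, σ_b; 0) (normal truncated at 0,
   estimated from out-of-band reads of Infinium I probes) and signal
   S ~ π·Exp(λ) + (1−π)·TN(μ_s, σ_s; 0).  The exponential/truncated-normal
   mixture accommodates the bimodal intensity distributions methylation
   arrays produce, which the single-exponential normexp model fits
   poorly.  Fitted per sample and per design stratum by EM; corrected
   intensity is the posterior mean E[S | X = x].
2. **Dye-bias correction.**  Paired internal normalization controls are
   read in both channels; per array, OLS of log(red) on log(green) over
   the controls gives an affine map that transfers the whole green
   channel onto the red scale.
3. **Optional inter-array quantile normalization** of intensities within
   the six subsets {methylated, unmethylated} × {I-Red, I-Grn, II}
   (recommended only for homogeneous sample sets; off by default).
4. **Probe-type calibration.**  Infinium I and II probes < 50 bp apart
   measure near-identical methylation; an OLS fit on the logit scale of
   their paired empirical beta quantiles gives a per-sample affine map
   applied to every type II beta.
5. **Quality control and imputation.**  Data points with detection
   p > 10⁻⁶ (negative-control normal null on M+U) or < 3 beads are
   masked; samples with > 5% masked points or mean bisulfite-control
   intensity < 5500 are flagged; masked betas are filled with the probe
   median.

Comparators: Illumina-style 5th-percentile background subtraction with
reference-sample dye scaling, Noob (normexp with out-of-band background),
and a dasen-like offset + subset quantile normalization; plus `raw`.

Evaluation statistics: centered correlation (per-probe population means
subtracted before correlating duplicate residuals), mean absolute
difference between duplicates, per-probe one-way ICC(1,1) with the
0.5/0.75/0.9 reliability classes, KDE-mode deviation from nominal levels
for titration standards, and paired Wilcoxon tests between pipelines.

## Worked example

Simulate five pairs of technical duplicates (20,000 probes) with default
artifacts, preprocess with the full pipeline and with no correction, and
evaluate duplicate concordance:

```sh
beadprep simulate --design duplicates --n-probes 20000 --n-pairs 5 --seed 7 --out demo/bundle
beadprep preprocess --bundle demo/bundle --pipeline enmix --out demo/enmix
beadprep preprocess --bundle demo/bundle --pipeline raw   --out demo/raw
beadprep evaluate --beta demo/enmix/beta.tsv --pairs demo/bundle/pairs.tsv --out demo/eval_enmix
beadprep evaluate --beta demo/raw/beta.tsv   --pairs demo/bundle/pairs.tsv --out demo/eval_raw
```

The two `evaluate` calls print:

```
{                                          {
  "n_pairs": 5,                              "n_pairs": 5,
  "mean_centered_correlation": 0.9465,       "mean_centered_correlation": 0.8114,
  "mean_abs_diff": 0.0111,                   "mean_abs_diff": 0.0237,
  "median_icc": 0.9459,                      "median_icc": 0.7893,
  "fraction_icc_gt_0.75": 0.8418             "fraction_icc_gt_0.75": 0.5587
}            (enmix)                       }            (raw)
```

Correction roughly halves the mean absolute difference between duplicate
measurements (0.024 → 0.011), raises the mean centered correlation from
0.81 to 0.95, and lifts the fraction of probes with good-or-better
reliability (ICC > 0.75) from 56% to 84%.  `beadprep compare` produces
head-to-head win fractions and Wilcoxon p-values across any set of
pipelines.

The same functionality is available as a library
(`beadprep.run_pipeline`, `beadprep.run_evaluation`, ...), and bundles
can be written as real binary IDAT pairs via `beadprep.write_idat`.

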