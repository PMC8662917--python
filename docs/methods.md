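# Methods

## Data model and conventions

A manifest row describes one probe.  Infinium II probes occupy one bead
address and are read in both channels: the green read is the methylated
signal, the red read the unmethylated signal.  Infinium I probes occupy
two addresses (A and B) and are read in a single declared channel:
AddressB carries the methylated signal and AddressA the unmethylated
signal, both from the declared channel.  The same two addresses read in
the opposite channel are the out-of-band (oob) intensities; they have no
complementary target there and measure background fluorescence only.
Coordinates follow the MAPINFO convention (1-based); probe-pair distance
is |position_i − position_j| on the same chromosome.

Betas are computed as β = M/(M+U+α) with offset α = 100 by default
(configurable); a zero denominator yields a missing value rather than an
error.  Beta matrices are written as TSV with `NA` for missing; the
matrix bundle (red/grn/nbeads TSVs + manifest CSV) round-trips bit-exact
via 17-significant-digit formatting and round-trip float parsing.  The
IDAT writer/reader uses the documented non-encrypted field-table binary
layout (magic `IDAT`, version 3, field codes for probe count, addresses,
Mean/SD as uint16, NBeads as uint8, barcode); unknown field codes are
skipped with a logged warning.

## Background model

Observed intensity is X = S + B.  The background B follows a normal
truncated at zero, TN(μ_b, σ_b; 0), estimated by maximum likelihood from
the channel's out-of-band reads (negative controls can substitute when a
design has no type I probes).  The signal is a two-component mixture

    S ~ π · Exp(λ) + (1 − π) · TN(μ_s, σ_s; 0),

where the exponential absorbs the dim population (the unmethylated
allele's signal at fully methylated CpGs and vice versa) and the
truncated normal the bright population.  Fitting is per sample and per
design stratum {I-Red in-band, I-Grn in-band, II-Grn, II-Red}, since each
stratum has distinct optics; the background is shared per channel.

The convolution densities and posterior moments have no closed form for
the truncated-normal component.  Both are evaluated by 64-point
Gauss–Legendre quadrature over the background variable restricted to
b ∈ [μ_b − 8σ_b, μ_b + 8σ_b] ∩ [0, x], where essentially all background
mass lies; the signal densities are smooth on that scale, so the
quadrature is accurate to ~10⁻⁹ relative (verified against adaptive
quadrature).  Because the nodes depend only on the background fit, which
is held fixed, the EM iterations operate on a fixed discretized model and
the log-likelihood trace is exactly non-decreasing.

EM details: initialization π = 0.5, λ = 1/mean(x − μ_b), (μ_s, σ_s) from
upper-half moments; E-step responsibilities and conditional moments
E[S|x,z], E[S²|x,z] from the quadrature; M-step closed-form for π and λ,
and a Nelder–Mead maximization of the expected complete-data
log-likelihood for (μ_s, σ_s) with a safeguard that keeps the previous
parameters if no improvement is found (preserving ascent).  Convergence
is declared when the change in mean per-observation log-likelihood drops
below `tol` (default 10⁻⁴), or at `max_iter` (default 500) with
`converged=False`.

Identifiability: a truncated normal with location near zero and a large
scale is monotone decreasing and can mimic the exponential component,
creating a likelihood ridge on which the mixture weight is poorly
determined.  The bright component is therefore constrained to a positive
location with σ_s < μ_s (log/logistic parametrization in the M-step), so
it keeps an interior mode.  Even so, when the data are genuinely pure
exponential the truncated normal sheds its weight slowly along the
remaining ridge; boundary-recovery checks use a tighter tolerance
(10⁻⁶).  Interior parameter recovery is unaffected (median relative
error < 5% at n = 50,000 across all six parameters).

Correction replaces x by E[S | X = x] floored at 1.0 intensity unit
(keeps betas and logarithms defined).  The pipeline fits each stratum's
model on a seeded random subsample of 4,000 intensities and applies the
correction through a 1,024-point monotone interpolation grid; both sizes
are configurable, and exact per-point evaluation is available through
`correct_intensities`.  The fit subsample keeps a 40-sample, 100k-probe
run in the minutes range while leaving parameter standard errors far
below the artifact magnitudes being corrected.

## Dye-bias correction

Each paired normalization control is one bead population read in both
channels, so per array log(red) = a + b·log(green) + ε over controls.
The map is fitted by OLS per sample (each array has its own dye
chemistry) with pseudo-count 1 before the log, and applied to every green
intensity — probes and control blocks alike — putting green on the red
scale: g → exp(a + b·log(g+1)) − 1, floored at 0.  Red is the reference
channel (configurable).  Applying fit+apply a second time is the identity
to within 0.1%.

## Quantile normalization and probe-type calibration

Subset quantile normalization equalizes each sample's intensity
distribution within the six subsets {meth, unmeth} × {I-Red, I-Grn, II};
the target is the across-sample mean of order statistics, rank ties map
to the average target value, and masked entries are excluded from the
pool and restored as masked (incomplete columns contribute through their
interpolated quantile function).  The implementation is exactly
idempotent on complete data.  Inter-array normalization is off by
default — it assumes similar overall distributions across samples and is
recommended only for relatively homogeneous sets (it is actively harmful
for the titration standards, whose distributions should differ).

RCP calibration pairs each type II probe with its nearest type I probe
< 50 bp away on the same chromosome (ties toward the lower position; the
window is configurable).  Per sample, the paired betas' empirical
quantiles on a 500-point grid are clipped to [10⁻⁶, 1−10⁻⁶],
logit-transformed, and OLS-fitted as logit(q_I) = c + m·logit(q_II) with
m > 0 enforced; every type II beta is then mapped through
expit(c + m·logit(β)).  Calibration is per sample because the probe-type
distortion varies between arrays.  One calibration per sample rather
than one pooled fit was the open design choice; per-sample matches the
stage's purpose of aligning each array's type II distribution with its
own type I distribution.

## Quality control

The detection null for a probe's total signal M+U is normal with mean
μ_R + μ_G and variance σ_R² + σ_G² from the sample's negative controls
(at least 10 per channel required); the p-value is the upper tail.  A
data point is masked when p > 10⁻⁶ or its bead count < 3; a sample is
flagged when its masked fraction exceeds 5% or its mean
bisulfite-conversion control intensity (average of both channels' reads
over all bisulfite controls) falls below 5500.  All threshold
comparisons are strict, exactly as printed.  Masking precedes the sample
screen.  Imputation fills masked betas with the probe's across-sample
median — deterministic and order-independent; fully-masked probes are
reported, never fabricated.

## Comparator pipelines

* Illumina-style: per channel, subtract the 5th percentile of that
  channel's negative controls; values below it become ε = 1.0.  Dye step:
  scale each sample's green channel so its control red/green ratio equals
  the first sample's.
* Noob: closed-form normexp posterior mean with (μ_b, σ_b) from the
  channel's oob reads and exponential mean α = mean(x) − μ_b; the
  φ/Φ ratio is evaluated with the scaled complementary error function so
  the far tail stays finite.  Dye step as Illumina but with the
  across-sample mean control intensities as reference.
* dasen-like: per sample, add the (median type II − median type I)
  intensity offset to type I intensities (meth and unmeth separately; the
  offset statistic is unspecified upstream, median chosen here), then
  quantile-normalize within {meth, unmeth} × {I, II}.  No flooring after
  the shift — rank-based normalization replaces the values anyway, and
  clipping would create ties.

## Evaluation statistics

Centered correlation subtracts each probe's population mean before
correlating a duplicate pair's residuals: 1 for identical duplicates, 0
in expectation for unrelated samples.  Plain Pearson correlation between
unrelated arrays exceeds 0.98 because the bimodal per-probe means carry
the correlation — the motivation for centering.  Population means use
all samples by default; a leave-pair-out option removes the small
in-sample bias (≈ −2/n) that matters only for small populations.
Pearson correlation is used (residual correlation is the standard
reading).

Per-probe reliability is one-way random-effects ICC(1,1): with 2
replicates per pair, (MSB − MSW)/(MSB + MSW) over complete pairs, at
least 3 pairs required, negative estimates reported as-is and classified
"poor".  Classes: < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good,
≥ 0.9 excellent (boundaries assigned upward).

Distribution modes use a Gaussian KDE with Silverman bandwidth on a
512-point grid over [−0.05, 1.05], ties broken toward the lower mode and
a degenerate (constant) input returning the constant.  Titration
accuracy is the mean |mode − nominal level| across standards.  Pipeline
comparisons use the two-sided Wilcoxon signed-rank test (exact for small
tie-free samples); an all-tie input returns p = 1 with a warning.

## Synthetic data generator

The generator emulates the measurement process the pipeline corrects:

* Population: per-probe mean methylation from 40% Beta(1,15) + 40%
  Beta(15,1) + 20% Uniform(0.2, 0.8) — most CpGs near 0 or 1 —
  with logit-normal individual deviations scaled to ≈ 0.05 beta-scale SD
  (damped at the extremes).
* Intensities: per probe and sample a lognormal total signal (median
  5,000, log-SD 0.4) split M = βT, U = (1−β)T; truncated-normal
  background TN(300, 50; 0) added to every in-band and out-of-band read;
  the whole green channel multiplied by the array's dye gain
  (default 1.25); type II betas compressed on the logit scale by κ
  (default 0.6) before intensity generation.  Artifacts vary between
  arrays (lognormal jitter of the dye gain with log-SD 0.05 and of the
  background level with log-SD 0.1; normal jitter of κ with SD 0.05) —
  the between-array variation that model-based preprocessing removes.
* Controls: 100 negative controls per channel (pure background), 30
  paired normalization controls (one shared realized intensity per
  control, wide lognormal spread, read in both channels), 20 bisulfite
  controls at mean 8,000.  Bead counts are 3 + Poisson(12) with a 0.1%
  fraction forced below 3.
* Designs: technical duplicates share true betas but draw independent
  artifacts; the titration series uses levels 0/5/10/20/40/50/60/80/100%
  with replicate counts 10,3,2,3,3,2,3,3,10 (39 samples), every probe at
  the sample's nominal level.
* Geometry: one synthetic chromosome, ~1 kb probe spacing, with 5% of
  type II probes relocated to within 30 bp of a type I probe so the
  probe-type calibration has pairs to learn from.

Defaults not fixed by the array designs above were chosen once from
typical published array characteristics.  What the generator does *not*
model: cross-hybridization signal in out-of-band reads, SNP-affected
probes, sex chromosomes, plate/batch structure beyond per-array artifact
jitter, and the true chemical mechanism of probe-type bias (compression
is injected in the logit domain, the same family RCP corrects — so
compression recovery shows the stage works when its model holds, not
that the logit-affine family captures real chemistry).  Passing tests on
synthetic duplicates therefore demonstrate correct mechanics and
artifact recovery, not field performance on real arrays.

## Problem sizes

The test suite runs the end-to-end duplicate comparison at 20 pairs ×
100,000 probes and the titration series at 39 samples × 10,000 probes;
EM parameter-recovery checks use 20 seeded draws of n = 50,000.  These
sizes put Monte-Carlo error well below every asserted margin while
keeping a full run in the minutes range.

## Known limitations

* The detection null uses the combined two-channel negative-control
  moments for all probes, including single-channel type I probes (the
  contract chosen here); a per-channel null would be slightly sharper
  for type I probes.
* The EM mixture weight converges slowly when one component is truly
  absent (see above); `converged=False` plus the fitted weight should be
  inspected when auditing fits on unusual strata.
* RCP requires ≥ 50 usable pairs and non-degenerate quantile variance;
  on degenerate inputs (e.g., an all-constant array) the pipeline skips
  calibration for that sample with a warning rather than failing.
* Quantile-normalization idempotence is bit-exact only for complete
  (unmasked) columns; incomplete columns go through interpolated
  quantile functions.
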