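# Methods

## Decay model

Every emitter class is a multi-exponential decay convolved with a Gaussian
instrument response function (IRF). For component lifetime τ, IRF centre μ
and width σ, the photon arrival-time density is the exponentially modified
Gaussian (EMG); its CDF is evaluated with `scipy.stats.exponnorm`
(shape K = τ/σ), with the pure-exponential limit used when σ = 0. Expected
per-bin counts are CDF differences at the bin edges ("unit total signal"
means the untruncated density integrates to one, so in-window mass can be
slightly below one for long lifetimes). Gate survival is the ratio of
gated to full-window CDF mass of the background-free signal; the loss rate
is (1 − survival) × 100 %.

Acquisition geometry defaults, chosen once and shared by the whole package:

| parameter | default | rationale |
| --- | --- | --- |
| repetition period | 12.5 ns | 80 MHz pulsing, consistent with an 11.5 ns maximum gate |
| recording window | [−1, 11.5] ns | t = 0 at the IRF peak; the −1 ns edge records the IRF rising flank |
| bin width | 0.05 ns (250 bins) | fine enough that gate-edge snapping errs ≤ 0.025 ns |
| IRF | Gaussian, μ = 0, σ = 0.15 ns | typical confocal TCSPC width; δ-IRF (σ = 0) available for analytic checks |
| wrap-around | off | τ ≪ period for all defaults; an optional 8-pulse periodic summation exists |

The named gates are UNFILTERED = [−1, 11.5] ns (the instrument's widest
gate) and FLF = [4, 11.5] ns.

## Class photophysics and the LD calibration

* LRO: single component, τ = 1.5 ns (the narrow short-lifetime peak).
* Autofluorescence: single component, τ = 1.0 ns.
* LD: two components with lifetimes fixed at 1.8 and 8.0 ns. Class-level
  gating measurements do not identify the component structure of the broad
  LD distribution, so the mixture weight is *calibrated*: the fraction on
  the 8.0 ns component is solved (bisection on the closed-form survival) so
  that the LD class loses exactly 58.3 % of its signal under the FLF gate,
  the measured class-level loss. With the default IRF this gives ≈ 0.86 on
  the long component. A companion helper reports the single "effective"
  lifetime with the same gating behaviour (≈ 5.7 ns). These are calibration
  targets, not measured component values.

Photon sampling uses the exact EMG decomposition — normal(μ, σ) plus
exponential(τ), rejected against the recording window — rather than
numerical CDF inversion. The sampling route and the closed-form route are
therefore algorithmically independent, and the tests exploit that: sampled
histograms are checked against the closed form by chi-square goodness of
fit, and the closed form itself is checked against a brute-force numerical
convolution oracle.

## Synthetic worms

A worm is an elliptical body mask (axes 0.7 × and 0.9 × the frame) filled
with disk organelles placed by rejection sampling (≤ 1000 retries each,
failure is an error naming the config). Organelle boundaries keep a ≥ 5 px
gap: organelles are resolvable structures, and the gap keeps them
individually countable after the 4× low-magnification pooling used in the
screening workflow — the regime in which by-eye mutant identification is
meaningful at all. Defaults per wild-type worm: 12 LDs (radius 3 ± 0.8 px),
12 LROs (radius 2 ± 0.5 px) in a 128 × 128 frame.

Brightness: expected photons per organelle pixel are a class base rate
(LD 100, LRO 400 at 1 µM — LROs outshine LDs at low concentration) times a
concentration multiplier times a per-organelle log-normal factor
(σ_log = 0.3), making "ten brightest per worm" selection meaningful.
Pixel counts are Poisson. Diffuse autofluorescence adds ~2 expected photons
per body pixel (6 in the aged preset, which also places discrete
autofluorescent granules and no dye-labelled organelles).

The concentration law is LD ∝ c and LRO ∝ √c (normalized to 1 µM,
exponents config-exposed). It is an invented minimal law reproducing the
observed direction — higher dye concentration closes the LD–LRO brightness
gap, so the unfiltered RLL rises with concentration and FLF and
concentration act together. The panel {1, 4, 8, 12} µM is the standard
staining series; screens run at 8 µM.

Genotype presets encode phenotype anchors: *glo-1* has no LROs; *daf-22*
has 2×-radius LDs (8 of them); high/low-fat presets vary LD count;
`unstained_aged` emits only short-lifetime autofluorescence. All generation
is deterministic in the config seed.

What the generator does **not** emulate: anatomical worm shape and
intestinal structure, optical PSF blur, depth sectioning, detector
afterpulsing or pile-up, organelle motion. Passing tests therefore
demonstrate the *logic* of lifetime filtering — gating arithmetic, class
discrimination, bias removal, screen detectability — under idealised
two-class scenes, not performance on real micrographs.

## Lifetime estimation

`tau_contrast_image` is the fast estimator: intensity-weighted mean photon
arrival time per pixel minus the IRF centre, clamped at zero; zero-count
pixels carry an explicit mask (NaN), never a silent zero. It inherits two
small biases — bin-centre discretisation and window truncation (the
truncated mean of a τ = 4 ns decay in this window is ≈ 0.7 ns below τ) —
both quantified in tests against a fine-grid analytic moment oracle.

`reconvolution_fit` is the quantitative estimator: weighted least squares
of the closed-form curve against an ROI histogram with Poisson variance
weights max(counts, 1) (a reduced *Pearson* chi-square; the convention is
stated because instrument-software conventions are unpublished).
Free parameters: component lifetimes, component amplitudes, and a
nonnegative uniform background; the Gaussian IRF parameters are inputs and
can optionally be co-fitted. Degrees of freedom are T − n_free with
n_free = 2n + 1 (+2 when co-fitting the IRF). Initialisation is
moment-based (background from the pre-pulse region, lifetimes spread
geometrically around the background-corrected mean arrival time); three
starts are tried — the moment start and two seeded ±25 % perturbations —
best chi-square wins, ties to the first start. Non-convergence returns
`converged=False` rather than raising; fewer than 100 photons is an error.
Fits require ≥ trust-region termination at xtol = ftol = gtol = 1e−12,
which recovers noiseless single-component curves to 1e−6 relative.

One ambiguity is worth stating: a photon *arrival-time* histogram of a
1.5 ns emitter peaks near the IRF (≈ 0 ns), not at 1.5 ns. The "narrow
distribution peaking at 1.5 ns" that distinguishes LROs is the *lifetime*
distribution; in this package it appears as the mode of the per-pixel
tau-contrast estimates over an LRO ROI, and that is what the tests assert.

## Gating and metrics

Gating selects photons by arrival time (as hardware Tau gating does), never
by a per-pixel fitted lifetime. Gate edges snap to the nearest bin edge;
a gate that snaps to zero bins is an error. Gated images are per-pixel sums
over the in-gate bins, so partitioning the window partitions every pixel's
counts exactly.

ROI mean intensity is the arithmetic mean over the ROI's labelled pixels.
The gate-threshold scan tabulates, for each minimum threshold in
{−1, 0, 1, 2, 3, 4, 5, 6} ns (maximum fixed at 11.5 ns), the RLL and the
per-class loss rates versus the unfiltered image. Loss rate, RLL and
control normalization are implemented exactly as defined; RLL is reported
as undefined (an error) when a group has no LRO signal, as in *glo-1*.
Brightness ranking for "ten brightest" selection uses unfiltered intensity
by default (flag to switch); ties break to the lower ROI id. Group fat
comparisons take per-worm mean intensity over the worm-body mask (the
synthetic stand-in for the intestinal ROI), normalize both groups to the
control group's average, and report Welch's unpaired t statistic and
Cohen's d — standard plumbing around the method, not part of it.

## Segmentation and the screen classifier

Segmentation is a global Otsu threshold computed on log1p of the *positive*
intensities (count images are heavy-tailed; linear-domain Otsu lands among
the bright objects), floored at 4× the median of the sub-threshold positive
pixels so that an overwhelming diffuse-background mode cannot capture the
split; then 8-connected components, dropping those below `min_area`.
Components segmented from a lifetime image are classed short/long by median
tau against a 3 ns cut.

The screen emulates the low-magnification mixed-population assay:
stacks are 4×-sum-pooled (photon-conserving), segmented on the pooled
tau-contrast image, and classified by two rules with exposed thresholds —
median LD-candidate area > 2.0 × the population-median reference flags an
enlarged-LD mutant; fewer than 3 short-lifetime components flags a missing-
LRO mutant; otherwise wild-type. Standalone calls use an analytic wild-type
reference area of π/4 · (d/f + 1)² pooled pixels (disk diameter d, pool
factor f — a pooled pixel counts whenever the disk touches it). Stacks
under 1e4 photons are flagged low-confidence. The rules operationalise what
a screener does by eye; the thresholds are design choices, not measured
quantities.

## Problem sizes

Defaults keep every computation at desk scale: 128 × 128 worms with
~4 × 10⁵ photons at 8 µM, 10-worm screen populations, 10–20 seeds per
repeated-seed property, 1e5–1e6 photons per fitted decay, 4-worm groups in
comparisons. These sizes make the full test suite and the acceptance script
each run in minutes on one CPU while leaving the statistical margins (3
standard errors; 19/20 identification) intact.

## Known limitations

* The LD two-component parameters are calibration artefacts; only the
  class-level FLF loss is anchored to measurement.
* The concentration law is phenomenological; only its direction is
  supported.
* Complete disappearance of LRO remnants from FLF images is a
  display-scaling effect; an adaptive threshold can still segment the ~7 %
  remnant, which is why the package's claim is the brightness inversion
  (LRO components fall below LD components under FLF), not component
  count zero.
* The fitter is least-squares, not maximum-likelihood; at very low counts
  per bin the Pearson weighting biases chi-square slightly below one.
* No phasor analysis, no global multi-pixel fitting, no measured
  (non-parametric) IRFs.
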