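# Methods

This note documents the models, parameter choices and numerical
behaviour of `reporterscreen`, and what the synthetic-data tests do and
do not establish about real screens.

## Generative model for single-cell fluorescence

Each cell's emitted signal in channel *c* (GFP or mCherry) is

    x_c = m_c · E · I_c        E, I_c lognormal with mean 1,

where `E` is an *extrinsic* factor shared by both channels within a
cell (cell size, ribosome content, global transcription machinery) and
`I_c` a channel-specific *intrinsic* factor. Lognormals were chosen
because fluorescence is strictly positive, single-cell expression
distributions are right-skewed, and the CV parameterization is closed
form: for independent unit-mean lognormals CVs combine as
`(1 + CV_total²) = (1 + η_ext²)(1 + η_int²)`, which
`synthlib.intrinsic_cv` inverts. A consequence used by the tests: the
between-channel correlation is exactly `η_ext² / (CV_gfp · CV_mch)`.
A requested total CV below the extrinsic CV is rejected — no intrinsic
noise level can produce it.

Autofluorescence (lognormal around `autofluorescence_mean`, CV
`autofluorescence_cv`) is added to the emitted signal of each channel,
and the detector then mixes the two emitted intensities linearly:
`raw = M · emitted` with `M = [[1, m12], [m21, 1]]`. Mixing after
autofluorescence reflects how detectors see total emitted light.
Forward and side scatter are lognormal with their log correlated
(default ρ = 0.5) with the extrinsic factor's log, so the scatter gate
interacts non-trivially with fluorescence. With probability `loh_rate`
(default 1.5%, matching the "usually below 2%" dropout seen in diploid
dual-reporter strains losing one allele) a cell's biological signal in
one random channel is zeroed while its autofluorescence remains.

### Library structure

Strains fall into four regimes relative to the normal state
(profile 1): profile 2 = repressed and noisy (silencing-like), profile
3 = repressed with normal noise (e.g. transcriptional interference),
profile 4 = overexpressed (clustering with co-regulated genes). Default
per-profile multipliers on (mean, CV) are (1, 1), (0.6, 3.0),
(0.6, 1.0), (1.6, 0.8). The 0.6 relative mean corresponds to the
repression depth typical of confirmed repressed outliers in screens of
this design; the remaining values are calibration choices — such
screens report example strains, not population effect-size parameters —
fixed once here and not tuned thereafter. The mCherry parameters are
profile-independent: the control reporter sits at the same fixed locus
in every strain.

Two parameters are deliberate additions to the minimal model:

* `strain_mean_cv` (default 0.05) — lognormal strain-to-strain spread
  of true means around the profile baseline. Without it the library SD
  of normalized means collapses to measurement error of the per-strain
  mean (≈0.4% at 5000 events) and a "3 SD" rule loses its meaning; 5%
  is a realistic magnitude for locus-to-locus variation among
  unremarkable insertion sites.
* `cv_mean_exponent` (default −0.25) — a mild decreasing noise-vs-mean
  trend (`CV ∝ mean^−0.25` at the strain level), the universally
  observed scaling that makes the profile-2/3 distinction a residual
  from a fitted trend rather than a raw CV threshold.

Defaults of 5000 events/strain, base CV 0.25 and extrinsic CV 0.15 give
the 3-SD screen essentially full power at these separations.

### What the generator does not emulate

No cell-cycle or lineage structure, no time drift within a run, no
instrument saturation or truncation, no spillover spreading (the
variance inflation real compensation causes at high signal), no
heavy-tailed debris in scatter beyond lognormal clusters, and no
batch-to-batch induction variability. Tests passing on this generator
show the pipeline's statistics are correct under the stated model; they
do not show robustness to those unmodelled artefacts.

## Event processing

* **Scatter gate** — events are ranked by a smoothed 2-D histogram
  density (64×64 bins, Gaussian filter σ = 1 bin) on
  (log FSC, log SSC) and the densest fraction (default 0.95) is kept,
  ties broken by event order so the retained count is exact. Density
  gating replaces hand-drawn polygons with a reproducible rule. Fewer
  than 50 events is refused; constant scatter retains everything with a
  warning.
* **Crosstalk** — after subtracting per-channel blank medians (medians
  resist outliers), each off-diagonal coefficient is the
  least-squares-through-origin slope of the opposite channel on the
  source channel over single-colour control events. Slopes ≥ 1 or below
  −0.01 indicate swapped or inverted controls and are refused; small
  negative estimates clamp to zero. The linear zero-intercept model is
  the standard compensation contract and is exactly invertible.
* **Unmixing** — `[gfp, mcherry] = M⁻¹(raw − background)`. Negative
  unmixed values are retained by default (they are noise around zero;
  clipping would bias strain means upward), with `clip_negative` as an
  option.
* **Dual-positivity gate** — cells must exceed per-channel thresholds
  (default: 99th percentile of the unmixed blank control), removing
  dropout cells. Removal above 50% warns loudly.

## The screen

Strain summaries use the sample SD (n−1); strains with fewer than 200
gated cells are flagged invalid — below that, CV estimates are too
noisy for a 3-SD screen. Normalization and outlier calling are mutually
circular (the anchor population is "non-outliers") and are resolved by
iteration: normalize by the library median, compute z-scores with mean
and SD over the current non-outlier set, reflag, and repeat to a stable
set (≤10 iterations; non-convergence reports the last set with a
warning), finally anchoring the scale so non-outlier strains average
exactly 1. The iterated SD is the deliberate choice: a single-pass SD
is inflated by the outliers themselves and masks moderate ones (a
`single_pass` switch reproduces that variant for comparison). A
degenerate all-identical library normalizes cleanly to 1 with no
outliers, but outlier *calling* on zero SD is refused.

Profile classification fits `CV = a·mean^b + c` (bounds a, c ≥ 0,
−3 ≤ b ≤ 0) to log-binned medians of the non-outlier cloud — binned
medians make the fit robust to stragglers, and any monotone decreasing
trend would serve; the contract is only the sign of the residual.
Repressed GFP outliers (z < −3) split at a residual threshold of
k·MAD (k = 3, MAD scaled to SD) of the non-outlier residuals: above is
profile 2, at/below is profile 3. Overexpressed outliers (z > +3) are
profile 4 regardless of noise. With under 20 non-outliers the trend
falls back to the global median CV with a warning.

`compare_noise` bootstraps cells with replacement within each strain
(default 10⁴ resamples) and reports the CV difference, a percentile CI
and a shift-based two-sided p-value with a +1 pseudocount.

## Proximity test

The reference point of a feature is the strand-aware ORF start (BED
`start` on "+", `end` on "−"); `ignore_strand` reproduces the naive
left-coordinate reading. Distance is unsigned, and a site inside a
feature still measures to its start. Null positions are uniform over
the genome — chromosome proportional to length, position uniform, no
exclusion zones — and may land on featureless chromosomes (infinite
distance), which can only make the test conservative. Two null modes:
`cohort-mean` (default; each permutation draws a cohort the size of the
observed site list and compares mean distances — calibrated p-values
for the mean statistic) and `per-site` (a histogram-style null of
single-position distances). The empirical p-value is
`(r + 1)/(n_perm + 1)` with `r` the number of null values ≤ observed,
so its floor is `1/(n_perm + 1)`: with the conventional 5000-draw null
no p below ≈2×10⁻⁴ is representable, and both modes report their own
floor rather than extrapolating a parametric tail.

## Quantification

Ratios of replicate means carry delta-method SEs (first-order error
propagation, independent groups); the reference group is exactly 1 with
the SE of its own spread. Fold changes between conditions first divide
each replicate by its batch's internal control (3C positive-control
amplicon; housekeeping transcript for RT-PCR), cancelling batch factors
exactly; batches lacking the control are dropped with a warning.
Hypothesis tests are Welch t-tests on log quantities — qPCR noise is
multiplicative — with a raw-scale switch. At n = 3 replicates the
Satterthwaite df approximation is known to be mildly conservative
(measured on this package's simulations: 96.5% coverage of a nominal
95% interval, 3.6% type-I at α = 0.05); the calibration tests assert
that actual behaviour. No multiple-testing correction is applied by
default (single planned contrasts); Benjamini–Hochberg is opt-in.
`cq_to_quantity` converts quantification cycles with a user-supplied
efficiency (default 2, perfect doubling).

## Problem sizes

The bundled calibration studies use a 1327-strain summary-level table
(the screen's library scale), a 1000-strain × 5000-event event-level
library for power/type-I, 500 repeats of a 1000-draw permutation null
for calibration, and 10⁴ simulated triplicate experiments for CI
coverage — sizes at which every binomial check has useful resolution
while the whole suite stays quick on a laptop.

## Known limitations

Only two channels are compensated; no spillover-spreading correction.
The screen operates on total CV; it does not decompose intrinsic vs
extrinsic noise (a dual-reporter analysis that would need per-cell
channel pairing downstream of the summaries). Whether a real screen's
"3 SD" rule used a single-pass or robust SD, and whether its
crosstalk removal was matrix compensation or channel subtraction, are
generally not stated in publications; both choices are explicit
switches here, with the iterated/compensation pair as defaults. FCS
ingestion is out of scope: the event interface is the documented CSV
dialect.
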