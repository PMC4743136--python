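# Methods

This note documents the physical model behind the simulator, the numerical
conventions of the pipeline, the parameter choices that matter, and what
the synthetic studies do and do not demonstrate.

## Polarization model

Light is tracked as Stokes vectors (s0, s1, s2, s3), optical elements as
4×4 Mueller matrices. All angles are in degrees; azimuths are measured
counter-clockwise from horizontal viewed against propagation; the scan
angle φ is 0 at the +x retinal direction. A linear retarder is built as
`rotator(−axis) · canonical_retarder(δ) · rotator(axis)`.

The double-pass train for one sample is

```
horizontal input → HWP(ψ) → [fixed WP] → cornea → Henle(axis(φ))
                → fundus reflection → Henle → cornea → [fixed WP] → HWP(ψ)
```

with ψ = (9/16)·φ. The polarizing beam splitter sends the component
orthogonal to the launched polarization, (s0 − s1)/2, to the detector;
depolarized return contributes a ψ-independent term of half its intensity.

**Double-pass convention.** Whether the return pass sees the HWP at the
same or the mirrored azimuth, and whether the fundus reflection flips
handedness, is not fixed by first principles alone at this level of
abstraction. All four combinations put the gaze-independent carrier at
4.5 fs, but only *identity reflection + same-azimuth return pass* makes
the relative split between the 2.5 and 6.5 fs central-fixation sidebands
depend on corneal retardance, which is the instrument's observed behavior.
That convention is the default and is asserted by the harmonic-signature
tests.

**Henle geometry.** The Henle-fiber axis at the scanned point is the radial
direction from the fovea center; the slow axis is taken radial (flag
`henle_slow_axis_radial`). When the fixation offset reaches the scan radius
(the 1.5° para-central calibration condition) one sample per revolution
lands exactly on the fovea center, where no fiber direction is preferred;
those samples get zero local retardance instead of raising the
invalid-geometry error that the scalar `henle_axis` API signals.

**Magnitudes.** Corneal retardance is drawn uniform on [20°, 80°] with a
uniform axis, Henle single-pass retardance defaults to 3° at the scan
circle — values in the range reported for human corneas and foveae, chosen
to give robust sidebands; they are free parameters of the simulator, not
measured constants. The fixed wave plate of the physical instrument is an
optional slot (default disabled); its exact retardance belongs to the
optical design, and the half-harmonic signature properties hold without
it. In the degenerate limit of near-zero corneal retardance (≲ 2°) the
HWP + cornea train generates almost no carrier and the carrier-dominance
property breaks down; with the fixed WP enabled it holds over the full
[0°, 90°] corneal range.

## Record synthesis

A record is 4 channels × 6000 samples (left/right × center/annulus), one
second at 6000 S/s, 200 samples per revolution, 30 rev/s. Noise has three
classes: scan-synchronous background (a random 200-sample harmonic profile
tiled exactly over the 30 revolutions), 60 Hz line interference (exactly
two cycles per revolution), and white noise. Defaults
(`background_amp=0.5`, `line_amp=0.2`, `white_sigma=0.02`) put the
periodic disturbances at the order of the polarization signal and the
white floor some 30 dB below the sidebands — a clean but not noiseless
photodetector chain. One `numpy` generator seeded at the top level drives
all draws; records are bit-reproducible for a fixed seed.

**Analog front-end emulation.** The instrument's programmable-gain stages
give the strong 4.5 fs carrier less gain than the fixation sidebands to
avoid saturating the analog chain. This is emulated as a per-harmonic gain
table applied to the synthesized record, default 1/8 at 4.5 fs and flat
elsewhere. The choice matters: normalized features are ratios of powers at
*different* frequencies, so the front-end response scales them directly.
With a flat response the simulated carrier exceeds the sidebands by a
factor ~64 in power and every r_cf value falls below the decision-grid
floor of 0.3; the 1/8 gain places the central-fixation ratios in ≈[0.4, 6]
— inside the grid the threshold sweep searches — while leaving the
focus statistic untouched (C and A live at the same frequency).

## Focus and accommodation

Accommodative demand is `stimulus vergence + refraction − trial lens`.
A cyclopleged eye does not respond. A natural eye responds with the demand
clipped between its tonic floor (`tonic_D`, habitual tone it cannot relax)
and its amplitude, minus a proportional lag (`accommodation_lag=0.3`, a
typical near-work lag). This reproduces the worked trial-lens arithmetic —
a +1.00 D hyperope viewing a 3.00 D target peaks at +4.00 D of added lens
under cycloplegia, at +3.25 D with +0.75 D of tonic tone — and makes the
natural-mode focus curve fall slowly but monotonically on the minus-lens
side, steeply on the plus side.

Blur moves the fraction `f_A(d) = 1 − exp(−(d/b)²)` of the returning light
onto the annulus. Channel *amplitudes* split (1−f)/f, so the spectral
powers entering (C−A)/(C+A) split quadratically and the statistic equals
(1−2f)/(1−2f+2f²). The blur scale b ≈ 1.625 D solves this quadratic so the
pipeline statistic crosses the 0.65 pass threshold at exactly 1.0 D of
defocus with an undilated pupil; cycloplegic dilation halves b (factor
0.5), steepening both limbs so the crossing moves to ≈0.5 D past the peak.
Curve peaks and threshold crossings are reported from the 0.25 D lens grid
with linear interpolation.

## Decision logic

* **Threshold sweep (Method 1).** The calibration objective is the pooled
  L1 distance of both classes' r_cf values to θ over the grid
  [0.3, 8.0] in steps of 0.001; its minimizer is the grid point nearest
  the pooled median, with ties broken to the smallest θ (a small relative
  tolerance absorbs float rounding on exactly flat stretches). Because the
  para-central class outnumbers the central one 480:120, the pooled median
  sits in the para cluster and the sweep lands on the grid floor whenever
  the clusters are separated — which is what makes it a usable separator
  here. A misclassification-count objective is available behind a flag as
  a non-standard alternative.
* **Linear discriminants (Method 2).** Two-class pooled-covariance LDA
  with equal priors despite the 120/480 imbalance (proportional priors by
  flag); a singular covariance raises with advice to set `ridge=1e−8`.
  The boundary is `K + P·L = 0`; published coefficient sets are loaded
  via the derived a-coefficients with L(last) = 1. Classification is
  strict: a measurement exactly on the boundary (or exactly at θ) fails.
* **Focus.** Pass at goodness ≥ 0.65 — the printed threshold is itself a
  passing level, a deliberate asymmetry with the fixation criterion's
  strict inequality, so that "falling to the threshold" still passes.
* **Sessions.** 2-of-12 per eye and criterion; alignment requires both
  eyes' central fixation. A degenerate eye-record (carrier below 1e−12 of
  the total half-harmonic power, e.g. a blink) is flagged unusable and
  counted as a failing record: excluded from the 2-of-12 numerator, kept
  in the denominator — conservative toward failing, in keeping with the
  screening intent.
* **Accounting.** Screening convention: positive = abnormal. Sensitivity
  = TP/(TP+FN), specificity = TN/(TN+FP); a rate with an empty
  denominator is reported as absent rather than as a number.

## Spectral conventions

One-sided power spectrum, P(f) = 2|X_k|²/N² at interior bins, so bin
powers of a real signal sum to its mean square. No window: the ADC is
paced by the scan clock, a record holds an integer number of revolutions,
and all characteristic frequencies (75, 105, 135, 165, 195 Hz) fall on
exact 1 Hz bins. Single-bin readout is the default; a ±1-bin band mode
exists for jittered-rate emulation. PhSS is circular over the record
(valid because of the integer period count); a truncated streaming mode is
available behind a flag. Per-eye features default to the sum of center and
annulus channels — the total collected light, robust to defocus — with a
center-only option.

The fixation-dependent power rides as a ±1 fs or ±2 fs sideband *pair*
around the carrier, and under the default double-pass convention the pair
is asymmetric (one member can be two orders of magnitude weaker than the
other, with the split depending on the cornea). Signature analyses
therefore rank the two candidate pairs by their summed power rather than
individual lines.

## Synthetic studies: what they show

`make_calibration_set` reproduces the *structure* of the instrument's
calibration: 5 subjects × 12 records × 2 eyes centered (120 "eyes") and
× 4 gaze directions at 1.5° (480 "eyes"), with random corneal parameters
per subject and per-record processing through PhSS and spectral feature
extraction. The threshold calibrated on one generated set separates a
freshly generated set essentially perfectly, and Monte-Carlo screening of
clearly-normal and clearly-abnormal simulated subjects misclassifies well
under 5 % of sessions.

These numbers validate the pipeline's internal consistency, not its
clinical performance: the generator does not model eye movements within a
record, pupil photometry beyond a single blur factor, wavelength
dispersion, instrument misalignment, or the population spread of fundus
reflectance, and real corneal/Henle birefringence is richer than two
uniform draws. The calibrated synthetic threshold (grid floor 0.3) is
therefore not comparable to the threshold shipped as the instrument
default (0.8750), which belongs to real recordings; both are carried in
the configuration, and synthetic studies recalibrate first, as the
instrument's own procedure does.

## Problem sizes

Default study sizes were chosen to keep every property estimate stable:
20 corneal draws × 4 gaze directions for the harmonic signatures, two
independent 600-eye calibration sets for the round trip, 200 sessions per
condition (≈2400 records each) for the Monte-Carlo screening bound, and
8 draws in the acceptance script's signature consensus.
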