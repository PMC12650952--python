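# Methods

## The measurement problem

A digital nucleic-acid amplification assay partitions a sample across many
femtoliter-scale microchambers so that each chamber holds 0 or a small
number of template molecules. After an isothermal amplification reaction,
chambers that held at least one template light up in a fluorescence
channel; the *fraction* of positive chambers then gives the absolute
template concentration without a calibration curve. `digichamber`
implements the image-analysis half of such an assay — chamber
localization, feature extraction, positive/negative classification and
concentration estimation — plus a synthetic image generator that acts as
its forward model and ground-truth source.

## Loading model and estimators

With template concentration c (mol/L), chamber volume V (L) and
Avogadro's number N_A, the number of templates per chamber is
Poisson-distributed with mean

    lambda = c * V * N_A.

V is the cylinder volume pi (d/2)^2 h; the default chamber dimensions are
d = 4.2 um and h = 3.15 um — midpoints of the fabricated ranges
4.0–4.4 um and 3.0–3.3 um — giving V = 4.364e-14 L (43.6 fL). The
fraction of occupied chambers converges to 1 − exp(−lambda).

Two estimators map the observed positive fraction f to concentration:

* **linear (default):** cE = f / (V N_A). This is the assay's printed
  estimator; it ignores multiple occupancy and under-reads by < 5% at
  f ≈ 0.1 (the factor is f / (−ln(1−f))).
* **Poisson-corrected (flagged, non-default):** −ln(1−f) / (V N_A),
  the exact inverse of the loading law; undefined at f = 1, where the
  package raises a saturation error advising dilution.

With 10,000 chambers of 43.6 fL, one positive chamber corresponds to
~3.8 fM (≈ 4 fM to one significant figure) and full occupancy to
~38 pM (≈ 40 pM) — the measurable range of the geometry.

## Image analysis

**Detection** runs on the reference channel (every chamber stained by a
passive dye, appearing as a ~10-px disk on a ~21.4-px pitch). The
original analysis used an unspecified ImageJ macro; here detection is a
difference-of-Gaussians band-pass at the chamber scale (sigmas d/6 and
d/2) followed by local-maximum picking with a minimum separation of
0.6 × pitch, which merges near-duplicates onto the brighter response.
This is deliberately parameter-light: the chip is a regular grid of
identical bright disks, so any reasonable band-pass + peak picker finds
them; sub-pixel refinement is not attempted. Chambers whose 16-px crop
would cross the image border are dropped. Coordinates are 0-based with
the pixel-center convention; the crop start index is
`floor(center + 0.5) − 8`, which puts the nominal center at local index 8
of a 16-px crop (within half a pixel of the geometric center 7.5).

**Features.** Per chamber, from the signal channel:

* mean intensity over a circular ROI of 10 px diameter (pixels whose
  centers lie within the radius);
* radius of gyration (ROG) of the 16 × 16 crop,
  ROG = sqrt((m20 + m02)/m00), the intensity-weighted RMS distance of
  the crop's signal from the crop center, with raw pixel values (no
  background subtraction — an optional crop-minimum subtraction exists
  but is off by default, matching the plain moment formulas).

A uniform crop gives ROG = sqrt(42.5) ≈ 6.52; a centered chamber-sized
disk gives ≈ 3.5–4.2. Note the uniform value is *not* an upper bound for
arbitrary nonnegative crops (intensity concentrated at the corners
exceeds it, up to 7.5·sqrt(2) ≈ 10.6 for a single corner pixel); it is
the operating point of blank and artifact-filled crops, which is what the
classifier exploits.

**Classification** is a two-gate logic tree: ROG above the ROG threshold
→ negative (the signal is diffuse, not a chamber-sized spot), regardless
of brightness; otherwise positive iff mean intensity strictly exceeds the
intensity threshold. Ties are negative — conservative for a diagnostic
count. The intensity threshold is mean + k·SD (k = 15 by default) of a
negative control, with mean and SD taken from a least-squares Gaussian
fit to the Freedman–Diaconis histogram of control intensities; the
histogram fit locks onto the dominant mode, so sparse bright
contamination barely moves it, unlike sample moments. If the fit fails
the code falls back to median and 1.4826·MAD with a logged warning. For
time-lapse series the thresholds come from the first frame of the same
series (no chamber has turned on yet, so the first frame is its own
negative control).

The ROG threshold default is 5.5 px for 16 × 16 crops — midway between
the uniform-crop value (6.52, where negatives and crop-filling artifacts
sit) and the chamber-disk band (3.5–4.2). It was never published
numerically, so it is fully configurable and a data-driven alternative
(low percentile of the negative control's ROG distribution) can be set by
the user. Manual exclusion of by-eye false positives is supported only as
an explicit roi_id list (logged, reported both raw and post-exclusion) —
never automatic — so analyses stay reproducible.

## Time-lapse metrics

With frames every 2 min, the *detection time* is the first time the
per-image positive count (expected ≤ 2 initially; a warning is raised
otherwise, and the result is still computed) strictly exceeds a trigger
of 10 — about 0.1% of a 10,000-chamber image. The *quantification time*
is the first time after detection at which the change in positive count
between consecutive frames falls below 20% of the previous frame's count
("change in signal" is read as the change in positive-chamber count, the
quantity the time-lapse curves plot, not raw fluorescence). Pairs with a
zero previous count are skipped to avoid dividing by zero. Both metrics
are invariant to frames appended after settling. Replicate spread is
summarized as CV% = 100 · sample SD (n−1) / mean.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Geometry:** defaults above; chamber centers on an exact grid with a
  12-px image margin. Pitch 21.43 px ≫ 16-px crop, so neighboring disks
  never clip a chamber's own crop.
* **Loading:** per-chamber Poisson(lambda) template counts; a chamber is
  positive iff it holds ≥ 1 template *and* an independent Bernoulli
  amplification-success draw passes. Default efficiency is 1 (ideal
  amplification); the knob exists because real per-target efficiencies
  deviate by up to an order of magnitude.
* **Kinetics:** positive-chamber disk amplitude
  baseline + (plateau − baseline)·sigmoid((t − onset)/tau), onset ~
  Normal(10, 3) min truncated at 0, tau = 2 min, plateau 600 a.u. over a
  background of 100 a.u. These are simulator knobs chosen so detection
  happens well before saturation in a 30-min series, not measured
  reaction constants. The sigmoid has a nonzero pre-onset tail, so a
  "t = 0" frame is only *approximately* blank (< 8% of plateau when all
  onsets are ≥ 5 min away).
* **Optics/noise:** disks rendered with a 1-px Gaussian-softened edge
  (erfc profile) standing in for the PSF; Poisson shot noise on the
  noise-free intensity, additive Gaussian read noise (sd 2 a.u.),
  clipped at 0; 16-bit output. The real camera's bit depth and
  per-chamber SNR are unpublished, so these defaults are plausible
  rather than calibrated — passing tests demonstrate correctness of the
  analysis under the assumed noise structure, not performance on any
  particular instrument.
* **Artifacts:** diffuse Gaussian blobs (diameter 20–60 px, i.e. always
  larger than a chamber; peak 50–200 a.u.; Poisson-distributed count) in
  both channels, emulating autofluorescent bubbles/aggregates. The
  artifact field is drawn from a seed-only sub-stream, so a time series
  shares one static field while camera noise is redrawn per frame.
  Chambers under an artifact are flagged in the truth table.

Not emulated: spatially varying illumination, chip warp, focus drift,
chamber-to-chamber volume variation, temperature-dependent enzyme
kinetics, and real amplification-failure correlations.

## Numerical and design choices

* All randomness derives from one integer seed via named sub-streams
  (loading / onset / artifacts / per-frame noise); identical seeds give
  bit-identical truth tables and images.
* Strict `>` comparisons at both classification thresholds; undefined
  ROG (all-zero crop) → negative.
* Gaussian threshold fit needs ≥ 100 control values; a zero-spread
  control is an error rather than a silent zero threshold. Because of
  this, end-to-end runs that fit thresholds use the default mild camera
  noise; exact truth-recovery on strictly noise-free renders is exercised
  with explicitly supplied thresholds.
* Positive fractions use the post-exclusion denominator
  (n_total − n_excluded).
* Concentrations are kept at full precision in JSON summaries; display
  rounding is left to callers.

## Problem sizes used in the shipped checks

Unit and property tests run on 400-chamber (20 × 20) chips, which keeps
every geometric ratio of the default chip (pitch/diameter, crop/pitch)
intact; the occupancy-law check draws 10^5 chambers (loading only, no
rendering); the end-to-end recovery checks use the full default
10,000-chamber chip, single-seed in the test suite and averaged over 10
seeds in `scripts/acceptance.py`. Artifact-robustness runs 20 seeded
negative-control chips with ~3 artifacts each.

## Known limitations

* Detection assumes approximately uniform chamber brightness in the
  reference channel; strong vignetting would need field-flattening,
  which is out of scope.
* The peak threshold (30% of the maximum band-pass response) presumes
  at least one genuine chamber dominates the band-passed image; an image
  containing only artifacts could yield spurious ROIs.
* The linear estimator saturates information near f → 1; both estimators
  are reported, but no confidence intervals are attached.
* Grid-model refinement (recovering missed chambers from the lattice) is
  not implemented; recall relies on the band-pass detector alone.
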