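# Methods

## Measurement model

An XZ confocal scan of an air–liquid-interface airway culture is reduced to
axial line profiles (mean over a small window of lateral columns). In the
reflection channel, light reflected at refractive-index steps produces three
peaks along depth z: medium→transwell (z₁), transwell→cell (z₂) and ASL→air
(z₃). ASL height is

h_ASL = (z₃ − z₂) − h_cell,

with h_cell the half-maximum width of the calcein-AM band that stains the
cell layer. The dye-based method measures h_ASL directly as the half-maximum
width of the rhodamine-dextran band. The transwell→cell peak and the lower
calcein edge mark the same physical surface, so their offset (z₂ − a) is
carried along as a QC metric on every measurement.

Peak positions are refined by least-squares fits of a Gaussian plus constant
baseline inside a ±2 µm window around each prominence-thresholded candidate
(threshold 0.1 × profile maximum); fit windows are intensity-normalised so
results are exactly invariant to global intensity scaling. Half-maximum
boundaries are linear interpolations of the first crossing of half the
plateau level on either side of the band maximum.

### Plateau reference for half-maximum edges

The baseline is the 5th percentile of the profile; the band is the contiguous
region above baseline + 10 % of the peak excursion containing the global
maximum. The plateau reference is the **median of band samples ≥ 0.8 × the
band's 95th percentile**. Two alternatives were considered and rejected:

- the raw band maximum is an extreme order statistic, biased high by detector
  noise and by the bright rim sometimes seen at the air interface;
- the median of the top decile of band samples is likewise an upper order
  statistic, biased high by ≈1.8 × the (column-averaged) noise sd. That bias
  shifts both half-max edges inward, which biases the fluorescence height low
  and — through the cell-layer subtraction — the reflection height high by the
  same amount, i.e. a systematic method disagreement that is purely an
  artefact of the estimator.

The core-plateau median is unbiased under symmetric noise (the median of
near-plateau samples) and robust to a narrow bright rim. Its one caveat:
for a pointed, plateau-free band (e.g. a triangular profile) it reads a few
percent below the apex, widening the bounds slightly; the layered bands this
pipeline measures are plateaus after PSF blur, for which the estimator is
exact — a step blurred by a symmetric PSF crosses half its plateau exactly at
the original edge.

### QC policy

Positions are flagged rather than silently dropped: `insufficient_peaks`
(< 3 reflection candidates), `fit_failure`, `fit_quality` (any interface fit
with r² < 0.9), `boundary_failure` (no half-max crossing). Flagged positions
are excluded from well summaries and logged. A negative computed height
(noise at near-zero ASL) is clamped to 0 and flagged `negative_clamped` but
**kept** in the well mean — excluding it would bias low-ASL wells upward.

## Phantom forward model

The simulator renders what the microscope would record for a known geometry:

- **Reflection:** impulse lines at z₁, z₂, z₃ with amplitudes given by the
  normal-incidence Fresnel law R = ((n₁−n₂)/(n₁+n₂))², evaluated
  analytically as Gaussians after axial PSF blur. Default indices: medium
  1.33, transwell 1.58, cell 1.37, ASL 1.34, air 1.00 — giving the observed
  amplitude ordering peak 3 > peak 1 > peak 2 (0.0211 > 0.0074 > 0.0051).
  The FEP support film is index-matched to water and contributes no
  interface. Oblique-incidence and polarisation effects are ignored; only
  the amplitude *ordering* matters to the pipeline.
- **Fluorescence:** unit plateaus over [z₂, z₂+h_cell] (calcein) and
  [z₂+h_cell, z₃] (rhodamine), blurred with the same PSF (analytic erf).
- **PSF:** axial Gaussian, σ = 0.7 µm by default (≈1.6 µm FWHM, the axial
  resolution of an NA 0.75 water-immersion objective at 488 nm).
- **Noise:** additive Gaussian, sd = 5 % of the channel's brightest
  amplitude by default, clipped at zero intensity. One noise knob keeps the
  recovery tests interpretable; Poisson shot noise is not modelled.
- **Geometry defaults:** 0.2 µm z sampling over 320 planes × 64 columns,
  transwell top at 15 µm (10 µm thick), 15 µm cell layer. Lateral `tilt`
  (default 0, 1 µm in the validation conditions) drifts all interfaces
  linearly across the field; each of the `n_positions` (default 15) scans of
  a well additionally receives an i.i.d. Gaussian whole-profile depth offset
  (sd 0.5 µm), emulating well-bottom unevenness between stage positions.
- **Volume challenge:** after apical volume addition the true height relaxes
  as h(t) = h_∞ + (h₀ − h_∞)·e^(−t/τ). The single exponential is a
  simulation convention — measured absorption curves are not claimed to
  follow it — chosen as the simplest monotone relaxation with one time
  constant.

Coordinates: z increases from the transwell toward air, depth 0 at the first
stack plane; pixel indices are 0-based internally and all reported depths are
in µm.

### What the phantom does not emulate

No lateral PSF or speckle, no mucus vs periciliary-layer substructure, no
meniscus curvature, no photobleaching or drift between time points, no
vendor metadata. Passing recovery tests therefore demonstrates correctness of
the *analysis* given the stated optical model, not robustness to every
artefact of real acquisitions.

## Aggregation and statistics

Wells are sampled on a serpentine rows × cols grid (default 3 × 5 = 15)
confined to the central 60 % of the field; the exact grid geometry and
central fraction are conventions, configurable. Summaries report mean, SD,
SEM and CV = 100·SD/mean over unflagged positions (≥ 2 required). Subsampling
stability draws seeded without-replacement subsets (default 200 replicates)
per size and reports mean-of-means, mean SD and mean CV.

Two-group comparisons use Student's t (paired/unpaired, two-tailed) or the
Wilcoxon signed-rank test via scipy; degenerate no-effect inputs (identical
groups, all-zero paired differences) report statistic 0, p = 1 rather than
NaN. FDR adjustment uses the two-stage linear step-up procedure
(statsmodels `fdr_tsbky`, α = 0.05 by default); a single p-value is returned
unchanged. Monte-Carlo power at published group parameters treats the
reported ± spreads as between-well SDs of normal well-mean distributions.
Mixed-effects/Tukey analyses of repeated-measures designs are deliberately
out of scope (standard off-the-shelf procedures; export the tidy CSV).

## Validation conditions and problem sizes

The validation suite uses 15-position wells at default noise, 1 µm tilt and
0.2 µm z sampling; method equivalence pairs the two readouts on 10 phantoms
spanning 4–16 µm; group-separation power uses 500 simulated two-group
experiments; subsampling stability uses a 20-position well with 200
replicates per size. These sizes give Monte-Carlo error comfortably below
the tolerances being checked while the whole suite runs in seconds on one
CPU.

## Known limitations

- The half-maximum convention measures optical path, not geometric height;
  refractive-index dispersion inside the layers is not corrected.
- Sub-resolution ASL (≲ the PSF width) merges peaks 2 and 3 and will be
  flagged rather than measured.
- The exponential relaxation and the phantom's default optics are
  conventions, not fitted to instrument data; absolute phantom intensities
  are arbitrary (the pipeline is scale-invariant by construction).
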