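# Methods

## Reconstruction model

A quadrant darkfield acquisition is four darkfield images of one field of
view, each illuminated from one quadrant of an LED annulus sitting outside
the objective NA (default annulus 1.05–1.33× NA, raster convention: row 0 at
the top, column 0 at the left). All processing is pixel-wise on
floating-point copies of the integer camera counts:

- darkfield `DF = TL + TR + BL + BR`;
- edge image `E = |TL − BR| + |BL − TR|`;
- quadrant darkfield `QDF = c·DF − E`.

The physical premise is that structures much larger than the wavelength
(cell boundaries, bead rims) refract light directionally, so each edge
element is seen almost exclusively under the illumination quadrant opposite
its outward normal; diagonal differences therefore isolate edges.
Wavelength-scale puncta scatter into a broad Mie cone, contribute nearly
equally to all four images, and cancel in `E`.

`QDF` is kept **signed** internally: where noise or imperfect calibration
makes `E > c·DF` the negative values are preserved for diagnostics, and are
clipped to zero only when computing per-cell totals and display images.
Negative excursions carry no puncta information, and summing them would bias
per-cell totals downward.

### Scaling factor c

`c` matches darkfield edge brightness to `E` before subtraction. The
published description of the method calls it system-specific and
experimentally determined without fixing a pixel set or estimator, so this
package defines it as the least-squares minimiser of `Σ(c·DF − E)²` over a
set of edge pixels, i.e. `c = Σ(DF·E)/Σ(DF²)`, reported together with the
residual edge-energy fraction. The default pixel set is everything above the
95th percentile of `E` (restricted to segmented objects when a segmentation
exists); a user-supplied mask overrides it. A numeric `c` in the optical
configuration bypasses calibration; the value `"auto"` triggers it on the
first frame of each position and reuses the result across that position —
one instrument, one factor.

## Phantom forward model

The simulator exists to make every downstream stage testable with
pixel-exact ground truth. It is deliberately a one-parameter caricature of
the scattering physics, not a wave-optics model:

- **Boundaries** (circles or straight segments) deposit light along a
  Gaussian-profile rim (default width 1.5 px). A per-object anisotropy
  `g ∈ [0, 1]` interpolates linearly between isotropic (equal quarters to all
  four images) and fully directional (all light into the image diagonally
  opposite the local outward normal). Mie theory enters only qualitatively —
  as the statement that puncta are broad scatterers (`g = 0`) and edges
  narrow ones (`g = 1`); no phase function is computed.
- **Edge leak** models the residual diffraction seen on the far side of real
  objects: a fraction `ℓ` of the directional deposit lands in the diagonally
  opposite image. On a pure edge this makes `E = (1 − 2ℓ)·DF`, so the
  effective scaling factor is `c = 1 − 2ℓ`; the population default `ℓ = 0.05`
  puts calibrated `c` near 0.9, inside the plausible 0.8–1.0 instrument
  range. The magnitude of this leak is not specified by any measurement and
  is exposed as a parameter.
- **Puncta** are Gaussian spots whose kernel is normalised over the canvas,
  so the stated amplitude is deposited exactly regardless of truncation.
  Light is conserved identically: `g` and `ℓ` redistribute a deposit over
  the four images, never change its total.
- **Noise** is additive Gaussian read noise followed by clipping to the
  camera range and integer quantisation (12-bit default). Poisson shot
  noise, fixed-pattern noise and out-of-focus light are deliberately out of
  scope; the noise model is the simplest one consistent with a CMOS camera
  at high gain.
- **Phase images** are rendered as one smooth blob per cell whose integrated
  phase is exact by construction, plus small bumps per punctum. Peak phase
  rises and support shrinks as a cell rounds, with the integral conserved.

What passing tests on these phantoms shows: the arithmetic, calibration,
segmentation and statistics behave as designed under the stated model. What
they do not show: performance on real acquisitions with coherent diffraction
ringing, focus drift, overlapping cells, or strongly non-Gaussian noise —
the published instrument numbers (per-cell SNR near 30, population p-values)
come from live-cell data and are not reproduced here, only their qualitative
structure.

### Study-condition defaults

- Bead phantom: radius 20 px (a 20 µm polystyrene bead at 0.5 µm/px),
  fully directional rim; the "imperfect bead" variant adds one isotropic
  internal punctum.
- Shape-change series: one cell interpolated over shape parameter
  `s ∈ [0.1, 0.9]`; radius shrinks by up to 45%, rim brightness grows by
  `1 + 2s` (rounded edges lens more strongly), puncta positions contract
  with the radius and amplitudes stay fixed, so summed puncta content is
  conserved exactly. Five frames.
- Populations: lognormal cell radii (median 20 px, σ_log 0.15), broadly
  lognormal rim brightness (σ_log 0.7 — darkfield's strong shape/edge
  variability), Poisson puncta counts with mean `density × πR²` (defaults
  0.01 and 0.03 puncta/px², a 3× contrast), lognormal punctum brightness
  (median 250 counts, σ_log 0.35). 200 cells per population in the
  simulation studies.
- Baseline-comparison cells: punctum peak brightness matched to rim peak
  brightness and some puncta placed near the rim — the regime where a single
  gradient threshold cannot separate the two, which is the failure mode the
  digital-baseline comparison probes.

## Image conditioning

Order of operations: bit rescale → empty-reference subtraction →
segmentation-derived object masking → polynomial background removal →
reconstruction. Each step is toggleable.

- Bit rescaling divides by a power-of-two (default 16, 16→12 bits) and
  rounds half-away-from-zero — the common camera-pipeline convention; the
  choice among nearest-integer tie rules is otherwise arbitrary.
- Reference subtraction is signed; clipping here would bias the polynomial
  fit.
- The background surface is a bivariate polynomial of total degree ≤ 8 (45
  coefficients) over coordinates normalised to [−1, 1]² for conditioning,
  solved by `lstsq` on non-object pixels only, uniformly subsampled (seeded)
  above 10⁵ pixels since the fit is heavily over-determined. Whether the
  removal applies to the four quadrant images, to `E`, or both is ambiguous
  in the published description; both switches exist and the default in
  `analyze_scene` removes it from the quadrant images only (it then cancels
  identically in `E`'s differences).

## Cells

- Watershed segmentation of the smoothed phase landscape (σ = 2 px),
  foreground at phase > 0.2 rad, seeds at local maxima ≥ 10 px apart,
  objects < 64 px discarded; all four numbers are configuration, chosen as
  sensible values for ~40 px cells at 0.5 µm/px, since the source method
  states only "watershed".
- Tracking is minimum-total-squared-displacement linking per frame pair
  (Hungarian algorithm on an augmented cost matrix, gate 20 px, 1-frame gap
  memory) — the Crocker–Grier linking strategy implemented directly.
- Dry mass uses the standard QPI relation `m = Σφ·(λ/2π)·A_px/α` with
  α = 1.8×10⁻⁴ m³/kg, reported in picograms.
- Puncta SNR: threshold at 4× the 99th percentile of background QDF;
  background = outside labels dilated by 3 px, excluding a 5 px border
  (dilation and border handling are this package's concretisation of
  "outside masked cells"); per-cell signal is the mean QDF over
  above-threshold pixels inside the label, divided by the background
  standard deviation. A zero-variance background raises an error rather than
  returning an infinite SNR.
- Debris filtering only flags records (area bounds, minimum track length,
  minimum mean phase/DF/QDF); nothing is deleted, so a QC pass can inspect
  the flags. There is no algorithmic stand-in for manual inspection of
  segmentation quality.

## Statistics

- `fit_vs_flat`: OLS with `F = (SS_flat − SS_fit)/(SS_fit/(n−2))` against
  the constant-y null on F(1, n−2). The null is read as a **horizontal**
  line; the phrase "flat line parallel to the y-axis" taken literally would
  describe a vertical line, for which no regression F-test exists, so the
  conventional zero-slope null is adopted and the discrepancy noted here.
- `binned_fit`: half-open bins `[k·w, (k+1)·w)`, per-bin mean and
  population (ddof = 0) standard deviation so a single-point bin reports 0.
- `kl_divergence`: shared bins (default 32) over the pooled 1st–99th
  percentile range, add-one (Laplace) smoothing of counts before
  normalisation so empty bins never produce infinities, base-2 logarithm
  (bits) by default with the base recorded in the result. Exact numeric
  parity with any particular library's binning is not a goal.
- `two_sample_t`: pooled variance by default, Welch by flag. Degenerate
  zero-variance inputs return (0, 1) for equal means and (±inf, 0) with a
  warning otherwise.

## Numerical and design notes

- All reconstruction arithmetic is float64; outputs are written as 32-bit
  float TIFFs. Integer inputs up to 16 bits cannot overflow the sum of four
  images in float.
- Quadrant-opposition convention: a normal pointing toward quadrant Q
  deposits into the image illuminated from the diagonally opposite quadrant;
  zero normal components tie-break toward top/left. The reconstruction
  equations are invariant to any relabeling that preserves the diagonal
  pairs (TL, BR) and (TR, BL).
- Baseline thresholds are fractions of the 99th percentile of the gradient
  magnitude so one grid transfers across images of different brightness;
  detected pixels are zeroed in the darkfield before scoring, the natural
  counterpart of QDF's subtraction.
- Simulation sizes in the test and acceptance runs (5-frame sequences,
  200-cell populations, 96–256 px canvases) were chosen as the smallest
  scales at which the population statistics are stable; all are parameters.

## Known limitations

- The forward model has no coherence, no point-spread function, no
  out-of-focus light; `c` calibration on real data may need a hand-drawn
  edge mask.
- Segmentation assumes one phase blob per cell; heavily overlapping cells
  will merge and must be caught by the debris/QC flags.
- Tracking has no division/lineage handling; a dividing cell starts a new
  track.
- KL divergence depends on the binning; only comparisons made with identical
  binning (as in the population analysis) are meaningful.
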