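# Methods

## Model

A subtracted angiographic run is a stack I(x, y, t) of T frames with
strictly increasing midpoint times. Iodinated contrast darkens the
subtracted image (DARK_CONTRAST; exported stacks may be inverted, hence
the polarity switch), so the per-pixel contrast proxy is

    C(t) = max(0, b − I(t)),    b = mean of the first n_baseline frames.

The per-pixel standard deviation of the raw intensity over the baseline
window is retained as the pixel's noise scale.

All curve metrics are evaluated inside one global signal-integration
window found on the spatial-mean curve g(t): the window opens at the
first frame where g exceeds `enh_frac` (default 0.05) of its maximum and
closes at the first post-peak frame from which every remaining per-frame
change stays below `arrest_frac` (default 0.01) of the maximum, else at
the last frame. A single global window (rather than per-pixel windows)
keeps the integrals of all pixels and of the AIF commensurable.

Bolus-tracking metrics per pixel:

* **AT** — crossing of `at_frac` (default 0.05) × peak on the rising edge
  attached to the global peak, linearly interpolated between the
  bracketing samples. For a clean single-pass curve this is exactly the
  first threshold crossing; anchoring the search to the peak prevents the
  estimate from latching onto pre-arrival baseline noise, whose clamped
  magnitude is commensurate with 5% of a typical peak at realistic DSA
  noise levels.
* **TTP** — time of the maximum sample, earliest on ties. No sub-sample
  refinement: the plateau tie-break would become ill-defined, and TTP
  enters the analysis only through pre/post differences where the
  quantization bias cancels.
* **TTD** — last downward crossing of `ttd_frac` (default 0.05) × peak
  after the peak. A curve still above threshold at the window end gets
  TTD = window end and a `truncated` flag.
* **MTT** — full width at half maximum: first upward minus last downward
  crossing of peak/2 (both interpolated). This is the curve-geometric
  MTT, *not* the deconvolution MTT of CT/MR perfusion. For multi-peak
  curves the FWHM spans all lobes above half maximum — a documented
  limitation, acceptable because half-maximum is far above the noise
  floor.
* **CBV** — trapezoid integral of the pixel curve over the window divided
  by the same integral of the AIF; **CBF** = CBV/MTT.

Sub-sample interpolation matters: DSA frame intervals (0.25–1 s) are
coarse against clinically relevant effects of a few tenths of a second.
Linear interpolation was chosen over higher-order schemes because it is
monotone (no overshoot at step-like edges) and makes the analytic
fixtures (triangle FWHM = 4 s, boxcar FWHM = 5 s) exact.

A pixel is **valid** when its peak exceeds `noise_floor_k` (default 3) ×
its baseline SD and its FWHM is positive; invalid pixels are NaN in every
map — never 0, so an invalid pixel cannot masquerade as instant arrival.

The AIF is the mean of bilinearly interpolated contrast along a manually
placed line spanning the injected vessel (sampled at ≥ pixel density;
endpoint-order invariant). Manual placement is deliberate — accuracy over
automation.

## Pre/post comparison

For each vascular-territory ROI the valid in-ROI pixels of each metric
form a distribution summarized by mean, median, SD (sample, n−1), skew
and excess kurtosis (adjusted Fisher–Pearson; conventions recorded in the
output metadata). The treatment effect per metric is the post−pre
difference of means, tested with Welch's unequal-variance t-test and
reported with a Welch-SE 95% CI. Welch-unpaired is the defensible default
because pre and post pixel sets are not registered to each other; a
paired per-pixel mode exists for registered phantoms. Pixel samples
within an ROI are spatially autocorrelated, so pixel-level p-values are
anticonservative; a block-subsampling effective-sample-size option
(`subsample_step`) is available and off by default. Across-case
aggregation uses the t-based 95% CI of per-case mean deltas (undefined,
with a warning, for a single case).

## Quality control

Mirroring the exclusion rules of clinical pre/post studies, `validate_pair`
checks: same projection view; same frame shape and (when present) pixel
spacing within 1% (magnification proxy); rigid-motion score — the median
per-frame translation between consecutive *baseline* frames, estimated by
cross-correlation (mean-subtracted, Hann-windowed, no spectral whitening:
subtraction residue is low-frequency and whitening destroys its
correlation peak) at 10× subpixel upsampling — below `motion_px` (default
2 px; "significant motion" is not quantified in the clinical literature,
so the threshold is configurable); and a full-transit check requiring the
mean contrast curve to fall back below `washout_frac` (default 0.5) of
its peak before the run ends. Baseline frames are used for the motion
estimate because contrast arrival itself changes intensity and would
confound whole-sequence registration. Frame-count mismatch is *not* an
error; the runs are analysed on their own time axes. Motion is excluded,
not corrected, matching clinical practice for these studies.

## Rendering

Pre and post maps of a metric share robust percentile bounds (default
2–98% of the pooled valid pixels; subtraction outliers would crush a
min/max scale). Timing metrics map low→red, flow metrics high→red, so red
always means increased perfusion; invalid pixels are black. The
256-entry red→yellow→blue→black LUT ships as CSV (`dsaperf/data/`); its
entries remain distinct after 8-bit quantization, so rendered images
invert to normalized values within 1/255.

## Digital flow phantom

The generator emulates a subtracted angiographic acquisition: polygonal
"territories" whose pixels share a peak-normalized gamma-variate transit

    C(t) = A ((t−t0)/(αβ))^α exp(α − (t−t0)/β),  t > t0,

(peak A at t0 + αβ — the canonical single-pass indicator-dilution shape),
a thick-line "vessel" carrying a taller, earlier bolus for AIF placement,
a baseline of 100 intensity units, additive Gaussian noise (default SD 2),
optional rigid per-frame drift, and a static smooth background texture
(default amplitude 3, Gaussian field σ=2 px) standing in for the
bone/soft-tissue residue of real subtraction — the structure the motion
QC registers on. Default geometry: 128×128 px, 40 frames at dt = 0.25 s,
a desk-scale configuration that generates and analyses in about a second.

Ground truth per territory holds the analytic TTP and AT/TTD/MTT/CBV/CBF
computed by a deliberately simple dense-grid (dt = 10⁻⁴ s) index scan of
the analytic curves — independent of the production implementation, so it
serves as the oracle in the equivalence tests.

The canonical pre/post pair programs a clinically scaled effect into the
"MCA" territory: the FWHM of the gamma variate is linear in β at fixed α,
so β is solved for ΔMTT = −1.1 s exactly and t0 for ΔTTP = −1.2 s
exactly, implying ΔAT ≈ −0.61 s; the "ACA" territory is an untreated
control. These magnitudes sit at the scale of reported pre/post
verapamil changes in vasospasm territories, which is what makes the
recovery test informative.

What the phantom does **not** emulate: anatomically realistic vascular
trees, X-ray physics (scatter, beam hardening), recirculation and venous
overlap, spatially varying noise, or deformable patient motion. Passing
recovery tests therefore demonstrates correctness of the estimator chain
under idealized single-pass kinetics, not clinical accuracy on real
angiograms.

## Numerical choices and edge cases

* Crossing searches are fully vectorized over (T, H·W); a 1024×1024×40
  stack maps in a few seconds on one core.
* Ties at the peak break to the earliest sample; a curve already above
  threshold at the window start gets AT = window start.
* Degenerate inputs raise: all-zero stacks ("no enhancement"), zero AIF
  integral ("AIF line sees no contrast"), empty ROI rasterizations,
  zero-area polygon rings.
* Known discretisation bounds at dt = 0.25 s (measured against the dense
  oracle): TTD/MTT ≤ 0.02 s; AT up to one frame interval (the bolus foot
  is non-smooth for α near 1); TTP up to one frame interval (maximum
  sample of an asymmetric peak); CBV up to a few ×10⁻³ relative
  (trapezoid across the onset kink). These are properties of the sampling,
  not the implementation — the CBV convergence test verifies ~10⁻⁴
  agreement at dt = 0.02 s.
* Pixel coordinates are 0-based (row, col); polygon rasterization is
  even-odd with center-inclusive boundaries.
* Kurtosis is reported as excess kurtosis (normal = 0) and skew/kurtosis
  are defined as 0 for zero-variance distributions; all conventions are
  written into the table metadata.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use the default 128×128×40
phantom (≈3.7k pixels per territory), 100 random gamma-variate curves for
oracle comparison, and 200 replicates × 10⁴ samples for the Welch-null
uniformity check — sizes chosen so the whole suite runs in well under a
minute while keeping Monte-Carlo error far below the asserted tolerances.
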