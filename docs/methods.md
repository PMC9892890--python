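# Methods

This note records the model, the numerical choices, and the reasoning
behind the places where the design was genuinely open.  Nothing here
states an empirical result that the test suite or the acceptance script
does not itself compute.

## Optical forward model

A cell at height z above the channel floor is a thin object with
transmission t = 1 − a·m·tex, where m is an antialiased disk membership
map (half-pixel edge ramp), a the amplitude contrast, and tex a
per-cell granular modulation (Gaussian noise smoothed to σ = 0.8 px,
scaled by `texture_strength` = 0.6, clipped to [0, 2]).  An optional
uniform phase term is available but off by default.  The perturbation
t − 1 is propagated to the hologram plane by the angular-spectrum
operator over d = recording distance + z; perturbations of all cells in
a frame superpose in the field before squaring (single scattering — the
linearity that reconstruction assumes, appropriate for sparse cells).
The recorded frame is illumination × |1 + Σ P(t−1)|² + Gaussian sensor
noise (σ = 1% of the mean level by default), with a smooth Gaussian
vignette standing in for real beam profiles.

Two simulator choices deserve emphasis because they are *physically
required*, not cosmetic:

- **Internal texture.**  A featureless disk of diameter D scatters only
  into angles ~λ/D, giving an axial depth of field ~D²/λ (≈ 700 µm for
  an 18 µm cell) — such an object cannot be axially localized to 5 µm
  by any estimator.  Real cells refocus well because organelle-scale
  structure scatters to high angles; the simulator must include it for
  the localization problem to be well-posed.
- **Weak contrast.**  Amplitude contrasts default to 0.4 (tumor) and
  0.25 (WBC).  Amplitude-only in-line reconstruction is linear in the
  object only for weak scatterers; at contrasts approaching 1 the
  quadratic term |s|² of the hologram intensity concentrates toward the
  hologram-side endpoint of the reconstruction range and measurably
  biases the autofocus.  The published sizes of MCF-7/SkOV3 cells and
  WBCs are kept (truncated normals 18 ± 2 µm and 10 ± 1.5 µm); optical
  contrasts of these cells are not established quantities, so they are
  configurable and the defaults sit deliberately in the weak-scattering
  regime.

Cell kinematics: arrivals are a Poisson process with rate
concentration × sample flow rate; each cell enters the field of view at
x = 0 with fixed (y, z) drawn uniformly from the sheath-confined core
(y) and from [z_margin, H − z_margin] (z, default margin 50 µm,
reflecting wall-lift depletion and keeping transit times finite), and
moves at the local speed of a product-of-parabolas duct profile
normalized so its cross-sectional integral equals the total volumetric
flow.  At the default geometry the center-line displacement per frame
exceeds the field of view (fast cells are seen once) while the slowest
near-interface cells persist for 2–3 consecutive frames — which is what
multiple-count removal must undo.  Motion blur during the 35 µs
exposure (≈ 15 µm at peak speed) is neglected.

## Reconstruction

The cleaned, flat-fielded contrast c = frame/background − 1 is treated
as the real-valued scattered amplitude at the hologram plane.  Whether
the raw difference or the flat-fielded ratio is the right input is an
open choice; the division variant is used because it makes the contrast
dimensionless and illumination-invariant, with a guard that clamps
background pixels below 1% of the median.  c is back-propagated with
the exact angular-spectrum transfer function (effective wavelength λ/n,
n = 1.33 aqueous medium; evanescent components zeroed) to 67 planes at
200–530 µm, endpoints included.  The DC term (unit reference) is kept
unpropagated, so each plane provides both the scattered intensity |g|²
and the image intensity |1 + g|².  No zero-padding is applied by
default: objects sit far from the FOV edges in the sheath core, and the
FFT wrap-around is below the detection threshold.  Phase retrieval and
twin-image suppression are deliberately out of scope — the twin is
carried along and the estimators are designed to tolerate it.

## Detection and plane of best focus

Detection thresholds the maximum-intensity projection of |g|² over
planes at median + 25·MAD.  The multiplier is set by extreme-value
statistics, not convention: the max over ~67 correlated noise planes
has a heavy tail reaching ~20 MAD on cell-free stacks, while focused
cells sit orders of magnitude higher.  The mask is dilated 3 px so
detached fringe fragments rejoin their parent blob, components are
filtered by pre-dilation area (9–50 000 px²), and candidates within
15 px collapse onto the strongest peak.  Touching cells are not
segmented.

The axial estimator addresses the twin-image bias directly.  Windowed
intensity statistics (the classical minimum-mean-intensity criterion,
Tamura, energy concentration) are biased by 5–200 µm for larger cells
because the cell's own defocus halo and the retained twin vary slowly
along z.  What does focus sharply is the high-spatial-frequency part of
the scattered field — the granularity band.  The estimator therefore:

1. high-passes the complex volume in a 36×36 window (subtracting a 4×4
   box mean per plane);
2. for each footprint radius r on a grid (3–16 px), forms the axial
   curve Σ_{disk r} |hp|² and takes its most prominent interior peak
   (prominence discriminates the focus peak from the endpoint ramp of
   the quadratic term), refined by a parabolic fit to ±1 plane;
3. reads the focus from the *plateau* of the estimate-vs-radius curve:
   at the correct footprint the estimate is stationary with respect to
   r, while too-small and too-large footprints drift monotonically.
   Runs of ≥3 consecutive radii agreeing within one plane spacing are
   candidate plateaus; the one closest to the measured cell radius
   (interpolated half-maximum crossing of the projection's radial
   profile), preferring longer runs, wins.  With no plateau the single
   curve at the measured radius + 3 px is used.

Ties along any axial curve break toward the smaller propagation
distance.  The 36×36 classifier crop is cut from |1+g|² at the selected
plane and min-max normalized to [0, 1] per crop, making the classifier
input illumination- and contrast-scale-invariant; sub-pixel centroids
are rounded to the pixel grid for cropping.  Detections whose window
would cross the FOV edge are dropped and logged.

## Multiple-count removal

A detection q in frame i+1 duplicates p in frame i when |y_q − y_p| ≤
3 µm and |z_q − z_p| ≤ 50 µm (laminar flow keeps y; the lenient z bound
matches the poorer axial coordinate).  The nearest predecessor in
(y, z) claims q; matches propagate transitively so 3-frame chains
collapse; each chain keeps its first-frame instance (the best-focus
instance would be the alternative; first-frame is simpler and the crops
are near-identical).  Only adjacent frames are compared by default
(configurable gap).  Streamwise x is deliberately unused.

## Classifier

s-Net: conv3×3(8)–BN–ReLU–pool2 → conv3×3(16)–BN–ReLU–pool2 →
conv3×3(32)–BN–ReLU → flatten(9·9·32 = 2592) → FC(2) → softmax.  The
middle filter count is fixed at 16: geometric doubling 8→16→32 is the
only choice consistent with both the 2592-node flatten and the ~11k
learnable budget (exact counts: 11 186 with batch-norm scale/offset,
11 074 without).  Training: softmax cross-entropy, Adam (lr 10⁻³, β =
0.9/0.999, ε = 10⁻⁸), minibatch 32, 20 epochs, He-uniform
initialization, per-class stratified 70/30 split; batch-norm running
statistics (momentum 0.1) are frozen at inference.  The implementation
is pure numpy (im2col convolutions) and is bit-deterministic given the
seed, which the tests rely on.  Training aborts on a non-finite loss.

## Gating, enumeration, limit of detection

ROC analysis computes TPR/FPR over a decade-stepped threshold grid
{0.5, 0.9, 0.99, …, 1−10⁻⁷}; the operating threshold is the smallest
grid value attaining the minimum FPR (raising it further changes
nothing).  Enumeration counts deduplicated cells with P_tumor > α and
divides by the imaged volume.  Two volume accountings exist: the
canonical time-based volume (frames / frame rate × sample flow rate;
10 100 frames at 420 fps and 2.5 mL/min ≈ 1 mL) and the per-hologram
geometric volume (streamwise FOV × core width × depth ≈ 0.13 µL), which
is reported for reference.  The limit of detection over ≥2
negative-control trials is LoD = μ_NC + 2σ_NC with the sample (n−1)
standard deviation.

## Problem sizes in the test suite

The suite runs the full physics at a 256×256 (localization) or 192×192
(end-to-end) field of view with a matching narrow channel, 67
reconstruction planes as in the full geometry, and a classifier corpus
of 3 500 training + 1 500 test crops per class.  For the spiked-run
experiment the acquisition is 400 frames and *all* concentrations
(spike levels 0/10/100/1000 per mL and the 1000 per mL WBC background)
are scaled by a common factor of 400.  The scaling is forced by
sampling physics, not convenience of the assertion: one hologram
snapshots only the geometric volume ≈ 0.01 µL, and cells cross the FOV
between frames, so at the nominal concentrations minutes of synthetic
acquisition would contain no countable tumor cells at the lower spike
levels.  Scaling every concentration together preserves the
tumor-to-background ratios, the per-cell appearance statistics and the
false-positive arithmetic; only absolute volumes shrink.

## What passing tests do and do not show

The simulator produces weak-phaseless amplitude scatterers with ideal
Poisson kinetics, Gaussian noise, and a stable background.  Passing
tests therefore demonstrate that the *computational chain* is correct
and self-consistent (propagation is exactly invertible, localization
recovers known 3D positions, dedup undoes known multiplicities, the
classifier separates classes that differ in size/texture scale, gating
behaves monotonically).  They do not show that real MCF-7/SkOV3/WBC
images are separable at the accuracies reported on synthetic data, nor
that the absolute LoD of a physical instrument matches: real cells have
phase structure, size overlap between classes, debris, and non-Gaussian
camera noise that the generator does not emulate.

## Known limitations

- Amplitude-only cells; the optional phase term is untested physics
  (real cells are predominantly phase objects).
- No speckle/partial-coherence model, no wall fringes (the sheath
  device removes them physically), no motion blur by default.
- Touching cells are merged by design; counts at very high
  concentrations will under-report.
- The axial estimator assumes internally textured objects; smooth beads
  would localize poorly (physically unavoidable with amplitude-only
  in-line data).
- In the frame-undersampled regime the time-based volume accounting
  overestimates the effectively sampled volume, biasing absolute
  concentrations low; relative comparisons (spike ordering, LoD logic)
  are unaffected.
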