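# Methods

## Image model and conventions

All slices are reduced to a unitless grey scale in [0, 1] before any
processing. DICOM stored values are rescaled by the file's
slope/intercept, clipped to a window and mapped affinely onto [0, 1];
the default window is the slice's own min/max because every downstream
algorithm consumes only relative grey structure, and no fixed
Hounsfield window is assumed. An optional explicit `(low, high)` window
is available when calibrated behaviour is wanted. PNGs are divided by
their bit-depth maximum.

Pixels are addressed (row, col), 0-based, row 0 at the top; "the lower
part of the image" therefore means high row indices. A pixel is
*background* (air) iff its value is ≤ `background_tol` (default 0.02):
min–max mapping sends true air to exactly 0 only in the noise-free
ideal, so a tolerance is needed, and 0.02 equals one standard
deviation of the default phantom noise.

## The phantom

The generator renders the scene the pipeline must survive on a real
axial abdominal slice: air background, a lumpy elliptical body
cross-section, a thin skin band (2 px), a subcutaneous fat ring
(10 px), a brighter visceral interior scattered with visceral-fat
islands, a scanner-couch strip near the bottom rows, and additive
Gaussian noise clipped to [0, 1]. Ground-truth masks are the exact
noise-free label sets.

Intensity defaults — fat 0.35, skin 0.55, viscera 0.65, couch 0.80,
noise sd 0.02 — make fat a distinct mid-dark band, hypodense to soft
tissue as on CT. They are fixture conventions, not calibrated physics;
the fat/neighbour contrast is required to exceed 3× the noise sd, the
working assumption of the growth criterion.

Two generator choices deserve explanation:

* **Lumpy outlines and fat islands.** Perfectly elliptical,
  piecewise-constant scenes are pathological for interest-point
  detection: every boundary is either straight (edge-culled) or of
  very low curvature, and a whole phantom yields under ten keypoints.
  Real abdominal outlines are lumpy and the visceral compartment
  contains fat islands; both are rendered here, drawn from a
  `shape_seed` ("anatomy" seed) that is deliberately separate from
  `rng_seed` (the acquisition-noise seed). The same subject can thus
  be imaged repeatedly with fresh noise, and different subjects differ
  in geometry — which is exactly the structure the intra-/inter-group
  matching experiments need. Islands share the fat grey value, so the
  noise-free histogram still has exactly five values, and they are
  kept strictly clear of the subcutaneous ring so its ground truth is
  unaffected.
* **Couch narrower than the body.** The bed-board detector rests on
  the premise that rows crossing the subject carry more non-background
  pixels than rows crossing only the couch. A couch drawn across the
  full frame width would invert that premise and be undetectable by
  this method (and would not resemble a scanner couch either); the
  default couch spans 0.4× the frame width, centred.

What the phantom does **not** emulate: organ boundaries and texture
inside the viscera, Hounsfield calibration, beam-hardening/metal
artefacts, couch curvature, partial-volume effects, and anisotropic
pixel spacing. Passing tests therefore demonstrate algorithmic
correctness and robustness at realistic contrast and noise, not
clinical-grade accuracy on patient data.

Default frame size is 128×128 (body semi-axes 45×55 px). This is a
deliberate scale-down from typical 512×512 acquisitions: all
behaviour under test is resolution-covariant, and the small frame
keeps the full suite and the acceptance script fast.

## Bed-board removal

Non-background counts are profiled per row and per column. Rows inside
the bottom `search_band` (default 25%) of the frame whose count falls
below `profile_frac` (default 0.5) × the maximum row count are couch
candidates; every 4-connected non-background component touching a
candidate row is deleted, except the largest component (the subject).
The component rule is what makes the operation safe when couch and
body share row ranges, and makes it idempotent.

Detection profiles are computed on a 3×3 median-filtered copy of the
image (removal still zeroes raw pixels). Without this, isolated noise
specks inflate air-row counts by ~16% at the default noise level and
push couch rows above the cutoff. Median filtering leaves the
noise-free case bit-identical, so exact recovery there is preserved.

## Seeded region growing

Eight rays — from the four edge midpoints and four corners, all aimed
at the frame centre — walk inward in half-pixel steps. A ray declares
body entry at the first run of `entry_run` = 5 consecutive distinct
non-background pixels (a single-sample rule would fire on chance noise
specks in the air long before the body), then advances `step_units` =
3 px of arc length and records that pixel as a seed: past the 2 px
skin band, inside any ring ≥ 5 px thick. Rays that never meet tissue
contribute nothing; finding no seed at all raises an error so a caller
can fall back to a manual seed.

Automatic seeds are screened before growth. Background seeds (a ray
that overshot a thin ring) are dropped, and each remaining seed must
satisfy the similarity criterion against the *median* seed value. All
valid seeds sample the same tissue, so a discordant seed marks a
failed ray; because the seed set initialises the running mean, one bad
seed would otherwise poison the criterion and collapse growth.

Growth is breadth-first: FIFO frontier, neighbours tested in fixed
N, S, W, E order, 4-connectivity. A neighbour of value `v` joins iff
it is non-background and `min(v, m)/max(v, m) ≥ ratio_tol` (default
τ = 0.9) where `m` is the arithmetic mean of the accepted sequence,
updated after every acceptance. The min/max ratio makes the test
symmetric and scale-free. Because the running mean makes the result
order-dependent, the fixed orders pin full determinism. `mean_mode`
switches `m` to the frozen initial seed mean (the variant with clean
monotonicity in τ, used for oracle comparisons) or to the whole-image
foreground mean.

At the defaults, τ = 0.9 around a fat mean of 0.35 accepts the band
[0.315, 0.389] ≈ ±1.75 noise sd: a few percent of true fat pixels are
rejected as outliers (mean Dice ≈ 0.96 at noise 0.02, exactly 1.0
noise-free), while skin at 0.55 (ratio 0.64) and viscera at 0.65
(ratio 0.54) are excluded with a wide margin.

## Iterative Bayes threshold

With two classes of equal variance, the Bayes rule "assign to the class
of higher posterior" has its boundary at the midpoint of the class
means (count-based priors are computed and logged, but under the
equal-variance assumption they do not move the boundary). Iterating
`t ← (μ_below(t) + μ_above(t))/2` from `t₀ = (min+max)/2` is then the
classical iterative-mean (ISODATA) threshold. Background pixels are
excluded from the histogram so air cannot drag the lower class mean.

Convergence: `eps` = 1e-4 (intensity units), `max_iter` = 100. On
quantised data the threshold can only take finitely many effective
values, and each step moves it toward a fixpoint of a monotone map, so
termination is immediate in practice (a handful of iterations on 8-bit
data). Degenerate (constant) images raise an error. On any two-valued
image the fixpoint is exactly the midpoint of the two values.

Thresholding at the result splits the foreground into below/above
masks. As expected of a global threshold, the fat class comes out more
fragmented than the region-growing mask on noisy slices — connections
break where noise crosses the boundary — which is precisely why region
growing is the primary segmentation path.

## SIFT

The implementation follows the standard recipe with these pinned
constants: s = 3 intervals per octave (s+3 Gaussian, s+2 DoG layers),
σ₀ = 1.6, octaves = ⌊log₂ min(h,w)⌋ − 3 (top octave ≥ 8 px), border
5 px, contrast threshold T = 0.04 applied as `|D̂| < T/s`, edge ratio
r = 10, 36 orientation bins of 10°, orientation weighting sd 1.5σ with
sampling extent 3×1.5σ, at most one auxiliary orientation at a
secondary local peak ≥ 80% of the main one, 4×4 descriptor grid of
8-bin histograms with subregion width 3σ, Gaussian weight sd = half
the descriptor window, trilinear interpolation, clip at 0.2,
renormalise. The input is *not* upsampled before the first octave, so
keypoint counts should be compared with that convention in mind.
Angles are measured counter-clockwise from +x (columns) with y up the
image; blurs use kernels truncated at 6 sd so sequential blurs compose
like the continuous Gaussian semigroup to ~1e-9 away from borders
(border replication breaks the semigroup in a ~6σ margin, which the
tests exclude).

Refinement solves the 3-variable Newton step from central-difference
gradient/Hessian, re-anchoring to the neighbouring lattice point when
an offset component exceeds 0.5, up to 5 iterations; non-convergence,
singular Hessians, out-of-bounds moves, low contrast and edge-like
spatial curvature all reject the candidate.

## Matching and experiments

Descriptor matching is one-directional (A→B) with the ratio test
d₁/d₂ < 0.8 on Euclidean distance; exact ties are rejected. The
exhaustive scan is the reference path; a k-d tree path
(scikit-learn) must return identical pairs and is verified to. With a
single candidate in B the ratio is undefined and an absolute cutoff
(0.3, logged) substitutes. Reported counts are one-directional to
match the single "matches" reporting column; a mutual-best filter is
available separately. Wall time is recorded per pair but is
hardware-dependent and never asserted.

The two experiment drivers: part-to-whole registration (a crop matched
against its source slice, validated by mapping matches through the
known crop offset) and the group experiment (all within- and
between-group pairs, rows tagged intra/inter, mean rows appended).

## Numerical / degenerate-input policy

Constant images: zero DoG everywhere (no keypoints), degenerate-input
error from thresholding, no-seed error from segmentation. A degenerate
DICOM window maps to a constant 0 image rather than dividing by zero.
Empty masks give Dice 1.0 against empty and 0 otherwise. All
randomness flows through explicit integer seeds; every stage is
bit-reproducible for fixed inputs and configuration.

## Problem sizes used in tests and the acceptance script

Segmentation accuracy: 20 phantoms at noise 0.02 plus the noise-free
exact case. Bed removal: 20 random geometries (couch narrower than the
body, per the method's premise). Oracle comparisons: 50 random 32×32
images (region growing), 50/20 random 64×64 images (threshold
fixpoint). Matching: 5 crop-registration seeds and 10
intra-/inter-subject seeds. These sizes give stable statistics while
keeping the whole suite under a minute of compute.

## Known limitations

* Single-slice 2-D only; no volume handling, no visceral-fat
  segmentation.
* The subcutaneous mask is whatever the criterion grows from the
  surviving seeds; pathology that interrupts the ring (hernias, drains)
  would require the manual-seed fallback.
* SIFT keypoint counts on piecewise-constant phantoms are one to two
  orders of magnitude below those on textured clinical CT; match-count
  *ratios* (intra vs inter, part-to-whole localisation) are the
  meaningful quantities at phantom scale, not absolute counts.
* The equal-variance reading of the Bayes threshold is implemented;
  a variance-/prior-aware boundary would shift the threshold on
  strongly unbalanced histograms and is left as an extension.
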