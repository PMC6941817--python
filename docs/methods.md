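# Methods

This note records the models behind `wormmri`, the parameters that matter,
and the choices made where the design was genuinely open. Conventions:
world coordinates in micrometres (x, y, y down); images row-major with the
origin top-left; intensities in [0, 1]; the body coordinate *s* ∈ [0, 1]
runs from head to tail along the centerline arc length.

## 1. Synthetic recordings (`synthgen`)

The generator emulates bright-field Petri-dish recordings of a single
adult *C. elegans*: 1.2 mm body, forward speed 130 µm/s, 12 Hz for 10 s
(120 frames). These four values define the study conditions and are the
fixed defaults; everything below is a free parameter of the generator with
its default and rationale.

**Locomotion model.** The head anchor advances at `speed` along a heading
that drifts as a random walk (`heading_drift_std` = 0.02 rad/frame). The
body is a backward-travelling sine wave behind the head:

* `undulation_wavelength` = 720 µm (≈0.6 body lengths, typical crawl);
* `undulation_amplitude` = 100 µm lateral half-amplitude;
* `undulation_frequency` = 0.3 Hz. Since the track-following frequency is
  `speed/wavelength` ≈ 0.18 Hz, the default wave runs faster than the worm
  advances — substrate slip, as on a soft gel — so the
  "each segment follows its predecessor" assumption that the predictor
  exploits holds approximately, not exactly. Passing
  `undulation_frequency=None` selects the zero-slip limit. (In that limit
  the worm sits on its own trail for most of the video and a
  temporal-median background model degenerates, which is also why the
  slipping default is the representative condition.)

The curve is built at fine resolution, resampled uniformly in arc length,
and scaled so total arc length equals `body_length` exactly in every frame.

**Head casting.** Worm heads move much faster and more erratically than
the rest of the body while foraging. The generator adds an independent
per-frame random lateral deflection of the anterior quarter (full strength
over the first 10 % of arc length, smoothly blending to zero at s = 0.25),
with angle `head_jitter_std` = 0.25 rad/frame on a ~300 µm lever arm. This
makes the head demonstrably the most mobile and least predictable body
part, which is both the biological situation and the premise of
difference-image head detection. The undulation amplitude itself tapers to
zero over the same anterior quarter so the head anchor's net advance
equals the nominal speed.

**Body shape.** Half-width profile: blunt head cap (~65 % of full
thickness at the nose), constant 40 µm mid-body half-width, quadratic
taper to a fine whip over the posterior fifth; floored at 5 µm.

**Rendering.** The worm is a dark tube (intensity 0.25) with a soft
anti-aliased edge on a static bright background (0.75 with smooth
low-contrast texture), plus per-frame Gaussian sensor noise (σ = 0.02).
Default optics are 3 µm/pixel so the worm spans ~400 raw pixels; the field
of view is sized from the full ground-truth trajectory.

**Trajectory admissibility.** Poses in which distant body segments
approach within about one body width (a coiling/self-occluding posture)
have no single-centerline ground truth; such trajectories are rejected at
generation time and redrawn from a derived sub-seed, deterministically.
This mirrors selecting usable recordings of openly crawling worms.

**Phantom library.** Fifty 64×64 cross sections at ≈1.6 µm in-plane
resolution stand in for a serial-section micrograph stack. They are
produced as synthetic bright-background sources (white field, darker
tissue): a smooth 3-D random field (axial correlation ≈1 slab, so
neighbouring 24 µm slabs resemble each other as real anatomy does), a
darker rim emulating the cuticle, disc radius following the body width
profile, and ~1 µm partial-volume edge softness. `build_slice_phantoms`
then applies the documented pipeline — background removal, intensity
inversion (bright = dense, as proton density would appear), area-weighted
downsampling to 64×64 — and assigns slab k the centre coordinate
s = (k − 0.5)/50. Slab boundaries belong to the lower-index slab.

## 2. Detection and the centerline coordinate system (`detect`)

Per frame: 9×9 block-mean downsampling (edge blocks partial) →
temporal-median background over the whole video → segmentation by Otsu's
threshold on the *signed* difference `background − frame` (the worm is
darker than the field; the signed form prevents ghost components where the
background model absorbed a lingering worm), morphological closing,
largest connected component, hole filling, minimum area 15 px.

**Head.** Squared inter-frame differences (motion energy) accumulated
over the last 10 frames are summed in a radius-7 neighbourhood of each
skeleton endpoint; the endpoint with the larger score is the head. Scores
within 10 % are low-confidence and keep the previous head. Because a head
cannot migrate to the far end of the body within 83 ms, a decisive flip is
additionally accepted only at an overwhelming (>2×) margin; the initial
side is chosen from the direction of net centre-of-gravity travel over a
~2 s warm-up (worms crawl head-first), falling back to the
difference score if the worm barely moved.

**Skeleton.** Morphological thinning; the centerline is the longest
geodesic through the thinned pixel graph (equivalent to pruning all side
spurs; an error is raised if the longest path covers under half the
skeleton, i.e. the shape is irreducibly branched). The path is then
extended through the grey difference image beyond the binary mask (the
faint tapered tips fall below Otsu's threshold), smoothed, and refined
transversely to sub-pixel accuracy by intensity-weighted centroids along
local normals. s is cumulative arc length normalized by total length.
Frames whose skeleton length jumps >20 % from the recent median (nose
folded onto the body, mask merged) are replaced by the last consistent
skeleton.

**COG and velocity.** The centre of gravity of the foreground is smoothed
with a first-order low pass (α = 0.5). Velocity in s-units/frame: per-frame
smoothed-COG displacements over the last 5 frames are projected on the net
travel direction, combined by their median (robust to single-frame
glitches), signed by the head-ward chord, normalized by skeleton length,
and clamped at zero for backward motion.

On the default recordings this chain delivers: mask IoU ≈ 0.9 against the
rasterized ground-truth tube, skeleton length within ~2 % of the true
1200 µm, head assignment ≈99 % of frames, and speed recovery within a few
per cent averaged across videos (single videos scatter by up to ~±10 %).

## 3. Prediction (`predict`)

The COG is extrapolated linearly by a least-squares line over its last ≤5
positions (robust to pixel quantization; a two-point slope is the
degenerate n = 2 case). The POI predictor is the centerline-following
rule `s_c = s − v·Δk` evaluated on the *current* skeleton, clamped to the
head at 0 (and to the tail at 1 for completeness; that clamp is logged).
Prediction error reports compare, in micrometres, the position predicted
at frame k for k + Δk against the tracked POI position at k + Δk — the
same comparison a real system can make — and ground-truth poses serve as
an independent oracle in the tests.

## 4. Gradient-echo acquisition (`mrisim`)

One k-space line per TR; TR = 83 ms is locked to the 12 Hz frame interval
(one line per video frame), TE = 4 ms is bookkeeping only because motion
within a line is ignored (short-TE assumption). Encoding follows the
Fourier-sampling contract: every FoV voxel contributes
`intensity · exp(−i[φ_J·ξ-index + ω_m·η-index])` with the phase-encode
step φ_J = −π + J·2π/N (J = 1..N, N = 64 lines) along the in-plane axis ξ
and the readout frequency along η; a uniform-sensitivity coil sums all
voxels, so line J equals the centred-DFT row of spatial frequency J − N/2
(J = N aliasing to −N/2, identical on the integer grid). No relaxation,
no off-resonance, no RF noise. Reconstruction is the magnitude of the
centred inverse 2-D DFT; a static acquisition reproduces the phantom to
1e−6.

**Moving gradient centre.** Per line, G_C is (a) the predicted POI
position mapped to world coordinates (`prediction`), (b) the true slice
position at the first acquisition frame (`no_prediction`; the acquisition
window starts at frame Δk, so this is the slice position after Δk frames
of motion), (c) the ground-truth slice position every line (`oracle`), or
(d) static with the worm frozen. In prediction mode the per-line G_C
trajectory is additionally low-passed (EMA, gain 0.35) with its smoothed
per-line step fed forward to cancel the filter's lag behind the sliding
slice — the acquisition-side counterpart of the tracker's COG smoothing.

**Error model.** The G_C error relative to the true slice is decomposed
in the local body frame of the ground-truth pose: the along-body component
selects which 24 µm slab actually fills the FoV (outside the body: zeros),
the in-plane component shifts the cross-section along ξ with zero fill.
The in-plane conversion uses the optical-pixel↔voxel correspondence of
the study design: at a 1:1 MR:optical resolution ratio, one pixel of
(downsampled) tracking-video error is one voxel of k-space error; at 2:1
and 4:1 the same physical error costs two and four voxels. The η axis
(out of the video plane) carries no error; orientation mismatch between
the planned and true slice planes is neglected (planar motion).

## 5. Evaluation (`evalsim`)

Structural similarity with the canonical parameters (11×11 Gaussian
window, σ = 1.5, K1 = 0.01, K2 = 0.03); the dynamic range defaults to 1
for images inside the package's [0, 1] intensity convention (and to the
joint range otherwise), keeping the measure symmetric; negative means are
clipped to 0. The three simulation paradigms: body position (slices
s = 0.02/0.5/1.0, horizon 1), resolution (s = 0.72, ratios 1:1/2:1/4:1),
and horizon (s = 0.52, Δk = 1..10, plus the four-slice statistical grid
s ∈ {0.1, 0.3, 0.5, 0.9}). The imageability taxonomy compares the sample
motion time t_motion and prediction compute time t_pred against TR:
t_motion < TR → not imageable; TR < t_motion but t_pred ≥ TR → imageable
with contrast restrictions; t_pred < TR < t_motion → unrestricted.

On the default conditions (8 videos × 4 slices × horizons 1–10) the
predictive gradient yields a mean-similarity improvement factor of ~2.5
over the fixed gradient, with mid-body slices reaching SSIM ≈ 0.6–0.8 at
horizon 1 and quality decaying monotonically with horizon.

## 6. What the synthetic data do and do not show

The generator reproduces the geometry and kinematics that drive the
method — arc-length-true centerlines, realistic speed/undulation/head
casting, bright-field contrast, anatomy-like smooth phantom stacks — so
passing tests demonstrate that the tracking, prediction and
moving-gradient acquisition chain works end to end and exhibits the
expected orderings (oracle ≥ prediction ≥ fixed; head worst; quality
falls with horizon and resolution ratio). They do not certify
performance on real videos: real worms pause, reverse and coil (coiling
postures are excluded here), backgrounds drift, optics defocus, and real
tissue contrast is not the synthetic random field. Two evaluation
caveats are inherent to plain SSIM on mostly-empty references: an almost
empty reconstruction of an almost empty tail-tip slice scores *high*
(background windows agree), which is why the fixed-gradient score can
exceed the predictive one at the extreme tail (s ≳ 0.9) even though the
predictive image contains the actual anatomy; and absolute SSIM levels
depend on the phantom's axial smoothness.

## 7. Numerical choices and degenerate inputs

* Slab boundaries belong to the lower-index slab; s = 0 → slab 1.
* k-space line J = N/2 is the DC line; J = N holds the most negative
  spatial frequency.
* `resample_area` integrates the cumulative sum, giving exact
  area-weighted (partial-)block means for any size ratio.
* Degenerate waves (amplitude 0) give exactly straight centerlines;
  empty poses render the pure background; a motionless worm yields zero
  velocity and keeps its previous head assignment.
* All randomness flows from a single per-recording seed through
  `numpy.random.SeedSequence` substreams (motion, rendering, phantoms);
  identical seeds reproduce byte-identical datasets.

## 8. Problem sizes used in the shipped checks

The test suite exercises the full study conditions: eight 10 s recordings
(120 frames each) for the statistical claims, one 10 s recording for
detection-quality invariants, and 6 s recordings for unit-level checks;
acquisitions are complete 64-line k-spaces throughout.
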