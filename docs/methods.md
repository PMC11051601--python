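# Methods

`holotrack` implements a complete desk-scale model of real-time 3D
microbe tracking with inline digital holographic microscopy (DHM): a
synthetic-hologram generator with known ground truth, a classical
reconstruction/localization engine, the box-size↔depth heuristic with
its polynomial correction, a reference bounding-box detector, track
linking, and detection metrics. This note records the models, the
parameters that matter, the numerical choices, and what the validation
experiments do and do not show.

## Optical model

The imaging geometry (`OpticalConfig`) defaults to a 512×512 px frame
covering 360×360 μm (pixel pitch 0.703 μm/px), illumination at
λ = 642 nm through a medium of index n = 1.33, an NA 0.5 objective, and
a sample chamber 280 μm deep. All propagation uses the effective
wavelength λ/n and the angular-spectrum (Rayleigh–Sommerfeld) transfer
function

    H(f; dz) = exp(i·2π·dz·sqrt((n/λ)² − f²)),   f² < (n/λ)²,

with evanescent components zeroed. Cells are modelled as point-like
weak scatterers (Rayleigh–Gans regime): a discrete delta of amplitude
ε ≤ 0.2 on the object plane, propagated to the focal plane with the
same kernel the reconstructor uses, so every localization test is a
true round trip through one optical model. The camera intensity is
I = |1 + Σ ψ_j|², optionally multiplied by a static artifact pattern
and degraded by additive Gaussian sensor noise (Poisson statistics are
not modelled).

Rendering always applies the objective pupil (spatial frequencies above
NA/λ removed). The finite aperture is not cosmetic: it is what makes
the apparent extent of a defocused scattering pattern finite and —
because the outermost visible fringe sits where the local fringe
frequency meets the pupil cutoff — linear in depth, the physical basis
of the box-size heuristic. The measured extent slope of the default
geometry, 0.406 μm radius per μm depth, equals the geometric cone slope
NA/√(n²−NA²). Tests that need aperture-free fields pass
`numerical_aperture = medium_index`, which reduces the pupil to the
evanescent cutoff.

A caveat of the default geometry: the NA 0.5 pupil (0.78 cycles/μm)
lies slightly above the grid Nyquist frequency (0.71 cycles/μm), so the
outermost fringes are barely sampled. This matters for template
matching (below) but not for reconstruction.

## Motion model

Swimming is run-and-tumble with Brownian jitter: straight runs at
constant speed, exponentially distributed tumbles that redraw the
heading uniformly on the sphere, and an isotropic Gaussian displacement
of per-axis variance 2DΔt each frame. Defaults (speed 20 μm/s, tumble
rate 1 s⁻¹, D = 0.4 μm²/s, 30 Hz frames) are typical literature values
for swimming *E. coli*; they are fixture parameters, not measurements.
Boundaries reflect both laterally (keeping the per-frame cell count
constant, which the tests rely on) and axially at z ∈ {0,
chamber_depth}. Real cell suspensions additionally show gravitational
sedimentation and wall accumulation; the generator does not emulate
those density gradients, so passing tests say nothing about
depth-distribution effects in real data.

## Classical localization (ground-truth engine)

A normalized frame (median-divided, background ≈ 1) is reduced to its
contrast `frame − 1`, edge-apodized with a 16 px cosine taper, and
back-propagated onto a uniform z grid (default Δz = 2 μm over the
chamber). The Gouy phase anomaly — the π phase flip through focus —
makes Im[ψ] change sign at a particle's plane, so the criterion

    G(x, y, z) = −∂z Im[ψ]

(central differences along z, optional 3×3 lateral smoothing) peaks
there. Voxels with |G| above 12× the volume's median absolute deviation
are clustered by 26-connectivity; clusters under 8 voxels are dropped.
Both knobs are config-exposed; the defaults were chosen by measuring
false-cluster counts on particle-free noise volumes (at 8×MAD ≈ 2.7σ a
512²×141 volume yields thousands of noise clusters; at 12×MAD with an
8-voxel minimum, none).

Two refinements fix measured biases of the raw criterion:

- **Lateral**: the cluster position is the |G|-weighted centroid of
  voxels at ≥ 50% of the cluster peak. The full defocus cone is
  axially asymmetric and would drag a whole-cluster centroid several
  μm.
- **Axial**: at Δz = 2 μm the axial phase carrier exp(−ikζ)
  (k = 2πn/λ ≈ 13 rad/μm) aliases to a ≈14 μm pseudo-period that
  displaces the |G| maximum and the Im zero crossing by up to ±4 μm
  for depths not commensurate with the plane grid. The through-focus
  energy Σ|ψ|² (3×3 px around the cluster peak) is carrier-free, so
  the final z is the vertex of a parabola through its three planes
  around the maximum. Measured axial error over z ∈ [20, 250] μm:
  mean +0.1 μm, rms 0.34 μm, maximum 1.0 μm.

G also has axial side lobes ≈10 μm from a particle (flanks of the
Im[ψ] S-curve); localizations within 4 px laterally and 15 μm axially
of a stronger one are merged. Consequently two real objects stacked
closer than ~15 μm along the optical axis are reported as one — the
axial resolution limit of this engine. Finally, localizations weaker
than 30% of the frame's strongest are discarded: in nearly noise-free
data the MAD scale calibrates to coherent ring residuals instead of a
noise floor, and those clusters sit far below real particles. This
dynamic-range floor assumes scatterer amplitudes within a factor ~3 of
each other (true of the generator's videos, which use one amplitude
per video); it is configurable and can be disabled for heterogeneous
samples.

## Box-size heuristic and annotation

Apparent pattern radii are measured programmatically: the fringe
envelope (local-maximum filter) of a rendered single-scatterer pattern,
thresholded at 10% of its peak — the analogue of drawing an ellipse
around the pattern where it fades into noise. A straight line
`side_px = m·z + c` is fitted by least squares **only** to pairs in the
intermediate regime 50 μm < z ≤ 200 μm, where the relation is linear;
an optional vertical offset raises the intercept, and a non-positive
intercept is replaced by a minimum box side (12 px) so boxes near the
focal plane always have positive size. Annotations are square boxes of
side s(z) centred on the localization, clipped at frame edges
(producing rectangles), and written as darknet-style normalized label
files, one per frame, empty files for cell-free frames (negative
controls).

## Reference detector

The detector contract is darknet boxes with confidences; anything that
emits them (e.g. a trained YOLO network) plugs into depth mapping and
tracking unchanged. The built-in reference detector correlates the
frame contrast with a bank of rendered ring templates:

- **Scoring** is a template-normalized matched filter, not an
  image-normalized cross-correlation. Scattering is weak, so
  overlapping patterns superpose linearly; a neighbour's fringes then
  perturb a cell's response additively, whereas local-variance
  normalization deflates it (measured recall at 40 cells dropped below
  0.4 with image-normalized scoring, even noise-free).
- **Confidence** is the response divided by that of a perfectly
  matched scatterer at the largest single-scattering amplitude
  (ε = 0.2), clipped to [0, 1] — an auto-calibrated scale with a
  physical meaning: match quality × relative scattering strength.
- **Band limit**: templates are rendered through a *narrower* pupil
  (NA 0.3) than the imaging NA, keeping only comfortably sampled
  fringes; near-Nyquist fringes decorrelate under subpixel shifts and
  halve the score for a half-pixel offset.
- **Template grid**: z = 16–160 μm in 4 μm steps. The fringe pattern's
  axial correlation length is ≈4 μm, essentially independent of depth
  (set by the pupil-limited outer-fringe chirp), so a coarser bank
  misses cells between templates. Above z ≈ 160 μm fringe contrast no
  longer supports reliable matching at any threshold — consistent with
  the working-depth limit reported for detector-based DHM tracking.

Per-scale local maxima above the confidence threshold (default 0.3)
become square boxes of side s(z_template); scales are merged by greedy
IoU non-maximum suppression (threshold 0.45). Measured on clean frames
with 20 cells in z ∈ [20, 150] μm: precision ≥ 0.95, recall 0.90–1.0.
The detector's box side is quantized to the template grid, so its depth
resolution is ~±2 μm before correction.

## Depth mapping and polynomial correction

`z_raw = (longest_edge − c)/m`, floored at 0; the longest edge makes
edge-clipped rectangles usable. Detectors trained on heuristic labels
systematically mis-size boxes in a smooth depth-dependent way; the
pipeline models this as a monotone quartic distortion and corrects it
with a 4th-order polynomial `z_corr = Σ aₖ z_rawᵏ` fitted by least
squares on validation data (first half of the video) and applied to
test data (second half). The fit uses a rescaled variable for
conditioning, needs ≥ 5 pairs with full-rank design, records its
domain, flags extrapolation outside it, and warns if the fitted
polynomial is non-monotone on the domain (a non-monotone size→depth
map makes inversion ambiguous).

## Tracking

Per-frame localizations are linked by optimal bipartite assignment
(Hungarian) on 3D Euclidean distance with a hard per-link gate
(default 30 μm ≈ the largest per-frame swimming displacement at
30 Hz), a gap tolerance of 2 frames, and a minimum track length of 5
— the step that rejects spurious transient detections. Optimal
assignment was chosen over greedy nearest-neighbour because it is
deterministic, independent of input order, and testable against
exhaustive enumeration. Box-proxy tracks use corrected depths for the
linking distance. Track agreement is quantified by the RMSE of 3D
point-to-point distances over common frames (≥ 3 frames required).

## Evaluation metrics

Single-class detection metrics pooled over frames: greedy
confidence-descending matching with one-to-one detection↔truth pairing
at minimum IoU; 101-point interpolated average precision; mAP(0.5) and
mAP(0.5:0.95) (mean over IoU thresholds 0.50–0.95 in steps of 0.05).
The 101-point interpolation is the convention of the COCO-style
benchmarks detector papers compare against. Because published
precision/recall figures differ in their operating point, the report
carries both a fixed-confidence operating point and the best-F1 point
of the PR sweep.

## Reference study conditions and problem sizes

The validation suite and `scripts/acceptance.py` run, at the default
512² geometry:

- **Propagation**: identity/round-trip on band-limited 256² fields;
  Gaussian-beam width law to 300 μm (tolerances 1e-8 relative and 1%).
- **Gouy recovery**: 50 single-scatterer frames, z ∈ [20, 250] μm,
  ε = 0.2, noise 0.01, Δz = 2 μm stacks over [0, 280] μm.
- **Depth correction**: 100 repetitions of the quartic-distortion
  experiment, 60 pairs each, 2 μm measurement noise, half held out.
- **End-to-end**: 10 cells, 100 frames, chamber depth 150 μm (the
  detector's working range), ε = 0.15, noise 0.002, a 5% static
  artifact pattern removed by median normalization, detection,
  synthetic quartic box distortion, correction fitted on the first 50
  frames, tracking of the last 50, RMSE against ground truth.

These sizes keep a full run in minutes on one CPU while exercising
every stage at the reference imaging geometry.

## Known limitations

- Scatterers are ideal points: no Mie/Lorenz–Mie structure, cell
  morphology, orientation effects, polarization or partial coherence.
- Sensor noise is Gaussian; no shot noise, fixed-pattern noise beyond
  the static artifact, or motion blur.
- The axial side-lobe merge limits axial two-point resolution to
  ~15 μm for the classical engine.
- The reference detector shares the renderer's optical model with the
  data generator; its absolute precision/recall say nothing about a
  CNN on recorded videos — it exists so the depth-proxy, correction,
  tracking and evaluation stages can be exercised end to end against
  ground truth.
- z is treated as an unsigned distance from the focal plane; the two
  sides of the focal plane are not distinguished.
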