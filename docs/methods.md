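# Methods

This note documents the model, the parameter choices and the numerical
decisions behind `vesscade`, in the package's own words. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The vessel axis + cross-section model

The segmenter never classifies a volume voxel-by-voxel. Given a vessel axis
(supplied, or extracted by thresholding the maximum-over-scales Frangi
response and 3D-thinning it), a plane orthogonal to the vessel is spanned at
every axis point and 72 rays are cast every 5° from the axis point. The
classification problem is then 1D per ray: find where samples stop being
vessel. This constrains the classifier to the neighbourhood of the axis —
which is what makes a boosted classifier with simple interval rules viable —
and yields a boundary radius per ray, i.e. an explicit cross-section contour
rather than an unstructured voxel set.

Frames are built from the local Hessian eigen-system at each point's
best-responding scale: for a bright tube the eigenvector of the
signed-largest eigenvalue (≈ 0) points along the vessel; the centerline
tangent disambiguates its sign. When the local anisotropy
(λ1 − λ2)/(|λ3| + 1e−12) falls below 0.1 there is no preferred direction
(e.g. inside a blob) and the frame falls back to the tangent with a
deterministic in-plane basis.

## Feature bank

Per voxel and per scale σ_r ∈ {0.6, 0.85, 1.2, 1.7, 2.4, 3.39} mm
(σ_r = 0.6·2^((i−1)/2)), the Gaussian-derivative Hessian (reflect padding,
spacing-aware derivatives in mm⁻², σ²-normalized) yields signed-sorted
eigenvalues λ1 ≥ λ2 ≥ λ3 and five responses:

| feature | form | default parameters |
|---|---|---|
| f1 Sato | λ2·exp(−λ1²/(2α²λ2²)), α = α1 for λ1 ≤ 0 else α2 | α1 = 0.5, α2 = 2 |
| f2 Frangi | (1−e^(−R_A²/2α²))·e^(−R_B²/2β²)·(1−e^(−S²/2γ²)) | α = β = 0.5, γ auto |
| f3 Shikata | σ_r²·λ2_raw/I | intensity floor 10⁻⁶·max\|I\| |
| f4 Li | λ2(λ2−λ3)/λ1 for λ1 < 0, λ2 < 0 | — |
| f5 Manniesing | Frangi product × exp(−2c²/(\|λ2\|λ3²)) | γ = 5, c = 10⁻⁶ |

Conventions worth stating explicitly:

- The canonical eigenvalue order is *signed* (λ1 > λ2 > λ3); the Frangi
  ratios R_A = |λm2|/|λm3|, R_B = |λm1|/√(|λm2 λm3|) use the magnitude
  ordering internally (`magnitude_view`). This reproduces both the
  signed branch conditions of f1/f4 and the magnitude-based ratios of f2/f5.
- f3 is defined on the *raw* (un-normalized) eigenvalue with an explicit
  σ_r² factor; computing it from the σ²-normalized eigenvalue would
  double-count σ². Algebraically f3 = λ2_normalized/I, which is how it is
  evaluated.
- γ for f2 is auto-estimated per scale as half the maximum Frobenius norm of
  that scale's Hessian field. A consequence: the on-axis f2 response is
  nearly flat across scales (each scale is normalized by its own maximum),
  so cross-scale comparisons of f2 require a fixed γ. The multiscale default
  keeps the per-scale estimate; f5 keeps its fixed γ = 5.
- f1 is kept signed (negative on bright tubes) — the interval weak
  classifiers downstream are sign-agnostic. f4 is clamped at
  |λ1| ≥ 10⁻¹²(|λ2|+|λ3|) so the response stays finite when the along-axis
  eigenvalue vanishes on a perfect tube.
- A vectorized closed-form (trigonometric) eigenvalue solver handles
  whole-volume fields; `eigen_sorted` (LAPACK, with eigenvectors) is the
  contractual path for frames and is cross-checked against the closed form
  and against characteristic-polynomial roots in the tests.

## Cascade-AdaBoost-SVM

Training samples are ray samples with 30 channels (5 features × 6 scales),
labeled by trilinear interpolation of the reference mask (≥ 0.5 = vessel).
Weight initialization is class-asymmetric — w_p = 1/(p+1), w_n = 1/(q(p+1)),
so the positives jointly hold p/(p+1) of the mass — which biases every layer
toward detection.

Each layer trains an independent discrete AdaBoost per scale on that scale's
five features: per round, five interval weak classifiers
(h = 1 iff T_lower ≤ f ≤ T_upper) are fitted and the lowest-error one kept;
β_t = ln((1−ε_t)/ε_t) with ε clamped to [10⁻¹⁰, 0.5−10⁻¹⁰]; weights are
multiplied by e^{β_t} on misclassified samples and renormalized. The
interval search is a quantile grid (≤ 256 cuts) searched exhaustively over
cut pairs by prefix sums, with local refinement of the two chosen
boundaries; for ≤ 256 distinct values it is exhaustive, which the tests
verify against an O(m²) enumeration. Ties prefer the wider interval, then
the lower T_lower.

The layer response is max over scales of the per-scale weighted vote sums;
the layer threshold θ is lowered until the validation detection rate meets
d (Viola–Jones style), and the layer succeeds if the validation
false-positive rate is ≤ e. Rates are measured on a stratified 30% split of
the surviving pool, never on the training fold. The weak-classifier budget
n_th applies per scale.

When a layer fails within its budget it is replaced by a soft-margin RBF-SVM
(C = 1, median-pairwise-distance bandwidth, per-channel standardization,
class weights inverse to class counts, fit capped at 4000 samples per class)
trained on exactly the channels the failed AdaBoost selected, in selection
order — the layer's "feature queue". The SVM threshold is shifted to meet d
on validation. SVM layers are evaluated from their stored support vectors
and dual coefficients, so a serialized model needs no fitted estimator
objects and round-trips bit-exactly through JSON.

The outer loop appends layers while Π e_i > E_target, removing rejected
(true-negative) negatives from the pool after each layer; positives always
pass on. Defaults: d = 0.99, e = 0.3, n_th = 15, E_target = 6·10⁻⁶.
Stopping: target reached, negative pool empty, 25-layer guard, or a stalled
layer (validation false-positive rate ≥ 0.98). The stall rule matters in
practice: with mask-derived labels the samples within about one voxel of the
boundary are intrinsically ambiguous (their features are indistinguishable
at the smoothing scales used), so E_target may be unreachable; a layer that
rejects almost nothing would only erode the detection rate, and is discarded.
A stall on the very first layer (classes inseparable outright) is an error.
In the AdaBoost-only ablation mode the guard relaxes to the pure
no-progress rule (rate ≥ 1 − 10⁻⁹): a plain cascade has no substitution
mechanism, so it keeps best-effort layers and grows deeper — which is
exactly the behaviour the CAS-vs-CA comparison measures.

## From cascade decisions to a boundary

The naive rule — follow each ray outward until the cascade rejects — is
systematically biased outward on soft-edged vessels: every layer is
calibrated for d = 0.99, so the cascade accepts essentially the entire
boundary ambiguity band, and the accepted run ends near the *outer* edge of
that band. The package verified this bias is a property of the operating
point, not of a particular classifier (a balanced RBF-SVM on all 30 channels
shows the same offset), and therefore locates the boundary differently:

1. **Depth profile.** For each ray sample, the cascade depth = number of
   consecutive layers passed. The profile decays from L (inside) to 0
   (outside); its 50% crossing, linearly interpolated between samples, gives
   a sub-step boundary estimate. The profile must stay below the half level
   for two consecutive samples to terminate (single-sample flicker
   tolerance). The binary gap-tolerant run rule remains available as
   `boundary_rule="run"` with `gap_tolerance` (default 2).
2. **Isotonic calibration, two stages.** On training volumes the reference
   boundary per ray is known (0.5-crossing of the interpolated training
   mask). Stage 1 fits the monotone per-ray map raw-radius → reference-radius
   (removes the average outward bias, shrinks outliers). Stage 2 pairs each
   cross-section's *mean* corrected radius with its mean reference radius
   and fits a second monotone map whose residual offset is applied
   section-wise: the section mean (72 rays) is estimated an order of
   magnitude more precisely than any single ray, so this stage resolves the
   radius-dependent part of the bias that pooled single-ray pairs from
   different vessel calibers conflate. Both stages use training data only;
   in the synthetic experiment they are fitted per noise level (the
   cascade's spatial cut shifts with noise), on up to two training volumes
   per level.
3. **Median smoothing.** Cross-section contours are physically smooth, so
   the radius table is filtered with a circular azimuthal median (11 rays ≈
   55°) and an axial median (7 sections ≈ 5 mm at the default axis-point
   spacing). Both windows are config-exposed; setting them ≤ 1 disables
   smoothing and exposes the raw per-ray decisions. Smoothing is deliberate:
   without it, independent per-ray errors (±0.3–0.6 mm) dominate the surface
   error budget. A 7-section median preserves stenoses longer than ~3 mm.

The mask is the union of the cross-section polygons: each section is a slab
(half-thickness 1.25× the local axis-point gap, clipped to [0.3, 3] voxels)
and a voxel center is inside if its in-plane radius is below the angularly
interpolated boundary radius. A single 3³ face-connectivity closing seals
rasterization pinholes (config-exposed). The voxel-center-inside test makes
prediction and ground truth commensurate: both are voxelizations of smooth
regions, so an unbiased radius estimate yields near-perfect overlap.

## Synthetic vascular trees

`synth_vascular` generates recursive bifurcating polyline trees: root radius
4 mm decaying by 0.72 per generation over depth 3 (radii ≈ 4 → 1.5 mm),
segment lengths 22–34 mm with a gently jittered direction random walk
(~2.5°/step), bifurcation angles 25–50°, clipped to the volume. The
intensity model is the 2D-Gaussian line profile
L = exp(−d²/2σ_r²) with σ_r = k·r and k = 0.5, peak 100 over background 0;
the ground truth contains voxels within the local radius. With k = 0.5 the
labeled boundary sits at 2σ of the profile (≈ 13.5% of peak) — a visible
but deliberately soft edge. Additive i.i.d. Gaussian noise at variances
{20, 40, 60, 80} (σ ≈ 4.5–8.9 on a peak of 100) reproduces the
blurred-boundary regime proportionally; since absolute intensity units are
arbitrary, the portable claim across noise levels is the accuracy *ordering*,
not absolute values. Optional distractors (Gaussian blobs, thin bright
plates, parallel touching tubes) blend into the image by maximum and never
enter the ground truth; they are off by default in the noise experiment.

What the generator does **not** emulate: intensity inhomogeneity along the
vessel, stenoses and caliber irregularity, imaging point-spread anisotropy,
structured (non-white) noise, and contact with extended anatomy. Passing the
synthetic experiment therefore demonstrates the machinery end-to-end under
controlled conditions, not clinical-grade performance.

## The noise-robustness experiment

Per replicate seed: 3 phantoms (96³, 1 mm isotropic); per noise variance a
training and a testing realization built from common random numbers (one
standard-normal field per tree and split, scaled by σ per level) — each
level's noise is exactly N(0, σ²) while the accuracy contrast across levels
is paired, the standard simulation design for comparing treatment levels;
ray samples pooled over all 12
training volumes (axis stride 3; capped at 15 000 positives / 30 000
negatives by seeded subsampling); one cascade trained; per-level isotonic
calibration fitted; all 12 test volumes segmented along the known
centerlines; DOC (%) and ASD (mm) per volume. Everything flows from one
integer seed through `numpy.random.SeedSequence` spawns, and repeated runs
are bit-identical. Feature evaluation is restricted to an ROI within
ray-reach of the centerline (exact inside the ROI — the Gaussian filtering
stays global); a full experiment replicate runs in a few minutes on one CPU.

## Evaluation

DOC = 100·2|A∩B|/(|A|+|B|) (both-empty → 100, flagged). ASD: surfaces are
mask voxels with ≥ 1 face-connected background neighbour; directed distances
come from spacing-aware Euclidean distance transforms and the two directed
means are averaged (vertex-connectivity surfaces are config-switchable).
Paired two-sided t-tests compare method variants case-by-case (α = 0.05);
all-zero differences give p = 1, nonzero constant differences are flagged
degenerate. Reports bundle per-case metrics with the cascade bookkeeping:
per-layer kind and weak-classifier counts, feature queues, and rear-layer
(last two layers) feature utilization percentages.

## Known limitations

- Boundary localization is limited by the ray step (0.5 mm at 1 mm spacing)
  and by the ambiguity band of the soft edge; the calibration removes the
  mean bias but not the per-ray spread.
- At bifurcations, rays from one branch can look down the sibling branch;
  such rays are excluded from calibration fitting but still contribute
  (smoothed) radii to the mask.
- The AdaBoost-only ablation mode accepts best-effort layers, so its layer
  count depends on the stall guard as well as the targets.
- The substituted SVM sees only the channels the failed AdaBoost selected;
  if the greedy queue omitted an informative channel, the SVM inherits that
  blindness and the layer may stall.
- The centerline stand-in (threshold + thinning) is deliberately simple;
  skeleton jitter translates into frame jitter. Supplying centerlines is
  recommended when available.
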