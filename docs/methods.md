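# Methods

This note documents the models, parameter choices and numerical conventions
behind `slovasc`, and what the synthetic validation does and does not
establish.

## Pipeline model

An analysis run is a fixed composition:

read image (+ JSON sidecar metadata) → segmentation bundle → threshold at
0.5 → post-process masks → landmarks (fovea centroid, disc ellipse) →
laterality/location (user metadata wins; otherwise inferred) → regions of
interest → vascular metrics → per-image outputs and a collated table.

Images are resized to a 768×768 working resolution for segmentation
(bilinear for intensities/probabilities, nearest-neighbor for labels);
probability maps are resized back to the native resolution, and
thresholding happens at native resolution. The threshold rule is p ≥ 0.5
(boundary included). Whether to threshold at working or native resolution is
a genuine free choice; native was picked so user-corrected masks (which live
at native resolution) and computed maps flow through identical code, and the
choice is switchable by resizing before thresholding.

Assumptions: grayscale en face images with bright vessels on a darker
fundus, an approximately elliptical bright optic disc, a dark foveal spot,
roughly isotropic spatial sampling, and a ~30° field of view. Metadata is
never guessed at read time; absent scale means pixel-space outputs flagged
`units=px`.

## Segmentation

Segmentation is pluggable by design. The first-class path ingests
user-supplied or manually corrected label masks (encoding 0 background,
1 artery, 2 vein, 3 crossing, 4 disc; fovea and binary-vessel masks are
separate single-channel files). A corrected file named
`<stem>_labels_corrected.png` in the image's output folder takes absolute
precedence on re-runs.

The built-in classical baseline exists so the measurement machinery can be
exercised end to end without trained models:

- **Vesselness**: scale-normalized Gaussian second-derivative (Hessian)
  filters at σ = w/2 for ridge widths w ∈ {1, 2, 4, 8} px; response =
  σ²·max(0, −λ_min), maximum over scales. Kernels are made exactly zero-sum
  (the truncated second-derivative kernel leaks a small DC term otherwise),
  so flat regions respond exactly 0 and the operator commutes with
  quarter-turn rotations to float precision. The response is normalized by
  the 95th percentile of its positive values so the pipeline's fixed 0.5
  threshold falls inside the ridge profile; this robust normalization was
  calibrated once against the generator's default contrast settings.
- **Fovea**: darkest minimum of a σ=25 px Gaussian-smoothed image within the
  central half, emitted as a disc of radius 60 px (the circular fovea-label
  geometry at working resolution) whose value is the normalized dip depth
  (full confidence at ≥16 intensity units of dip, on the 8-bit scale); a
  flat or disc-centered image therefore thresholds to "fovea absent". Ties
  break to the leftmost, then topmost pixel.
- **Optic disc**: bright-blob morphology (σ=6 smoothing, threshold between
  background median and the 99.5th percentile, opening with a radius-12
  disc, largest blob ≥1500 px, hole-filled).
- **Artery/vein split**: a surrogate classifier that scores vessel segments
  by mean centerline intensity and splits at a 1-D two-means cut (dim →
  artery, bright → vein, matching the generator's contrast ordering), then
  assigns vessel pixels to the nearest segment. It exists to give the
  CRAE/CRVE/AVR code realistic inputs; it is not a claim about real images.

## Post-processing

On binary masks, 8-connected throughout (keeps diagonal vessels connected):

- `clean_mask`: remove components smaller than `min_area_px`
  (default 10 px at 768², scaled quadratically with resolution; components
  of exactly the threshold size are kept).
- `bridge_gaps`: join skeleton endpoints of different components whose
  pixel distance is ≤ `max_gap_px` + 2 (the two endpoint pixels span ~2 px)
  and whose walking-direction tangents are within 30° of the connecting
  line; the connecting stroke uses the local width and is clipped to the
  input dilated by `max_gap_px`, so bridging never grows the mask beyond
  that support and never increases the component count. Default
  `max_gap_px` = 3 at 768², scaled linearly. Endpoint tangents are taken by
  walking 8 steps back along the skeleton (a local-centroid estimate is
  thrown off by the short diagonal spurs skeletonization leaves at blunt
  ends). Both operations are idempotent.

Neither the small-region area threshold nor the gap-joining rule is a
published constant; both are deliberately small (remove speckle, keep
capillary-scale detail) and exposed in the config.

## Landmarks and zones

The foveal pit is the centroid of the fovea mask. The optic disc is an
ellipse fitted by image moments of the largest component (centroid + second
central moments — deterministic and robust for filled masks, unlike boundary
least squares); its diameter D is the mean of the axis lengths. Inference
rules when metadata is absent: location = "disc" if the disc center lies in
the central third of the image width, else "macula" if the fovea does;
laterality = right iff the disc is right of the fovea (right-half rule when
the fovea is absent); undecidable cases resolve to "unknown" rather than a
guess.

Zones treat the disc as a circle of radius D/2 at the ellipse center (the
zones are defined in units of the single diameter D; true elliptical offsets
are available via `zones.shape=elliptical`): zone B = radii [D, 1.5D],
zone C = [0.5D, 2.5D], bounds inclusive, clipped to the image. Segments are
clipped at ROI boundaries and contribute their in-ROI portion (midpoint
membership available via `zones.boundary_rule=midpoint`). Whole-image
metrics include vessels over the disc by default
(`zones.exclude_disc_from_whole` flips this).

## Measurement details

- **Skeleton & segments**: `skimage` topology-preserving skeletonization;
  junction pixels have ≥3 skeleton neighbors, endpoints exactly 1; removing
  junctions yields simple paths, traced in walking order (axial steps
  preferred over diagonal at forks). Paths shorter than `min_segment_len`
  (10 px at 768², scaled linearly) are discarded. Arc length counts 1 per
  axial and √2 per diagonal step; the chord is the Euclidean endpoint
  distance.
- **Widths**: 2× the Euclidean distance transform at skeleton points,
  evaluated on a 4× nearest-neighbor-upsampled mask (max over the point's
  fine block). The upsampling resolves the half-pixel boundary convention
  that biases native-grid 2×EDT by ±1 px depending on width parity;
  axis-aligned drawn calibers are recovered essentially exactly, oblique
  ones read a fraction of a pixel low.
- **Tortuosity density**: the path is smoothed (Gaussian, σ=5 samples),
  curvature κ = (x′y″ − y′x″)/|v|³ is computed by finite differences, and
  the path splits where κ changes sign with |κ| ≥ 0.005 px⁻¹ (a 200 px
  radius of curvature — below that, sign flips are rasterization jitter).
  TD = (n−1)/n + (1/L)·Σ(Lᵃᵢ/Lᶜᵢ − 1). Exactly straight paths give 0.
- **Fractal dimension**: box counting over the ROI bounding box with dyadic
  grid sizes 2 … shorter-side/4 anchored at the box origin; ordinary least
  squares on (log s, log N); undefined (None) with fewer than 3 sizes or an
  empty mask. Computed on the full-thickness mask by default
  (`metrics.fd_on_skeleton` switches to the skeleton; FD shifts
  systematically between the two).
- **Knudtson equivalents**: the six widest segment mean-widths per class
  (an odd count is trimmed to the largest even number; fewer than two gives
  null); iteratively pair largest with smallest, replace by k·√(w₁²+w₂²)
  (k = 0.88 arteries / 0.95 veins), carry an odd middle value, repeat. The
  pairing is permutation-invariant and positively homogeneous, so micron
  and pixel computations commute with scaling.
- **Aggregation**: ROI values of segment metrics are arc-length-weighted
  means by default (`metrics.aggregation=mean` for plain means).
- Metrics undefined for a class/ROI are explicitly null, never 0.

## Evaluation statistics

Dice (2|A∩B|/(|A|+|B|), with dice(∅,∅) := 1 — identical masks), midrank
Mann–Whitney AUC, MAE, Bland–Altman mean difference with LoA = MD ±
1.96·SD(d), and ICC(3,1) = (BMS−EMS)/(BMS+EMS) for k = 2 from the two-way
ANOVA, consistency form (a fixed offset between repeats does not reduce it;
the absolute-agreement variant is out of scope), with the standard F-based
95% CI. Sample (n−1) standard deviations throughout.

The eye-level measurement-noise statistic λ is computed per eye as the
sample SD of that eye's repeated measurements divided by the SD of eye-level
means across the population, ×100. With only k = 2 repeats the per-eye SD is
σ_w·|z| (half-normal), so the *median* per-eye λ at a true within/between
ratio ρ converges to 100·ρ·0.6745/√(1+ρ²/2) — about two-thirds of 100·ρ —
while the pooled within-eye SD over the between-eye SD (also reported by the
acceptance script as `lambda_pooled_pct`) converges to 100·ρ itself. This
distinction matters when comparing per-eye λ distributions against
population-level noise ratios. The population denominator uses eye-level
means (pooling all measurements instead changes it by under 2% at small ρ).

## Synthetic data: what it emulates, and what it does not

Scenes are built from parametric centerline curves (polylines, sinusoids
with amplitude/period/phase, circular arcs) of constant width; a vessel's
mask is exactly the set of pixels within width/2 of the centerline, so
caliber, arc length (closed form or high-accuracy quadrature) and chord are
known analytically. Rendering adds a raised-cosine intensity ridge on a 25%
pedestal (every vessel pixel is strictly brighter than the local
background), an optional central light reflex (bright strip of width w/3),
a bright elliptical disc with a short edge ramp, a dark Gaussian foveal spot
(σ = 45 px, depth 40 of 255), background 60, vein contrast 90, arteries at
0.8× vein contrast and 0.8× vein width, and seeded Gaussian noise
(default SD 5). Quantization to 8 bits happens at generation time, so
written-then-read scenes are bit-identical and batches are reproducible at
the byte level. Default scene layouts place arcades around a central fovea
with the disc cropped at the nasal edge (macula-centered) or radial vessels
plus circumferential arcs around a central disc (disc-centered, disc offset
25 px nasally so laterality stays decidable); crossings between artery and
vein curves are labeled as such. Repeated-pair generation re-renders the
same tree under a small translation (≤10 px) with independent noise,
emulating unregistered repeat acquisitions.

Passing tests on these scenes establishes that the measurement machinery is
correct on known geometry — they do not establish segmentation accuracy on
real SLO images (no optics simulation, no pathology, no pigmentation or
illumination variation, no motion artifacts), and the artery/vein surrogate
split exploits a contrast ordering the generator itself creates.

## Problem sizes

The test suite and acceptance script run everything at full working
resolution except the batch-determinism check, which uses ten 512×512
scenes; straight-vessel fixtures are ~600 px long, the reproducibility
simulation uses 200 eyes, and invariance sweeps use 100 random draws. These
sizes were chosen as the smallest at which the measured quantities are
stable against discretization and Monte-Carlo error.

## Known limitations

- Global caliber is a pixel-count ratio by definition; oblique vessels read
  up to √2 higher than their true caliber. Local caliber does not share
  this bias and is the better estimator away from axis alignment.
- Even-width vessels centered on integer pixel rows necessarily rasterize
  one pixel wide of nominal under the d ≤ w/2 pixel-center rule; the
  generator supports sub-pixel centerline placement for exact-caliber
  fixtures.
- Tortuosity density is sensitive to segment fragmentation (crossings cut
  segments), inherited from its per-segment definition.
- The baseline segmentation is calibrated to the generator's contrast
  model and makes no claims on real images; real-image use should supply
  externally produced or manually corrected masks.
- Laterality inference assumes posterior-pole framing; wide-field or
  off-center acquisitions fall back to "unknown".
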