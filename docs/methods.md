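# Methods

This note documents the models, numerical choices and limitations behind
greenspot. It describes what the code does and why; every number quoted as a
result here is computed by the test suite or `scripts/acceptance.py`, not
asserted from memory.

## Segmentation

Vegetation is separated from soil with the excess-green index
ExG = 2G − R − B, clamped to [0, 255]. The full chain is fixed as
downsample → ExG → 5×5 mean filter → Otsu threshold → 3×3 opening → 3×3
closing. Choices worth stating:

* **Downsampling** halves the image per pyramid level (Gaussian smooth,
  σ = 1, then discard even rows/columns) while both dimensions remain at
  least twice the target, and finishes with one bilinear resize to land
  exactly on the working size. From a 2592×1944 camera frame, halving twice
  gives 648×486; the final resize reaches 640×480 exactly.
* **Thresholding** is Otsu's between-class-variance maximum over the 256
  intensity levels, foreground strictly above the threshold. A constant
  image yields an empty mask by convention (no variance to split). The
  implementation (scikit-image) is tested for exact mask equality against a
  brute-force scan of all 256 thresholds.
* **Filtering order**: the mean filter runs on the ExG response, not on the
  color channels. Filtering channels first and then applying the (linear)
  ExG operator would give the same result up to rounding, so nothing hinges
  on this.
* Borders replicate edge values; connectivity is 8-connected; blobs below
  `min_area` (default 50 px at 640×480) are dropped. All are conventional
  defaults, fixed so tests are deterministic.

## Shape descriptors

* **Point-to-line ratio (RAT_I_L)**: the skeleton is the Zhang–Suen thinning
  of the blob; its *length* is defined as the skeleton pixel count (a
  geodesic length would differ by √2 factors on diagonals without changing
  the ranking). Branch points are skeleton pixels with ≥ 3 skeleton
  neighbors in the 8-neighborhood; 8-connected clusters of such pixels merge
  into a single intersection, because thinning routinely emits 2–3 adjacent
  high-degree pixels at one physical junction and counting them separately
  would triple-count.
* **Circularity (Rod)** is 4πA/P² with P estimated by the 4-direction
  Crofton formula on the hole-filled footprint. Crofton was chosen because
  the naive pixel-edge perimeter of a rasterized disc is ~8r rather than
  2πr, biasing Rod of a disc to ≈ 0.91, and a marching-squares contour
  length overshoots on staircase edges (disc ≈ 0.89); Crofton gives ≈ 0.99.
  The cost is a +0.1 bias on sharp-cornered shapes (a square reads 0.88
  against the analytic π/4 ≈ 0.785), acceptable because the discriminated
  shapes are organic. Filling holes first keeps interior soil gaps from
  counting toward the contour; a one-pixel blob is defined to have Rod = 1.
* **Maximum inscribed radius (R)** is the maximum of the Euclidean distance
  transform over the blob, computed against a 1-px padded background so
  image borders count as background.
* **Minimum enclosing circle** is Welzl's algorithm over the convex hull of
  the blob's pixel centers, run in blob-local coordinates (this makes the
  result exactly translation-invariant; global coordinates introduced
  1e-14-level wobble in the circumcircle arithmetic). Verified against a
  brute-force search over all pair/triple circles.
* **Ring profile and b/a**: 8 annuli with radii k·r/8 about the blob
  centroid, r the minimum enclosing radius. Ring k holds grid pixels with
  (k−1)·r/8 < d ≤ k·r/8; the proportion p_k divides the foreground count by
  the annulus pixel count (the alternative — dividing by blob area — is kept
  behind `ring_denominator="blob"`). A quadratic in k is fit by least
  squares; only a and b feed the b/a feature, c absorbs the offset. Fits
  with |a| < 1e-6 clamp the ratio to ±1e6 (sign of b), or 0 when b also
  vanishes; the clamp keeps degenerate flat profiles from emitting infinities.
* **Normalization** is per-feature min–max to [0, 1] on training extremes,
  clamped outside; a training-constant feature maps to 0.5.

## Classifier

RBF kernel exp(−γ‖x_i − x‖²) with γ = 1/(2σ²). The hyperparameter grid is
exhaustive over integer powers of two, C ∈ 2⁻¹⁵…2¹⁵ and σ ∈ 2⁻¹⁰…2¹⁰
(31 × 21 = 651 points), scored by stratified N-fold cross-validated
accuracy with a single fold assignment shared across the grid (seeded,
shuffled). N defaults to 5 and is reduced to the largest N ≤ 5 satisfying
the sample-budget rule n/N > 3d (error below N = 2). Ties in CV accuracy
break toward smaller C (less overfitting), then larger σ (smoother
kernel). The final model refits on all data at the winning point;
multi-class decisions use one-vs-one voting. Models persist as versioned
JSON carrying the scaler, (C, σ), labels and the scaled training set, and
are re-fit deterministically on load — chosen over binary coefficient dumps
to keep artifacts text-only and round-trips byte-reproducible.

For the permutation-null check, the *grid-averaged* CV accuracy is compared
with chance: the maximum over 651 correlated grid points is upward-biased
under the null by selection, so only the unselected average is expected to
sit within sampling error of 1/k.

## Sprayer simulation

The world is one-dimensional along the travel axis; lateral geometry enters
only through the pixel calibration (1.5 m across 1280 px ⇒ 1200 mm along
1024 px, same scale both axes). The camera's ROI threshold line leads the
nozzle by L_cn = 0.7 m. Per frame (28 Hz) a target triggers when its front
edge first passes the line. The controller compensates four delays —
identification t₁ = 38 ms, communication t₂ = 0.82 ms, valve response
t₃ = 20 ms, droplet fall t₄ = 35 ms — whose sum must satisfy
L_cn/v ≥ t₁+t₂+t₃+t₄ (otherwise the configuration errors out). These four
are independent config values; no total latency is hard-coded.

Commands are scheduled on encoder distance: the reading d₀ latched at
command receipt anchors an open interval (d₀+open, d₀+close), with offsets
derived from the measured target extent, the 30 mm advance/lag presets and
the delay compensation. Overlapping windows of successive targets merge. A
command whose open time falls below the valve response time is dropped
(missed). Encoder skid is a multiplicative slip factor plus optional
zero-mean Gaussian jitter per valve window; the controller believes the
encoder, so slip displaces deposits — at slip > 1 the valve opens early and
closes early, growing D_open and shrinking D_close, the drift pattern the
simulator is meant to expose at higher speeds. `SprayerConfig.field_preset`
bundles a speed-dependent slip/jitter level (slip up to ≈1.013, jitter up to
≈40 mm at 0.93 m/s) with 4.5 % identification misses and 2.5 % partial
detections (70 % extent loss); the field system reports no error model, so
these magnitudes are this package's own choice of a realistic regime, fixed
once.

Scoring: D_open = plant_front − deposit_start, D_close = deposit_end −
plant_rear (positive = margin). A target is *missed* when no deposit touches
it, *invalid* when either margin falls below −70 mm (the −7 cm rule; the
threshold is a config value), else *effective*. The saving rate per target
is ε = (L_sp − s)/L_sp·100 with s the deposit length; s > L_sp clamps to 0
with a warning. Aggregation reports outcome rates (count/total·100, rounded
half-up to 1 decimal — half-up, not banker's, so 286/304 prints 94.1),
means/SDs of |D_open| and |D_close| plus their signed means (the field
protocol takes absolute values; both are kept), mean spray length, mean
centroid offset and mean ε over effective events. Dosage is flow rate ×
open time; the continuous-pass reference sprays the whole ridge.

**Ideal-loop identity** (the simulator's primary oracle): with slip 1, no
jitter and no injected identification error, closed-loop algebra gives
deposit_start = front − advance and deposit_end = rear + lag exactly, so
D_open = D_close = 30 mm to machine precision and ε equals
(L_sp − l − 60)/L_sp in closed form. The acceptance suite asserts this at
all three operating speeds.

## Synthetic generator

The generator reproduces the *statistical structure* the descriptors
exploit, not botanical appearance:

* **Rosette crop** ("cabbage"): 6–12 overlapping elliptical lobes around a
  filled core, with 10–16 small interior holes standing in for soil showing
  between leaves. The holes matter: a solid rosette thins to a tiny central
  skeleton whose junctions all merge into one cluster (RAT_I_L ≈ 0), whereas
  each hole adds a skeleton loop with distributed junctions, giving the high
  point-to-line ratio the method relies on. Canopy size draws around the
  field mean of 160.3 mm.
* **Weed morphotypes**: thin pinnate branching (low Rod ≈ 0.04), a prostrate
  mat of fleshy leaves along crawling stems (Rod ≈ 0.25, intermediate R),
  and a sparse upright brancher (Rod ≈ 0.15). Leaves sit *on* stems rather
  than beside them so they do not manufacture spurious skeleton junctions.
* **Soil** is a brownish base modulated by multi-scale luminance noise —
  multiplicative only, so soil ExG stays non-positive by construction and
  segmentation ground truth is exact. Illumination is uniform ("active
  light") or a vertical gradient ("natural"); a darkness multiplier stands
  in for surface-moisture variation. Highlights (washed-out patches) and
  bite damage are optional per-plant corruptions.
* **Determinism**: every object derives its RNG from the master seed via a
  seed sequence keyed by stable CRC32 hashes of its role and index, so
  outputs are byte-identical per (config, seed) and any single image can be
  regenerated in isolation.
* **Scenarios**: plant slots every 400 mm along a 70 m ridge, each empty
  with the configured void probability; canopy lengths are a clipped normal
  around 160.3 mm (SD 25 mm — the field source gives a mean only; the SD is
  this package's choice).

Separability on the default generator (measured through the full
segmentation pipeline, 25–100 images per class): cabbage vs. each weed
morphotype differs by ≥ 2 pooled SD on RAT_I_L, and grid-search CV accuracy
exceeds 95 % at 100 images/class. Passing these tests shows the method
works when its geometric assumptions hold; it does **not** show field
robustness — real imagery adds occlusion between plants, specular
highlights that fragment masks, shadows, wind blur and genuine biological
shape variance far beyond the parametric jitter here.

## Problem sizes

The default test/acceptance runs use 100 images per class (400 total) for
the classifier, 50 random blobs for the ring-profile oracle, and 70 m
single-row scenarios (≈175 targets) per simulated pass — sizes chosen so
the corpus statistics are stable while a full run stays in the tens of
seconds on one CPU. The reference corpus in the motivating study was 2,000
images; the 80/20 split here mirrors its protocol shape, not its scale.

## Known limitations

* Single plant per image is assumed when building the training corpus; the
  field-image generator supports multiple plants and overlap, but
  overlapping-blob features are not disentangled (matching the method's own
  failure mode on overlapping weeds).
* The sprayer model is longitudinal only; lateral nozzle placement, spray
  cone shape, drift and hydraulic coupling between nozzles are out of scope.
* CAN bus framing is abstracted into the communication delay t₂; command
  records are plain Python objects.
* Crofton circularity biases polygonal shapes high by up to ~0.1; rankings
  among the generated morphotypes are unaffected.
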