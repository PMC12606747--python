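# Methods

## Problem and model

`structpose` performs single-stage multi-animal 2D pose estimation: all
instances in an image are detected and their keypoints localized in one
forward pass, with no object detector and no keypoint-grouping
post-processing. The design targets dense recordings of small model
organisms (C. elegans, zebrafish, Drosophila) where 1–15 visually
similar, highly deformable animals overlap and occlude each other.

Three ideas carry the model:

1. **Hierarchical pose grouping.** A species schema organizes the K
   keypoints into P anatomical parts (worm 5/5, fish 10/5, fly 26/9;
   each part owns 1–6 keypoints). The hierarchy
   `center -> parts -> keypoints` is what the regression follows.
2. **Two-hop offset regression.** Instead of regressing long
   center-to-keypoint displacements directly, the network predicts a
   first hop from the instance center to P adaptive *part points* and a
   second hop from each part point to that part's keypoints. The final
   displacement is the sum `off = off1 + off2`. Only the sum is
   supervised (one L1 loss on the composed displacement), so the hop
   split is free and the part points are learned, never annotated.
3. **Structure-aware features.** The first hop steers *Multi-scale
   Feature Sampling* (MFS): each pyramid level is channel-standardized
   (CT1 `conv–ReLU–conv`, or CT2 adding BN, ReLU and a deformable conv),
   bilinearly sampled at the displaced part position of every cell, and
   fused by learnable per-part softmax weights over levels (`a_add`) or
   concatenation + 1x1 mix (`con_cat`). The fused per-part features are
   then refined by *Structure-Guided Learning* (SGL): at every output
   cell the P part tokens pass through a pre-norm transformer layer
   (LayerNorm → MHSA → LayerNorm → FFN with residuals) with a learnable
   P×C part-type embedding added to the query/key path. Cells never
   interact; all cells share weights. Per-part linear heads finally map
   refined tokens to the second-hop offsets of each part's own
   keypoints, so keypoint ownership is structural, not learned.

Heads: a center heatmap (sigmoid, 1 channel) anchors decoding; an
auxiliary per-keypoint heatmap head (K channels) is supervised during
training only and is absent from the inference graph — decoding never
reads it, so removing it cannot change results.

## Losses

Center and keypoint heatmaps use the penalty-reduced focal loss

    L = -1/N [ Σ_{t=1} (1-p)^α log p + Σ_{t<1} (1-t)^β p^α log(1-p) ]

with α=2, β=4, natural log, and predictions clamped to
[1e-6, 1-1e-6]. N counts positive cells (centers) or supervised
keypoints. A widely printed variant of this expression omits the
leading minus, which would make the loss negative; the negated
(non-negative) form is implemented. The offset loss is the L1 norm of
`(off1[part] + off2[keypoint]) - target` gathered at ground-truth
center cells, divided by the number of supervised keypoints (a bare sum
is available via `raw_sum_offsets`). The total is the weighted sum with
λ_hm = λ_hp = λ_hm_hp = 1 by default.

Offsets are encoded and regressed in output-stride pixel units (stride
4 by default), keeping magnitudes O(10); decoding multiplies by the
stride. Target heatmaps place an unnormalized Gaussian at each
quantized (floor) center cell with value exactly 1 at the cell;
the spread uses the CornerNet-style radius (largest corner displacement
keeping IoU ≥ 0.3 with the instance's keypoint bbox), σ = radius/3.
When two instances quantize to the same center cell the later one wins
the cell's offset slots; collisions are counted and reported.

## Decoding and evaluation

Centers are 3×3 local maxima of the center heatmap with score ≥ 0.05,
top 30 per image (ties broken by (row, col)). Both offset fields are
read at the center cell: the part-point displacement is already baked
into the sampled features, so the regressed fields live on the center's
cell (reading the second hop at the part-point cell is available behind
`off2_at_part`). Flip testing decodes the mirrored image, un-mirrors
(x → W−1−x), applies the schema's bilateral permutation, matches poses
to the direct pass by center distance (16 px default) and averages
matched pairs. Fusion happens at pose level; when an inference resize is
active the mirror axis is taken in original coordinates, which is exact
at scale 1 and approximate otherwise.

Evaluation is COCO-style OKS AP/AR. OKS uses per-keypoint constants
k_i from the schema; **no per-keypoint constants are published for
these species**, so built-ins use a uniform k = 0.1 and metrics are
self-consistent rather than comparable across toolchains. The object
scale s is the square root of the tight bbox area of labeled keypoints
padded 10% per side. AP interpolates precision on the 101-point recall
grid; AR is recall at 30 detections, both averaged over OKS thresholds
0.50:0.05:0.95. Matching is greedy one-to-one, best score first; every
GT with at least one labeled keypoint is matchable (no crowd regions).

## Synthetic scenes

The generator emulates the dense-occlusion regime of in-orbit
behavioral imaging and is the package's only data source; every
annotation is exact by construction:

- worm: spline centerline through random turning angles (±1.2 rad,
  self-coiling allowed), tapering tube body, keypoints at arclength
  fractions {0, .25, .5, .75, 1};
- fish: body ellipse + articulated tail with a random bend (±0.9 rad),
  10 keypoints at anatomically plausible loci;
- fly: head/thorax/abdomen ellipses, two swept-back wings, six
  two-segment legs, 26 keypoints.

Later-drawn instances occlude earlier ones; a keypoint whose 3-px disc
is ≥ 60% covered by later foreground is downgraded to v=1.
`occlusion_prob` controls how often an instance is deliberately placed
near an earlier one (0 enforces clear separation, so every keypoint
stays v=2). Optional degradations: Gaussian blur, additive glare,
textured background. One integer seed drives a `SeedSequence` split
into per-instance streams, so adding instances does not perturb
earlier ones.

What the generator does **not** model: photometric realism, body
texture, motion blur from locomotion, camera noise statistics, and true
3D occlusion geometry. Tests passing on these scenes therefore
demonstrate the correctness of the pipeline (encoding, network
mechanics, decoding, metrics) and its trainability, not performance on
real microscopy footage.

## Numerical and design choices

- The whole tensor stack (reverse-mode autodiff, conv via im2col,
  deformable conv, bilinear warp with gradients to features *and*
  coordinates, MHSA, BatchNorm/LayerNorm, Adam) is implemented in
  NumPy float64 inside the package; gradients are verified against
  central differences in the test suite.
- The fly schema's keypoint names and part memberships are a documented
  plausible assignment (head 3, antennae 2, thorax 1, abdomen 4, wings
  2×2, three leg-pair groups of 4 — 9 parts, 26 keypoints); the true
  annotation key is only published pictorially. Users can override via
  schema files. The same caveat applies to the zebrafish names.
- Ground-truth instance centers are the centroid of labeled keypoints
  (robust for limbless midline skeletons); bbox-center is selectable
  per schema.
- MHSA uses 4 heads by default and projected Q/K built from
  token + type-embedding (the literal unprojected reading is available
  via `sgl_raw_qk`); attention scaling is per-head √d.
- Adaptive-fusion weights are scalar per (part, level), softmax
  normalized; per-channel or spatial alternatives were considered and
  rejected as underdetermined by the available description.
- Heatmap head biases initialize to −4.6 (prior probability ≈ 0.01),
  the standard focal-loss detector initialization; without it the
  background term dominates early training.
- The Part Perception module reads the raw stride-4 level; the default
  fusion set is strides {4, 8} with CT2 + a_add, and the SGL default is
  1 layer, FFN 512, type embeddings on — the configuration reported
  best in the ablations this design follows.
- Two learning-rate schedules ship because the training protocol this
  reimplements describes both: ×10 step drops at epochs {90, 120} and
  cosine annealing η_min + ½(η_0−η_min)(1+cos(t/T·π)) with
  η_0 = 1.25e-4, η_min = 1e-5. Cosine is the default.
- Augmentation: rotation ±30°, scale 0.75–1.5, translation ±40 px
  (input pixels), hflip p=0.5, applied about the image center with
  mean-fill borders.

## Problem sizes used by the shipped experiments

The library trains at any size; the bundled tests and the
reproduction script run CPU-sized problems chosen to exercise every
component end to end: 128×128 scenes, a light backbone
(8/16/24/32 channels), C=16 part features, FFN 32, and an overfit run
of 20 worm scenes for 200 epochs (batch 5, cosine 2e-3 → 1e-4, no
augmentation) that must reach AP50 ≥ 0.9 on its training scenes —
an end-to-end trainability check, not a benchmark. Encode→decode
round-trip checks use 100 scenes per species. Full-scale presets
(512/640 input, batch 16/10, 140/280 epochs, milestones 90/120 and
230/260) mirror the published protocol and are practical on GPU-class
hardware with an HRNet-grade backbone plugged into the backbone
contract.

## Known limitations

- No identity tracking, no temporal modeling, single category per
  image.
- Center-cell collisions (two instances quantizing to one stride-4
  cell) drop the earlier instance's offset supervision and merge
  detections; collisions are counted during encoding.
- The deformable convolution is v1 (no modulation masks).
- CPU-only; the NumPy engine favors clarity and testability over
  throughput.
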