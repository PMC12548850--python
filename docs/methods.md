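# Methods

## Problem and approach

Detecting ripe fruit in orchard imagery from RGB alone is brittle: lighting
shifts distort color, and foliage clutter mimics fruit contours.  This
package implements a multimodal alternative: an RGB-D camera's color frame,
depth raster, and accumulated point cloud are fused into a single
8-channel raster `[R, G, B, F, D, X, Y, Z]` — appearance, an engineered
key-feature band, metric depth, and per-pixel 3D coordinates — and a
single-stage detector consumes that stack through a widened input layer.
The package's experiments compare detector quality across input-channel
configurations under an otherwise identical training budget.

## Projection model

Cloud-to-image alignment is a pinhole chain: an extrinsic rigid transform
(identity for a single fixed rig), perspective projection
`u = x·fx/z + cx`, `v = y·fy/z + cy`, a horizontal mirror flip
`u' = mw − 1 − u` (the sensor's projection is a mirror mapping), and
additive per-dataset offsets `(uo, vo) = (u' + xoffset, v + yoffset)`.
Offsets default to `(0, 0)` and are calibration constants loaded from the
config; no lens distortion is modeled.  Pixels are 0-based
`(column, row)`; in-image membership uses half-open bounds
`[0, mw) × [0, mh)`.  Continuous coordinates are kept throughout the
math; rounding (half-away-from-zero) happens only at rasterization.
Points landing outside the raster are dropped and counted, never clamped
— clamping would corrupt the XYZ bands.  The chain is numerically tight:
back-projected pixels re-project to within 1e-6 px.

## Point-cloud cleaning

Accumulating ~30 near-simultaneous frames densifies the cloud but
multiplies noise.  Cleaning is: (1) exact-duplicate collapse during
accumulation (bitwise coordinate equality; near-duplicates are left to the
voxel filter); (2) voxel downsampling with 5 mm cells (the cell size is
not dictated by the data recipe, so it is config-exposed; 5 mm matches the
depth quantization scale), keeping the first point per cell in input
order, with cell index `floor(coord / size)` anchored at the origin;
(3) statistical outlier removal: for each point the mean Euclidean
distance `d_i` to its k = 30 nearest neighbors (query point excluded),
with removal threshold `mean({d_i}) + 2·std({d_i})` taken globally over
all points — a 2-sigma variant of the 3-sigma rule.  The wording of the
underlying recipe is ambiguous between per-point and global statistics;
the global formulation is used because it matches the standard
statistical-outlier-removal filter and makes the threshold a population
property.  A KD-tree serves the kNN queries; tests pin the removal set to
an O(N²) brute-force oracle.  Note that a bounded uniform grid is *not*
neighborhood-uniform: corner points have wider neighborhoods and are
legitimately flagged at 2 sigma.

"Filling empty regions with zeros" is meaningful only on the raster, not
on a point set: unsampled pixels of the D/X/Y/Z bands hold 0, which the
detector can learn to treat as no-data.

## Key-feature band

Two cues are fused into the F band: the R−G chroma difference (computed in
widened integers, negatives clipped to zero — green-dominant pixels carry
no red-fruit signal), and the magnitude of the 4-neighbor Laplacian of the
BT.601 grayscale image.  Both maps are min-max normalized per image
(a constant map normalizes to zeros, avoiding division by zero) and
combined as `F = 0.6·chroma + 0.4·edge`.  The Laplacian variant and
grayscale weights are not dictated by the recipe; the 4-neighbor kernel
and BT.601 are the common defaults and both are selectable.  Clipping
negatives before normalization (rather than after) is a documented choice:
it keeps the chroma band a pure red-excess signal.

## 8-channel composition

Depth rasters are Z16: 16-bit unsigned millimeters, 0 = no-data, valid
range (0, 4] m; decoding divides by 1000 and zeroes anything outside the
range.  The XYZ bands are produced by projecting every cleaned cloud point
through the full chain and storing its coordinates at the hit pixel;
collisions resolve nearest-depth-wins (occlusion-correct).  The container
format is a raw little-endian float32 blob plus a JSON sidecar (shape,
dtype, band names, calibration and preprocessing provenance) — lossless
and readable from any language.  Raw meters are stored; normalization is a
training-time view only: R, G, B, F in [0,1], D and Z divided by the 4 m
sensor range, X and Y by configurable scene half-extents (defaults 1.0 m
and 0.6 m, the synthetic rig's field of view at working distance).

## Anchor optimization

Anchor adequacy uses the worst-dimension size ratio
`r = max(w/wa, wa/w, h/ha, ha/h)`.  AAT is the per-box mean fraction of
anchors with `r` under the threshold; BPR the fraction of boxes whose best
anchor beats it.  The threshold (4.0) and BPR cutoff (0.98) follow common
single-stage detector practice since the recipe names the gate but not its
constants; both are config-exposed.  When the stock anchor list fails the
gate, k-means re-estimates k centroids on axis-normalized (w, h) label
dimensions — Lloyd iterations (30 by default) from a seeded draw of k
distinct boxes, written in-house so the per-iteration objective is
observable (it is nonincreasing, and on small instances reaches the
exhaustively enumerated optimum) — followed by an elitist mutation-only
genetic search: multiplicative per-dimension factors near 1
(probability 0.9, spread 0.1, 1000 generations by default), candidate kept
only on fitness improvement.  Fitness is the mean of `1/r_best` counted
only when `r_best` beats the ratio threshold, so degenerate shrunken
anchors score zero.  The exact fitness form is a reconstruction from a
qualitative description; the threshold gate implements its "sieve out
overly diminutive anchors" role.  `check_anchors` returns whichever of
{refined, stock} scores the higher BPR, so it never regresses.

## Detector

The detector is deliberately compact, because the quantity under study is
the input-layer channel configuration, not architecture: a 6×6 stride-2
convolution with m ∈ [3, 8] input channels and 32 filters (parameter
count `6·6·m·32 + 32`), three 3×3 conv blocks (48, 64, 64 channels, leaky
ReLU, overall stride 8), and a single-scale anchor head emitting
objectness and four box offsets per anchor.  Changing m touches only the
first layer.  The network and its backward pass are written directly in
NumPy (im2col convolutions, explicit gradients), which keeps the whole
study runnable on one CPU core.

Training is SGD: batch 4, initial learning rate 0.01 with linear decay by
a factor of 0.01 over the run, momentum 0.937 (0.8 throughout the warm-up
epochs), weight decay 5e-4 on weights only, 3 warm-up epochs during which
the bias learning rate starts at 0.1; within warm-up the per-iteration
learning rates ramp linearly to the schedule, and gradients are globally
norm-clipped at 10 — both standard stabilizers for small-batch detector
training.  The loss is a focal objectness BCE (alpha 0.25, gamma 2)
normalized by positive count, plus MSE box regression in sigmoid space
against a bounded decode (center offset `2σ−0.5` cells, size `(2σ)²`
anchor units).  Ground truth is assigned to the center cell plus its two
nearest neighbor cells, and to every anchor within the ratio threshold.
There is a single class, so no separate classification term.

Evaluation: predictions above confidence 0.25 are NMS-filtered at IoU
0.45, then greedily matched one-to-one to ground truth in descending
confidence at IoU ≥ 0.5 (the conventional threshold; the recipe does not
state one).  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), all in
percent; zero denominators report 0 with a warning.

## Synthetic scenes

No orchard dataset ships with the package, so a generator renders
stand-in scenes: red quasi-spherical fruits (3–6 cm radius, 0.6–2.0 m
depth) over a mottled green background plane (2.4–3.4 m) with elliptical
green/brown clutter for leaves and branches, a per-scene global
illumination gain in [0.5, 1.3] spanning a dawn-to-noon brightness spread,
and with probability 0.35 a foreground leaf partially covering each
fruit.  The rig is a quarter-resolution analogue of an 848×480 RGB-D
camera (212×120, fx = fy = 200 px).  Rendering goes through one z-buffer;
the Z16 depth raster is its millimeter quantization and the point cloud is
the back-projection of that quantized raster through the full (mirrored)
chain, so depth, cloud, and image are mutually consistent by construction
(D and Z bands agree to < 1 mm).  Visible fractions are computed by
z-buffer pixel counting; a fruit more than 80% obscured is omitted from
the labels, mirroring orchard annotation practice.  Boxes cover the
fruit's full projected extent clipped to the image.

What the generator does not emulate: photorealistic texture, specular
highlights, IR-stereo speckle and edge artifacts, correlated depth
dropout, motion blur.  Passing tests therefore demonstrate the pipeline's
internal consistency and the direction of the channel-configuration
effect under controlled conditions — not field performance on real
orchards.

## Scaled-down channel experiment

The directional experiment trains the same compact detector on the same
200 generated scenes (70/10/20 split, ≈140 training images) for 15
epochs per configuration — sized so the full three-seed comparison runs
in minutes on one CPU core — once with 3-channel RGB input and once with
the 8-channel RGB+XYZ+D+F stack, for three seeds, and compares median
test F1.  Anchors are re-estimated per run by k-means (k = 3) on the
training labels.  The package asserts only the ordering (8-channel ≥
RGB), not absolute scores: a from-scratch compact network trained for
minutes is not comparable to a full pretrained detector, but the ordering
mirrors the multimodal claim the pipeline exists to support.  At this
budget the 8-channel configuration's margin comes mostly from recall on
occluded and dim fruit, where depth and coordinate bands disambiguate
what RGB alone cannot.

## Numerical and degenerate-input conventions

- Projection rejects z ≤ 0 (behind camera); `project_cloud` counts and
  drops such points.
- Voxel boundary ties go to the lower-index cell (floor semantics).
- Outlier removal on clouds with N ≤ k returns the cloud unchanged with a
  warning — the neighborhood statistic is undefined.
- Min-max normalization of a constant map yields zeros.
- Empty clouds rasterize to all-zero bands with a warning; an empty label
  list is a valid scene.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); scene generation is a pure function of
  (parameters, intrinsics).

## Known limitations

- The detector is a compact stand-in; absolute P/R/F1 on synthetic scenes
  are not comparable to full-scale detectors on real data.
- The mirror flip is implemented as specified without a hardware
  justification; rigs that do not mirror can disable it by composing the
  flip into the offsets/extrinsics.
- Training augmentations (rotation, scaling, cropping, color jitter,
  noise) are not applied in the scaled-down experiment; the generator's
  per-scene illumination and geometry variation plays that role at this
  scale.
- PLY I/O supports XYZ + RGB only (no normals or custom properties).
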