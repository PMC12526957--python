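# Methods

## Scope and coordinate conventions

rootscape measures root-system architecture from single 2D views and
aggregates many views of one plant into an accession-level phenotype.
All modules share one convention: 0-based `(row, col)` indexing with the
origin at the top-left, so the row index is depth below the crown; all
band intervals are half-open; images are float intensities in [0, 1]
(8-bit / 255, 16-bit / 65535, RGB collapsed by ITU-R 601 luminance,
chosen because it is the common broadcast-standard conversion). View
identity (accession, replicate, turntable angle) travels in the filename
and is recovered with a user-supplied `{accession}/{replicate}/{angle}`
pattern; nothing is read from EXIF.

## Segmentation

Two routes produce the binary root mask.

*Otsu route.* Polarity is normalized first: the Otsu majority class is
taken to be background, and the image is inverted if that majority is
bright, so the pipeline always sees bright roots. The background is then
estimated by grayscale morphological opening with a disc (default radius
15 px — wider than any root stroke, narrower than illumination
gradients), subtracted and clipped; a global Otsu threshold binarizes
the residue. This route needs no training and is the CLI default.

*Random-forest route.* A `RootPixelClassifier` (scikit-learn estimator)
classifies pixels from a small feature stack: raw intensity plus, at
each scale σ ∈ {1, 2, 4} px, Gaussian-smoothed intensity, gradient
magnitude, the smaller Hessian eigenvalue (a ridge detector, strongly
negative on thin bright curvilinear structures) and local variance —
1 + 4 × 3 = 13 planes. Training consumes image/mask pairs (in practice
the synthetic library), subsampling a balanced ≤ 5,000 pixels per class
per image; the forest has 100 trees and a fixed seed, so training is
deterministic. The feature configuration is stored with the model and
re-validated at predict time; serialized models carry a format-version
tag and a mismatch refuses to predict. Defaults (scales, tree count,
sample budget) are package choices exposed in the estimator's
parameters.

Mask cleanup removes 8-connected components below `min_size` (strictly
smaller), optionally fills interior holes and keeps the largest
component; the operation is idempotent.

## Skeleton graph

Masks are thinned to a 1-px 8-connected centerline. Raster thinning is
not symmetric under rotations or mirror flips, which would make length
and tip measurements depend on how the plant happened to be framed; we
therefore thin a canonical representative of the mask's symmetry orbit
(the lexicographically smallest of its 8 axis-aligned transforms) and
map the skeleton back. Skeleton-derived measurements are then exactly
invariant under 90° rotations and flips by construction.

Endpoints (1 skeleton neighbor) and isolated pixels become nodes;
junction pixels (≥ 3 neighbors) form small 8-connected clumps where
strokes cross, and each clump is merged into a single junction node at
its most central pixel. Maximal degree-2 chains between nodes become
edges; a pure cycle gets one anchor node with a self-edge. Measurements:

- **length** — Σ over chain steps, 1 per axial step, √2 per diagonal.
  Chain pixels interior to junction clumps are not traversed, so length
  is biased low by roughly the clump diameter (≈ stroke width) per
  junction; on the synthetic benchmark this stays inside the 5%
  recovery band.
- **tip_count** — degree-1 nodes, excluding the endpoint nearest the
  top-center of the root bounding box (the cutting's attachment, not a
  biological root tip). The exclusion is optional.
- **diam_mean** — mean over skeleton pixels of 2·EDT − 1, where EDT is
  the Euclidean distance transform of the mask; the −1 makes odd-width
  bars report their true pixel width. Floor of 1 px.
- **directionality** — each edge chain is split into chords every k = 5
  chain pixels (per-pixel directions are quantized to multiples of 45°,
  chords smooth this); each chord contributes its absolute angle from
  the downward vertical, weighted by chord length; the mean lies in
  [0°, 90°].

## Layered descriptors

All banded descriptors operate on the root bounding box rather than the
full frame, making them invariant to framing and zoom; empty bands
report 0 so vectors have fixed length. Band edges use equal integer
heights with the last band absorbing the remainder.

The default registry reproduces the published channel budget of 16
macrophenotypes + 96 microphenotypes: 30 horizontal + 30 vertical
crossing layers, 10 `coord_x` + 10 `diff_x` layers, 4 `rect` strata and
a 12-rung `ellips` ladder (30 + 30 + 10 + 10 + 4 + 12 = 96). The 30/10/4
counts follow the published protocol; the vertical-crossing layer count,
the `diff_x` layer count and the ellipse ladder size are package
defaults chosen to complete the printed totals, and every count is
configurable through the registry. Macro summaries of the layered
blocks: `ellips` = coverage of the mid-ladder ellipse (rung ⌈K/2⌉),
`rect` = top-stratum share, `coord_x` = mean over layers, `diff_x` =
mean over layers 1..L−1. Whether `coord_x` is a band width or a boundary
coordinate is not fixed by the protocol; we use the normalized band
width, with `diff_x` as its first difference so positive values mean a
root system opening with depth.

The ellipse ladder centers on the apex (centroid of the topmost
foreground row) with base semi-axes (W/2, H) from the bounding box, and
rescales by the maximal normalized radius so the last rung always
covers the root exactly — hence the final channel is 1 by construction
and the profile is non-decreasing.

Convex hull area uses Qhull on pixel centers with the shoelace value of
the hull polygon; collinear point sets report 0. The test suite and
acceptance script verify it against an independent gift-wrapping +
shoelace oracle.

A single-pixel root has a skeleton with no edges; `directionality` is
reported as 0 for such degenerate masks inside the full trait vector
(the standalone function raises instead).

## Multiangle aggregation

The accession phenotype is the arithmetic mean (and population standard
deviation) over all replicate × angle vectors, with every view weighted
equally — replicates are not nested, since per-replicate view counts are
equal by design and any missing angle is logged. Pearson correlations
between channels are computed over accession means; constant channels
yield undefined entries reported as NaN with a warning. The suggestive
GWAS threshold is 1/n for n effective independent tests (1.56 × 10⁻⁶ at
n = 639,988).

## Synthetic root simulator

The generator is the package's source of labeled training data and its
measurement test bed. Each axis is a 3D polyline grown in fixed steps
(default 4 px, 40 steps): at every step the direction is rotated by
N(0, σ_θ) about a random perpendicular axis (tortuosity, default 0.15
rad/step) and blended toward the downward vertical with weight g
(gravitropism, default 0.3). Laterals arise as a Poisson process along
the parent (default 1 branch per 100 px), leave at N(50°, 12°) from the
parent direction, carry radius × 0.7 per order (taper) and half the
parent's steps, to a maximum order of 3. A short vertical stem (10 px)
sits above the crown so that, with several primaries meeting at one
point, the skeleton has exactly one non-tip endpoint for the crown
exclusion to remove. Axes stop at a radial/depth bound inside the
canvas, so every rotation of the system stays in frame. Defaults
emulate a ~40-day cutting in a 256² px frame; the library builder
samples n_primary ∈ [2,5], steps ∈ [30,50], tortuosity ∈ [0.05,0.25],
gravitropism ∈ [0.2,0.6], branch rate ∈ [0.5,2], radius ∈ [1.5,2.5]
uniformly per image.

Rendering rotates the polylines about the vertical axis by the
turntable angle, projects orthographically (centered on (w−1)/2 so
θ and θ+180° rasterize as exact mirrors), and stamps discs of the axis
radius along the densified projected path; the image adds optional
Gaussian blur (default σ 1 px), additive noise (default σ 0.05) and
either polarity.

*Projected ground truth.* An orthographic projection foreshortens
out-of-plane segments, so the 3D arclength is not the right oracle for
anything measured on a view. Each rendered view therefore records its
own projected polyline length, tip count and per-row crossing counts
(the last computed by an explicit run-walking loop that shares no code
with the descriptor route). Recovery tests compare against these
projected values.

*Clean-recovery regime.* Exact tip and crossing recovery is only
well-posed when distinct strokes do not merge in projection. With
`no_overlap=True` the simulator resamples (seeds derived from the spec
seed) until, at the checked angles, no two axes without a legitimate
attachment come within the sum of their stroke radii + 2 px, contact
near attachments is confined to a zone around the attachment point,
every distal tip clears other axes, and no axis touches itself at
distant arclengths. The recovery benchmark uses this regime with planar
growth (azimuths confined to the image plane), stroke width 3 px, two
primaries, branch rate 0.8 and order ≤ 2.

## What the synthetic data does and does not show

The simulator emulates thin curvilinear strokes with branching
topology, realistic multiangle consistency, blur, noise and either
polarity. It does not emulate soil or agar texture, specular highlights
on the tube, root hairs, water-line artifacts or overlapping
root/condensation clutter — so passing recovery and segmentation tests
demonstrates correctness of the measurement chain, not field-readiness
of any particular threshold on real photographs. Segmentation F1 on
held-out synthetic images (≈ 0.98) should be read as an upper bound on
real-image performance.

## Numerical choices and problem sizes

Determinism: every stochastic component takes an explicit seed;
`numpy.random.default_rng` sequences are derived from (seed, stream)
pairs, and the RF classifier runs single-threaded with a fixed
`random_state`. Tests and the acceptance script use 20 recovery roots,
20 training + 10 held-out segmentation images, and 100-mask property
sweeps — sizes at which every check completes in seconds to a couple of
minutes on one CPU while keeping the Monte-Carlo margins (recovery
rates at 100% against a 90% bar; F1 ≈ 0.98 against a 0.90 bar) wide.

## Known limitations

- Skeleton length underestimates inside junction clumps (see above) and
  at stroke tips (thinning retracts by about the stroke radius).
- No root-order classification (primary vs lateral) and no time series.
- No physical-unit calibration beyond a scalar mm/px multiplier applied
  downstream by the user.
- The on-disk layout of the original acquisitions is not recoverable;
  the filename-pattern parser is the interchange contract.
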