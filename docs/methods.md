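# Methods

This note records how each stage of the pipeline works, the tunable
parameters and their defaults, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate and calibration conventions

All rasters use `(row, col)`, 0-based, row 0 at the top; roots grow toward
larger rows, "ascending" means decreasing row.  Calibration is a single
`mm_per_px` scalar (default 1.0, i.e. trait values in pixels; a 300-dpi
scan is 0.0847 mm/px).  Tomography stacks carry `voxel_edge_mm`.

## Stitching

Keypoints are detected with scikit-image's SIFT on the luminance channel of
both halves, matched with cross-checked descriptor matching (ratio 0.9),
and a projective homography is estimated by RANSAC (`min_samples=4`,
residual threshold 2 px, 1000 trials, seeded — the estimate is
deterministic for a fixed seed).  The contract is the inlier reprojection
bound, not the detector brand.  Merging warps the bottom half into the top
frame on the union bounding box and averages the overlap band; averaging
avoids visible seams on flatbed scans, whose exposure is stable between
halves.  Exposure equalization, lens-distortion correction and >2-tile
mosaics are out of scope.  Homographies are reported in `(row, col, 1)`
homogeneous convention.

## Segmentation

Otsu's threshold is computed on the trimmed 256-bin histogram (exactly the
argmax of between-class variance over every split point; verified against
an exhaustive search in the tests).  Foreground is the class on the root
side: `auto` polarity picks the brighter class, matching white-on-dark
rhizotron scans; `dark` inverts for setups where roots are the dark class.
Connected components smaller than `min_object_px` (default 20 px at
300 dpi, 8-connectivity) are removed — real scans carry debris; set 0 to
disable.  No despeckling precedes thresholding.

## Skeletonization and point classification

Thinning uses scikit-image's `thin` (iterative deletion of simple points to
convergence), followed by a cleanup pass that deletes simple points from
any residual all-active 2×2 block, so the output is strictly 1 px wide.
Foreground component count (8-connected) and hole count (4-connected
background) are preserved; the tests verify this on random blob masks.

Each skeleton pixel is classified by the cyclic change count C of its 8
neighbors (out-of-image neighbors count as inactive): C = 0 isolated, C = 2
endpoint, C = 4 normal, C ≥ 6 junction.  C equals twice the number of
maximal runs of active neighbors; the single degenerate case is the
all-active ring (one cyclic "run" but zero transitions), which cannot occur
on a 1-px skeleton.  Reading endpoints as C = 2 deliberately admits root
tips whose two active neighbors are mutually adjacent — thinned tips of
thick roots often end that way.

## Ascending Path

Anchors of each skeleton component: start = lowest active pixel,
breakpoint = highest, ties broken toward the smaller column.  The walk
marks pixels visited; at junctions each unvisited branch is scored by a
greedy look-ahead of L pixels (default **L = 15**) and the branch whose
look-ahead endpoint has the smallest row wins; a single-pixel "up" decision
would be hostage to skeleton jitter.  Ties break by smaller column
deviation from the current heading, then smaller column — deterministic.
Dead ends trigger depth-first backtracking (visited marks persist), so the
traversal is total on trees; on pathological loops exhausting every branch
raises an explicit error.  Components below `min_component_px` (default 10)
are ignored as debris.  One path is extracted per component; an optional
`iterative` mode re-anchors tall residual pieces of the same component as
further adventitious roots — an extension for merged root systems, off by
default.

## Radius profile and reconstruction

Radii are measured from each path pixel perpendicular to the local tangent,
stepping in unit increments and counting foreground pixels until the first
background pixel — 1-px accuracy by construction.  The tangent is estimated
over ±3 path steps: ±2 proved too short to average out the 1–2 px
centerline wobble thinning introduces at junctions, which tilted the scan
off the lateral and split its peak across both sides.

Peak handling per side:

* baseline — running median, window **61** positions.  The window must
  exceed twice the widest expected peak; nodule bulges are ~25 px wide
  along the path, so a 31-window median would ride up inside them.
* a peak exists where the radius exceeds baseline + **Th1** (default 1 px);
  its span extends outward to the baseline crossings (width at base), so
  the flanks are treated as part of the excursion.
* classification: *lateral* if width ≤ **12 px** and height ≥ **3 px**;
  *nodule* if width > 12 px and area ≥ **40 px²**; anything else is a
  sub-threshold bump and ignored.  These cutoffs are calibrated on the
  synthetic generator at the 1 mm/px scale and are exposed in
  `PeakParams`.
* suppression — within each span (padded by 2 positions) radii are replaced
  by a linear interpolation between the just-outside values, clamped to the
  band [baseline − Th1, baseline + Th1]; peaks are re-detected and the step
  repeats until none remain (cap 10 iterations).  The clamp band is one
  consistent reading of "between the two thresholds around a peak"; the
  reported upper threshold Th2 = median + 3·MAD of the radii is
  diagnostic.  Total area above baseline is non-increasing across
  iterations.

Reconstruction stamps, at every path position, the cross-section segment of
length r_left + 1 + r_right using the filtered radii, then intersects with
the 1-px dilation of the original mask (no invented foreground).  Stamp
centers follow a median-11 smoothing of the path and fractional radii are
floored: both choices keep junction-zone cross-sections from spilling onto
lateral pixels (≤ 0.8% of true lateral area across the fixture suite)
without touching the reported path or diameter profile
d(i) = r_left(i) + r_right(i) + 1.

## Traits

* **ARL** — geodesic path length (1 per direct step, √2 per diagonal) ×
  mm_per_px.  A `pixel_count` flag reproduces literal pixel counting, which
  overestimates diagonal segments.
* **DIA** — mean diameter and apical diameter (mean over the K = 20
  positions nearest the tip, i.e. path start).  The unbranched apical zone
  is the geodesic distance from the tip to the first lateral peak.
* **LRN / LLRL** — lateral skeletons are the components of
  (skeleton − path) touching the path; a component counts when its
  attachment index falls within 10 positions of a lateral-class peak.
  Lengths run from the attachment to the farthest pixel (Dijkstra with √2
  diagonals) plus the attachment step and the end-cap correction (the mask
  half-width at the far tip, where thinning stops short of the boundary).
  LLRL ("longest lateral root length") and TNN/PNN ("total"/"on-primary
  nodule number") are acronym readings of ours; with measurement along the
  adventitious path only, TNN = PNN.  Nodule counting is optional — void
  for grapevine, retained for legumes.
* **Projected area** — foreground count × mm_per_px²; exact on noiseless
  masks.
* **growth_series** — per-timepoint table with ratios against the previous
  *present* timepoint; missing timepoints are flagged, never interpolated.

## Tomography

Preprocessing: 3×3 median despeckle; outlier removal replaces pixels
deviating from the radius-2-disc median by more than 50 (gray levels) with
that median; normalization divides by the pixel-wise mean open beam.  The
order matters: outliers are clipped before division so gamma spikes cannot
survive as transmission > 1.

Quantification binarizes at an explicit threshold (roots are the
low-transmission class) or, with `auto`, Otsu on the pooled stack
histogram.  `auto` assumes a bimodal histogram: on a stack that also
contains open beam around the sample holder it will split beam vs. sample,
so pass an explicit threshold between the sand and root modes there.
Voxels are counted per slice and in total; fraction = count / stack size;
RSV = count × voxel_edge³ / 1000 cm³.  An optional 26-connected minimum
component size mirrors "particle analysis" speck rejection.  Stacks are
consumed at full resolution (no 50% rescale); tomographic reconstruction
and ring-artifact filtering happen upstream.

## Synthetic generator

`render_root` strokes a spline through the trunk control points, rasterizes
it into an 8-connected Bresenham chain and stamps discs (radius ρ, so the
true width is exactly 2ρ + 1 on a vertical trunk); laterals are straight
strips at an insertion angle measured from the *local trunk tangent* (real
laterals insert relative to the parent root, and an angle fixed in the
image frame can degenerate to near-parallel geometry on curved trunks);
nodules are ellipses centered on the trunk.  Intensities: background 20,
root 200 (8-bit), optional Gaussian noise, blur and smooth background
texture (the latter gives keypoint detectors something to match in
split-pair fixtures).  All randomness comes from the spec seed; rendering
is byte-identical for identical specs.  Ground truth includes the mask,
ordered trunk/lateral skeleton chains, per-pixel true widths, branch
points, lateral-only pixel sets and closed-form trait values.

The 12-spec fixture suite (`fixtures/root_specs.json`) spans bare,
five-lateral, curved, dense-lateral, nodule, noisy, tapered, two-root and
long-lateral cases at 400×260 px — a deliberately scaled-down stand-in for
144-Mpx rhizotron scans; every algorithmic step is resolution-independent,
and the methods' accuracy statements are per-pixel.

What the generator does **not** emulate: soil texture and moisture
gradients, root overlap and crossing loops, root hairs, intensity falloff,
curved laterals, or multiple adventitious roots sharing one connected
skeleton.  Passing tests demonstrate correctness of the algorithmic chain
under the stated geometry, not robustness to every field condition.

`render_tomo_stack` fills a cylindrical sample region with sand-level
transmission (0.8), inserts wobbling root tubes with voxel values uniform
in [0.2, 0.4] and open beam (1.0) outside the cylinder.
`render_radiograph` produces raw-count frames with open-beam band, sand and
root columns, gamma spikes and matching open-beam frames.

## Benchmark problem sizes

The seeded benchmarks (`rootascent.benchmarks`, also driven by
`scripts/acceptance.py`) use 10 noiseless ~350-px roots for the diameter
figure, 20 split pairs at 320×240 for stitching, and the 12-spec suite for
path/trait recovery — sizes chosen so the whole validation runs in about a
minute on one core while keeping every per-pixel accuracy statement
meaningful.  In the diameter benchmark, positions are compared against the
nearest truth-skeleton pixel; positions within 5 px of a branch point, on
the rounded end caps (within trunk radius + 2 of a chain end), within 3
positions of a discrete width step, or farther than 1.5 px from the truth
chain are excluded — at those places a 1-px-scale "true local width" is
not defined.  The diameter is taken from the suppressed profile, i.e. the
DIA the method actually reports after reconstruction.

## Known limitations

* The Ascending Path assumes laterals do not locally out-climb the trunk at
  a junction; a lateral that rises more steeply than the parent for ≥ L
  pixels would capture the walk.
* Skeleton centerline wobble at junctions (±2 px) propagates a few-percent
  overestimate into ARL.
* LLRL is accurate to ~10% for laterals ≳ 30 px; shorter laterals lose
  proportionally more to junction and tip effects.
* Peak-classification defaults are scale-bound (calibrated at 1 mm/px);
  re-derive them for other magnifications via `PeakParams`.
* `auto` thresholding on three-class tomography stacks picks the wrong
  split (see Tomography above).
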