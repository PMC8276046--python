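# rootascent

Automated phenotyping of root system architecture (RSA) from 2D root images
and neutron-tomography stacks.

Grapevine — like most plants propagated from cuttings — forms *adventitious*
roots directly from the stem, with *lateral* roots branching off them.
Quantifying their architecture in rhizotrons (thin, flat containers that
constrain roots to a plane for scanning) requires separating each
adventitious root from its laterals in the image, which most root-imaging
tools only manage semi-automatically.  `rootascent` implements a fully
automatic pipeline:

1. **Stitching** — a rhizotron is taller than a scanner bed, so each
   acquisition is two overlapping halves; scale-invariant keypoints are
   matched and a homography estimated by RANSAC merges them (typical
   residual ≲ 1 px).
2. **Segmentation** — Otsu's threshold `t* = argmax_t ω₀(t)ω₁(t)(μ₀(t)−μ₁(t))²`
   on the gray-level histogram splits bright roots from the dark substrate.
3. **Skeletonization & point classification** — the mask is thinned to a
   1-px skeleton by topology-preserving (homotopic) erosion.  Each skeleton
   pixel P is classified from the cyclic change count of its 8 neighbors
   P1…P8 (direct P2, P4, P6, P8; diagonal P1, P3, P5, P7):
   `C = Σᵢ [Pᵢ ≠ Pᵢ₊₁]` = 2 × (number of branches meeting at P), giving
   endpoints (C = 2), normal points (C = 4) and junctions (C ≥ 6).
4. **Ascending Path** — the adventitious skeleton is traced from the lowest
   skeleton point upward, always taking the most ascending branch at every
   junction (with a short look-ahead and backtracking), to the highest
   point.
5. **Reconstruction** — left/right radii are measured perpendicular to the
   path with 1-px accuracy; lateral roots and nodules appear as peaks in
   the radius profile, classified by height, width and area, and suppressed
   by an iterated filter clamped between two thresholds (baseline ± Th1)
   around the running-median baseline.  The result is the adventitious root
   alone, with its local diameter profile d(i) = r_left + r_right + 1.
6. **Traits** — ARL (adventitious root length), DIA (local/apical
   diameter), LRN (lateral root number), LLRL (longest lateral root
   length), TNN/PNN (nodule counts), projected root area, ARN, plus growth
   ratios across a weekly time series.

A separate module quantifies **root system volume (RSV)** from neutron
tomography: radiographs are despeckled, gamma-ray outliers removed (radius-2
disc median, threshold 50) and normalized by the open beam into transmission
images (sand ≈ 0.8, roots 0.2–0.4); a reconstructed stack is binarized and
root voxels counted per slice and in total.

Because no public dataset accompanies this kind of experiment, the package
ships a **synthetic generator** (`rootascent.synth`) that renders root
images, split scan pairs and tomography stacks with exact ground truth
(masks, skeletons, widths, trait values), used by the entire test suite.

## Worked example

```sh
rootascent simulate root --out root.png --seed 4   # or bring your own scan
rootascent run --out out/ root.png
```

On the bundled five-lateral synthetic root this prints:

```
 arn     arl_mm  dia_mean_mm  dia_apical_mm  unbranched_apical_mm  lrn   llrl_mm  tnn  pnn  projected_area_mm2
   1 358.284271          7.0            7.0             83.414214    5 43.355339    0    0              3132.0
```

Reading: one adventitious root (`arn`), 358.3 mm long at the default
1 mm/px calibration (`arl_mm`; the generator's true trunk is 350 mm — the
excess is junction-zone jitter of the skeleton), constant 7 mm local
diameter, five laterals detected (`lrn`, exactly the number generated), the
longest 43.4 mm (true 46.0 mm), an 83.4 mm unbranched apical zone below the
first lateral, and a projected area equal to the ground-truth mask pixel
count.  `out/` also holds the per-stage rasters (mask, skeleton,
reconstructed root) and `overlay.png` with the traced path in red and the
lateral skeletons in green.

Two-half scans are stitched first when two images are given:

```sh
rootascent run --out out/ top.tif bottom.tif
```

Tomography:

```sh
rootascent simulate stack --out stack.tif --seed 1
rootascent tomo volume --stack stack.tif --voxel-mm 0.1 --threshold 0.6 --out volume.json
```

## Scope

The package analyzes images; it does not model plant growth, reconstruct
tomograms from sinograms (it consumes reconstructed stacks), or predict
biomass from area.  See `docs/methods.md` for the full method description,
parameter defaults and limitations.
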