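# Methods

## The statistic

A plant silhouette's convex-hull chain is a piecewise-linear curve
v = f(u) with u the height and v the lateral offset. For three
consecutive hull corners the corner change rate

    K' = [ (Y3-Y2)/(X3-X2) - (Y2-Y1)/(X2-X1) ] / (X3-X1)

is the second divided difference of f — a discrete curvature with units
1/length. A cylinder-type canopy (nearly parallel sides) bends its chains
only slightly, so |K'| is small; a tower-type canopy (wide base, narrow
top) bends them strongly. Classification counts pooled |K'| samples from
both chains of all rotational views against two closed reference
intervals, cylinder [0, 0.2] and tower [0.4, 1.5], and labels the plant
cylinder only when the cylinder count strictly exceeds the tower count
(ties and neither-interval samples default to tower). Samples in the gap
(0.2, 0.4) or above 1.5 influence neither count.

Two conventions make the statistic well-defined across plants:

* **Absolute value.** Raw K' signs differ between the left and right
  chain of the same hull (verified on a real reference hull: left-chain
  K' values are positive, right-chain negative, with overlapping
  magnitudes); the reference intervals are nonnegative, so chains are
  pooled on |K'|.
* **Scale normalization.** K' scales by 1/s under uniform scaling by s,
  and photogrammetric reconstruction scale is arbitrary. Every view is
  therefore rescaled so its vertical extent is 5 model units (the scale
  of the reference hull) before hulls are built; the interval thresholds
  are only meaningful at this common scale. Both the target height and a
  raw mode are configurable.

## Pipeline stages and parameters

| stage | parameter | default | why |
| --- | --- | --- | --- |
| orientation | — | PCA, largest variance → +Y | growth axis has the largest spatial extent of a single-plant cloud; sign picked so the point-denser half is up |
| statistical filter | k, std_mult | 30, 1.0 | common neighborhood size for 10⁴–10⁵-point clouds; one-σ Gaussian band removes scattered reconstruction outliers |
| color filter | keep band (RGB) | (41,41,41)–(255,255,255) | channelwise keep-band; the lower corner drops the near-black speckle photogrammetry leaves along stem/leaf edges |
| voxel grid | leaf | 2% of bbox diagonal | order-of-magnitude point reduction while preserving the silhouette |
| projection | step | 10° (36 views) | enough angular coverage to sample silhouette extremes; 5°/72 doubles cost for little change, 15°/24 under-samples |
| normalization | target height | 5.0 units | see above |
| chain simplification | tol | 0.05 (1% of height) | suppresses sampling micro-corners so only architectural corners contribute triples |
| intervals | cylinder, tower | [0, 0.2], [0.4, 1.5] | reference thresholds the classifier is calibrated to |

Douglas–Peucker simplification is what reconciles dense clouds
(10⁴–10⁵ points) with the ~6-corner chains the method reasons about:
without it, every silhouette sampling wiggle becomes a corner triple with
a near-random rate.

## Numerical choices

* Quickhull uses a strict-outside tolerance of 1e-12 relative to the
  squared coordinate magnitude (the side statistic is a 2×2 determinant);
  collinear boundary points are never vertices, so piecewise-linear
  synthetic silhouettes yield exactly their designed corners.
* Baseline seeds are the extreme-lateral points, ties broken toward the
  extreme vertical, and the farthest-point selection uses the
  perpendicular line distance; both halves recurse exactly as the
  divide-and-conquer scheme prescribes.
* Chain splitting cuts the CCW vertex cycle at the top/bottom extremes.
  A unique extreme belongs to both chains; tied extremes (flat caps, as
  on an axis-aligned rectangle) become per-chain terminals and the cap
  edge belongs to neither chain.
* Corner triples whose vertical gaps fall below 1e-9 are skipped, not
  fatal: flat cap corners can tie after simplification.
* Statistical-filter σ is the population standard deviation (ddof 0);
  the keep band is closed on both ends, so a zero-variance cloud keeps
  every point.
* Report tables truncate metrics toward zero at two decimals (8/11 prints
  as 0.72); JSON output always carries full precision.

## Synthetic plants

The generator emulates what the classifier actually consumes: a body of
revolution about the vertical axis with a piecewise-linear radius profile,
sampled on a ring × azimuth grid (defaults 60 rings, 360 azimuths, so
every 10° view aligns exactly with sampled azimuths and the silhouette
equals the profile). Presets:

* cylinder — corners (5.0, 0.72), (4.9, 0.78), (1.0, 0.80), (0.5, 0.72);
  normalized chain rates 0.1338 and 0.0338, strictly inside [0, 0.2];
* tower — corners (5.0, 0.02), (4.4, 1.30), (0.5, 1.42); normalized
  chain rate 0.4205, strictly inside [0.4, 1.5].

Noise channels: inward-only radial jitter (radius × (1−|ε|), ε Gaussian),
which keeps the designed corners on the hull; near-black points pinned to
the silhouette (edge noise for the color filter); and uniform far
outliers in a 3×-inflated bounding box (for the statistical filter).
Dataset generation jitters corner half-widths by up to 5%, rejecting
draws that break chain convexity or push a corner under the
simplification tolerance — the generator's contract is that its truth
label is recoverable by the pipeline, so profiles whose corners the
pipeline cannot see are resampled.

What the generator does **not** emulate: leaves, branches, occlusion,
asymmetry, outward noise, ground/pot returns, and reconstruction scale
drift. Passing tests therefore demonstrate the geometry pipeline is
correct and the statistic behaves as designed — not that field plants of
either type are perfectly separated; the published validation accuracy on
real plants is 0.75, not 1.0.

## Evaluation toolkit

Confusion counts are tallied with a caller-designated positive class;
accuracy is invariant to that choice. Fleiss kappa (≥2 raters) is
computed via statsmodels and Cohen kappa (2 raters) via scikit-learn,
both cross-checked against direct textbook formulas in the tests. The
location test on rate samples is Welch's unequal-variance t (scipy), and
the mean confidence interval is the Student-t two-sided 95% form. The
k-fold harness shuffles plants once with a seeded generator, cuts
near-equal contiguous folds (30 plants, k=5 → folds of 6), refits the
intervals (min–max or central-95%) on the training folds, and scores the
held-out plants; everything is deterministic given the seed.

## Problem sizes

Default synthetic plants carry ~22–23k points (60 rings × 360 azimuths);
tests use reduced grids (10–30 rings, 36–90 azimuths) where full angular
alignment is not needed, keeping the whole suite near ten seconds. The
acceptance script runs the full-resolution tower preset.

## Known limitations

* The PCA orientation assumes the growth axis dominates spatial variance
  and the canopy half carries more points; heavily pruned or pot-heavy
  clouds may need a user-supplied rigid transform (supported).
* The classifier is interval-based, not learned; plants whose rate
  profiles straddle the gap (0.2, 0.4) resolve by the tie rule (tower).
* Binary PLY, meshes, and normals are out of scope; the I/O layer is
  deliberately restricted to diffable text formats.
* Width is defined as the maximum pairwise horizontal distance (ruler
  intent); other width conventions (e.g. mean cross-section) differ.
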