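"""Point-cloud preprocessing: orientation, denoising, down-sampling, traits.

The pipeline assumes a single plant reconstructed by photogrammetry, so the
cloud arrives in an arbitrary pose and scale.  Preprocessing (in pipeline
order):

1. rigid coordinate correction so the growth axis is +Y (``Y`` is "height"
   everywhere downstream);
2. statistical outlier removal — discard points whose mean distance to
   their k nearest neighbors falls outside a Gaussian band
   ``[mu - sigma*std_mult, mu + sigma*std_mult]`` around the cloud-wide mean;
3. color conditional filtering — keep points inside a channelwise RGB band,
   by default dropping the near-black speckle that photogrammetry leaves
   along stem and leaf edges;
4. voxel-grid down-sampling, replacing each occupied cube by its centroid.

Plus simple trait extraction (plant height and canopy width).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud

__all__ = [
    "RigidTransform",
    "StatFilterParams",
    "TraitPair",
    "apply_rigid_transform",
    "principal_axis_transform",
    "statistical_outlier_filter",
    "color_condition_filter",
    "voxel_downsample",
    "measure_height_width",
    "DEFAULT_BLACK_MIN_RGB",
]

logger = logging.getLogger(__name__)

#: Keep-band lower corner that removes near-black edge noise by default.
DEFAULT_BLACK_MIN_RGB = (41, 41, 41)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation + translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class StatFilterParams:
    """Statistical-outlier-removal parameters.

    ``k`` is the neighbor count for the mean-distance statistic and
    ``std_mult`` the width of the Gaussian keep-band in standard deviations.
    The defaults (k=30, one standard deviation) suit photogrammetric plant
    clouds of 10^4–10^5 points.
    """

    k: int = 30
    std_mult: float = 1.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.std_mult <= 0:
            raise ValueError("std_mult must be > 0")


@dataclass(frozen=True)
class TraitPair:
    """Extracted plant traits in model units."""

    height: float
    width: float


def apply_rigid_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Rotate and translate every coordinate; colors and order unchanged."""
    return cloud.replace(coords=t.apply(cloud.coords))


def principal_axis_transform(cloud: PointCloud) -> RigidTransform:
    """Construct the coordinate correction that uprights the plant.

    The largest-variance principal component of the coordinates is mapped to
    +Y and the centroid's horizontal (X, Z) position to the origin.  The sign
    of the axis is chosen so the denser half of the cloud — the canopy —
    ends up above the centroid, on the assumption that a plant carries more
    reconstructed points in its foliage than near the stem base.

    Raises if N < 3 or the coordinate covariance is degenerate (rank < 2,
    i.e. collinear points).
    """
    coords = cloud.coords
    if len(coords) < 3:
        raise ValueError("need at least 3 points to orient a cloud")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[1] <= 1e-12 * max(eigvals[2], 1.0):
        raise ValueError("degenerate covariance: points are collinear")
    axis = eigvecs[:, 2]  # largest-variance direction

    proj = centered @ axis
    if np.sum(proj > 0) < np.sum(proj < 0):
        axis = -axis

    # Rotation sending `axis` to +Y; any right-handed completion works
    # because downstream views sweep the full turn about Y.
    y = axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, y)) > 0.9:
        seed = np.array([0.0, 0.0, 1.0])
    x = seed - np.dot(seed, y) * y
    x /= np.linalg.norm(x)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])  # rows are target basis -> R @ axis = +Y

    rotated_centroid = R @ centroid
    translation = -np.array([rotated_centroid[0], 0.0, rotated_centroid[2]])
    return RigidTransform(R, translation)


def statistical_outlier_filter(
    cloud: PointCloud, params: StatFilterParams = StatFilterParams()
) -> PointCloud:
    """Remove points whose mean k-NN distance is outside the Gaussian band.

    For each point the mean Euclidean distance S_i to its k nearest
    neighbors is computed; with mu and sigma the mean and (population)
    standard deviation of all S_i, exactly the points with
    ``mu - sigma*std_mult <= S_i <= mu + sigma*std_mult`` are kept, in
    their original order.
    """
    n = len(cloud)
    if n <= params.k:
        raise ValueError(f"need more than k={params.k} points, got {n}")
    tree = cKDTree(cloud.coords)
    # k+1 because each point is its own nearest neighbor at distance 0
    dists, _ = tree.query(cloud.coords, k=params.k + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    mu = mean_dist.mean()
    sigma = mean_dist.std()  # population sd, ddof=0
    lo = mu - sigma * params.std_mult
    hi = mu + sigma * params.std_mult
    keep = (mean_dist >= lo) & (mean_dist <= hi)
    logger.info(
        "statistical filter (k=%d, std_mult=%g): %d -> %d points",
        params.k, params.std_mult, n, int(keep.sum()),
    )
    return cloud.replace(coords=cloud.coords[keep], colors=cloud.colors[keep])


def color_condition_filter(
    cloud: PointCloud,
    min_rgb: tuple[int, int, int] = DEFAULT_BLACK_MIN_RGB,
    max_rgb: tuple[int, int, int] = (255, 255, 255),
) -> PointCloud:
    """Keep exactly the points with ``min_rgb <= color <= max_rgb`` on all
    three channels; may return an empty cloud.  The default band drops
    near-black edge noise."""
    lo = np.asarray(min_rgb, dtype=int)
    hi = np.asarray(max_rgb, dtype=int)
    if not (np.all(lo >= 0) and np.all(lo <= hi) and np.all(hi <= 255)):
        raise ValueError("require 0 <= min_rgb <= max_rgb <= 255 channelwise")
    colors = cloud.colors.astype(int)
    keep = np.all((colors >= lo) & (colors <= hi), axis=1)
    logger.info(
        "color filter [%s, %s]: %d -> %d points",
        tuple(lo), tuple(hi), len(cloud), int(keep.sum()),
    )
    return cloud.replace(coords=cloud.coords[keep], colors=cloud.colors[keep])


def voxel_downsample(cloud: PointCloud, leaf: float | None = None) -> PointCloud:
    """Voxel-grid down-sampling: one output point per occupied cube.

    Space is partitioned into axis-aligned cubes of edge ``leaf`` anchored
    at the cloud's minimum corner; each occupied voxel is replaced by the
    arithmetic mean of its members' coordinates (its center of gravity)
    with the channelwise rounded mean color.  Output is ordered by voxel
    index (z-major, then y, then x).

    ``leaf=None`` uses 2% of the bounding-box diagonal.
    """
    if len(cloud) < 1:
        raise ValueError("cannot down-sample an empty cloud")
    if leaf is None:
        extent = cloud.coords.max(axis=0) - cloud.coords.min(axis=0)
        leaf = 0.02 * float(np.linalg.norm(extent))
        if leaf <= 0:
            leaf = 1.0  # all points coincide; any leaf yields one voxel
    if leaf <= 0:
        raise ValueError("leaf must be > 0")
    origin = cloud.coords.min(axis=0)
    idx = np.floor((cloud.coords - origin) / leaf).astype(np.int64)
    # z-major ordering: sort key (z, y, x)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))
    sorted_idx = idx[order]
    _, starts = np.unique(sorted_idx, axis=0, return_index=True)
    starts.sort()
    bounds = np.append(starts, len(cloud))
    coords_out = np.empty((len(starts), 3))
    colors_out = np.empty((len(starts), 3))
    for v, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
        members = order[s:e]
        coords_out[v] = cloud.coords[members].mean(axis=0)
        colors_out[v] = np.rint(cloud.colors[members].astype(float).mean(axis=0))
    logger.info(
        "voxel down-sample (leaf=%g): %d -> %d points (%.1f%% retained)",
        leaf, len(cloud), len(starts), 100.0 * len(starts) / len(cloud),
    )
    return cloud.replace(coords=coords_out, colors=colors_out)


def measure_height_width(cloud: PointCloud) -> TraitPair:
    """Plant height and canopy width.

    Height is the vertical (Y) extent; width is the maximum pairwise
    distance between points projected to the horizontal (X, Z) plane —
    the span a ruler across the widest part of the canopy would read.
    """
    if len(cloud) < 2:
        raise ValueError("need at least 2 points to measure traits")
    y = cloud.coords[:, 1]
    height = float(y.max() - y.min())
    horiz = cloud.coords[:, [0, 2]]
    # width: only hull vertices can realize the diameter
    from scipy.spatial import ConvexHull, QhullError  # noqa: PLC0415

    try:
        pts = horiz[ConvexHull(horiz).vertices]
    except QhullError:  # degenerate (collinear) horizontal footprint
        pts = horiz
    diff = pts[:, None, :] - pts[None, :, :]
    width = float(np.sqrt((diff**2).sum(axis=2)).max())
    return TraitPair(height=height, width=width)
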