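"""Synthetic plant point clouds with known plant-type ground truth.

A plant body is modelled as a surface of revolution about the vertical
axis: a piecewise-linear radius profile (ordered corner list, top ->
bottom) swept over a ring/azimuth grid.  The two presets mimic the two
field architectures — a *cylinder* canopy whose upper and lower widths are
nearly equal and a *tower* canopy that is wide at the bottom and tapers to
the top — with corner geometry chosen so their silhouette corner change
rates sit strictly inside the respective reference intervals.

Real reconstruction artifacts are emulated by three independent noise
channels: inward-only radial jitter of body points (so designed silhouette
corners stay on the hull), near-black points pinned to the silhouette
(edge noise), and scattered far outliers in an inflated bounding box.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .planttype import CYLINDER, TOWER, TypeIntervals, corner_change_rate
from .pointcloud_io import PointCloud
from .projection import DEFAULT_TARGET_HEIGHT

__all__ = [
    "ProfilePreset",
    "NoiseSpec",
    "make_profile",
    "profile_rates",
    "profile_label",
    "generate_plant_cloud",
    "generate_dataset",
]

_PRESET_CORNERS = {
    # (height u, half-width r), top -> bottom
    CYLINDER: ((5.0, 0.72), (4.9, 0.78), (1.0, 0.80), (0.5, 0.72)),
    TOWER: ((5.0, 0.02), (4.4, 1.30), (0.5, 1.42)),
}


@dataclass(frozen=True)
class ProfilePreset:
    """Piecewise-linear radius profile of a surface-of-revolution plant."""

    name: str
    corners: tuple[tuple[float, float], ...]

    def __post_init__(self):
        corners = tuple((float(u), float(r)) for u, r in self.corners)
        object.__setattr__(self, "corners", corners)
        heights = [u for u, _ in corners]
        if len(corners) < 2:
            raise ValueError("profile needs at least 2 corners")
        if any(b >= a for a, b in zip(heights, heights[1:])):
            raise ValueError("corner heights must be strictly decreasing")
        if any(r < 0 for _, r in corners):
            raise ValueError("half-widths must be nonnegative")
        if not _slopes_strictly_increasing(corners):
            raise ValueError(
                "profile silhouette is not convex "
                "(right-chain slopes must increase top -> bottom)"
            )

    @property
    def height_span(self) -> float:
        return self.corners[0][0] - self.corners[-1][0]


def _slopes_strictly_increasing(corners) -> bool:
    slopes = [
        (r2 - r1) / (u2 - u1)
        for (u1, r1), (u2, r2) in zip(corners, corners[1:])
    ]
    return all(b > a for a, b in zip(slopes, slopes[1:]))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise channels of the generator.

    ``radial_sigma`` is the sd of the inward-only fractional radius jitter
    (body radii are multiplied by ``1 - |eps|``); ``n_black_edge`` black
    points sit exactly on the silhouette; ``n_outliers`` scatter through a
    3x-inflated bounding box.
    """

    radial_sigma: float = 0.0
    n_outliers: int = 0
    n_black_edge: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.radial_sigma < 0:
            raise ValueError("radial_sigma must be >= 0")
        if self.n_outliers < 0 or self.n_black_edge < 0:
            raise ValueError("noise counts must be >= 0")


def make_profile(name: str) -> ProfilePreset:
    """Return a named preset profile (``cylinder`` or ``tower``)."""
    if name not in _PRESET_CORNERS:
        raise ValueError(
            f"unknown profile {name!r}; known: {sorted(_PRESET_CORNERS)}"
        )
    return ProfilePreset(name=name, corners=_PRESET_CORNERS[name])


def profile_rates(
    profile: ProfilePreset,
    target_height: float | None = DEFAULT_TARGET_HEIGHT,
) -> np.ndarray:
    """Analytic |K'| values of one silhouette chain of the profile.

    With ``target_height`` set, the corners are first rescaled exactly the
    way the pipeline normalizes a view (vertical extent -> target_height,
    minimum -> 0), which divides every rate by the scale factor.  This is
    the ground-truth oracle the generated clouds are verified against.
    """
    corners = np.array(profile.corners, dtype=float)
    if target_height is not None:
        span = profile.height_span
        scale = target_height / span
        corners[:, 0] = (corners[:, 0] - corners[:, 0].min()) * scale
        corners[:, 1] *= scale
    return np.array(
        [
            abs(corner_change_rate(corners[i], corners[i + 1], corners[i + 2]))
            for i in range(len(corners) - 2)
        ]
    )


def profile_label(
    profile: ProfilePreset, intervals: TypeIntervals = TypeIntervals()
) -> str:
    """Ground-truth label: majority vote of the profile's chain rates over
    the two reference intervals (ties -> tower, as in classification)."""
    rates = profile_rates(profile)
    c_lo, c_hi = intervals.cylinder
    t_lo, t_hi = intervals.tower
    n_cyl = int(np.sum((rates >= c_lo) & (rates <= c_hi)))
    n_tow = int(np.sum((rates >= t_lo) & (rates <= t_hi)))
    return CYLINDER if n_cyl > n_tow else TOWER


def _body_points(
    profile: ProfilePreset,
    rings: int,
    azimuth_steps: int,
    radial_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    corner_u = np.array([u for u, _ in profile.corners])
    corner_r = np.array([r for _, r in profile.corners])
    heights = np.union1d(
        np.linspace(corner_u.min(), corner_u.max(), rings), corner_u
    )
    # np.interp wants ascending x
    radii = np.interp(heights, corner_u[::-1], corner_r[::-1])
    az = np.deg2rad(np.arange(azimuth_steps) * 360.0 / azimuth_steps)
    u_grid = np.repeat(heights, azimuth_steps)
    r_grid = np.repeat(radii, azimuth_steps)
    phi = np.tile(az, len(heights))
    if radial_sigma > 0:
        shrink = 1.0 - np.abs(rng.normal(0.0, radial_sigma, len(u_grid)))
        r_grid = r_grid * np.clip(shrink, 0.0, 1.0)
    x = r_grid * np.sin(phi)
    z = r_grid * np.cos(phi)
    return np.column_stack([x, u_grid, z])


def _plant_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Foliage-green RGB, every channel comfortably above the black
    threshold so the default color filter keeps body points."""
    r = rng.integers(60, 121, n)
    g = rng.integers(120, 201, n)
    b = rng.integers(45, 101, n)
    return np.column_stack([r, g, b])


def generate_plant_cloud(
    profile: ProfilePreset,
    rings: int = 60,
    azimuth_steps: int = 360,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[PointCloud, str]:
    """Sample one plant cloud from a profile; returns (cloud, truth label).

    Rings are placed at ``rings`` uniformly spaced heights plus every
    profile corner height; each ring carries ``azimuth_steps`` points at
    the azimuth grid including 0 (the default of 360 aligns silhouette
    extremes exactly with every 10-degree view).  Noise channels follow
    :class:`NoiseSpec`.  Deterministic given ``noise.seed``.
    """
    if rings < len(profile.corners):
        raise ValueError("rings must be >= number of profile corners")
    if azimuth_steps < 8:
        raise ValueError("azimuth_steps must be >= 8")
    rng = np.random.default_rng(noise.seed)
    body = _body_points(profile, rings, azimuth_steps, noise.radial_sigma, rng)
    colors = [_plant_colors(len(body), rng)]
    parts = [body]

    corner_u = np.array([u for u, _ in profile.corners])
    corner_r = np.array([r for _, r in profile.corners])

    if noise.n_black_edge:
        u = rng.uniform(corner_u.min(), corner_u.max(), noise.n_black_edge)
        r = np.interp(u, corner_u[::-1], corner_r[::-1])
        phi = rng.uniform(0.0, 2 * np.pi, noise.n_black_edge)
        edge = np.column_stack([r * np.sin(phi), u, r * np.cos(phi)])
        parts.append(edge)
        colors.append(rng.integers(0, 41, (noise.n_black_edge, 3)))

    if noise.n_outliers:
        lo = body.min(axis=0)
        hi = body.max(axis=0)
        center = (lo + hi) / 2
        half = np.maximum((hi - lo) / 2, 1e-3)
        pts = np.empty((noise.n_outliers, 3))
        count = 0
        while count < noise.n_outliers:
            cand = rng.uniform(center - 3 * half, center + 3 * half,
                               (noise.n_outliers, 3))
            # keep only candidates clear of the body's bounding box
            far = np.any(np.abs(cand - center) > 1.2 * half, axis=1)
            take = cand[far][: noise.n_outliers - count]
            pts[count:count + len(take)] = take
            count += len(take)
        parts.append(pts)
        colors.append(rng.integers(100, 201, (noise.n_outliers, 3)))

    cloud = PointCloud(
        coords=np.vstack(parts),
        colors=np.vstack(colors),
        name=profile.name,
    )
    return cloud, profile_label(profile)


def _corners_survive_simplification(corners) -> bool:
    """True when every corner of the normalized silhouette chain stays
    beyond the default Douglas-Peucker tolerance, so the pipeline recovers
    the designed corner set (the generator's ground-truth contract)."""
    from .hull import DEFAULT_SIMPLIFY_TOL, simplify_chain  # noqa: PLC0415

    pts = np.array(corners, dtype=float)
    scale = DEFAULT_TARGET_HEIGHT / (pts[:, 0].max() - pts[:, 0].min())
    pts = pts * scale
    return len(simplify_chain(pts, DEFAULT_SIMPLIFY_TOL)) == len(pts)


def _jitter_profile(
    profile: ProfilePreset, rng: np.random.Generator, max_frac: float = 0.05
) -> ProfilePreset:
    """Perturb corner half-widths by at most ``max_frac``, re-validating
    silhouette convexity and corner detectability (rejection-resampled)."""
    for _ in range(100):
        corners = tuple(
            (u, r * (1.0 + rng.uniform(-max_frac, max_frac)))
            for u, r in profile.corners
        )
        if _slopes_strictly_increasing(corners) and (
            _corners_survive_simplification(corners)
        ):
            return replace(profile, corners=corners)
    return profile  # profile too tight to jitter; use as-is


def generate_dataset(
    n_cylinder: int,
    n_tower: int,
    noise: NoiseSpec = NoiseSpec(),
    rings: int = 60,
    azimuth_steps: int = 360,
) -> list[tuple[PointCloud, str]]:
    """Generate a labelled dataset of jittered preset plants.

    Per-plant seeds are spawned from ``noise.seed``; each plant's profile
    half-widths are independently perturbed by up to 5% within
    convexity-preserving bounds.
    """
    if n_cylinder < 0 or n_tower < 0:
        raise ValueError("counts must be >= 0")
    master = np.random.default_rng(noise.seed)
    plants = []
    for name, count in ((CYLINDER, n_cylinder), (TOWER, n_tower)):
        base = make_profile(name)
        for i in range(count):
            plant_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(plant_seed)
            prof = _jitter_profile(base, rng)
            cloud, label = generate_plant_cloud(
                prof,
                rings=rings,
                azimuth_steps=azimuth_steps,
                noise=replace(noise, seed=plant_seed),
            )
            cloud = cloud.replace(name=f"{name}_{i:03d}")
            plants.append((cloud, label))
    return plants
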