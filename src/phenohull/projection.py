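"""Multi-view orthographic silhouettes of an upright plant cloud.

The corrected cloud is rotated about the vertical (Y) axis in fixed angular
steps and each pose is projected onto the XOY plane, giving one 2D
silhouette per view — 36 views at the default 10° step.  A 2D point is
stored as ``(u, v)`` = (vertical, lateral): downstream hull chains and the
corner change rate statistic all treat the first coordinate as height.

Because the corner change rate has units 1/length while reconstruction
scale is arbitrary, views are normalized to a common vertical extent
(default 5 model units) before hulls are built, which makes the statistic
comparable across plants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud_io import PointCloud

__all__ = [
    "ProjectionView",
    "DEFAULT_STEP_DEG",
    "DEFAULT_TARGET_HEIGHT",
    "rotate_about_vertical",
    "project_views",
    "normalize_view",
]

DEFAULT_STEP_DEG = 10.0
DEFAULT_TARGET_HEIGHT = 5.0


@dataclass(frozen=True)
class ProjectionView:
    """One rotational silhouette: view angle plus M (vertical, lateral)
    pairs, where M equals the source cloud's point count."""

    angle_deg: float
    points2d: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points2d, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(pts)):
            raise ValueError("projected points must be finite")
        object.__setattr__(self, "points2d", pts)

    @property
    def vertical_extent(self) -> float:
        u = self.points2d[:, 0]
        return float(u.max() - u.min()) if len(u) else 0.0


def rotate_about_vertical(coords: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate 3D points about the Y axis:
    ``x' = x cos(t) + z sin(t); y' = y; z' = -x sin(t) + z cos(t)``."""
    coords = np.asarray(coords, dtype=float)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    single = coords.ndim == 1
    pts = coords.reshape(-1, 3)
    out = np.empty_like(pts)
    out[:, 0] = pts[:, 0] * c + pts[:, 2] * s
    out[:, 1] = pts[:, 1]
    out[:, 2] = -pts[:, 0] * s + pts[:, 2] * c
    return out[0] if single else out


def project_views(
    cloud: PointCloud, step_deg: float = DEFAULT_STEP_DEG
) -> list[ProjectionView]:
    """Produce silhouettes at angles ``{0, step, ..., 360 - step}``.

    ``step_deg`` must divide 360 evenly (10° gives the standard 36 views,
    5° gives 72, 15° gives 24).  Each view's 2D points are ``(y, x')`` of
    the rotated coordinates.
    """
    if not (0 < step_deg <= 180):
        raise ValueError("step_deg must be in (0, 180]")
    n_views = 360.0 / step_deg
    if abs(n_views - round(n_views)) > 1e-9:
        raise ValueError(f"step_deg={step_deg} does not divide 360 evenly")
    n_views = int(round(n_views))
    views = []
    for k in range(n_views):
        angle = k * step_deg
        rot = rotate_about_vertical(cloud.coords, angle)
        pts2d = np.column_stack([rot[:, 1], rot[:, 0]])  # (vertical, lateral)
        views.append(ProjectionView(angle_deg=angle, points2d=pts2d))
    return views


def normalize_view(
    view: ProjectionView, target_height: float = DEFAULT_TARGET_HEIGHT
) -> ProjectionView:
    """Uniformly scale a view so its vertical extent equals
    ``target_height``, shifting the vertical minimum to 0.  Idempotent."""
    if target_height <= 0:
        raise ValueError("target_height must be > 0")
    extent = view.vertical_extent
    if extent <= 0:
        raise ValueError("view has zero vertical extent")
    scale = target_height / extent
    u0 = view.points2d[:, 0].min()
    pts = view.points2d.copy()
    pts[:, 0] = (pts[:, 0] - u0) * scale
    pts[:, 1] = pts[:, 1] * scale
    return ProjectionView(angle_deg=view.angle_deg, points2d=pts)
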