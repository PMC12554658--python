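"""Corner change rate and interval-based plant-type classification.

The *corner change rate* K' is a discrete curvature of a silhouette chain:
for three consecutive hull corners (X1,Y1), (X2,Y2), (X3,Y3) — X vertical,
Y lateral —

    K' = [ (Y3-Y2)/(X3-X2) - (Y2-Y1)/(X2-X1) ] / (X3-X1)

i.e. the change in lateral-vs-vertical slope across the triple divided by
its vertical span, with units 1/length.  A cylinder-shaped canopy (upper
and lower width similar) produces small |K'| along its chains; a
tower-shaped canopy (wide bottom tapering upward) produces large |K'|.

Classification pools |K'| samples from both chains of every rotational
view and counts how many fall inside each reference interval — cylinder
[0, 0.2] and tower [0.4, 1.5] — labelling the plant cylinder only when the
cylinder count strictly exceeds the tower count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hull import DEFAULT_SIMPLIFY_TOL, quickhull, simplify_chain
from .projection import ProjectionView

__all__ = [
    "CornerRateSample",
    "TypeIntervals",
    "PlantTypeResult",
    "DegenerateTripleError",
    "corner_change_rate",
    "chain_rates",
    "plant_rate_profile",
    "classify_plant",
    "fit_intervals",
    "mean_ci95",
    "CYLINDER",
    "TOWER",
]

logger = logging.getLogger(__name__)

CYLINDER = "cylinder"
TOWER = "tower"

_X_TOL = 1e-9  # minimum vertical gap between corners of a triple


class DegenerateTripleError(ValueError):
    """Corner triple with a vertical gap below tolerance; callers skip it."""


@dataclass(frozen=True)
class CornerRateSample:
    """One (view angle, height, |K'|) observation."""

    view_angle_deg: float
    height: float
    rate: float


@dataclass(frozen=True)
class TypeIntervals:
    """Closed |K'| reference intervals for the two canopy architectures."""

    cylinder: tuple[float, float] = (0.0, 0.2)
    tower: tuple[float, float] = (0.4, 1.5)

    def __post_init__(self):
        for name in ("cylinder", "tower"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval has low > high")


@dataclass(frozen=True)
class PlantTypeResult:
    """Per-plant rate profile, interval counts, and final label."""

    samples: tuple[CornerRateSample, ...]
    n_cylinder: int
    n_tower: int
    label: str
    intervals: TypeIntervals = field(default_factory=TypeIntervals)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_cylinder": self.n_cylinder,
            "n_tower": self.n_tower,
            "n_samples": len(self.samples),
            "intervals": {
                "cylinder": list(self.intervals.cylinder),
                "tower": list(self.intervals.tower),
            },
        }


def corner_change_rate(p1, p2, p3) -> float:
    """Signed corner change rate K' of one corner triple.

    Raises :class:`DegenerateTripleError` when any vertical gap within the
    triple is below tolerance (flat cap corners can tie after chain
    simplification; callers skip such triples rather than fail).
    """
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    if (
        abs(x2 - x1) < _X_TOL
        or abs(x3 - x2) < _X_TOL
        or abs(x3 - x1) < _X_TOL
    ):
        raise DegenerateTripleError(
            "corner triple has vertical coordinates closer than tolerance"
        )
    return ((y3 - y2) / (x3 - x2) - (y2 - y1) / (x2 - x1)) / (x3 - x1)


def chain_rates(chain, view_angle_deg: float = 0.0) -> list[CornerRateSample]:
    """|K'| samples over every consecutive corner triple of a chain.

    The chain must be ordered top -> bottom; the sample height is the
    middle corner's vertical coordinate.  Degenerate triples are skipped;
    a chain with fewer than 3 corners yields an empty list.
    """
    pts = np.asarray(chain, dtype=float).reshape(-1, 2)
    samples: list[CornerRateSample] = []
    for i in range(len(pts) - 2):
        try:
            k = corner_change_rate(pts[i], pts[i + 1], pts[i + 2])
        except DegenerateTripleError:
            continue
        samples.append(
            CornerRateSample(
                view_angle_deg=view_angle_deg,
                height=float(pts[i + 1, 0]),
                rate=abs(k),
            )
        )
    return samples


def plant_rate_profile(
    views: list[ProjectionView],
    simplify_tol: float = DEFAULT_SIMPLIFY_TOL,
) -> list[CornerRateSample]:
    """Pooled |K'| samples over all views of one plant.

    Each view is reduced to its convex hull, the hull is cut into left and
    right chains, each chain is Douglas-Peucker simplified, and Eq-style
    triple rates are collected from both chains.  A view whose points are
    all collinear is skipped with a warning; if every view degenerates, an
    error is raised.
    """
    if not views:
        raise ValueError("need at least one view")
    samples: list[CornerRateSample] = []
    n_skipped = 0
    for view in views:
        try:
            hull = quickhull(view.points2d)
        except ValueError as exc:
            warnings.warn(
                f"view at {view.angle_deg}°: {exc}; skipped", stacklevel=2
            )
            n_skipped += 1
            continue
        for chain in (hull.left_chain, hull.right_chain):
            reduced = simplify_chain(chain, simplify_tol)
            samples.extend(chain_rates(reduced, view.angle_deg))
    if n_skipped == len(views):
        raise ValueError("all views were degenerate")
    return samples


def classify_plant(
    samples: list[CornerRateSample],
    intervals: TypeIntervals = TypeIntervals(),
) -> PlantTypeResult:
    """Majority count of |K'| samples in the two closed intervals.

    The label is cylinder iff the cylinder count strictly exceeds the
    tower count (ties go to tower); samples falling in neither interval
    count toward neither type.
    """
    if not samples:
        raise ValueError("cannot classify an empty sample list")
    rates = np.array([s.rate for s in samples])
    c_lo, c_hi = intervals.cylinder
    t_lo, t_hi = intervals.tower
    n_cyl = int(np.sum((rates >= c_lo) & (rates <= c_hi)))
    n_tow = int(np.sum((rates >= t_lo) & (rates <= t_hi)))
    label = CYLINDER if n_cyl > n_tow else TOWER
    logger.info(
        "classification: %d samples, %d cylinder / %d tower -> %s",
        len(rates), n_cyl, n_tow, label,
    )
    return PlantTypeResult(
        samples=tuple(samples),
        n_cylinder=n_cyl,
        n_tower=n_tow,
        label=label,
        intervals=intervals,
    )


def fit_intervals(
    rates_by_label: dict[str, "np.ndarray | list[float]"],
    method: str = "minmax",
) -> TypeIntervals:
    """Estimate per-type |K'| intervals from labelled rate collections.

    ``minmax`` takes the observed [min, max] per label; ``percentile95``
    the central 95% range (2.5th-97.5th percentiles, linear
    interpolation).  Both labels must be present with >= 2 rates each.
    """
    bounds = {}
    for label in (CYLINDER, TOWER):
        if label not in rates_by_label:
            raise ValueError(f"missing rates for label {label!r}")
        rates = np.asarray(rates_by_label[label], dtype=float)
        if len(rates) < 2:
            raise ValueError(f"need >= 2 rates for label {label!r}")
        if method == "minmax":
            bounds[label] = (float(rates.min()), float(rates.max()))
        elif method == "percentile95":
            lo, hi = np.percentile(rates, [2.5, 97.5])
            bounds[label] = (float(lo), float(hi))
        else:
            raise ValueError(f"unknown method {method!r}")
    return TypeIntervals(cylinder=bounds[CYLINDER], tower=bounds[TOWER])


def mean_ci95(rates) -> tuple[float, float, float]:
    """Student-t two-sided 95% confidence interval for the mean:
    ``mean ± t(0.975, n-1) * s / sqrt(n)`` with the sample sd (ddof=1)."""
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return mean, mean - half, mean + half
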