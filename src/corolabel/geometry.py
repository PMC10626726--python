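"""Core 3D geometry for coronary centerline analysis.

All coordinates are world millimetres in a fixed anatomical frame:

* ``x`` increases toward the patient's left (right-to-left),
* ``y`` increases toward the anterior (back-to-front),
* ``z`` increases toward the inferior (top-to-bottom).

The module provides the two primitives the circumflex identification rule
is built on: the minimum Euclidean distance from a centerline point to an
unordered chamber point cloud (left atrium or left ventricle surface
samples), and the count of centerline points whose minimum distance falls
strictly below a threshold. Distances are always computed in millimetres,
never in voxel units, because the decision thresholds (25 mm to the LA,
30 mm to the LV) are metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "Centerline",
    "DistanceProfile",
    "min_distance_to_cloud",
    "distance_profile",
    "count_within",
    "arc_length",
    "point_along",
    "resample",
]


def _as_points(points, name: str = "points") -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1 and arr.size == 3:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class PointCloud:
    """Unordered 3D point set, typically LA or LV surface samples.

    Parameters
    ----------
    points : (n, 3) array of float
        World coordinates in mm.
    role : str
        One of ``"LA"``, ``"LV"`` or ``"other"``.
    """

    points: np.ndarray
    role: str = "other"
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.points = _as_points(self.points, "cloud points")
        if self.role not in ("LA", "LV", "other"):
            raise ValueError(f"unknown point-cloud role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        """Lazily built spatial index over the cloud."""
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree


@dataclass
class Centerline:
    """Ordered 3D polyline in world mm; the unit of labeling.

    Points are indexed 0..n-1 in sequence along the vessel; consecutive
    points must be distinct and there must be at least two of them.
    """

    points: np.ndarray

    def __post_init__(self):
        self.points = _as_points(self.points, "centerline points")
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError("consecutive centerline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def index(self) -> np.ndarray:
        return np.arange(len(self.points))

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def cumulative_lengths(self) -> np.ndarray:
        """Arc length from the first point to each point (first entry 0)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])


@dataclass
class DistanceProfile:
    """Per-point minimum distances of a centerline to the LA and LV clouds."""

    d_min_la: np.ndarray
    d_min_lv: np.ndarray

    def __post_init__(self):
        self.d_min_la = np.asarray(self.d_min_la, dtype=float)
        self.d_min_lv = np.asarray(self.d_min_lv, dtype=float)
        if self.d_min_la.shape != self.d_min_lv.shape:
            raise ValueError("LA and LV profiles must have equal length")
        if np.any(self.d_min_la < 0) or np.any(self.d_min_lv < 0):
            raise ValueError("distances must be non-negative")


def min_distance_to_cloud(p, cloud: PointCloud) -> float:
    """Minimum Euclidean distance (mm) from point ``p`` to the cloud.

    Implements min over cloud members (xi, yi, zi) of
    sqrt((x-xi)^2 + (y-yi)^2 + (z-zi)^2).
    """
    if len(cloud) == 0:
        raise ValueError("reference point cloud is empty")
    p = np.asarray(p, dtype=float).reshape(3)
    d, _ = cloud.tree.query(p)
    return float(d)


def distance_profile(c: Centerline, la: PointCloud, lv: PointCloud) -> DistanceProfile:
    """Per-point minimum distances from a centerline to LA and LV clouds."""
    if len(la) == 0 or len(lv) == 0:
        raise ValueError("reference point cloud is empty")
    d_la, _ = la.tree.query(c.points)
    d_lv, _ = lv.tree.query(c.points)
    return DistanceProfile(d_min_la=d_la, d_min_lv=d_lv)


def count_within(profile_component, threshold: float) -> int:
    """Number of distances strictly less than ``threshold`` (mm).

    The comparison is strict: a distance exactly at the threshold does not
    count.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(profile_component, dtype=float)
    return int(np.count_nonzero(values < threshold))


def arc_length(c: Centerline) -> float:
    """Total polyline length in mm (sum of consecutive-point distances)."""
    return float(c.segment_lengths().sum())


def point_along(c: Centerline, s: float) -> np.ndarray:
    """Linear interpolation along the polyline at arc-length ``s`` (mm)."""
    total = arc_length(c)
    if not 0.0 <= s <= total + 1e-9:
        raise ValueError(f"arc length {s} outside [0, {total}]")
    s = min(s, total)
    cum = c.cumulative_lengths()
    i = int(np.searchsorted(cum, s, side="right")) - 1
    if i >= len(c) - 1:
        return c.points[-1].copy()
    seg = cum[i + 1] - cum[i]
    t = (s - cum[i]) / seg
    return (1 - t) * c.points[i] + t * c.points[i + 1]


def resample(c: Centerline, spacing: float = 0.5) -> Centerline:
    """Resample a centerline at uniform arc-length spacing (mm).

    Opt-in: the labeling rules count raw centerline points by default, and
    point density changes the proximity-count attributes, so resampling is
    never applied implicitly.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = arc_length(c)
    n = max(int(np.floor(total / spacing)) + 1, 2)
    ss = np.linspace(0.0, total, n)
    pts = np.array([point_along(c, s) for s in ss])
    # collapse any numerically duplicate consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
    return Centerline(pts[keep])
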