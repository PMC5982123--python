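"""Depth frames as point clouds, and their partition into aggregates.

A valid pixel ``(i, j)`` with perpendicular depth ``z`` becomes the 3D
point ``(x, y, z)`` with ``x = z tan(theta_j)``, ``y = z tan(phi_i)``; its
radial distance from the focal-plane center is ``r = sqrt(x^2+y^2+z^2)``.
All sphere-cut operations use ``r`` (the depth-sphere is centered on the
focal-plane center), while the stored frame keeps the device's
perpendicular-depth convention.

Aggregates are connected components under "8-neighbours on the pixel grid
AND radial continuity |dr| <= link_tau"; they are then labelled branch
(thin elongated footprint), isolated or adherent (point-count split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .frames import DepthFrame
from .sensor import SensorModel

__all__ = [
    "DepthPoint",
    "PointCloud",
    "Aggregate",
    "frame_to_points",
    "closest_point",
    "cluster_aggregates",
    "footprint_moments",
    "filter_branches",
    "split_isolated_adherent",
]


class DepthPoint(NamedTuple):
    """One depth pixel lifted to 3D."""

    row: int
    col: int
    z: float
    theta: float
    phi: float
    x: float
    y: float
    z3: float
    r: float


@dataclass
class PointCloud:
    """Column-array point cloud; one entry per valid pixel."""

    rows: np.ndarray
    cols: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    sensor: Optional[SensorModel] = None

    def __len__(self) -> int:
        return self.rows.size

    @property
    def z3(self) -> np.ndarray:
        return self.z

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def point(self, k: int) -> DepthPoint:
        return DepthPoint(
            int(self.rows[k]), int(self.cols[k]), float(self.z[k]),
            float(self.theta[k]), float(self.phi[k]),
            float(self.x[k]), float(self.y[k]), float(self.z[k]),
            float(self.r[k]),
        )

    def select(self, idx: np.ndarray) -> "PointCloud":
        """Sub-cloud at the given indices."""
        return PointCloud(
            self.rows[idx], self.cols[idx], self.z[idx], self.theta[idx],
            self.phi[idx], self.x[idx], self.y[idx], self.r[idx], self.sensor,
        )


@dataclass
class Aggregate:
    """A connected cluster of depth points (indices into a parent cloud)."""

    cloud: PointCloud
    indices: np.ndarray
    id: int
    kind: str = "unset"  # isolated | adherent | branch | unset

    def __post_init__(self) -> None:
        if self.indices.size == 0:
            raise ValueError("aggregate must be non-empty")

    @property
    def count(self) -> int:
        return int(self.indices.size)

    @property
    def points(self) -> PointCloud:
        return self.cloud.select(self.indices)

    @property
    def rows(self) -> np.ndarray:
        return self.cloud.rows[self.indices]

    @property
    def cols(self) -> np.ndarray:
        return self.cloud.cols[self.indices]

    @property
    def r(self) -> np.ndarray:
        return self.cloud.r[self.indices]

    @property
    def pixel_footprint(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def frame_to_points(frame: DepthFrame, sensor: SensorModel) -> PointCloud:
    """Lift every valid pixel of a frame to a 3D depth point."""
    if frame.shape != sensor.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match sensor {sensor.shape}"
        )
    ii, jj = np.nonzero(frame.values > 0)
    z = frame.values[ii, jj]
    theta = sensor.col_angles()[jj]
    phi = sensor.row_angles()[ii]
    x = z * np.tan(theta)
    y = z * np.tan(phi)
    r = np.sqrt(x * x + y * y + z * z)
    return PointCloud(ii, jj, z, theta, phi, x, y, r, sensor)


def closest_point(points: Union[PointCloud, Aggregate]) -> DepthPoint:
    """The point of minimal radial distance r; ties break on (row, col)."""
    cloud = points.points if isinstance(points, Aggregate) else points
    if len(cloud) == 0:
        raise ValueError("empty point set has no closest point")
    k = int(np.lexsort((cloud.cols, cloud.rows, cloud.r))[0])
    return cloud.point(k)


_NEIGHBOR_OFFSETS = [(0, 1), (1, -1), (1, 0), (1, 1)]  # forward half of 8-hood


def cluster_aggregates(cloud: PointCloud, link_tau: float = 10.0) -> list[Aggregate]:
    """Partition a cloud into aggregates.

    Two points are linked when their pixels are 8-neighbours and their
    radial distances differ by at most ``link_tau`` mm.  Aggregate ids are
    assigned in order of each component's (min row, min col).
    """
    if link_tau <= 0:
        raise ValueError("link_tau must be positive")
    npts = len(cloud)
    if npts == 0:
        return []
    h = int(cloud.rows.max()) + 2
    w = int(cloud.cols.max()) + 2
    grid = np.full((h, w), -1, dtype=np.int64)
    grid[cloud.rows, cloud.cols] = np.arange(npts)

    src_list, dst_list = [], []
    rgrid = np.full((h, w), np.nan)
    rgrid[cloud.rows, cloud.cols] = cloud.r
    for di, dj in _NEIGHBOR_OFFSETS:
        a = grid[max(0, -di): h - max(0, di), max(0, -dj): w - max(0, dj)]
        b = grid[max(0, di): h - max(0, -di), max(0, dj): w - max(0, -dj)]
        ra = rgrid[max(0, -di): h - max(0, di), max(0, -dj): w - max(0, dj)]
        rb = rgrid[max(0, di): h - max(0, -di), max(0, dj): w - max(0, -dj)]
        ok = (a >= 0) & (b >= 0) & (np.abs(ra - rb) <= link_tau)
        src_list.append(a[ok])
        dst_list.append(b[ok])
    src = np.concatenate(src_list) if src_list else np.array([], dtype=np.int64)
    dst = np.concatenate(dst_list) if dst_list else np.array([], dtype=np.int64)
    adj = coo_matrix(
        (np.ones(src.size), (src, dst)), shape=(npts, npts)
    )
    n_comp, labels = connected_components(adj, directed=False)

    order = []
    for c in range(n_comp):
        idx = np.nonzero(labels == c)[0]
        order.append((int(cloud.rows[idx].min()), int(cloud.cols[idx].min()), idx))
    order.sort(key=lambda t: (t[0], t[1]))
    return [
        Aggregate(cloud, idx, id=k) for k, (_, _, idx) in enumerate(order)
    ]


def footprint_moments(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Eigenvalues (major, minor) of the second-central-moment matrix of a footprint."""
    pts = np.column_stack([rows, cols]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    lam2, lam1 = np.linalg.eigvalsh(cov)
    return float(lam1), float(max(lam2, 0.0))


def filter_branches(
    aggregates: list[Aggregate],
    max_minor_px: float = 6.0,
    min_elong: float = 4.0,
) -> list[Aggregate]:
    """Drop thin elongated (branch-like) aggregates.

    An aggregate is a branch when its pixel footprint's minor-axis length
    (4 sqrt(minor second moment), the standard ellipse-equivalent measure)
    is below ``max_minor_px`` AND its major/minor elongation exceeds
    ``min_elong``.  Branches are labelled and excluded from the result.
    """
    if max_minor_px <= 0 or min_elong <= 0:
        raise ValueError("thresholds must be positive")
    kept: list[Aggregate] = []
    for agg in aggregates:
        lam1, lam2 = footprint_moments(agg.rows, agg.cols)
        minor_len = 4.0 * np.sqrt(lam2)
        if lam1 <= 0:
            elong = 1.0  # single pixel: not a line
        elif lam2 <= 0:
            elong = np.inf  # exact pixel line
        else:
            elong = float(np.sqrt(lam1 / lam2))
        if minor_len < max_minor_px and elong > min_elong:
            agg.kind = "branch"
        else:
            kept.append(agg)
    return kept


def split_isolated_adherent(aggregates: list[Aggregate], N0: int) -> list[Aggregate]:
    """Label aggregates isolated (< N0 points) or adherent (>= N0 points)."""
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    for agg in aggregates:
        agg.kind = "adherent" if agg.count >= N0 else "isolated"
    return aggregates
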