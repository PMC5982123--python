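"""Shell extraction, intersection-curve analysis and detection merging.

One depth-sphere cut of an aggregate selects the points whose radial
distance lies within a thin shell ``|r - RC| <= w``.  The selected pixels
are decomposed into 8-connected regions; each region is an intersection
curve carrying its pixel count ``AN``, its eccentricity ``E`` (from the
second central moments of its pixel coordinates: 0 for a perfect circle,
1 for a line) and the mean 3D position of its member points.  A region is
a fruit candidate when ``E <= E0`` and ``AN >= AN0`` jointly hold — the
double threshold that separates the closed circular curves of spherical
fruit from the open arcs of leaves and the slivers of branches and noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .cloud import Aggregate, PointCloud, closest_point
from .geometry import FRUIT_SPECS, circle_radius, cut_radius, expected_count
from .sensor import SensorModel, make_sensor

__all__ = [
    "IntersectionCurve",
    "Thresholds",
    "Detection",
    "extract_shell",
    "region_eccentricity",
    "curve_regions",
    "classify_region",
    "successive_cut",
    "single_cut",
    "merge_detections",
    "estimate_fruit_center",
    "anchor_radius",
]


@dataclass
class IntersectionCurve:
    """One connected region produced by one depth-sphere cut."""

    pixels: np.ndarray          # (AN, 2) array of (row, col)
    AN: int
    E: float
    centroid: tuple[float, float]
    cut_radius: float
    source_id: int
    center3d: np.ndarray        # (3,) mean of member points, mm
    cut_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.AN < 1:
            raise ValueError("intersection curve must contain pixels")
        if not (0.0 <= self.E <= 1.0):
            raise ValueError("eccentricity must lie in [0, 1]")


def _default_AN0() -> float:
    # Half the expected circle count of the smallest mean-radius variety
    # (tangerine) at the far end of the close-shot window, with its own L.
    spec = FRUIT_SPECS["tangerine"]
    sensor = make_sensor("F200")
    return 0.5 * expected_count(spec.mean_radius, 650.0, float(spec.L), sensor, 0.8)


def _default_merge_radius() -> float:
    # 0.8x the smallest mean fruit radius in the built-in variety table.
    return 0.8 * min(s.mean_radius for s in FRUIT_SPECS.values())


@dataclass
class Thresholds:
    """Tunable parameters of the cut-and-classify stage.

    ``N0`` is the fixed isolated/adherent point-count split; ``None``
    selects the pipeline's range-adaptive split.
    """

    E0: float = 0.85
    AN0: float = field(default_factory=_default_AN0)
    N0: Optional[int] = None
    shell_halfwidth: float = 1.5
    L_start: float = 2.0
    L_step: float = 2.0
    L_max: float = 12.0
    merge_radius: float = field(default_factory=_default_merge_radius)
    ka: float = 0.8
    an_hi_factor: Optional[float] = 1.5  # size-consistency ceiling; None disables

    def __post_init__(self) -> None:
        if not (0 < self.E0 < 1):
            raise ValueError("E0 must lie in (0, 1)")
        if self.AN0 < 1:
            raise ValueError("AN0 must be >= 1")
        if self.shell_halfwidth <= 0 or self.L_step <= 0:
            raise ValueError("shell_halfwidth and L_step must be positive")
        if not (0 < self.ka <= 1):
            raise ValueError("ka must lie in (0, 1]")


def anchor_radius(agg: Aggregate, robust: bool = True) -> float:
    """Radial distance of the aggregate's closest point, noise-robustly.

    The raw minimum over thousands of noisy pixels is biased low by about
    three noise standard deviations, which mis-anchors the cut schedule (and
    turns grazing cuts of gently curved leaves into broad shallow bands).
    The robust anchor takes the minimum of the 3x3-median-filtered radial
    distances over the aggregate's pixel footprint; on noise-free data it
    agrees with the exact closest point to within the surface curvature
    across one pixel.
    """
    if not robust or agg.count < 9:
        return float(closest_point(agg).r)
    rows, cols = agg.rows, agg.cols
    r0, c0 = int(rows.min()), int(cols.min())
    h = int(rows.max()) - r0 + 3
    w = int(cols.max()) - c0 + 3
    grid = np.full((h, w), np.nan)
    grid[rows - r0 + 1, cols - c0 + 1] = agg.r
    stack = np.stack([
        grid[1 + di: h - 1 + di, 1 + dj: w - 1 + dj]
        for di in (-1, 0, 1) for dj in (-1, 0, 1)
    ])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        med = np.nanmedian(stack, axis=0)
    vals = med[rows - r0, cols - c0]
    return float(np.nanmin(vals))


def extract_shell(agg: Aggregate, RC: float, w: float) -> PointCloud:
    """Points of the aggregate within the shell |r - RC| <= w (may be empty)."""
    if RC <= 0 or w <= 0:
        raise ValueError("RC and w must be positive")
    pts = agg.points
    mask = np.abs(pts.r - RC) <= w
    return pts.select(np.nonzero(mask)[0])


def region_eccentricity(pixels: Sequence) -> float:
    """Eccentricity of a pixel region from its second central moments.

    E = sqrt(1 - lam2/lam1) with lam1 >= lam2 the eigenvalues of the 2x2
    covariance of the pixel coordinates; a single pixel (or any degenerate
    isotropic region) gives 0, a straight line gives 1.
    """
    pts = np.asarray(list(pixels), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("pixels must be a non-empty set of (row, col) pairs")
    if pts.shape[0] == 1:
        return 0.0
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    lam2, lam1 = np.linalg.eigvalsh(cov)
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - max(lam2, 0.0) / lam1)))


def curve_regions(
    shell: PointCloud,
    sensor: Optional[SensorModel] = None,
    cut_radius_mm: float = 0.0,
    source_id: int = -1,
    cut_depth: Optional[float] = None,
) -> list[IntersectionCurve]:
    """Decompose shell points into 8-connected intersection-curve regions.

    Eccentricity is computed in angular coordinates (pixel indices scaled by
    the per-axis field of view) so that the sensor's unequal horizontal and
    vertical pixel densities do not distort the shape measure; without a
    sensor the raw pixel coordinates are used.
    """
    if len(shell) == 0:
        return []
    if sensor is None:
        sensor = shell.sensor
    r0, c0 = int(shell.rows.min()), int(shell.cols.min())
    h = int(shell.rows.max()) - r0 + 1
    w = int(shell.cols.max()) - c0 + 1
    grid = np.zeros((h, w), dtype=bool)
    grid[shell.rows - r0, shell.cols - c0] = True
    labels, n_lab = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    lab_of_point = labels[shell.rows - r0, shell.cols - c0]
    curves: list[IntersectionCurve] = []
    for lab in range(1, n_lab + 1):
        idx = np.nonzero(lab_of_point == lab)[0]
        sub = shell.select(idx)
        pix = np.column_stack([sub.rows, sub.cols])
        if sensor is not None:
            epix = np.column_stack([
                sub.rows / sensor.ppr_v, sub.cols / sensor.ppr_h
            ])
        else:
            epix = pix
        curves.append(
            IntersectionCurve(
                pixels=pix,
                AN=len(sub),
                E=region_eccentricity(epix),
                centroid=(float(sub.rows.mean()), float(sub.cols.mean())),
                cut_radius=cut_radius_mm,
                source_id=source_id,
                center3d=sub.xyz.mean(axis=0),
                cut_depth=cut_depth,
            )
        )
    # deterministic order: by centroid row, then col
    curves.sort(key=lambda c: c.centroid)
    return curves


def classify_region(curve: IntersectionCurve, E0: float, AN0: float) -> str:
    """Double threshold: fruit candidate iff E <= E0 and AN >= AN0."""
    if not (0 < E0 < 1) or AN0 < 1:
        raise ValueError("invalid thresholds")
    return "fruit_candidate" if (curve.E <= E0 and curve.AN >= AN0) else "rejected"


def _cut_once(
    agg: Aggregate, RC: float, thresholds: Thresholds, L: Optional[float]
) -> list[IntersectionCurve]:
    shell = extract_shell(agg, RC, thresholds.shell_halfwidth)
    curves = curve_regions(
        shell, agg.cloud.sensor, cut_radius_mm=RC, source_id=agg.id, cut_depth=L
    )
    return [
        c for c in curves
        if classify_region(c, thresholds.E0, thresholds.AN0) == "fruit_candidate"
    ]


def single_cut(
    agg: Aggregate, thresholds: Thresholds, L: float
) -> list[IntersectionCurve]:
    """One cut at RC = RA + L anchored at the aggregate's closest point."""
    RA = anchor_radius(agg)
    return _cut_once(agg, cut_radius(RA, L), thresholds, L)


def successive_cut(
    agg: Aggregate, thresholds: Thresholds, L_max: Optional[float] = None
) -> list[IntersectionCurve]:
    """Cuts of increasing depth L = L_start, L_start + L_step, ... <= L_max.

    Returns every fruit-candidate curve over the whole schedule, tagged with
    the cutting depth that produced it; curves of the same physical fruit
    are collapsed later by :func:`merge_detections`.  ``L_max`` overrides the
    thresholds' schedule end, e.g. to sweep an adherent aggregate's whole
    depth extent so that cuts reach the objects behind its closest one.
    """
    RA = anchor_radius(agg)
    if L_max is None:
        L_max = thresholds.L_max
    candidates: list[IntersectionCurve] = []
    L = thresholds.L_start
    while L <= L_max + 1e-9:
        candidates.extend(_cut_once(agg, cut_radius(RA, L), thresholds, L))
        L += thresholds.L_step
    return candidates


@dataclass
class Detection:
    """One recognized fruit: a group of mutually close intersection curves."""

    id: int
    center: np.ndarray                 # (3,) mm, count-weighted mean
    supporting_curves: list[IntersectionCurve]

    def __post_init__(self) -> None:
        if not self.supporting_curves:
            raise ValueError("detection needs at least one supporting curve")

    @property
    def min_E(self) -> float:
        return min(c.E for c in self.supporting_curves)

    @property
    def total_AN(self) -> int:
        return sum(c.AN for c in self.supporting_curves)


def estimate_fruit_center(curve: IntersectionCurve, fruit_radius: float) -> np.ndarray:
    """Push a curve's 3D center to the implied fruit center.

    The intersection circle lies on the cut plane at chord offset ``b`` in
    front of the fruit center, along the sensor-to-fruit direction; pushing
    the curve center outward by ``b`` (computed for the nominal fruit
    radius) recovers the center itself — the quantity a harvesting effector
    needs.  Falls back to the raw curve center when the cut geometry is
    unavailable or invalid.
    """
    from .geometry import chord_offset

    c = curve.center3d
    if curve.cut_depth is None or curve.cut_radius <= curve.cut_depth:
        return c
    try:
        b = chord_offset(
            fruit_radius, curve.cut_radius - curve.cut_depth, curve.cut_depth
        )
    except ValueError:
        return c
    norm = float(np.linalg.norm(c))
    if norm == 0:
        return c
    return c * (1.0 + b / norm)


def merge_detections(
    curves: list[IntersectionCurve],
    merge_radius: float,
    fruit_radius: Optional[float] = None,
) -> list[Detection]:
    """Group curves whose 3D centers are within merge_radius (single linkage).

    Each group becomes one detection at the AN-weighted mean center;
    detections are ordered by the depth of their closest member curve.
    When ``fruit_radius`` is given, each curve center is first pushed to its
    implied fruit center (see :func:`estimate_fruit_center`), so the
    detection reports the fruit center rather than the curve centroid.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    if not curves:
        return []
    if fruit_radius is not None:
        centers = np.array([estimate_fruit_center(c, fruit_radius) for c in curves])
    else:
        centers = np.array([c.center3d for c in curves])
    n = len(curves)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    for a in range(n):
        for b in range(a + 1, n):
            if d2[a, b] <= merge_radius * merge_radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)

    dets = []
    for members in groups.values():
        cs = [curves[k] for k in members]
        wts = np.array([c.AN for c in cs], dtype=float)
        center = (centers[members] * wts[:, None]).sum(0) / wts.sum()
        depth = min(float(np.linalg.norm(c.center3d)) for c in cs)
        dets.append((depth, cs, center))
    dets.sort(key=lambda t: t[0])
    return [
        Detection(id=k, center=center, supporting_curves=cs)
        for k, (_, cs, center) in enumerate(dets)
    ]
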