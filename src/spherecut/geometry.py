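"""Depth-sphere cutting geometry.

A fruit is idealised as a sphere of radius ``R`` whose point cloud has its
closest point at radial distance ``RA`` from the sensor's focal-plane
center.  Cutting the scene with a sphere of radius ``RC = RA + L`` about
that center (``L`` = cutting depth into the fruit surface) intersects the
fruit along a circle.  With ``b`` the distance from the fruit center to the
cut plane,

    b   = (2 R^2 + 2 RA (R - L) - L^2) / (2 (RA + R))
    RC' = sqrt(R^2 - b^2)

and the cutting depth satisfies the closed form

    L = RC - sqrt(RC^2 - RC'^2) + R - sqrt(R^2 - RC'^2).

The expected number of depth points on the intersection circle is the
circle's angular circumference at range RC times the coarser of the two
pixel densities, derated by a safety factor ka in (0, 1] that absorbs
shape error and peel roughness:

    N1 = 2 ka pi (RC'/RC) min(m/theta0, n/phi0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .sensor import SensorModel

__all__ = [
    "FruitSpec",
    "FRUIT_SPECS",
    "cut_radius",
    "chord_offset",
    "circle_radius",
    "max_cut_depth",
    "expected_count",
    "min_cut_depth",
    "projected_pixel_count",
    "expected_curve_pixels",
]


@dataclass(frozen=True)
class FruitSpec:
    """Measured geometry of one citrus variety.

    ``Dp``/``De`` are the mean polar and equatorial diameters (mm) with
    their observed minus/plus spreads; ``rho = Dp/De`` is the shape
    coefficient (<0.9 oblate, 0.9-1 circular, >1 oval); ``L`` is the
    variety's cutting depth in integer mm.
    """

    variety: str
    Dp: float
    Dp_minus: float
    Dp_plus: float
    De: float
    De_minus: float
    De_plus: float
    rho: float
    rho_minus: float
    rho_plus: float
    L: int

    @property
    def mean_radius(self) -> float:
        """Single-sphere radius used by the cut geometry: (Dp + De) / 4."""
        return (self.Dp + self.De) / 4.0

    @property
    def max_radius(self) -> float:
        """Mean radius of the largest measured specimen of the variety."""
        return (self.Dp + self.Dp_plus + self.De + self.De_plus) / 4.0

    @property
    def Dp_range(self) -> tuple[float, float]:
        return (self.Dp - self.Dp_minus, self.Dp + self.Dp_plus)

    @property
    def De_range(self) -> tuple[float, float]:
        return (self.De - self.De_minus, self.De + self.De_plus)

    @property
    def rho_range(self) -> tuple[float, float]:
        """Measured spread of the shape coefficient Dp/De."""
        return (self.rho - self.rho_minus, self.rho + self.rho_plus)

    def shape_coefficient(self) -> float:
        """Recompute rho = Dp / De from the mean diameters."""
        return self.Dp / self.De


FRUIT_SPECS: dict[str, FruitSpec] = {
    s.variety: s
    for s in [
        FruitSpec("tangerine", 43.2, 9.9, 10.5, 55.0, 5.9, 6.2, 0.785, 0.107, 0.092, 5),
        FruitSpec("sugar_orange", 49.9, 3.1, 2.2, 54.3, 1.7, 0.8, 0.919, 0.029, 0.027, 6),
        FruitSpec("sichuan_orange", 55.0, 2.2, 4.3, 68.7, 2.5, 2.9, 0.802, 0.004, 0.026, 4),
        FruitSpec("ponkan", 58.6, 7.5, 7.9, 75.0, 6.1, 3.8, 0.781, 0.050, 0.063, 4),
        FruitSpec("gannan_navel", 66.9, 2.8, 2.5, 71.4, 3.0, 2.9, 0.937, 0.003, 0.001, 4),
        FruitSpec("egyptian_orange", 86.6, 2.1, 3.5, 77.9, 1.5, 1.2, 1.111, 0.005, 0.028, 3),
    ]
}


def cut_radius(RA: float, L: float) -> float:
    """Depth-sphere radius RC = RA + L for cutting depth L at closest point RA."""
    if RA <= 0:
        raise ValueError("RA must be positive")
    if L < 0:
        raise ValueError("cutting depth L must be >= 0")
    return RA + L


def max_cut_depth(R: float, RA: float) -> float:
    """Largest geometrically valid cutting depth (the cut plane reaches b=0).

    Solves b(L) = 0: L = sqrt((RA + R)^2 + R^2) - RA.
    """
    if R <= 0 or RA <= 0:
        raise ValueError("R and RA must be positive")
    return math.hypot(RA + R, R) - RA


def chord_offset(R: float, RA: float, L: float) -> float:
    """Distance b from the fruit center to the cut plane.

    b = (2 R^2 + 2 RA (R - L) - L^2) / (2 (RA + R)); b = R at L = 0 (the cut
    sphere touches the fruit at its closest point).
    """
    if R <= 0 or RA <= 0:
        raise ValueError("R and RA must be positive")
    if L < 0:
        raise ValueError("cutting depth L must be >= 0")
    b = (2.0 * R * R + 2.0 * RA * (R - L) - L * L) / (2.0 * (RA + R))
    if b < 0:
        raise ValueError(
            f"cut depth L={L} passes the fruit equator (b={b:.3f} < 0); "
            f"max valid L is {max_cut_depth(R, RA):.3f}"
        )
    if b > R * (1 + 1e-12):
        raise ValueError(f"cut misses the fruit sphere (b={b:.3f} > R={R})")
    return min(b, R)


def circle_radius(R: float, RA: float, L: float) -> float:
    """Radius RC' of the circular intersection curve: sqrt(R^2 - b^2)."""
    b = chord_offset(R, RA, L)
    return math.sqrt(max(R * R - b * b, 0.0))


def expected_count(
    R: float, RA: float, L: float, sensor: SensorModel, ka: float = 0.8
) -> float:
    """Expected depth-point count N1 of the intersection circle.

    N1 = 2 ka pi (RC'/RC) min(m/theta0, n/phi0): the circle's angular
    circumference seen from the sensor times the coarser pixel density,
    derated by the safety factor ka.
    """
    if not (0 < ka <= 1):
        raise ValueError("ka must lie in (0, 1]")
    rc = cut_radius(RA, L)
    rcp = circle_radius(R, RA, L)
    return 2.0 * ka * math.pi * (rcp / rc) * min(sensor.ppr_h, sensor.ppr_v)


def min_cut_depth(
    R: float,
    RA: float,
    sensor: SensorModel,
    ka: float = 0.8,
    required: float = 0.0,
) -> int:
    """Smallest integer cutting depth whose half-curve still yields enough points.

    Returns the smallest integer L >= 1 with 0.5 * N1(L) >= required — the
    factor 0.5 derates for a fruit of which only half the surface may be
    visible.  Raises if no geometrically valid L satisfies the bound.
    """
    if required < 0:
        raise ValueError("required count must be >= 0")
    L_hi = int(math.floor(max_cut_depth(R, RA)))
    for L in range(1, L_hi + 1):
        if 0.5 * expected_count(R, RA, float(L), sensor, ka) >= required:
            return L
    raise ValueError(
        f"no valid cutting depth up to {L_hi} mm yields {required} points"
    )


def expected_curve_pixels(
    R: float, RA: float, L: float, w: float, sensor: SensorModel
) -> float:
    """Approximate pixel count of the shell ring a fruit produces.

    The shell |r - RC| <= w maps to a ring of angular circumference
    2 pi RC'/RC and radial thickness 2 w dRC'/dL on the image; the product
    of circumference (in pixels of mean density) and thickness (plus one
    pixel of rasterisation) estimates the region size.  Used as a
    size-consistency ceiling: regions far larger than any fruit could
    produce at that range are leaf bands or merged clutter.
    """
    rc = cut_radius(RA, L)
    b = chord_offset(R, RA, L)
    rcp = math.sqrt(max(R * R - b * b, 1e-12))
    ppr = math.sqrt(sensor.ppr_h * sensor.ppr_v)
    circumference = 2.0 * math.pi * (rcp / rc) * ppr
    drcp_dl = b * (RA + L) / (rcp * (RA + R))
    thickness = 2.0 * w * drcp_dl * ppr / rc + 1.0
    return circumference * thickness


def projected_pixel_count(R: float, center_dist: float, sensor: SensorModel) -> float:
    """Expected pixel footprint of an unoccluded sphere.

    A sphere of radius R centered at radial distance d subtends an angular
    radius asin(R/d); its image is approximately an ellipse with semi-axes
    asin(R/d) * (pixels per radian) in each direction.
    """
    if center_dist <= R:
        raise ValueError("sphere must lie entirely in front of the sensor")
    alpha = math.asin(R / center_dist)
    return math.pi * alpha * alpha * sensor.ppr_h * sensor.ppr_v
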