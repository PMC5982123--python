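"""Virtual depth-camera description and pixel/angle conventions.

The sensor is an angular grid: pixel ``(i, j)`` (row ``i`` from the top,
column ``j`` from the left, 0-based) looks along the horizontal deflection
``theta = (j + 0.5 - m/2) * theta0 / m`` and the vertical deflection
``phi = (n/2 - i - 0.5) * phi0 / n``.  Depth values are perpendicular
distances to the focal plane (the device convention), so the ray through a
pixel is ``z * (tan(theta), tan(phi), 1)`` parameterised directly by depth
``z`` in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SensorModel", "make_sensor", "SENSOR_PRESETS"]


@dataclass(frozen=True)
class SensorModel:
    """Angular/resolution/range/noise description of a depth camera.

    Parameters
    ----------
    m, n : int
        Horizontal and vertical resolution in pixels.
    theta0, phi0 : float
        Horizontal and vertical field of view in radians.
    d_min, d_max : float
        Valid depth range in mm; returns outside it are invalid (0).
    noise_sd : float
        Standard deviation of additive per-pixel depth noise, mm.
    dropout_p : float
        Probability that a pixel returns an invalid (0) reading.
    """

    m: int
    n: int
    theta0: float
    phi0: float
    d_min: float
    d_max: float
    noise_sd: float = 1.0
    dropout_p: float = 0.01

    def __post_init__(self) -> None:
        if self.m <= 0 or self.n <= 0:
            raise ValueError("resolution must be positive")
        if not (0 < self.theta0 < math.pi and 0 < self.phi0 < math.pi):
            raise ValueError("field of view must lie in (0, pi)")
        if not (0 < self.d_min < self.d_max):
            raise ValueError("require 0 < d_min < d_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape as (rows, columns)."""
        return (self.n, self.m)

    @property
    def ppr_h(self) -> float:
        """Horizontal pixel density, pixels per radian (m / theta0)."""
        return self.m / self.theta0

    @property
    def ppr_v(self) -> float:
        """Vertical pixel density, pixels per radian (n / phi0)."""
        return self.n / self.phi0

    def col_angles(self) -> np.ndarray:
        """Horizontal deflection angle theta of every column (radians)."""
        j = np.arange(self.m)
        return (j + 0.5 - self.m / 2.0) * self.theta0 / self.m

    def row_angles(self) -> np.ndarray:
        """Vertical deflection angle phi of every row (radians)."""
        i = np.arange(self.n)
        return (self.n / 2.0 - i - 0.5) * self.phi0 / self.n

    def ray_slopes(self) -> tuple[np.ndarray, np.ndarray]:
        """(tan theta, tan phi) grids of shape (n, m).

        The 3D point seen at depth z through pixel (i, j) is
        ``(z * tan_theta[i, j], z * tan_phi[i, j], z)``.
        """
        tt = np.tan(self.col_angles())[None, :]
        tp = np.tan(self.row_angles())[:, None]
        return (
            np.broadcast_to(tt, (self.n, self.m)),
            np.broadcast_to(tp, (self.n, self.m)),
        )

    def scaled(self, m: int, n: int) -> "SensorModel":
        """Same optics and range at a different pixel resolution."""
        return replace(self, m=m, n=n)


# Nominal F200 optics: the device's angular field of view is not part of its
# published range/resolution sheet, so it is a configurable preset value.
SENSOR_PRESETS: dict[str, dict] = {
    "F200": dict(
        m=640,
        n=480,
        theta0=math.radians(73.0),
        phi0=math.radians(59.0),
        d_min=160.0,   # stable close-shot floor observed for the device
        d_max=1200.0,
        noise_sd=1.0,
        dropout_p=0.01,
    ),
}


def make_sensor(preset: str = "F200", **overrides) -> SensorModel:
    """Build a :class:`SensorModel` from a named preset.

    Any field may be overridden by keyword, e.g.
    ``make_sensor("F200", noise_sd=0.0, m=64, n=48)``.
    """
    try:
        params = dict(SENSOR_PRESETS[preset])
    except KeyError:
        known = ", ".join(sorted(SENSOR_PRESETS))
        raise ValueError(f"unknown sensor preset {preset!r}; known presets: {known}")
    params.update(overrides)
    return SensorModel(**params)
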