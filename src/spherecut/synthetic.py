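"""Synthetic canopy scenes rendered into depth frames with ground truth.

This module stands in for the physical depth camera: parametric fruit,
leaf and branch primitives are placed in the sensor frustum and rendered
by per-pixel analytic ray casting (z-buffer).  Fruits are spheroids with a
polar/equatorial diameter pair; leaves are elliptical patches, optionally
bent onto a cylinder (curl); branches are thin finite cylinders.  The
renderer adds Gaussian depth noise and pixel dropout, and reports per-pixel
class and object-id labels, per-fruit visible fractions, and which object
pairs are in surface contact — the ground truth every experiment scores
against.

Rendered depth is the perpendicular distance to the focal plane (device
convention); a ray through pixel (i, j) is ``z * (tan theta_j, tan phi_i, 1)``
so the depth value parameterises the ray directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .frames import DepthFrame, write_pgm
from .sensor import SensorModel, make_sensor

__all__ = [
    "SpheroidFruit",
    "LeafPatch",
    "BranchCylinder",
    "Scene",
    "GroundTruth",
    "ObjectInfo",
    "CollocationSpec",
    "sample_scene",
    "render_depth",
    "adhesion_level",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
    "write_ground_truth",
]

LABEL_CODES = {"background": 0, "fruit": 1, "leaf": 2, "branch": 3}


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def _orthobasis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic in-plane basis (u, w) for a given unit normal."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(float(normal @ ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(ref, normal))
    w = np.cross(normal, u)
    return u, w


@dataclass
class SpheroidFruit:
    """A fruit: spheroid with polar diameter Dp along `axis`, equatorial De."""

    center: np.ndarray
    Dp: float
    De: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    variety: str = "tangerine"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.Dp <= 0 or self.De <= 0:
            raise ValueError("diameters must be positive")
        self.axis = _unit(self.axis)

    @property
    def mean_radius(self) -> float:
        return (self.Dp + self.De) / 4.0

    @property
    def kind(self) -> str:
        return "fruit"


@dataclass
class LeafPatch:
    """An elliptical leaf patch, optionally curled onto a cylinder.

    The patch lies on a cylinder of radius 1/curl_curvature whose axis runs
    along the patch's major axis; curl_curvature = 0 is a flat ellipse.
    `normal` is the outward surface normal at the patch center.
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    normal: np.ndarray
    curl_curvature: float = 0.0
    major_axis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.curl_curvature < 0:
            raise ValueError("curl_curvature must be >= 0")
        self.normal = _unit(self.normal)
        if self.major_axis is None:
            self.major_axis = _orthobasis(self.normal)[0]
        else:
            ma = np.asarray(self.major_axis, dtype=float)
            ma = ma - (ma @ self.normal) * self.normal  # enforce in-plane
            self.major_axis = _unit(ma)

    @property
    def kind(self) -> str:
        return "leaf"


@dataclass
class BranchCylinder:
    """A thin finite cylinder between endpoints p0 and p1."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate cylinder: p0 == p1")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)

    @property
    def kind(self) -> str:
        return "branch"


SceneObject = Union[SpheroidFruit, LeafPatch, BranchCylinder]


@dataclass
class Scene:
    """A collection of primitives in front of a sensor.

    `backdrop_depth`, when set, fills otherwise-empty pixels with a far
    wall at that constant depth (labelled background).  `illumination` is
    carried for bookkeeping only — depth rendering never reads it.
    """

    objects: list
    sensor: SensorModel
    seed: int = 0
    backdrop_depth: Optional[float] = None
    illumination: str = "light"

    def __post_init__(self) -> None:
        for obj in self.objects:
            if float(obj.center[2]) <= 0:
                raise ValueError("object centers must lie in front of the sensor")

    def fruits(self) -> list[tuple[int, SpheroidFruit]]:
        return [(k, o) for k, o in enumerate(self.objects) if o.kind == "fruit"]

    def rotated(self, angle_deg: float, pivot: np.ndarray) -> "Scene":
        """The scene rotated about the vertical axis through `pivot`."""
        a = math.radians(angle_deg)
        rot = np.array(
            [[math.cos(a), 0.0, math.sin(a)],
             [0.0, 1.0, 0.0],
             [-math.sin(a), 0.0, math.cos(a)]]
        )
        pivot = np.asarray(pivot, dtype=float)

        def rp(p):  # rotate position
            return rot @ (np.asarray(p, dtype=float) - pivot) + pivot

        def rd(d):  # rotate direction
            return rot @ np.asarray(d, dtype=float)

        new_objs = []
        for o in self.objects:
            if o.kind == "fruit":
                new_objs.append(
                    SpheroidFruit(rp(o.center), o.Dp, o.De, rd(o.axis), o.variety)
                )
            elif o.kind == "leaf":
                new_objs.append(
                    LeafPatch(rp(o.center), o.semi_major, o.semi_minor,
                              rd(o.normal), o.curl_curvature, rd(o.major_axis))
                )
            else:
                new_objs.append(BranchCylinder(rp(o.p0), rp(o.p1), o.radius))
        return replace(self, objects=new_objs)


@dataclass
class ObjectInfo:
    """Ground-truth summary of one scene object."""

    id: int
    kind: str
    center: np.ndarray
    radius: float


@dataclass
class GroundTruth:
    """Per-pixel labels plus per-object visibility and contact topology."""

    label_image: np.ndarray       # uint8 codes per LABEL_CODES
    object_id_image: np.ndarray   # int32 object index, -1 = none
    visible_fraction: dict        # fruit id -> fraction of solo pixels visible
    contact_pairs: list           # sorted (id, id) tuples with surface contact
    objects: list                 # list of ObjectInfo

    def fruit_ids(self) -> list[int]:
        return [o.id for o in self.objects if o.kind == "fruit"]


# ---------------------------------------------------------------------------
# ray casting

@lru_cache(maxsize=8)
def _ray_grid(m: int, n: int, theta0: float, phi0: float):
    sensor = SensorModel(m, n, theta0, phi0, 1.0, 2.0, 0.0, 0.0)
    tt, tp = sensor.ray_slopes()
    return np.ascontiguousarray(tt), np.ascontiguousarray(tp)


def _dot_rays(tt, tp, vec):
    """Per-pixel dot product of ray direction (tt, tp, 1) with a constant vector."""
    return tt * vec[0] + tp * vec[1] + vec[2]


def _intersect_spheroid(tt, tp, fruit: SpheroidFruit) -> np.ndarray:
    ap = fruit.Dp / 2.0
    ae = fruit.De / 2.0
    a_hat = fruit.axis
    c = fruit.center
    k = 1.0 / (ae * ae)
    dk = 1.0 / (ap * ap) - k
    v_dot_a = _dot_rays(tt, tp, a_hat)
    v_dot_c = _dot_rays(tt, tp, c)
    v_sq = tt * tt + tp * tp + 1.0
    c_dot_a = float(c @ a_hat)
    vMv = v_sq * k + v_dot_a * v_dot_a * dk
    vMc = v_dot_c * k + v_dot_a * c_dot_a * dk
    cMc = float(c @ c) * k + c_dot_a * c_dot_a * dk
    disc = vMc * vMc - vMv * (cMc - 1.0)
    z = np.full(tt.shape, np.inf)
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    z1 = np.where(hit, (vMc - sq) / vMv, np.inf)
    z2 = np.where(hit, (vMc + sq) / vMv, np.inf)
    z = np.where(z1 > 0, z1, np.where(z2 > 0, z2, np.inf))
    return np.where(hit, z, np.inf)


def _intersect_leaf(tt, tp, leaf: LeafPatch) -> np.ndarray:
    n_hat = leaf.normal
    u = leaf.major_axis
    w_dir = np.cross(n_hat, u)
    a, b = leaf.semi_major, leaf.semi_minor
    c = leaf.center
    if leaf.curl_curvature < 1e-9:
        denom = _dot_rays(tt, tp, n_hat)
        num = float(c @ n_hat)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = num / denom
        z = np.where((np.abs(denom) > 1e-12) & (z > 0), z, np.inf)
        finite = np.isfinite(z)
        zf = np.where(finite, z, 0.0)
        px = zf * tt - c[0]
        py = zf * tp - c[1]
        pz = zf - c[2]
        xi = px * u[0] + py * u[1] + pz * u[2]
        eta = px * w_dir[0] + py * w_dir[1] + pz * w_dir[2]
        inside = (xi / a) ** 2 + (eta / b) ** 2 <= 1.0
        return np.where(finite & inside, z, np.inf)

    # curled: the patch lies on a cylinder of radius rho with axis along u
    rho = 1.0 / leaf.curl_curvature
    q0 = c - rho * n_hat  # axis point
    v_dot_u = _dot_rays(tt, tp, u)
    q0_dot_u = float(q0 @ u)
    # perpendicular components (relative to the axis direction u)
    vperp = [
        tt - v_dot_u * u[0],
        tp - v_dot_u * u[1],
        1.0 - v_dot_u * u[2],
    ]
    q0perp = q0 - q0_dot_u * u
    A = vperp[0] ** 2 + vperp[1] ** 2 + vperp[2] ** 2
    B = -2.0 * (vperp[0] * q0perp[0] + vperp[1] * q0perp[1] + vperp[2] * q0perp[2])
    C = float(q0perp @ q0perp) - rho * rho
    disc = B * B - 4.0 * A * C
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    best = np.full(tt.shape, np.inf)
    for sign in (-1.0, 1.0):
        z = np.where(hit, (-B + sign * sq) / (2.0 * A), np.inf)
        ok = hit & (z > 0)
        zf = np.where(ok, z, 0.0)
        px = zf * tt - q0[0]
        py = zf * tp - q0[1]
        pz = zf - q0[2]
        xi = px * u[0] + py * u[1] + pz * u[2]
        ex = px - xi * u[0]
        ey = py - xi * u[1]
        ez = pz - xi * u[2]
        cos_comp = ex * n_hat[0] + ey * n_hat[1] + ez * n_hat[2]
        sin_comp = ex * w_dir[0] + ey * w_dir[1] + ez * w_dir[2]
        alpha = np.arctan2(sin_comp, cos_comp)
        eta = rho * alpha
        inside = (xi / a) ** 2 + (eta / b) ** 2 <= 1.0
        cand = np.where(ok & inside, z, np.inf)
        best = np.minimum(best, cand)
    return best


def _intersect_branch(tt, tp, br: BranchCylinder) -> np.ndarray:
    u = _unit(br.p1 - br.p0)
    length = float(np.linalg.norm(br.p1 - br.p0))
    v_dot_u = _dot_rays(tt, tp, u)
    p0_dot_u = float(br.p0 @ u)
    vperp = [
        tt - v_dot_u * u[0],
        tp - v_dot_u * u[1],
        1.0 - v_dot_u * u[2],
    ]
    p0perp = br.p0 - p0_dot_u * u
    A = vperp[0] ** 2 + vperp[1] ** 2 + vperp[2] ** 2
    B = -2.0 * (vperp[0] * p0perp[0] + vperp[1] * p0perp[1] + vperp[2] * p0perp[2])
    C = float(p0perp @ p0perp) - br.radius ** 2
    disc = B * B - 4.0 * A * C
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    best = np.full(tt.shape, np.inf)
    for sign in (-1.0, 1.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(hit & (A > 0), (-B + sign * sq) / (2.0 * A), np.inf)
        ok = hit & (z > 0) & np.isfinite(z)
        zf = np.where(ok, z, 0.0)
        axial = (zf * tt - br.p0[0]) * u[0] + (zf * tp - br.p0[1]) * u[1] \
            + (zf - br.p0[2]) * u[2]
        inside = (axial >= 0) & (axial <= length)
        cand = np.where(ok & inside, z, np.inf)
        best = np.minimum(best, cand)
    return best


def _intersect(tt, tp, obj: SceneObject) -> np.ndarray:
    if obj.kind == "fruit":
        return _intersect_spheroid(tt, tp, obj)
    if obj.kind == "leaf":
        return _intersect_leaf(tt, tp, obj)
    return _intersect_branch(tt, tp, obj)


def render_depth(scene: Scene, seed: Optional[int] = None) -> tuple[DepthFrame, GroundTruth]:
    """Render a scene to a noisy depth frame plus noise-free ground truth.

    Per pixel the nearest analytic ray-primitive intersection wins
    (z-buffer); labels and object ids come from the winner before noise.
    Gaussian noise (sensor.noise_sd) and dropout (sensor.dropout_p) are then
    applied with a generator seeded by `seed` (default: scene.seed).
    Per-fruit visible fraction = occluded-render pixels / solo-render
    pixels; contact pairs are object pairs whose noise-free surface clouds
    come within 2 mm of each other.
    """
    sensor = scene.sensor
    if seed is None:
        seed = scene.seed
    tt, tp = _ray_grid(sensor.m, sensor.n, sensor.theta0, sensor.phi0)

    n_obj = len(scene.objects)
    zmaps = [_intersect(tt, tp, o) for o in scene.objects]
    if n_obj:
        stack = np.stack(zmaps)
        winner = np.argmin(stack, axis=0)
        zbuf = np.take_along_axis(stack, winner[None], axis=0)[0]
    else:
        winner = np.zeros(sensor.shape, dtype=int)
        zbuf = np.full(sensor.shape, np.inf)

    in_range = np.isfinite(zbuf) & (zbuf >= sensor.d_min) & (zbuf <= sensor.d_max)
    object_id = np.where(in_range, winner, -1).astype(np.int32)
    label = np.zeros(sensor.shape, dtype=np.uint8)
    for k, obj in enumerate(scene.objects):
        label[object_id == k] = LABEL_CODES[obj.kind]

    # per-fruit visibility from the already-computed per-object maps
    visible_fraction: dict[int, float] = {}
    solo_valid = []
    for k, obj in enumerate(scene.objects):
        sv = np.isfinite(zmaps[k]) & (zmaps[k] >= sensor.d_min) & (zmaps[k] <= sensor.d_max)
        solo_valid.append(sv)
        if obj.kind == "fruit":
            solo = int(sv.sum())
            vis = int(((object_id == k) & sv).sum())
            visible_fraction[k] = (vis / solo) if solo else 0.0

    # contact: min distance between noise-free surface clouds <= 2 mm
    contact_pairs: list[tuple[int, int]] = []
    if n_obj > 1:
        clouds = []
        for k in range(n_obj):
            sv = solo_valid[k]
            svs = sv.copy()
            svs[::2, :] = False  # subsample rows for speed
            if svs.sum() < 30:
                svs = sv
            zk = zmaps[k][svs]
            pts = np.column_stack([zk * tt[svs], zk * tp[svs], zk])
            clouds.append(pts)
        trees = [cKDTree(c) if len(c) else None for c in clouds]
        for a in range(n_obj):
            for b in range(a + 1, n_obj):
                if trees[a] is None or len(clouds[b]) == 0:
                    continue
                d, _ = trees[a].query(clouds[b], k=1, distance_upper_bound=2.0)
                if np.any(np.isfinite(d)):
                    contact_pairs.append((a, b))

    rng = np.random.default_rng(seed)
    vals = np.where(in_range, zbuf, 0.0)
    if scene.backdrop_depth is not None:
        back = ~in_range
        vals = np.where(back, scene.backdrop_depth, vals)
    measured = vals > 0
    if sensor.noise_sd > 0:
        noise = rng.normal(0.0, sensor.noise_sd, size=vals.shape)
        vals = np.where(measured, vals + noise, 0.0)
    if sensor.dropout_p > 0:
        drop = rng.random(vals.shape) < sensor.dropout_p
        vals = np.where(drop, 0.0, vals)
    vals = np.where((vals >= sensor.d_min) & (vals <= sensor.d_max), vals, 0.0)

    infos = []
    for k, obj in enumerate(scene.objects):
        if obj.kind == "fruit":
            radius = obj.mean_radius
        elif obj.kind == "leaf":
            radius = obj.semi_major
        else:
            radius = obj.radius
        infos.append(ObjectInfo(k, obj.kind, np.asarray(obj.center, float), radius))

    truth = GroundTruth(label, object_id, visible_fraction, contact_pairs, infos)
    return DepthFrame(vals, sensor_tag="F200" if (sensor.m, sensor.n) == (640, 480) else None), truth


def adhesion_level(truth: GroundTruth, fruit_id: int) -> str:
    """'little' iff >50% of the fruit surface is visible and nothing touches it."""
    if fruit_id not in truth.visible_fraction:
        raise KeyError(f"object {fruit_id} is not a fruit of this scene")
    touched = any(fruit_id in pair for pair in truth.contact_pairs)
    if truth.visible_fraction[fruit_id] > 0.5 and not touched:
        return "little"
    return "serious"


# ---------------------------------------------------------------------------
# scene sampling

@dataclass
class CollocationSpec:
    """Counts, variety and placement ranges for one sampled arrangement."""

    n_fruits: int = 1
    n_leaves: int = 0
    n_branches: int = 0
    variety: str = "tangerine"
    depth_range: tuple[float, float] = (250.0, 600.0)
    adherent_fruit_pairs: int = 0
    leaf_mode: str = "free"            # free | adjacent | occluding | mixed
    leaf_tilt_max_deg: float = 60.0
    leaf_curl_max: float = 1.0 / 60.0
    leaf_semi_major: tuple[float, float] = (25.0, 60.0)
    rotation_deg: float = 0.0
    backdrop_depth: Optional[float] = None
    noise_sd: float = 1.0
    dropout_p: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_fruits, self.n_leaves, self.n_branches) < 0:
            raise ValueError("object counts must be >= 0")
        if self.leaf_mode not in ("free", "adjacent", "occluding", "mixed"):
            raise ValueError(f"unknown leaf_mode {self.leaf_mode!r}")


def _rand_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _leaf_orientation(rng, tilt_max_deg: float):
    """Leaf normal facing the sensor, tilted up to tilt_max from frontal.

    The tilt is distributed uniformly over the spherical cap (density
    proportional to sin tilt): a random 3D posture, under which near-frontal
    leaves — the one geometry whose depth-sphere cut is circular — are
    appropriately rare.
    """
    cap = 1.0 - math.cos(math.radians(tilt_max_deg))
    tilt = math.acos(1.0 - rng.uniform(0.0, 1.0) * cap)
    az = rng.uniform(0.0, 2.0 * math.pi)
    n_hat = np.array(
        [math.sin(tilt) * math.cos(az), math.sin(tilt) * math.sin(az), -math.cos(tilt)]
    )
    if rng.random() < 0.5:
        n_hat = -n_hat  # curled blades bow away from the sensor as often as toward
    u, w = _orthobasis(n_hat)
    spin = rng.uniform(0.0, 2.0 * math.pi)
    major = math.cos(spin) * u + math.sin(spin) * w
    return n_hat, major


def _vertical_dominant_dir(rng, z_damp: float = 0.35) -> np.ndarray:
    """Random offset direction biased toward the vertical (y) axis."""
    beta = math.radians(rng.uniform(0.0, 40.0))     # from vertical
    gamma = rng.uniform(0.0, 2.0 * math.pi)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    d = np.array(
        [math.sin(beta) * math.cos(gamma),
         sign * math.cos(beta),
         z_damp * math.sin(beta) * math.sin(gamma)]
    )
    return _unit(d)


def _inside_frustum(center, margin, sensor: SensorModel, d_lo, d_hi) -> bool:
    x, y, z = float(center[0]), float(center[1]), float(center[2])
    if not (d_lo + margin <= z <= d_hi - margin):
        return False
    half_w = z * math.tan(sensor.theta0 / 2.0)
    half_h = z * math.tan(sensor.phi0 / 2.0)
    return abs(x) <= half_w - margin and abs(y) <= half_h - margin


def sample_scene(collocation: CollocationSpec, seed: int) -> Scene:
    """Sample a random scene matching a collocation spec; deterministic in seed.

    Fruit diameters are drawn uniformly within the variety's measured
    min/max bounds.  Multi-object arrangements are built around a pivot and
    finally rotated by ``rotation_deg`` about the vertical axis through it
    (the turn-table of the physical experiments).  Placement is retried a
    bounded number of times until everything sits inside the frustum
    between d_min and d_max.
    """
    from .geometry import FRUIT_SPECS

    spec = FRUIT_SPECS[collocation.variety]
    rng = np.random.default_rng(seed)
    sensor = make_sensor(
        "F200", noise_sd=collocation.noise_sd, dropout_p=collocation.dropout_p
    )
    d_lo, d_hi = collocation.depth_range
    n_total = collocation.n_fruits + collocation.n_leaves + collocation.n_branches
    if n_total == 0:
        return Scene([], sensor, seed=seed, backdrop_depth=collocation.backdrop_depth)

    for _attempt in range(60):
        objects: list[SceneObject] = []
        fruits: list[SpheroidFruit] = []
        single = n_total == 1
        if single:
            zc = rng.uniform(d_lo, d_hi)
            half_w = zc * math.tan(sensor.theta0 / 2.0)
            half_h = zc * math.tan(sensor.phi0 / 2.0)
            pivot = np.array(
                [rng.uniform(-0.5, 0.5) * half_w, rng.uniform(-0.5, 0.5) * half_h, zc]
            )
        else:
            zc = rng.uniform(max(d_lo, 330.0), min(d_hi, 520.0))
            pivot = np.array(
                [rng.uniform(-40.0, 40.0), rng.uniform(-40.0, 40.0), zc]
            )

        ok = True
        for k in range(collocation.n_fruits):
            # uniform within the measured diameter bounds, constrained to the
            # measured spread of the shape coefficient Dp/De
            rho_lo, rho_hi = spec.rho_range
            for _draw in range(200):
                Dp = rng.uniform(*spec.Dp_range)
                De = rng.uniform(*spec.De_range)
                if rho_lo <= Dp / De <= rho_hi:
                    break
            axis = _rand_unit(rng)
            R = (Dp + De) / 4.0
            if k == 0:
                center = pivot + np.array(
                    [rng.uniform(-15, 15), rng.uniform(-15, 15), rng.uniform(-15, 15)]
                ) * (0.0 if single else 1.0)
            elif k <= collocation.adherent_fruit_pairs:
                partner = fruits[k - 1]
                dz = rng.uniform(-0.3, 0.3)
                az = rng.uniform(0.0, 2.0 * math.pi)
                lat = math.sqrt(1.0 - dz * dz)
                d = np.array([lat * math.cos(az), lat * math.sin(az), dz])
                center = partner.center + d * (partner.mean_radius + R) * 0.995
            else:
                placed = False
                for _try in range(40):
                    az = rng.uniform(0.0, 2.0 * math.pi)
                    dist = rng.uniform(70.0, 150.0)
                    center = pivot + np.array(
                        [dist * math.cos(az), dist * math.sin(az), rng.uniform(-25, 25)]
                    )
                    gaps = [
                        np.linalg.norm(center - f.center) - R - f.mean_radius
                        for f in fruits
                    ]
                    if not gaps or min(gaps) > 20.0:
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            fruit = SpheroidFruit(center, Dp, De, axis, collocation.variety)
            fruits.append(fruit)
            objects.append(fruit)
        if not ok:
            continue

        for _k in range(collocation.n_leaves):
            a = rng.uniform(*collocation.leaf_semi_major)
            b = a * rng.uniform(0.35, 0.6)  # lanceolate blade proportions
            curl = rng.uniform(0.0, collocation.leaf_curl_max)
            n_hat, major = _leaf_orientation(rng, collocation.leaf_tilt_max_deg)
            mode = collocation.leaf_mode
            if mode == "mixed":
                mode = "adjacent" if rng.random() < 0.5 else "occluding"
            if mode in ("adjacent", "occluding") and fruits:
                host = fruits[int(rng.integers(len(fruits)))]
                if mode == "adjacent":
                    d = _vertical_dominant_dir(rng)
                    center = host.center + d * (host.mean_radius + 0.35 * b)
                else:
                    d = _vertical_dominant_dir(rng)
                    lat = d * host.mean_radius * rng.uniform(0.8, 1.3)
                    center = host.center + lat - np.array(
                        [0.0, 0.0, host.mean_radius + rng.uniform(10.0, 30.0)]
                    )
            else:
                if single:
                    center = pivot
                else:
                    az = rng.uniform(0.0, 2.0 * math.pi)
                    dist = rng.uniform(60.0, 160.0)
                    center = pivot + np.array(
                        [dist * math.cos(az), dist * math.sin(az), rng.uniform(-40, 40)]
                    )
            objects.append(LeafPatch(center, a, b, n_hat, curl, major))

        for _k in range(collocation.n_branches):
            bc = pivot + np.array(
                [rng.uniform(-30, 30), rng.uniform(-30, 30), rng.uniform(35.0, 85.0)]
            )
            gamma = rng.uniform(0.0, 2.0 * math.pi)
            d = _unit(np.array(
                [math.cos(gamma), rng.uniform(-0.3, 0.3), 0.15 * math.sin(gamma)]
            ))
            hl = rng.uniform(120.0, 200.0)
            objects.append(
                BranchCylinder(bc - d * hl, bc + d * hl, rng.uniform(3.0, 6.0))
            )

        scene = Scene(
            objects, sensor, seed=seed, backdrop_depth=collocation.backdrop_depth
        ).rotated(collocation.rotation_deg, pivot)

        good = True
        for obj in scene.objects:
            margin = getattr(obj, "mean_radius", None)
            if margin is None:
                margin = 10.0
            if not _inside_frustum(obj.center, margin, sensor, sensor.d_min, sensor.d_max):
                good = False
                break
        if good:
            return scene
    raise RuntimeError("could not place all objects inside the frustum")


# ---------------------------------------------------------------------------
# scene/ground-truth serialization

def scene_to_dict(scene: Scene) -> dict:
    objs = []
    for o in scene.objects:
        if o.kind == "fruit":
            objs.append(dict(
                type="fruit", center=o.center.tolist(), Dp=o.Dp, De=o.De,
                axis=o.axis.tolist(), variety=o.variety,
            ))
        elif o.kind == "leaf":
            objs.append(dict(
                type="leaf", center=o.center.tolist(), semi_major=o.semi_major,
                semi_minor=o.semi_minor, normal=o.normal.tolist(),
                curl_curvature=o.curl_curvature, major_axis=o.major_axis.tolist(),
            ))
        else:
            objs.append(dict(
                type="branch", p0=o.p0.tolist(), p1=o.p1.tolist(), radius=o.radius,
            ))
    s = scene.sensor
    return dict(
        sensor=dict(m=s.m, n=s.n, theta0=s.theta0, phi0=s.phi0, d_min=s.d_min,
                    d_max=s.d_max, noise_sd=s.noise_sd, dropout_p=s.dropout_p),
        seed=scene.seed,
        backdrop_depth=scene.backdrop_depth,
        illumination=scene.illumination,
        objects=objs,
    )


def scene_from_dict(d: dict) -> Scene:
    sensor = SensorModel(**d["sensor"])
    objects: list[SceneObject] = []
    for o in d.get("objects", []):
        t = o["type"]
        if t == "fruit":
            objects.append(SpheroidFruit(
                np.array(o["center"]), o["Dp"], o["De"],
                np.array(o.get("axis", [0, 1, 0])), o.get("variety", "tangerine"),
            ))
        elif t == "leaf":
            ma = o.get("major_axis")
            objects.append(LeafPatch(
                np.array(o["center"]), o["semi_major"], o["semi_minor"],
                np.array(o["normal"]), o.get("curl_curvature", 0.0),
                np.array(ma) if ma is not None else None,
            ))
        elif t == "branch":
            objects.append(BranchCylinder(
                np.array(o["p0"]), np.array(o["p1"]), o["radius"],
            ))
        else:
            raise ValueError(f"unknown object type {t!r}")
    return Scene(
        objects, sensor, seed=int(d.get("seed", 0)),
        backdrop_depth=d.get("backdrop_depth"),
        illumination=d.get("illumination", "light"),
    )


def save_scene(scene: Scene, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh, sort_keys=False)


def load_scene(path) -> Scene:
    with open(path) as fh:
        return scene_from_dict(yaml.safe_load(fh))


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Write the label image as a PGM plus a CSV object table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pgm(DepthFrame(truth.label_image.astype(float)), out / "labels.pgm")
    import pandas as pd

    rows = []
    for o in truth.objects:
        rows.append(dict(
            id=o.id, type=o.kind,
            x_mm=o.center[0], y_mm=o.center[1], z_mm=o.center[2],
            radius_mm=o.radius,
            visible_fraction=truth.visible_fraction.get(o.id, ""),
        ))
    pd.DataFrame(rows).to_csv(out / "objects.csv", index=False)
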