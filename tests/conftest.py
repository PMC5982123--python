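import math

import numpy as np
import pytest
from hypothesis import settings

from spherecut import Scene, SpheroidFruit, make_sensor

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def f200():
    return make_sensor("F200")


@pytest.fixture(scope="session")
def clean_f200():
    """Full-resolution sensor without noise or dropout."""
    return make_sensor("F200", noise_sd=0.0, dropout_p=0.0)


@pytest.fixture(scope="session")
def tiny_sensor():
    """Low-resolution noise-free sensor for brute-force oracles."""
    return make_sensor("F200", m=64, n=48, noise_sd=0.0, dropout_p=0.0)


@pytest.fixture()
def axis_sphere_scene(clean_f200):
    """A 55 mm sphere centered on the optical axis at 400 mm."""
    fruit = SpheroidFruit([0.0, 0.0, 400.0], 55.0, 55.0)
    return Scene([fruit], clean_f200)


# ---------------------------------------------------------------------------
# independent brute-force ray oracle (kept separate from the renderer's math)

def _roots_smallest_positive(coeffs):
    roots = np.roots(coeffs)
    best = math.inf
    for r in roots:
        if abs(r.imag) < 1e-9 and r.real > 1e-9:
            best = min(best, r.real)
    return best


def oracle_pixel_depth(scene, i, j):
    """Nearest analytic intersection depth for pixel (i, j), or inf.

    Independent implementation: quadratics are solved via np.roots after an
    explicit change of basis per primitive.
    """
    s = scene.sensor
    theta = (j + 0.5 - s.m / 2.0) * s.theta0 / s.m
    phi = (s.n / 2.0 - i - 0.5) * s.phi0 / s.n
    d = np.array([math.tan(theta), math.tan(phi), 1.0])
    best = math.inf
    for obj in scene.objects:
        if obj.kind == "fruit":
            a_hat = obj.axis
            e1 = np.cross(a_hat, [1.0, 0.0, 0.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(a_hat, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(a_hat, e1)
            basis = np.vstack([a_hat, e1, e2])
            scale = np.array([2.0 / obj.Dp, 2.0 / obj.De, 2.0 / obj.De])
            dd = scale * (basis @ d)
            cc = scale * (basis @ obj.center)
            z = _roots_smallest_positive(
                [dd @ dd, -2.0 * dd @ cc, cc @ cc - 1.0]
            )
        elif obj.kind == "leaf":
            n_hat, u = obj.normal, obj.major_axis
            w_dir = np.cross(n_hat, u)
            if obj.curl_curvature < 1e-9:
                denom = d @ n_hat
                if abs(denom) < 1e-12:
                    continue
                z = (obj.center @ n_hat) / denom
                if z <= 0:
                    continue
                q = z * d - obj.center
                if (q @ u / obj.semi_major) ** 2 + (q @ w_dir / obj.semi_minor) ** 2 > 1:
                    continue
            else:
                rho = 1.0 / obj.curl_curvature
                q0 = obj.center - rho * n_hat
                dp = d - (d @ u) * u
                qp = q0 - (q0 @ u) * u
                roots = np.roots([dp @ dp, -2.0 * dp @ qp, qp @ qp - rho * rho])
                z = math.inf
                for root in roots:
                    if abs(root.imag) > 1e-9 or root.real <= 1e-9:
                        continue
                    p = root.real * d - q0
                    xi = p @ u
                    rad = p - xi * u
                    alpha = math.atan2(rad @ w_dir, rad @ n_hat)
                    eta = rho * alpha
                    if (xi / obj.semi_major) ** 2 + (eta / obj.semi_minor) ** 2 <= 1:
                        z = min(z, root.real)
                if not math.isfinite(z):
                    continue
        else:  # branch
            u = obj.p1 - obj.p0
            length = np.linalg.norm(u)
            u = u / length
            dp = d - (d @ u) * u
            qp = obj.p0 - (obj.p0 @ u) * u
            roots = np.roots([dp @ dp, -2.0 * dp @ qp, qp @ qp - obj.radius**2])
            z = math.inf
            for root in roots:
                if abs(root.imag) > 1e-9 or root.real <= 1e-9:
                    continue
                axial = (root.real * d - obj.p0) @ u
                if 0 <= axial <= length:
                    z = min(z, root.real)
            if not math.isfinite(z):
                continue
        if math.isfinite(z) and s.d_min <= z <= s.d_max:
            best = min(best, z)
    return best
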