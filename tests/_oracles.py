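"""Independent numerical oracles used by the test suite.

Each oracle avoids the closed forms and quadrature rules of the package:
volumes come from Monte-Carlo point-in-solid sampling, areas from a
parametric triangulation, and growth curves from an adaptive ODE solver.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from livergrowth.geometry import PrismLiverShape, TorusLiverShape
from livergrowth.growth import GrowthConfig
from livergrowth.partial import PartialGrowthParams, active_volume


def mc_torus_volume(r: float, d: float, P: float, n: int = 10**7,
                    seed: int = 20140609) -> float:
    """Monte-Carlo volume of the capped partial torus sliced at z = 0.

    Samples the half-space box (y >= 0 exploited by symmetry) and tests
    membership in the union of the tube (angular span ``2 pi P`` symmetric
    about +x) and the hemisphere cap beyond the end plane at angle
    ``pi P``.
    """
    rng = np.random.default_rng(seed)
    lim = d + r
    phi0 = np.pi * P
    cap_c = np.array([d * np.cos(phi0), d * np.sin(phi0), 0.0])
    cap_t = np.array([-np.sin(phi0), np.cos(phi0), 0.0])  # outward tangent
    total_in = 0
    chunk = 2 * 10**6
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        x = rng.uniform(-lim, lim, m)
        y = rng.uniform(0.0, lim, m)       # y >= 0 half; solid is mirror-symmetric
        z = rng.uniform(0.0, r, m)
        phi = np.arctan2(y, x)
        rad = np.hypot(x, y)
        in_tube = (phi <= phi0) & ((rad - d) ** 2 + z**2 <= r**2)
        dx = x - cap_c[0]
        dy = y - cap_c[1]
        in_cap = (dx**2 + dy**2 + z**2 <= r**2) \
            & (dx * cap_t[0] + dy * cap_t[1] >= 0)
        total_in += int(np.count_nonzero(in_tube | in_cap))
    box = (2 * lim) * lim * r  # y-half box
    return 2.0 * box * total_in / n


def mc_prism_volume(shape: PrismLiverShape, length: float, n: int = 10**7,
                    seed: int = 20140609) -> float:
    """Monte-Carlo volume of the cut trapezoidal prism."""
    rng = np.random.default_rng(seed)
    c = shape.cot_alpha
    if shape.lobe == "left":
        h_max = shape.B + c * length
        def height(x):
            return shape.B + c * x
    else:
        h_max = shape.B_X
        def height(x):
            return shape.B_X - c * x
    total_in = 0
    chunk = 2 * 10**6
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        x = rng.uniform(0.0, length, m)
        y = rng.uniform(0.0, h_max, m)
        total_in += int(np.count_nonzero(y <= height(x)))
    box = length * h_max * shape.W
    return box * total_in / n


def _patch_area(points: np.ndarray) -> float:
    """Total area of a (nu, nv, 3) parametric grid, split into triangles."""
    a = points[:-1, :-1]
    b = points[1:, :-1]
    c = points[:-1, 1:]
    d = points[1:, 1:]

    def tri(p, q, r):
        return 0.5 * np.linalg.norm(np.cross(q - p, r - p), axis=-1)

    return float(np.sum(tri(a, b, c) + tri(d, c, b)))


def mesh_torus_surface(r: float, d: float, P: float, n: int = 800) -> float:
    """Triangulated area of the curved faces of the sliced capped torus
    (upper tube half plus the two quarter-sphere caps)."""
    phi0 = np.pi * P
    u = np.linspace(0.0, np.pi, n)          # poloidal, z >= 0 half
    phi = np.linspace(-phi0, phi0, n)
    uu, pp = np.meshgrid(u, phi, indexing="ij")
    tube = np.stack([(d + r * np.cos(uu)) * np.cos(pp),
                     (d + r * np.cos(uu)) * np.sin(pp),
                     r * np.sin(uu)], axis=-1)
    area = _patch_area(tube)

    for sgn in (+1.0, -1.0):
        ang = sgn * phi0
        e_r = np.array([np.cos(ang), np.sin(ang), 0.0])
        e_t = sgn * np.array([-np.sin(ang), np.cos(ang), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        center = d * e_r
        theta = np.linspace(0.0, np.pi / 2, n)      # polar from +z
        psi = np.linspace(-np.pi / 2, np.pi / 2, n)  # azimuth about e_t
        tt, ss = np.meshgrid(theta, psi, indexing="ij")
        direc = (np.sin(tt)[..., None] * (np.cos(ss)[..., None] * e_t
                                          + np.sin(ss)[..., None] * e_r)
                 + np.cos(tt)[..., None] * e_z)
        area += _patch_area(center + r * direc)
    return area


def ode_growth_curve(shape, config: GrowthConfig,
                     params: PartialGrowthParams | None = None,
                     rtol: float = 1e-10):
    """Adaptive high-accuracy solve of the growth equation.

    Integrates the growth variable x(t) with
    ``dx/dt = (K/rho) V_a(V(x)) G(x) / V'(x)`` (central-difference V'),
    stopping just short of the maximum size.  Returns a callable
    ``volume(t)`` and the terminal time.
    """
    x_b, x_e = shape.growth_range
    s_max = shape.surface(x_e)
    v_max = shape.volume(x_e)
    v_b = shape.volume(x_b)
    h = (x_e - x_b) * 1e-7

    def dxdt(t, x):
        xx = np.clip(x[0], x_b, x_e)
        V = shape.volume(xx)
        G = (shape.surface(xx) / s_max) / (V / v_max) - 1.0
        va = V if params is None else active_volume(V, params, v_b)
        dV = (shape.volume(min(xx + h, x_e)) - shape.volume(max(xx - h, x_b))) \
            / (min(xx + h, x_e) - max(xx - h, x_b))
        return [(config.K / config.rho) * va * max(G, 0.0) / dV]

    # stop at 99.99% of the growth range; time diverges at the endpoint
    x_stop = x_e - 1e-4 * (x_e - x_b)

    def reached(t, x):
        return x[0] - x_stop
    reached.terminal = True
    reached.direction = 1.0

    sol = solve_ivp(dxdt, (0.0, 1e9), [x_b], rtol=rtol, atol=1e-12,
                    dense_output=True, events=reached, max_step=np.inf)

    def volume(t):
        x = np.clip(sol.sol(np.atleast_1d(t))[0], x_b, x_e)
        return shape.volume(x)

    return volume, float(sol.t[-1])
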