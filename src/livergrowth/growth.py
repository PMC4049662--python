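"""Integration of the growth equation for normally growing organs.

The mass balance behind the general growth law reads

    ``rho dV/dt = K V G(V)``

where ``K`` is the nutrient influx per unit volume per unit time (normalized
to 1 — its value only sets the unknown time scale), ``rho`` the tissue
density, and ``G`` the growth ratio of :mod:`livergrowth.geometry`.  The
equation is separable: all volume-dependent terms are collected on one side
and time is obtained by quadrature over the shape's growth variable.

Numerically, the growth-variable range is split into ``n_steps`` equal
intervals and the integrand is evaluated at interval midpoints (rectangular
midpoint rule).  Evaluating at midpoints avoids the endpoint where ``G``
vanishes and the time integral diverges logarithmically: a real organ
approaches its maximum size asymptotically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import (DomainError, EmptyRangeError, NumericalError, RangeError)
from .geometry import LiverShape

__all__ = [
    "GrowthConfig",
    "GrowthCurve",
    "integrate_normal_growth",
    "surface_growth_increment",
    "max_mass_from_influx",
    "time_rescale",
    "volume_at_time",
]


@dataclass(frozen=True)
class GrowthConfig:
    """Influx, density and discretization constants of the growth equation.

    ``K`` is the volumetric nutrient influx (normalized, sets the time
    scale), ``k`` the specific per-surface influx used by surface-fed
    scenarios, ``rho`` the tissue density.  All default to 1; absolute rates
    are deferred to time calibration against data.
    """

    K: float = 1.0
    k: float = 1.0
    rho: float = 1.0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if self.K <= 0 or self.k <= 0 or self.rho <= 0:
            raise DomainError("K, k and rho must be positive")
        if self.n_steps < 10:
            raise DomainError("n_steps must be at least 10")


@dataclass(frozen=True)
class GrowthCurve:
    """Ordered time/volume/growth-ratio trajectory.

    ``time`` and ``volume`` are strictly increasing; the first point is the
    initial condition ``(0, V_b)`` and the last volume stays below the
    maximum volume ``v_max``.  ``active_fraction`` is 1 everywhere for
    normal growth and below 1 during the partial-growth phase.
    """

    time: np.ndarray
    volume: np.ndarray
    growth_ratio: np.ndarray
    active_fraction: np.ndarray
    v_max: float
    time_unit: str = "model"

    def __post_init__(self) -> None:
        for name in ("time", "volume", "growth_ratio", "active_fraction"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if any(getattr(self, a).size != n
               for a in ("volume", "growth_ratio", "active_fraction")):
            raise DomainError("curve columns must have equal length")

    @property
    def v_b(self) -> float:
        return float(self.volume[0])

    @property
    def span(self) -> tuple:
        return (float(self.time[0]), float(self.time[-1]))

    def scale_volume(self, factor: float) -> "GrowthCurve":
        """Return the curve with volumes (and ``v_max``) multiplied by
        ``factor``, e.g. to convert model units to cm^3."""
        if factor <= 0:
            raise DomainError("volume factor must be positive")
        return replace(self, volume=self.volume * factor,
                       v_max=self.v_max * factor)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.time,
            "volume": self.volume,
            "growth_ratio": self.growth_ratio,
            "active_fraction": self.active_fraction,
        })


def _integrate(shape: LiverShape, config: GrowthConfig,
               active_volume: Optional[Callable] = None,
               active_fraction: Optional[Callable] = None) -> GrowthCurve:
    """Shared midpoint-rule quadrature over the shape's growth variable.

    ``active_volume`` maps total volume to the biomass-producing volume
    (identity for normal growth).  Reported points are the initial state
    followed by the interval midpoints; the time at midpoint ``m_i`` is the
    accumulated full-interval time plus half of interval ``i``'s own
    contribution, which keeps the rule's second-order accuracy.
    """
    x_b, x_e = shape.growth_range
    if not (x_e > x_b):
        raise EmptyRangeError("shape has no growth range (initial size equals "
                              "final size)")
    n = config.n_steps
    nodes = np.linspace(x_b, x_e, n + 1)
    mids = 0.5 * (nodes[:-1] + nodes[1:])

    v_nodes = shape.volume(nodes)
    v_mids = shape.volume(mids)
    s_mids = shape.surface(mids)
    s_max = shape.surface(x_e)
    v_max = float(v_nodes[-1])

    g_mids = (s_mids / s_max) / (v_mids / v_max) - 1.0
    if active_volume is None:
        va_mids = v_mids
    else:
        va_mids = active_volume(v_mids)

    # Growth stops where the production term K * V_a * G vanishes; for
    # geometries whose growth ratio hits zero before full size (right-lobe
    # grafts) the curve is truncated at that point.
    positive = (g_mids > 0) & (va_mids > 0)
    if not positive[0]:
        raise DomainError("biomass production is non-positive at the initial "
                          "state; nothing can grow")
    last = int(np.argmin(positive)) if not positive.all() else n
    sl = slice(0, last)

    dv = np.diff(v_nodes)[sl]
    rate = (config.K / config.rho) * va_mids[sl] * g_mids[sl]
    dt = dv / rate
    if not np.all(np.isfinite(dt)):
        bad = int(np.flatnonzero(~np.isfinite(dt))[0])
        raise NumericalError(f"non-finite time increment at step {bad}")
    t_mids = np.cumsum(dt) - 0.5 * dt

    s_b = shape.surface(x_b)
    v_b = float(v_nodes[0])
    g_b = (s_b / s_max) / (v_b / v_max) - 1.0
    if active_fraction is None:
        af = np.ones(t_mids.size + 1)
    else:
        af = active_fraction(np.concatenate(([v_b], v_mids[sl])))

    return GrowthCurve(
        time=np.concatenate(([0.0], t_mids)),
        volume=np.concatenate(([v_b], v_mids[sl])),
        growth_ratio=np.concatenate(([g_b], g_mids[sl])),
        active_fraction=af,
        v_max=v_max,
    )


def integrate_normal_growth(shape: LiverShape,
                            config: GrowthConfig = GrowthConfig()) -> GrowthCurve:
    """Volume-versus-time curve of a normally growing organ.

    Separable midpoint-rule integration of ``rho dV/dt = K V G(V)`` from the
    shape's initial state toward its maximum size.  Doubling ``K`` exactly
    halves every time coordinate.
    """
    return _integrate(shape, config)


def surface_growth_increment(k: float, S: float, G: float, dt: float) -> float:
    """Mass increment ``k * S * G * dt`` of a surface-fed organ over a time
    step: the influx through the supplying surface times the fraction of it
    available for biomass production.  Linear in each argument."""
    for name, val in (("k", k), ("S", S), ("G", G), ("dt", dt)):
        if val < 0:
            raise DomainError(f"{name} must be non-negative")
    return k * S * G * dt


def max_mass_from_influx(k: float, k_min: float, k_max: float,
                         M_min: float, M_max: float) -> float:
    """Maximum attainable mass for a nutrient influx ``k``, by linear
    interpolation between the masses reached at the minimum and maximum
    influxes (all referred to the same phase of growth):

    ``M(k) = M_min + (M_max - M_min) (k - k_min) / (k_max - k_min)``

    Extrapolation outside ``[k_min, k_max]`` is refused.
    """
    if not (k_min < k_max):
        raise DomainError("k_min must be below k_max")
    if not (M_min < M_max):
        raise DomainError("M_min must be below M_max")
    if not (k_min <= k <= k_max):
        raise RangeError(f"influx {k} outside [{k_min}, {k_max}]; "
                         "extrapolation refused")
    return M_min + (M_max - M_min) * (k - k_min) / (k_max - k_min)


def time_rescale(curve: GrowthCurve, factor: float) -> GrowthCurve:
    """Multiply all time coordinates by ``factor``; volumes untouched.

    Rescaling time is how the normalized influx ``K = 1`` is reconciled
    with data measured in days: it changes no property of the curve's shape.
    """
    if factor <= 0:
        raise DomainError("time-rescale factor must be positive")
    return replace(curve, time=curve.time * factor)


def volume_at_time(curve: GrowthCurve, t, extrapolation: str = "raise"):
    """Linearly interpolated volume at time ``t``.

    ``extrapolation="raise"`` rejects times outside the curve's span;
    ``"hold"`` clamps to the boundary volumes (used internally during time
    calibration where trial rescalings may not yet cover the data).
    """
    t_arr = np.asarray(t, dtype=float)
    t0, t1 = curve.span
    if extrapolation == "raise":
        if np.any(t_arr < t0 - 1e-12) or np.any(t_arr > t1 * (1 + 1e-12) + 1e-12):
            raise RangeError(f"time {t} outside the curve span [{t0}, {t1}]")
    elif extrapolation != "hold":
        raise ValueError("extrapolation must be 'raise' or 'hold'")
    out = np.interp(t_arr, curve.time, curve.volume)
    return float(out) if out.ndim == 0 else out
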