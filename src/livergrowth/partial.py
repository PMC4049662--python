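"""Partial growth: gradual engagement of hepatocytes after transplantation.

Right after a major resection or transplantation the liver does not grow the
way an intact organ would: only a fraction of the hepatocytes proliferate at
first, and cells are recruited progressively until, at the *joining point*
``V_j``, the whole organ takes part and growth proceeds normally.

The organ is split into an *active* part (produces biomass) and a *passive*
part (consumes maintenance resources only).  The passive volume shrinks with
total volume ``V`` as

    ``V_p(V) = (1 - A) V_b ((V_j - V) / (V_j - V_b))**p``

where ``A`` is the initially active fraction, ``p`` shapes the decline
(``p = 1`` is linear in the normalized volume, ``p < 1`` convex recruitment
accelerating toward the joining point), and ``V_p`` vanishes at ``V_j`` by
construction.  The growth equation becomes

    ``rho dV/dt = K V_a(V) G(V)``,  ``V_a = V - V_p``

which reduces to the normal growth equation for ``A = 1`` and continues it
smoothly beyond ``V_j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IncompatibilityError
from .geometry import LiverShape
from .growth import GrowthConfig, GrowthCurve, _integrate

__all__ = [
    "PartialGrowthParams",
    "passive_volume",
    "active_volume",
    "integrate_partial_growth",
    "active_fraction_series",
]


@dataclass(frozen=True)
class PartialGrowthParams:
    """Parameters (A, p, V_j) of the active/passive growth extension.

    ``A``: initially active fraction of the organ, in (0, 1].
    ``p``: convexity exponent of the passive part's decline, > 0.
    ``V_j``: joining volume (model units) at which the passive part
    vanishes; must exceed the initial volume.
    """

    A: float
    p: float
    V_j: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A <= 1.0):
            raise DomainError(f"A must lie in (0, 1], got {self.A}")
        if self.p <= 0:
            raise DomainError(f"p must be positive, got {self.p}")
        if self.V_j <= 0:
            raise DomainError("V_j must be positive")

    @classmethod
    def from_fraction(cls, A: float, p: float, fraction: float,
                      shape: LiverShape) -> "PartialGrowthParams":
        """Build parameters with ``V_j`` given as a fraction of the shape's
        final (maximum) volume."""
        if not (0.0 < fraction <= 1.0):
            raise DomainError("joining fraction must lie in (0, 1]")
        v_max = shape.final_state().volume
        return cls(A=A, p=p, V_j=fraction * v_max)


def passive_volume(V, params: PartialGrowthParams, V_b: float):
    """Passive (non-proliferating) volume at total volume ``V``.

    Continuous and non-increasing on ``[V_b, V_j]``; equals ``(1 - A) V_b``
    at the start and 0 at the joining volume.
    """
    if params.V_j <= V_b:
        raise DomainError("V_j must exceed the initial volume V_b")
    arr = np.asarray(V, dtype=float)
    if np.any(arr < V_b * (1 - 1e-12)) or np.any(arr > params.V_j * (1 + 1e-12)):
        raise DomainError(f"V must lie in [V_b={V_b}, V_j={params.V_j}]")
    u = np.clip((params.V_j - arr) / (params.V_j - V_b), 0.0, 1.0)
    out = (1.0 - params.A) * V_b * u**params.p
    return float(out) if out.ndim == 0 else out


def active_volume(V, params: PartialGrowthParams, V_b: float):
    """Active (biomass-producing) volume: the complement of the passive
    part.  Equals ``V`` at and beyond the joining volume."""
    arr = np.asarray(V, dtype=float)
    pre = arr <= params.V_j
    out = np.where(pre,
                   arr - passive_volume(np.minimum(arr, params.V_j),
                                        params, V_b),
                   arr)
    return float(out) if out.ndim == 0 else out


def integrate_partial_growth(shape: LiverShape, config: GrowthConfig,
                             params: PartialGrowthParams) -> GrowthCurve:
    """Growth curve of a partially growing organ.

    Integrates ``rho dV/dt = K V_a(V) G(V)`` on the same midpoint grid as
    normal growth.  Below ``V_j`` only the active part produces biomass (the
    passive part draws maintenance but contributes nothing); beyond ``V_j``
    the equation coincides with normal growth, and since ``V_a`` is
    continuous, so is the slope of the curve at the joining point.  The
    active fraction ``V_a / V`` is recorded at every point.
    """
    v_b = shape.initial_state().volume
    if params.V_j <= v_b:
        raise DomainError(f"joining volume V_j={params.V_j} must exceed the "
                          f"initial volume V_b={v_b}")

    def va(V):
        return active_volume(V, params, v_b)

    def af(V):
        return va(V) / np.asarray(V, dtype=float)

    return _integrate(shape, config, active_volume=va, active_fraction=af)


def active_fraction_series(curve: GrowthCurve, reference: GrowthCurve):
    """Fraction of hepatocytes replicating, relative to normal growth, along
    a partial-growth curve.

    In this model the proliferating volume under normal growth is the whole
    organ, so at matched volumes the relative fraction equals the recorded
    ``active_fraction = V_a / V`` — both normalizations coincide.  The
    reference curve is required to share the initial volume and maximum
    volume (same geometry); it anchors the matched-volume comparison.

    Returns an array of ``(t, fraction)`` pairs; the fraction is 1 at and
    beyond the joining volume.
    """
    if not np.isclose(curve.v_b, reference.v_b, rtol=1e-9) or \
            not np.isclose(curve.v_max, reference.v_max, rtol=1e-9):
        raise IncompatibilityError(
            "curves do not share initial volume and geometry")
    return np.column_stack([curve.time, curve.active_fraction])
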