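"""Idealized liver geometries and the growth ratio.

Two closed-form solids are used as organ models:

* a *dog liver* is a partial torus (fraction ``P`` of the full ring) whose
  open ends are capped by hemispheres, the whole solid then sliced in half
  through the torus' equatorial symmetry plane;

* a *human liver* is a prism whose side profile is a right trapezoid:
  parallel transverse faces of heights ``B`` (thin, left-lobe end) and
  ``B_X`` (thick, right-lobe end), length ``L_full`` between them, extruded
  to width ``W``.  A transplant graft or donor remnant is the part of the
  prism on one side of a transverse boundary plane; it regrows by moving
  that plane toward the opposite end.

Growth is driven by the dimensionless *growth ratio*

    ``G = (S / S_max) / (V / V_max) - 1``

where ``S_max`` and ``V_max`` belong to the fully grown state.  ``G`` is the
fraction of the nutrient influx available for producing new biomass; the
remainder maintains existing tissue.  Because surface grows more slowly than
volume, ``G`` decreases monotonically and vanishes at the maximum size,
which is what terminates growth.

Surface convention
------------------
The surface entering the growth ratio is the *exchange* surface of the
growing organ: for the torus, the curved tube-plus-cap surface (the flat
slice faces scale like every other face, so they would only rescale ``S``
by a constant and leave ``G`` untouched); for a prism graft, the lateral
faces plus the regenerating boundary face, excluding the graft's fixed,
transected end face.  This convention keeps the growth ratio non-negative
over the whole growth range and reproduces the observed ordering that a
growing left (thin) lobe has a larger growth ratio than a growing right
(thick) lobe at equal relative volume.  See ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Tuple, Union

import numpy as np

from .errors import DomainError

__all__ = [
    "TorusLiverShape",
    "PrismLiverShape",
    "ShapeState",
    "LiverShape",
    "torus_volume",
    "torus_surface",
    "prism_base_angle",
    "prism_volume",
    "prism_surface",
    "graft_length_from_fraction",
    "relative_surface_volume",
    "growth_ratio",
]


def _check_torus_args(r, d, P) -> None:
    if np.any(np.asarray(r) <= 0):
        raise DomainError("torus tube radius r must be positive")
    if np.any(np.asarray(d) <= np.asarray(r)):
        raise DomainError("torus center distance d must exceed the tube radius r "
                          "(self-intersecting torus)")
    if not (0.0 < P <= 1.0):
        raise DomainError(f"torus fraction P must lie in (0, 1], got {P}")


def torus_volume(r, d, P):
    """Volume of the hemisphere-capped partial torus sliced through its
    symmetry plane.

    The retained fraction ``P`` of the full ring contributes half of a full
    torus' ``2 pi^2 r^2 d``; the two hemisphere caps together form one full
    sphere, of which the slice keeps half.

    ``V = P pi^2 r^2 d + (2/3) pi r^3``
    """
    _check_torus_args(r, d, P)
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    out = P * np.pi**2 * r * r * d + (2.0 / 3.0) * np.pi * r**3
    return float(out) if out.ndim == 0 else out


def torus_surface(r, d, P):
    """Exchange surface of the sliced, capped partial torus.

    Keeps the curved faces only: half of the tube surface ``4 pi^2 r d``
    over the fraction ``P``, plus the curved surface of the two sliced
    hemisphere caps (half a sphere in total):

    ``S = 2 pi^2 P r d + 2 pi r^2``

    The flat slice faces also scale as ``r^2`` when the shape dilates with
    ``d/r`` fixed, so including them would rescale ``S`` by a constant and
    leave every relative-surface quantity unchanged.
    """
    _check_torus_args(r, d, P)
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    out = 2.0 * np.pi**2 * P * r * d + 2.0 * np.pi * r * r
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TorusLiverShape:
    """Dog-liver model: capped, sliced partial torus growing by dilation.

    Parameters
    ----------
    r_b, r_e:
        Tube radius at the beginning and at the end of growth (model units).
    d_b:
        Initial distance from the torus center to the tube-circle center.
        During growth ``d = kappa * r`` with ``kappa = d_b / r_b`` held
        constant, so the solid dilates uniformly.
    P:
        Fraction of the full ring retained, e.g. ``2/3``.
    unit_scale:
        Physical length (cm) per model length unit; volumes in cm^3 are
        ``unit_scale**3`` times model volumes.  Purely cosmetic: the growth
        ratio is dimensionless.
    """

    r_b: float
    r_e: float
    d_b: float
    P: float
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r_b <= 0:
            raise DomainError("r_b must be positive")
        if self.r_e < self.r_b:
            raise DomainError("r_e must be >= r_b (the organ does not shrink)")
        if self.d_b <= self.r_b:
            raise DomainError("d_b must exceed r_b (self-intersecting torus)")
        if not (0.0 < self.P <= 1.0):
            raise DomainError(f"P must lie in (0, 1], got {self.P}")
        if self.unit_scale <= 0:
            raise DomainError("unit_scale must be positive")

    @property
    def kappa(self) -> float:
        """Scaling coefficient ``d / r`` held constant during growth."""
        return self.d_b / self.r_b

    @property
    def volume_scale(self) -> float:
        """Physical volume (cm^3) per model volume unit."""
        return self.unit_scale**3

    @property
    def growth_range(self) -> Tuple[float, float]:
        return (self.r_b, self.r_e)

    def volume(self, r):
        return torus_volume(r, self.kappa * np.asarray(r, dtype=float), self.P)

    def surface(self, r):
        return torus_surface(r, self.kappa * np.asarray(r, dtype=float), self.P)

    def state(self, r: float) -> "ShapeState":
        return ShapeState(self, float(r))

    def initial_state(self) -> "ShapeState":
        return self.state(self.r_b)

    def final_state(self) -> "ShapeState":
        return self.state(self.r_e)

    @classmethod
    def with_initial_volume(cls, r_b, r_e, d_b, P, initial_volume_cm3):
        """Anchor ``unit_scale`` so the initial model volume maps to a
        physical volume in cm^3."""
        shape = cls(r_b=r_b, r_e=r_e, d_b=d_b, P=P)
        scale = (initial_volume_cm3 / shape.volume(r_b)) ** (1.0 / 3.0)
        return cls(r_b=r_b, r_e=r_e, d_b=d_b, P=P, unit_scale=scale)


def prism_base_angle(shape: "PrismLiverShape") -> float:
    """Base angle of the prism's slanted face, ``arctan(L_full/(B_X - B))``.

    Lies strictly inside ``(0, pi/2)`` for a genuine wedge; tends to
    ``pi/2`` as the two transverse heights coincide and the slanted face
    degenerates into the top of a rectangular box.  Scale free.
    """
    if shape.B_X <= shape.B:
        raise DomainError("degenerate prism: B_X must exceed B")
    return math.atan2(shape.L_full, shape.B_X - shape.B)


def _check_length(shape: "PrismLiverShape", length) -> None:
    arr = np.asarray(length, dtype=float)
    if np.any(arr <= 0) or np.any(arr > shape.L_full * (1 + 1e-12)):
        raise DomainError(
            f"graft length must lie in (0, L_full={shape.L_full}], got {length}")


def prism_volume(shape: "PrismLiverShape", length):
    """Volume of the cut prism truncated at the boundary plane.

    For the left lobe the graft extends a distance ``length`` from the thin
    end (height ``B``); for the right lobe from the thick end (``B_X``).
    With the slant slope ``cot(alpha) = (B_X - B)/L_full``:

    left:  ``V = W (B  l + cot(alpha) l^2 / 2)``
    right: ``V = W (B_X l - cot(alpha) l^2 / 2)``

    Both parameterizations give the whole-liver volume
    ``W L_full (B + B_X)/2`` at full length.
    """
    _check_length(shape, length)
    el = np.asarray(length, dtype=float)
    c = shape.cot_alpha
    if shape.lobe == "left":
        out = shape.W * (shape.B * el + 0.5 * c * el * el)
    else:
        out = shape.W * (shape.B_X * el - 0.5 * c * el * el)
    return float(out) if out.ndim == 0 else out


def prism_surface(shape: "PrismLiverShape", length):
    """Exchange surface of the cut prism of the given graft length.

    Counts the two trapezoidal side faces (each ``V/W``), the bottom face,
    the slanted face, and the regenerating boundary face; the graft's fixed
    transected end face is excluded (see module docstring).
    """
    _check_length(shape, length)
    el = np.asarray(length, dtype=float)
    c = shape.cot_alpha
    csc = math.sqrt(1.0 + c * c)  # slant length per unit run
    lateral = 2.0 * prism_volume(shape, el) / shape.W \
        + shape.W * el + shape.W * el * csc
    if shape.lobe == "left":
        boundary = shape.W * (shape.B + c * el)
    else:
        boundary = shape.W * (shape.B_X - c * el)
    out = lateral + boundary
    return float(out) if np.ndim(out) == 0 else out


def graft_length_from_fraction(shape: "PrismLiverShape", F: float) -> float:
    """Graft length whose cut-prism volume is a fraction ``F`` of the whole
    liver, by inverting the quadratic volume formula in closed form.

    left:  ``l = (-B  + sqrt(B^2  + 2 cot(a) F V_whole / W)) / cot(a)``
    right: ``l = ( B_X - sqrt(B_X^2 - 2 cot(a) F V_whole / W)) / cot(a)``
    """
    if not (0.0 < F <= 1.0):
        raise DomainError(f"volume fraction F must lie in (0, 1], got {F}")
    c = shape.cot_alpha
    target = F * shape.whole_volume / shape.W
    if shape.lobe == "left":
        disc = shape.B**2 + 2.0 * c * target
        if disc < 0:
            raise DomainError("internal consistency error: negative discriminant")
        length = (-shape.B + math.sqrt(disc)) / c
    else:
        disc = shape.B_X**2 - 2.0 * c * target
        if disc < 0:
            raise DomainError("internal consistency error: negative discriminant")
        length = (shape.B_X - math.sqrt(disc)) / c
    return min(length, shape.L_full)


@dataclass(frozen=True)
class PrismLiverShape:
    """Human-liver model: extruded right-trapezoid prism, with a lobe graft
    defined by a transverse boundary plane.

    Parameters
    ----------
    W:
        Width of the extrusion (model units).
    B, B_X:
        Heights of the thin (left-lobe) and thick (right-lobe) transverse
        end faces; ``0 < B < B_X``.
    L_full:
        Distance between the two end faces.
    lobe:
        ``"left"`` measures graft length from the thin end, ``"right"``
        from the thick end.
    F:
        Initial graft/remnant volume as a fraction of the whole liver.
    unit_scale:
        Physical length (cm) per model unit, as for the torus.
    """

    W: float
    B: float
    B_X: float
    L_full: float
    lobe: Literal["left", "right"] = "left"
    F: float = 1.0
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.W <= 0 or self.L_full <= 0:
            raise DomainError("W and L_full must be positive")
        if not (0.0 < self.B < self.B_X):
            raise DomainError("prism bases must satisfy 0 < B < B_X")
        if self.lobe not in ("left", "right"):
            raise DomainError(f"lobe must be 'left' or 'right', got {self.lobe!r}")
        if not (0.0 < self.F <= 1.0):
            raise DomainError(f"graft fraction F must lie in (0, 1], got {self.F}")
        if self.unit_scale <= 0:
            raise DomainError("unit_scale must be positive")

    @property
    def alpha(self) -> float:
        return prism_base_angle(self)

    @property
    def cot_alpha(self) -> float:
        return (self.B_X - self.B) / self.L_full

    @property
    def whole_volume(self) -> float:
        return self.W * self.L_full * (self.B + self.B_X) / 2.0

    @property
    def volume_scale(self) -> float:
        return self.unit_scale**3

    @property
    def initial_length(self) -> float:
        return graft_length_from_fraction(self, self.F)

    @property
    def growth_range(self) -> Tuple[float, float]:
        return (self.initial_length, self.L_full)

    def volume(self, length):
        return prism_volume(self, length)

    def surface(self, length):
        return prism_surface(self, length)

    def state(self, length: float) -> "ShapeState":
        return ShapeState(self, float(length))

    def initial_state(self) -> "ShapeState":
        return self.state(self.initial_length)

    def final_state(self) -> "ShapeState":
        return self.state(self.L_full)

    @classmethod
    def from_width_units(cls, width, small_base, large_base, length,
                         lobe="left", F=1.0, whole_volume_cm3=None):
        """Build a shape from proportions given in multiples of the width,
        optionally anchoring physical units to a whole-liver volume."""
        shape = cls(W=width, B=small_base * width, B_X=large_base * width,
                    L_full=length * width, lobe=lobe, F=F)
        if whole_volume_cm3 is None:
            return shape
        scale = (whole_volume_cm3 / shape.whole_volume) ** (1.0 / 3.0)
        return cls(W=width, B=small_base * width, B_X=large_base * width,
                   L_full=length * width, lobe=lobe, F=F, unit_scale=scale)


LiverShape = Union[TorusLiverShape, PrismLiverShape]


@dataclass(frozen=True)
class ShapeState:
    """A liver shape frozen at one value of its growth variable (tube radius
    for the torus, graft length for the prism)."""

    shape: LiverShape
    growth_variable: float

    def __post_init__(self) -> None:
        lo, hi = self.shape.growth_range
        x = self.growth_variable
        if not (lo * (1 - 1e-12) <= x <= hi * (1 + 1e-12)):
            raise DomainError(
                f"growth variable {x} outside the shape's range [{lo}, {hi}]")

    @property
    def volume(self) -> float:
        return self.shape.volume(self.growth_variable)

    @property
    def surface(self) -> float:
        return self.shape.surface(self.growth_variable)

    @property
    def volume_cm3(self) -> float:
        return self.volume * self.shape.volume_scale


def relative_surface_volume(state: ShapeState,
                            final_state: ShapeState) -> Tuple[float, float]:
    """Dimensionless pair ``(S/S_max, V/V_max)`` for a state against the
    fully grown state of the same shape.  Both lie in ``(0, 1]`` and are
    invariant under a change of ``unit_scale``."""
    if state.shape is not final_state.shape and state.shape != final_state.shape:
        raise DomainError("states must belong to the same shape")
    if state.growth_variable > final_state.growth_variable * (1 + 1e-12):
        raise DomainError("state exceeds the final (maximum) state")
    return (state.surface / final_state.surface,
            state.volume / final_state.volume)


def growth_ratio(relative_surface, relative_volume):
    """Growth ratio ``G = relative_surface / relative_volume - 1``.

    The fraction of the nutrient influx available for biomass production.
    Dimensionless and scale free; equals 0 at the maximum size, where all
    influx is consumed by maintenance and growth stops.
    """
    s = np.asarray(relative_surface, dtype=float)
    v = np.asarray(relative_volume, dtype=float)
    if np.any(s <= 0) or np.any(s > 1 + 1e-12):
        raise DomainError("relative surface must lie in (0, 1]")
    if np.any(v <= 0) or np.any(v > 1 + 1e-12):
        raise DomainError("relative volume must lie in (0, 1]")
    out = s / v - 1.0
    return float(out) if out.ndim == 0 else out
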