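"""Jacobian surface summaries, Hessian elements, frames and curvatures.

The six first partial derivatives of ``(x, y, z)`` with respect to
``(u, v)``, evaluated at a reference point (default ``u = v = 0``), form a
3x2 Jacobian matrix that summarizes the tangent structure of the whole
surface.  Because the generators in :mod:`morphosurf.surfaces` are
homogeneous of degree 1 in their radii, the summary scales linearly with
size, and ratio-normalized models yield size-free descriptors suitable for
ordination.

Distinct models can share a Jacobian summary (tangent lines and planes
coincide at the reference point even though the surfaces differ — e.g.
ammonites whose pleat wave is phase-shifted along ``v``).  For such pairs
the second partial derivatives (Hessian elements) discriminate, and this
module provides them as a post-processing descriptor.

Also here: Darboux and Serret-Frenet frames along parameter curves, and
principal curvatures from the first/second fundamental forms — the
differential-geometric scaffolding the torus-based generators rest on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import sympy as sp

from .surfaces import (
    U,
    V,
    DomainError,
    MorphosurfError,
    SurfaceModel,
    lambdify_uv,
)

__all__ = [
    "JACOBIAN_ELEMENT_ORDER",
    "HESSIAN_ELEMENT_NAMES",
    "DEFAULT_HESSIAN_ELEMENTS",
    "DEGENERACY_TOL",
    "SingularityError",
    "StepError",
    "UnknownElementError",
    "RegularityError",
    "DegenerateCurveError",
    "JacobianSummary",
    "HessianElements",
    "CurvatureSet",
    "DarbouxFrame",
    "FrenetFrame",
    "jacobian",
    "numeric_jacobian",
    "jacobian_minors",
    "hessian_elements",
    "principal_curvatures",
    "darboux_frame",
    "frenet_frame",
    "jacobians_identical",
]

#: flattening order used everywhere a summary becomes a table row
JACOBIAN_ELEMENT_ORDER = ("dx_du", "dx_dv", "dy_du", "dy_dv", "dz_du", "dz_dv")

#: all recognised second-partial names (mixed partials are symmetric, so the
#: single mixed name per coordinate covers both differentiation orders)
HESSIAN_ELEMENT_NAMES = (
    "d2x_du2", "d2x_dv2", "d2x_dudv",
    "d2y_du2", "d2y_dv2", "d2y_dudv",
    "d2z_du2", "d2z_dv2", "d2z_dudv",
)

#: default six-element subset used for post-processing degenerate pairs
DEFAULT_HESSIAN_ELEMENTS = (
    "d2x_du2", "d2y_du2", "d2z_du2",
    "d2x_dudv", "d2y_dudv", "d2z_dudv",
)

#: two summaries closer than this (max absolute difference) count as identical
DEGENERACY_TOL = 1e-9


class SingularityError(MorphosurfError):
    """A derivative is non-finite at the requested point."""


class StepError(MorphosurfError):
    """Non-positive finite-difference step."""


class UnknownElementError(MorphosurfError):
    """An unrecognised Hessian element name."""


class RegularityError(MorphosurfError):
    """The first fundamental form is singular at the requested point."""


class DegenerateCurveError(MorphosurfError):
    """The chosen parameter curve has (numerically) zero speed."""


# ---------------------------------------------------------------------------
# derivative machinery
# ---------------------------------------------------------------------------

def _deriv_cache(model: SurfaceModel) -> dict:
    cache = model.__dict__.get("_diffgeo_cache")
    if cache is None:
        cache = {}
        model.__dict__["_diffgeo_cache"] = cache
    return cache


def _deriv_fn(model: SurfaceModel, coord: str, du: int, dv: int):
    """Cached lambdified partial derivative d^(du+dv) coord / du^du dv^dv."""
    cache = _deriv_cache(model)
    key = (coord, du, dv)
    fn = cache.get(key)
    if fn is None:
        expr = {"x": model.x_expr, "y": model.y_expr, "z": model.z_expr}[coord]
        dexpr = sp.diff(expr, U, du, V, dv)
        fn = lambdify_uv(dexpr)
        cache[key] = fn
    return fn


def _eval_deriv(model: SurfaceModel, coord: str, du: int, dv: int, u0: float, v0: float) -> float:
    return float(_deriv_fn(model, coord, du, dv)(u0, v0))


def _check_domain(model: SurfaceModel, u0: float, v0: float) -> None:
    if not model.domain.contains(u0, v0):
        raise DomainError(
            f"reference point ({u0}, {v0}) outside domain "
            f"{model.domain.u_range} x {model.domain.v_range}"
        )


# ---------------------------------------------------------------------------
# Jacobian summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JacobianSummary:
    """The six first partials at a reference point, the size-free descriptor.

    ``matrix`` arranges them 3x2 with rows ``(x, y, z)`` and columns
    ``(u, v)``; ``flat`` follows :data:`JACOBIAN_ELEMENT_ORDER`.
    """

    dx_du: float
    dx_dv: float
    dy_du: float
    dy_dv: float
    dz_du: float
    dz_dv: float
    point: tuple[float, float] = (0.0, 0.0)

    @property
    def flat(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in JACOBIAN_ELEMENT_ORDER)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dx_du, self.dx_dv],
                [self.dy_du, self.dy_dv],
                [self.dz_du, self.dz_dv],
            ]
        )


def jacobian(model: SurfaceModel, u0: float = 0.0, v0: float = 0.0) -> JacobianSummary:
    """Exact symbolic Jacobian summary of ``model`` at ``(u0, v0)``.

    Each element is the symbolic partial derivative of the coordinate
    expression, evaluated numerically at the reference point.  A non-finite
    element raises :class:`SingularityError` naming the offending element.
    """
    _check_domain(model, u0, v0)
    values = {}
    for name in JACOBIAN_ELEMENT_ORDER:
        coord = name[1]          # "dx_du" -> "x"
        du = 1 if name.endswith("du") else 0
        dv = 1 - du
        val = _eval_deriv(model, coord, du, dv, u0, v0)
        if not math.isfinite(val):
            raise SingularityError(
                f"Jacobian element {name} of model {model.label!r} is non-finite "
                f"at ({u0}, {v0})"
            )
        values[name] = val if val != 0.0 else 0.0  # normalize -0.0
    return JacobianSummary(point=(u0, v0), **values)


def numeric_jacobian(
    model: SurfaceModel, u0: float = 0.0, v0: float = 0.0, h: float = 1e-6
) -> JacobianSummary:
    """Central-finite-difference Jacobian summary, the symbolic path's oracle.

    Steps ``u0 +/- h`` and ``v0 +/- h`` may fall just outside the parameter
    domain; the coordinate functions are evaluated without a domain check.
    """
    if not h > 0:
        raise StepError(f"finite-difference step must be > 0, got {h}")
    xp, yp, zp = model.eval_raw(u0 + h, v0)
    xm, ym, zm = model.eval_raw(u0 - h, v0)
    du = (np.array([xp, yp, zp]) - np.array([xm, ym, zm])) / (2 * h)
    xp, yp, zp = model.eval_raw(u0, v0 + h)
    xm, ym, zm = model.eval_raw(u0, v0 - h)
    dv = (np.array([xp, yp, zp]) - np.array([xm, ym, zm])) / (2 * h)
    return JacobianSummary(
        dx_du=float(du[0]), dx_dv=float(dv[0]),
        dy_du=float(du[1]), dy_dv=float(dv[1]),
        dz_du=float(du[2]), dz_dv=float(dv[2]),
        point=(u0, v0),
    )


def jacobian_minors(J: JacobianSummary) -> tuple[float, float, float]:
    """The three 2x2 determinants of row pairs (x,y), (x,z), (y,z).

    All three vanish exactly when the tangent map has rank < 2 — in
    particular for a surface collapsed to a plane curve or a point, the
    planarity criterion for falling back to 2D outline methods.
    """
    m_xy = J.dx_du * J.dy_dv - J.dx_dv * J.dy_du
    m_xz = J.dx_du * J.dz_dv - J.dx_dv * J.dz_du
    m_yz = J.dy_du * J.dz_dv - J.dy_dv * J.dz_du
    return (m_xy, m_xz, m_yz)


# ---------------------------------------------------------------------------
# Hessian elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HessianElements:
    """Requested second partial derivatives at a reference point."""

    values: dict[str, float]
    point: tuple[float, float] = (0.0, 0.0)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def flat(self) -> tuple[float, ...]:
        return tuple(self.values.values())


def hessian_elements(
    model: SurfaceModel,
    u0: float = 0.0,
    v0: float = 0.0,
    which: Sequence[str] | None = None,
) -> HessianElements:
    """Exact second partials at ``(u0, v0)``.

    ``which`` defaults to :data:`DEFAULT_HESSIAN_ELEMENTS`, the six
    u-dominant elements used to discriminate Jacobian-degenerate pairs.
    Unknown names raise :class:`UnknownElementError`.
    """
    _check_domain(model, u0, v0)
    names = tuple(which) if which is not None else DEFAULT_HESSIAN_ELEMENTS
    values: dict[str, float] = {}
    for name in names:
        if name not in HESSIAN_ELEMENT_NAMES:
            raise UnknownElementError(
                f"unknown Hessian element {name!r}; valid names: {HESSIAN_ELEMENT_NAMES}"
            )
        coord = name[2]          # "d2x_du2" -> "x"
        suffix = name.split("_", 1)[1]
        du, dv = {"du2": (2, 0), "dv2": (0, 2), "dudv": (1, 1)}[suffix]
        val = _eval_deriv(model, coord, du, dv, u0, v0)
        if not math.isfinite(val):
            raise SingularityError(
                f"Hessian element {name} of model {model.label!r} is non-finite"
            )
        values[name] = val
    return HessianElements(values=values, point=(u0, v0))


def jacobians_identical(
    a: JacobianSummary, b: JacobianSummary, tol: float = DEGENERACY_TOL
) -> bool:
    """True when the two summaries differ by less than ``tol`` in every element."""
    return max(abs(x - y) for x, y in zip(a.flat, b.flat)) < tol


# ---------------------------------------------------------------------------
# fundamental forms, curvature, frames
# ---------------------------------------------------------------------------

def _surface_derivatives(model: SurfaceModel, u0: float, v0: float):
    """S_u, S_v, S_uu, S_uv, S_vv as arrays at (u0, v0)."""
    def vec(du, dv):
        return np.array([_eval_deriv(model, c, du, dv, u0, v0) for c in "xyz"])

    return vec(1, 0), vec(0, 1), vec(2, 0), vec(1, 1), vec(0, 2)


@dataclass(frozen=True)
class CurvatureSet:
    """Principal curvatures with ``k1 <= k2`` (units 1/model-unit).

    Orientation follows the classical torus convention: the standard torus
    parameterization yields ``k1 = cos(v) / (R + r cos v)`` (parallel) and
    ``k2 = 1/r`` (meridian).
    """

    k1: float
    k2: float

    @property
    def gaussian(self) -> float:
        return self.k1 * self.k2

    @property
    def mean(self) -> float:
        return 0.5 * (self.k1 + self.k2)


def principal_curvatures(model: SurfaceModel, u0: float, v0: float) -> CurvatureSet:
    """Eigenvalues of the shape operator from the fundamental forms.

    Raises :class:`RegularityError` where the first fundamental form is
    singular (e.g. the pole of a sphere parameterization).
    """
    _check_domain(model, u0, v0)
    su, sv, suu, suv, svv = _surface_derivatives(model, u0, v0)
    E, F, G = su @ su, su @ sv, sv @ sv
    det_I = E * G - F * F
    scale = max(E, G, 1e-300)
    if det_I <= 1e-12 * scale * scale or E <= 0 or G <= 0:
        raise RegularityError(
            f"first fundamental form singular at ({u0}, {v0}) for model {model.label!r}"
        )
    # normal oriented so the classical torus curvatures come out positive
    n = np.cross(sv, su)
    n = n / np.linalg.norm(n)
    L, M, N = suu @ n, suv @ n, svv @ n
    shape_op = np.linalg.solve(np.array([[E, F], [F, G]]), np.array([[L, M], [M, N]]))
    k = np.sort(np.linalg.eigvals(shape_op).real)
    return CurvatureSet(k1=float(k[0]), k2=float(k[1]))


@dataclass(frozen=True)
class DarbouxFrame:
    """Orthonormal frame {t, u_vec, v_vec} along a parameter curve.

    ``t`` is the unit tangent of the chosen curve, ``u_vec`` the unit surface
    normal ``(S_u x S_v)/|.|`` (sign is a convention), ``v_vec = u_vec x t``
    the tangent normal.  ``kappa_g`` and ``tau_g`` are the geodesic curvature
    and geodesic torsion of the curve.
    """

    t: np.ndarray
    u_vec: np.ndarray
    v_vec: np.ndarray
    kappa_g: float
    tau_g: float


def darboux_frame(
    model: SurfaceModel,
    u0: float,
    v0: float,
    along: Literal["u_curve", "v_curve"] = "u_curve",
) -> DarbouxFrame:
    """Darboux frame at ``(u0, v0)`` along a parameter curve.

    Geodesic torsion is obtained from the arc-length derivative of the unit
    surface normal along the curve (central difference, step 1e-5); a curve
    with numerically zero speed raises :class:`DegenerateCurveError`.
    """
    if along not in ("u_curve", "v_curve"):
        raise ValueError(f"along must be 'u_curve' or 'v_curve', got {along!r}")
    _check_domain(model, u0, v0)
    su, sv, suu, suv, svv = _surface_derivatives(model, u0, v0)
    cross = np.cross(su, sv)
    norm_cross = np.linalg.norm(cross)
    if norm_cross < 1e-12:
        raise RegularityError(f"surface not regular at ({u0}, {v0})")
    n = cross / norm_cross

    velocity = su if along == "u_curve" else sv
    accel = suu if along == "u_curve" else svv
    speed = np.linalg.norm(velocity)
    if speed < 1e-12:
        raise DegenerateCurveError(f"{along} has zero speed at ({u0}, {v0})")
    t = velocity / speed
    v_vec = np.cross(n, t)

    kappa_g = float(accel @ v_vec) / speed**2

    # tau_g = -(dN/ds) . v_vec via central difference of the unit normal
    h = 1e-5
    def unit_normal(uu, vv):
        s_u, s_v, *_ = _surface_derivatives(model, uu, vv)
        c = np.cross(s_u, s_v)
        return c / np.linalg.norm(c)

    if along == "u_curve":
        dn = (unit_normal(u0 + h, v0) - unit_normal(u0 - h, v0)) / (2 * h)
    else:
        dn = (unit_normal(u0, v0 + h) - unit_normal(u0, v0 - h)) / (2 * h)
    tau_g = float(-(dn / speed) @ v_vec)

    return DarbouxFrame(t=t, u_vec=n, v_vec=v_vec, kappa_g=kappa_g, tau_g=tau_g)


@dataclass(frozen=True)
class FrenetFrame:
    """Serret-Frenet frame {t, n, b} of a parameter curve with kappa, tau, w."""

    t: np.ndarray
    n: np.ndarray
    b: np.ndarray
    kappa: float
    tau: float
    w: np.ndarray


def frenet_frame(
    model: SurfaceModel,
    u0: float,
    v0: float,
    along: Literal["u_curve", "v_curve"] = "u_curve",
) -> FrenetFrame:
    """Serret-Frenet frame of a parameter curve at ``(u0, v0)``.

    Needs nonzero speed and nonzero curvature (the principal normal of a
    straight line is undefined).
    """
    if along not in ("u_curve", "v_curve"):
        raise ValueError(f"along must be 'u_curve' or 'v_curve', got {along!r}")
    _check_domain(model, u0, v0)
    if along == "u_curve":
        orders = [(1, 0), (2, 0), (3, 0)]
    else:
        orders = [(0, 1), (0, 2), (0, 3)]
    w, acc, jerk = (
        np.array([_eval_deriv(model, c, du, dv, u0, v0) for c in "xyz"])
        for du, dv in orders
    )
    speed = np.linalg.norm(w)
    if speed < 1e-12:
        raise DegenerateCurveError(f"{along} has zero speed at ({u0}, {v0})")
    t = w / speed
    cross = np.cross(w, acc)
    norm_cross = np.linalg.norm(cross)
    kappa = norm_cross / speed**3
    if norm_cross < 1e-12:
        raise DegenerateCurveError(
            f"{along} has zero curvature at ({u0}, {v0}); principal normal undefined"
        )
    n = np.cross(cross, w)
    n = n / np.linalg.norm(n)
    b = np.cross(t, n)
    tau = float(cross @ jerk) / norm_cross**2
    return FrenetFrame(t=t, n=n, b=b, kappa=float(kappa), tau=tau, w=w)
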