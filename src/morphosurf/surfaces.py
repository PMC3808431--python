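"""Parametric 3D surface models of mollusk shells, echinoid tests and basic forms.

Every model is a triple of symbolic expressions ``x(u, v)``, ``y(u, v)``,
``z(u, v)`` derived from the ring torus

    x = (R + r cos v) cos u,   y = (R + r cos v) sin u,   z = r sin v,

where ``R`` is the major (whorl) radius and ``r`` the minor (aperture) radius.
Coiled-shell generators wind and taper the torus tube; bivalve, limpet,
scaphopod and echinoid generators reshape it with sines, cosines, hyperbolic
tangents/secants, exponentials and polynomials of the surface parameters
``u`` and ``v``.  All generators are homogeneous of degree 1 in the radii, so
scaling ``(R, r)`` scales the whole surface — the property that makes the
Jacobian summary (see :mod:`morphosurf.diffgeo`) behave linearly under size
change.

The parameter domain defaults to ``[0, 2*pi]`` for both ``u`` and ``v``;
whorl count is carried by the winding coefficient ``b`` rather than by an
extended domain.  Angles are radians everywhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "TWO_PI",
    "MorphosurfError",
    "MissingCoefficientError",
    "DegenerateRadiusError",
    "DomainError",
    "ResolutionError",
    "ScaleError",
    "RegistryError",
    "ParameterDomain",
    "CoefficientSet",
    "ModelKind",
    "Point3",
    "SurfaceGrid",
    "SurfaceModel",
    "make_model",
    "model_from_expressions",
    "evaluate_point",
    "sample_grid",
    "scale_model",
    "canonical_model",
    "canonical_names",
    "U",
    "V",
]

TWO_PI = 2.0 * math.pi

#: the two surface parameters, shared by every generator
U, V = sp.symbols("u v", real=True)

# real-valued overrides for functions the numpy printer would otherwise
# route through complex exponentials
_LAMBDIFY_MODULES = (
    {"sech": lambda x: 1.0 / np.cosh(x), "csch": lambda x: 1.0 / np.sinh(x)},
    "numpy",
)


def lambdify_uv(expr: sp.Expr) -> Callable:
    """Compile an expression in :data:`U`, :data:`V` to a numpy callable."""
    return sp.lambdify((U, V), expr, modules=list(_LAMBDIFY_MODULES))


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class MorphosurfError(Exception):
    """Base class for all errors raised by this package."""


class MissingCoefficientError(MorphosurfError):
    """A coefficient required by the chosen model kind was not supplied."""


class DegenerateRadiusError(MorphosurfError):
    """A radius required by the model is zero or negative.

    Spiral curves may use an arbitrarily small aperture radius, but an exact
    zero collapses the tube to a measure-zero set and is rejected.
    """


class DomainError(MorphosurfError):
    """An evaluation point lies outside the model's parameter domain."""


class ResolutionError(MorphosurfError):
    """A grid sample count is below the minimum of 2 per parameter."""


class ScaleError(MorphosurfError):
    """A non-positive scale factor, or a model that cannot be rescaled."""


class RegistryError(MorphosurfError):
    """An unknown model kind or canonical-model name."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDomain:
    """Closed rectangular parameter domain, in radians.

    Both intervals default to ``[0, 2*pi]``; lower bounds must be strictly
    below upper bounds.
    """

    u_range: tuple[float, float] = (0.0, TWO_PI)
    v_range: tuple[float, float] = (0.0, TWO_PI)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("u", self.u_range), ("v", self.v_range)):
            if not lo < hi:
                raise DomainError(f"{name}_range must satisfy lower < upper, got {(lo, hi)}")

    def contains(self, u: float, v: float, tol: float = 1e-9) -> bool:
        (ulo, uhi), (vlo, vhi) = self.u_range, self.v_range
        return (ulo - tol <= u <= uhi + tol) and (vlo - tol <= v <= vhi + tol)


@dataclass(frozen=True)
class CoefficientSet:
    """Named radii and shape coefficients of a surface generator.

    ``R``/``r`` are the torus radii for unwound and planispiral forms;
    ``R_max``/``r_max`` are the maximum whorl and aperture radii of the
    coiled-gastropod generators (both pairs in the same model units, cm when
    taken from measurements).  Shape coefficients are dimensionless:

    ``a``, ``c``
        overall width and height scaling,
    ``b``, ``j``
        whorl count (winding) and spire pitch,
    ``k``, ``l``, ``m``
        whorl/aperture radius taper along the spire,
    ``q``
        ammonite pleat frequency; for *Vermicularia* the uncoiling
        (squared z-term) coefficient.

    ``z_offset`` adds ``z_offset * v * r`` to the z-equation — the augmentation
    used to split Jacobian-degenerate model pairs.  ``pleat_shift_u`` and
    ``pleat_shift_v`` phase-shift the ammonite pleat wave along ``u`` and ``v``.
    Unset coefficients are ``None``; kinds fill their own defaults and any
    coefficient a kind does not reference is treated as 0.
    """

    R: float | None = None
    r: float | None = None
    R_max: float | None = None
    r_max: float | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None
    j: float | None = None
    k: float | None = None
    l: float | None = None
    m: float | None = None
    q: float | None = None
    z_offset: float = 0.0
    pleat_shift_u: float = 0.0
    pleat_shift_v: float = 0.0

    def as_dict(self) -> dict[str, float]:
        """Mapping of set (non-``None``) fields to their values."""
        out: dict[str, float] = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if val is not None:
                out[f.name] = float(val)
        return out


class ModelKind(str, Enum):
    """Enumeration of the implemented equation systems."""

    gastropod_system1 = "gastropod_system1"
    gastropod_system2 = "gastropod_system2"
    turritellid = "turritellid"
    vermicularia = "vermicularia"
    spiral_curve = "spiral_curve"
    limpet = "limpet"
    clam = "clam"
    oyster = "oyster"
    scallop = "scallop"
    ammonite = "ammonite"
    scaphopod = "scaphopod"
    echinoid = "echinoid"
    torus = "torus"
    cylinder = "cylinder"
    cone = "cone"
    dome = "dome"
    sphere = "sphere"
    ellipsoid = "ellipsoid"


@dataclass(frozen=True)
class Point3:
    """A finite point in model coordinates."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class SurfaceGrid:
    """An ``nu`` x ``nv`` lattice of surface points with its (u, v) values.

    ``points`` has shape ``(nu, nv, 3)``; ``u_values``/``v_values`` are the
    inclusive, evenly spaced parameter samples that generated it.
    """

    nu: int
    nv: int
    u_values: np.ndarray
    v_values: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.points.shape != (self.nu, self.nv, 3):
            raise ValueError("points shape must be (nu, nv, 3)")

    @property
    def n_points(self) -> int:
        return self.nu * self.nv

    def flat_points(self) -> np.ndarray:
        """Points as an ``(nu*nv, 3)`` array, v varying fastest."""
        return self.points.reshape(-1, 3)


# ---------------------------------------------------------------------------
# the equation registry
# ---------------------------------------------------------------------------
# One entry per ModelKind: required coefficient names, per-kind defaults for
# optional coefficients, and a builder returning (x, y, z) sympy expressions
# from a complete numeric coefficient mapping.  Builders keep every additive
# term linear in exactly one radius so the whole registry is homogeneous of
# degree 1 in (R, r, R_max, r_max).

_S = U / TWO_PI      # fraction of the u-sweep (0 = aperture end, 1 = apex)
_RHO = V / TWO_PI    # fraction of the v-sweep (radial fraction for cap forms)


def _helical_gastropod(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Shared conispiral generator behind System 1 and its special cases.

    The tube winds ``b`` times while the whorl profile shrinks as
    ``exp(-k b s) sech(l s)`` and the aperture additionally as ``exp(-m s)``;
    the spire descends at pitch ``c j b R_max`` per full sweep.  With
    ``l = m = 0`` the taper is a pure logarithmic spiral (growth factor
    ``e^-k`` per whorl), which makes whorl series self-similar — the
    turritellid isometric-growth case.  *Vermicularia* adds ``q s^2`` in z
    (whorl separation) and uncoils for negative ``b``.
    """
    a, b, c, j = c_["a"], c_["b"], c_["c"], c_["j"]
    k, l, m, q = c_["k"], c_["l"], c_["m"], c_["q"]
    Rm, rm = c_["R_max"], c_["r_max"]
    whorl = sp.exp(-k * b * _S) * sp.sech(l * _S)
    aper = sp.exp(-m * _S)
    radial = whorl * (Rm + rm * aper * sp.cos(V))
    x = a * radial * sp.cos(b * U)
    y = a * radial * sp.sin(b * U)
    z = -c * j * b * Rm * _S + c * whorl * rm * aper * sp.sin(V) + q * Rm * _S**2
    return x, y, z + c_["z_offset"] * V * rm


def _system2(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Second gastropod generator: tapering whorl, constant-size aperture.

    Produces globose, low-spired shells whose aperture stays full-sized while
    the whorl centerline spirals inward.
    """
    a, b, c, j, k = c_["a"], c_["b"], c_["c"], c_["j"], c_["k"]
    Rm, rm = c_["R_max"], c_["r_max"]
    radial = Rm * sp.exp(-k * b * _S) + rm * sp.cos(V)
    x = a * radial * sp.cos(b * U)
    y = a * radial * sp.sin(b * U)
    z = -c * j * b * Rm * _S + c * rm * sp.sin(V)
    return x, y, z + c_["z_offset"] * V * rm


def _limpet(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Uncoiled cap: radial fan in (x, y), sech height profile in z."""
    a, c, k, R, r = c_["a"], c_["c"], c_["k"], c_["R"], c_["r"]
    x = a * R * _RHO * sp.cos(U)
    y = a * R * _RHO * sp.sin(U)
    z = c * r * sp.sech(k * _RHO)
    return x, y, z + c_["z_offset"] * V * r


def _clam(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Clam valve: elliptical outline (length via j), umbo height via b."""
    a, b, j, R, r = c_["a"], c_["b"], c_["j"], c_["R"], c_["r"]
    x = j * R * _RHO * sp.cos(U)
    y = R * _RHO * sp.sin(U)
    z = r * sp.sech(a * _RHO) + b * r * (1 - _RHO)
    return x, y, z + c_["z_offset"] * V * r


def _oyster(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Oyster valve: c stretches the outline and shallows the cup."""
    c, R, r = c_["c"], c_["R"], c_["r"]
    x = c * R * _RHO * sp.cos(U)
    y = R * _RHO * sp.sin(U)
    z = r * sp.sech(c * _RHO)
    return x, y, z + c_["z_offset"] * V * r


def _scallop(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Scallop valve: auricles near the hinge (a, b), j ribs of depth c,
    outline width m, convexity l."""
    a, b, c, j = c_["a"], c_["b"], c_["c"], c_["j"]
    l, m, R, r = c_["l"], c_["m"], c_["R"], c_["r"]
    x = m * R * _RHO * sp.cos(U)
    y = m * R * _RHO * sp.sin(U) + a * R * _RHO * sp.sech(b * sp.sin(U / 2))
    z = l * r * (1 - _RHO) + c * r * _RHO * sp.cos(j * U)
    return x, y, z + c_["z_offset"] * V * r


_PLEAT_AMPLITUDE = 0.2  # pleat depth as a fraction of the aperture radius


def _ammonite(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Planispiral ammonite: l whorls of logarithmic coiling, q pleats in z.

    The pleat wave ``sin(q (v + shift_v)) (1 - cos(l (u + shift_u)))``
    vanishes to first order at (u, v) = (0, 0) whatever ``shift_v`` is, so
    models differing only in the v-phase of their pleats share the same
    Jacobian summary while their second u-derivatives differ — the
    degenerate pair that motivates Hessian post-processing.
    """
    l, q, R, r = c_["l"], c_["q"], c_["R"], c_["r"]
    su, sv = c_["pleat_shift_u"], c_["pleat_shift_v"]
    g = sp.exp(l * (_S - 1))
    radial = g * (R + r * sp.cos(V))
    pleat = _PLEAT_AMPLITUDE * sp.sin(q * (V + sv)) * (1 - sp.cos(l * (U + su)))
    x = radial * sp.cos(l * U)
    y = radial * sp.sin(l * U)
    z = g * r * (sp.sin(V) + pleat)
    return x, y, z + c_["z_offset"] * V * r


def _scaphopod(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Tusk shell: circular-arc centerline (bend a), tapering tube (width k)."""
    a, k, R, r = c_["a"], c_["k"], c_["R"], c_["r"]
    taper = sp.Rational(1, 5) + sp.Rational(4, 5) * _S
    x = a * R * (1 - sp.cos(sp.pi * _S / 2)) + k * r * taper * sp.cos(V)
    y = k * r * taper * sp.sin(V)
    z = a * R * sp.sin(sp.pi * _S / 2)
    return x, y, z + c_["z_offset"] * V * r


def _echinoid(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Echinoid test: a torus whose hole (a R) almost disappears, flattened
    along z by tanh, with a small sine/cosine-polynomial sculpture term."""
    a, b, c, d = c_["a"], c_["b"], c_["c"], c_["q"]
    R, r = c_["R"], c_["r"]
    radial = a * R + r * sp.cos(V)
    x = radial * sp.cos(U)
    y = radial * sp.sin(U)
    z = -c * r * sp.tanh(b * sp.sin(V)) - d * r * sp.sin(5 * U) ** 2 * sp.sin(V) ** 3
    return x, y, z + c_["z_offset"] * V * r


def _torus(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    R, r = c_["R"], c_["r"]
    return (
        (R + r * sp.cos(V)) * sp.cos(U),
        (R + r * sp.cos(V)) * sp.sin(U),
        r * sp.sin(V) + c_["z_offset"] * V * r,
    )


def _cylinder(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    R, r = c_["R"], c_["r"]
    return r * sp.cos(U), r * sp.sin(U), R * (V / sp.pi - 1) + c_["z_offset"] * V * r


def _cone(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    R, r = c_["R"], c_["r"]
    return (
        r * _RHO * sp.cos(U),
        r * _RHO * sp.sin(U),
        R * (1 - _RHO) + c_["z_offset"] * V * r,
    )


def _dome(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    # upper hemisphere, rim at v = 0, apex at v = 2*pi
    r = c_["r"]
    return (
        r * sp.cos(V / 4) * sp.cos(U),
        r * sp.cos(V / 4) * sp.sin(U),
        r * sp.sin(V / 4) + c_["z_offset"] * V * r,
    )


def _sphere(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    # equator at v = 0 so the reference point is parameterization-regular
    r = c_["r"]
    return (
        r * sp.cos(V / 2) * sp.cos(U),
        r * sp.cos(V / 2) * sp.sin(U),
        -r * sp.sin(V / 2) + c_["z_offset"] * V * r,
    )


def _ellipsoid(c_: Mapping[str, float]) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    a, r = c_["a"], c_["r"]
    return (
        r * sp.cos(V / 2) * sp.cos(U),
        r * sp.cos(V / 2) * sp.sin(U),
        -a * r * sp.sin(V / 2) + c_["z_offset"] * V * r,
    )


@dataclass(frozen=True)
class _KindSpec:
    builder: Callable[[Mapping[str, float]], tuple[sp.Expr, sp.Expr, sp.Expr]]
    required: frozenset[str]
    defaults: Mapping[str, float]
    #: radius fields that must be strictly positive / nonzero
    positive_radii: frozenset[str]


def _ks(builder, required: Iterable[str], defaults: Mapping[str, float] | None = None):
    req = frozenset(required)
    radii = frozenset(n for n in ("R", "r", "R_max", "r_max") if n in req)
    return _KindSpec(builder, req, dict(defaults or {}), radii)


_SYSTEM1_DEFAULTS = {"a": 1.0, "b": 3.0, "j": 0.45, "q": 0.0}
_TURRITELLID_DEFAULTS = {"a": 1.0, "c": 1.0, "l": 0.0, "m": 0.0, "q": 0.0}

_KINDS: dict[ModelKind, _KindSpec] = {
    ModelKind.gastropod_system1: _ks(
        _helical_gastropod, ["c", "k", "l", "m", "R_max", "r_max"], _SYSTEM1_DEFAULTS
    ),
    ModelKind.gastropod_system2: _ks(
        _system2, ["b", "c", "j", "k", "R_max", "r_max"], {"a": 1.0}
    ),
    ModelKind.turritellid: _ks(
        _helical_gastropod, ["b", "j", "k", "R_max", "r_max"], _TURRITELLID_DEFAULTS
    ),
    ModelKind.vermicularia: _ks(
        _helical_gastropod, ["b", "j", "k", "q", "R_max", "r_max"],
        {"a": 1.0, "c": 1.0, "l": 0.0, "m": 0.0},
    ),
    ModelKind.spiral_curve: _ks(
        _helical_gastropod, ["b", "j", "k", "R_max", "r_max"], _TURRITELLID_DEFAULTS
    ),
    ModelKind.limpet: _ks(_limpet, ["a", "c", "k", "R", "r"]),
    ModelKind.clam: _ks(_clam, ["a", "b", "j", "R", "r"]),
    ModelKind.oyster: _ks(_oyster, ["c", "R", "r"]),
    ModelKind.scallop: _ks(_scallop, ["a", "b", "c", "j", "l", "m", "R", "r"]),
    ModelKind.ammonite: _ks(_ammonite, ["l", "q", "R", "r"]),
    ModelKind.scaphopod: _ks(_scaphopod, ["a", "k", "R", "r"]),
    ModelKind.echinoid: _ks(_echinoid, ["a", "b", "c", "R", "r"], {"q": 0.02}),
    ModelKind.torus: _ks(_torus, ["R", "r"]),
    ModelKind.cylinder: _ks(_cylinder, ["R", "r"]),
    ModelKind.cone: _ks(_cone, ["R", "r"]),
    ModelKind.dome: _ks(_dome, ["r"]),
    ModelKind.sphere: _ks(_sphere, ["r"]),
    ModelKind.ellipsoid: _ks(_ellipsoid, ["a", "r"]),
}

_ALL_COEFF_NAMES = [f.name for f in fields(CoefficientSet)]


# ---------------------------------------------------------------------------
# SurfaceModel
# ---------------------------------------------------------------------------

@dataclass
class SurfaceModel:
    """A parametric surface: symbolic coordinate expressions plus metadata.

    Instances come from :func:`make_model`, :func:`canonical_model` or
    :func:`model_from_expressions`.  The expressions are in the shared
    symbols :data:`U` and :data:`V` with all coefficients substituted as
    numbers, so they are symbolically differentiable; numeric evaluation
    goes through cached :func:`sympy.lambdify` callables.
    """

    kind: ModelKind | None
    coefficients: CoefficientSet
    domain: ParameterDomain
    x_expr: sp.Expr
    y_expr: sp.Expr
    z_expr: sp.Expr
    label: str | None = None
    _eval_fns: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def expressions(self) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
        return self.x_expr, self.y_expr, self.z_expr

    def _lambdified(self):
        if self._eval_fns is None:
            fns = tuple(lambdify_uv(e) for e in self.expressions)
            object.__setattr__(self, "_eval_fns", fns)
        return self._eval_fns

    def eval_raw(self, u, v) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate the coordinate functions without a domain check.

        Accepts scalars or arrays; broadcasting follows numpy rules.  Used
        internally by grid sampling and finite differencing (which needs to
        step slightly past the domain edge).
        """
        fx, fy, fz = self._lambdified()
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        shape = np.broadcast_shapes(u.shape, v.shape)
        out = []
        for f in (fx, fy, fz):
            val = np.asarray(f(u, v), dtype=float)
            out.append(np.broadcast_to(val, shape).copy() if val.shape != shape else val)
        return out[0], out[1], out[2]


def _resolve_coefficients(kind: ModelKind, coefficients: CoefficientSet) -> dict[str, float]:
    spec = _KINDS[kind]
    resolved: dict[str, float] = {}
    missing: list[str] = []
    for name in _ALL_COEFF_NAMES:
        val = getattr(coefficients, name)
        if val is None:
            if name in spec.required:
                missing.append(name)
            else:
                val = spec.defaults.get(name, 0.0)
        resolved[name] = float(val) if val is not None else 0.0
    if missing:
        raise MissingCoefficientError(
            f"model kind {kind.value!r} requires coefficient(s) {sorted(missing)}"
        )
    for name in spec.positive_radii:
        val = resolved[name]
        if name in ("r", "r_max"):
            if val == 0.0:
                raise DegenerateRadiusError(
                    f"{name} must be nonzero for kind {kind.value!r} "
                    "(it may approach 0 but an exact 0 is rejected)"
                )
        elif val <= 0.0:
            raise DegenerateRadiusError(f"{name} must be > 0 for kind {kind.value!r}")
    return resolved


def make_model(
    kind: ModelKind | str,
    coefficients: CoefficientSet | Mapping[str, float],
    domain: ParameterDomain | None = None,
    label: str | None = None,
) -> SurfaceModel:
    """Build a :class:`SurfaceModel` from a kind and coefficient values.

    Raises :class:`MissingCoefficientError` if a coefficient the kind's
    equations reference is absent, :class:`DegenerateRadiusError` for a zero
    aperture radius, and :class:`RegistryError` for an unknown kind.
    """
    if isinstance(coefficients, Mapping):
        unknown = set(coefficients) - set(_ALL_COEFF_NAMES)
        if unknown:
            raise MissingCoefficientError(f"unknown coefficient name(s) {sorted(unknown)}")
        coefficients = CoefficientSet(**coefficients)
    try:
        kind = ModelKind(kind)
    except ValueError as exc:
        raise RegistryError(f"unknown model kind {kind!r}") from exc
    resolved = _resolve_coefficients(kind, coefficients)
    x, y, z = _KINDS[kind].builder(resolved)
    return SurfaceModel(
        kind=kind,
        coefficients=coefficients,
        domain=domain or ParameterDomain(),
        x_expr=sp.sympify(x),
        y_expr=sp.sympify(y),
        z_expr=sp.sympify(z),
        label=label or kind.value,
    )


def model_from_expressions(
    x: sp.Expr,
    y: sp.Expr,
    z: sp.Expr,
    domain: ParameterDomain | None = None,
    label: str = "custom",
) -> SurfaceModel:
    """Wrap raw sympy expressions in ``U``, ``V`` as a model.

    An escape hatch for surfaces outside the registry (degenerate planar
    maps, ad-hoc experiments).  Such models cannot be rescaled through
    :func:`scale_model` because they carry no radius fields.
    """
    return SurfaceModel(
        kind=None,
        coefficients=CoefficientSet(),
        domain=domain or ParameterDomain(),
        x_expr=sp.sympify(x),
        y_expr=sp.sympify(y),
        z_expr=sp.sympify(z),
        label=label,
    )


def evaluate_point(model: SurfaceModel, u: float, v: float) -> Point3:
    """Evaluate the surface at ``(u, v)``; the point must lie in the domain."""
    if not model.domain.contains(u, v):
        raise DomainError(
            f"(u, v) = ({u}, {v}) outside domain {model.domain.u_range} x {model.domain.v_range}"
        )
    x, y, z = model.eval_raw(u, v)
    pt = Point3(float(x), float(y), float(z))
    if not all(math.isfinite(c) for c in (pt.x, pt.y, pt.z)):
        raise MorphosurfError(f"non-finite coordinates at (u, v) = ({u}, {v})")
    return pt


def sample_grid(model: SurfaceModel, nu: int, nv: int) -> SurfaceGrid:
    """Sample an inclusive, evenly spaced ``nu`` x ``nv`` lattice of the domain."""
    if nu < 2 or nv < 2:
        raise ResolutionError(f"grid resolution must be >= 2 per parameter, got ({nu}, {nv})")
    us = np.linspace(*model.domain.u_range, nu)
    vs = np.linspace(*model.domain.v_range, nv)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    x, y, z = model.eval_raw(uu, vv)
    pts = np.stack([x, y, z], axis=-1)
    if not np.all(np.isfinite(pts)):
        raise MorphosurfError(f"non-finite coordinates in grid of model {model.label!r}")
    return SurfaceGrid(nu=nu, nv=nv, u_values=us, v_values=vs, points=pts)


def scale_model(model: SurfaceModel, factor: float) -> SurfaceModel:
    """Return the model with all radii multiplied by ``factor`` (> 0).

    Shape coefficients are untouched; because every generator is homogeneous
    of degree 1 in the radii, the surface (and its Jacobian summary) scales
    by exactly ``factor``.
    """
    if not factor > 0:
        raise ScaleError(f"scale factor must be > 0, got {factor}")
    if model.kind is None:
        raise ScaleError("cannot rescale a model built from raw expressions")
    updates = {
        name: getattr(model.coefficients, name) * factor
        for name in ("R", "r", "R_max", "r_max")
        if getattr(model.coefficients, name) is not None
    }
    return make_model(
        model.kind, replace(model.coefficients, **updates), model.domain, model.label
    )


# ---------------------------------------------------------------------------
# canonical models
# ---------------------------------------------------------------------------
# Printed coefficient recipes: cone shell, volute, olive, Melampus, sundial
# and bubble carry the published values; remaining coefficients (winding b,
# pitch j, scale a, c) are package defaults documented in docs/methods.md.

_SPIRAL_EPSILON = 1e-3  # aperture radius for spiral "curves": near, never exactly, zero


def _sys1(label, **kw):
    base = dict(a=1.0, b=3.0, c=1.0, j=0.45)
    base.update(kw)
    return ModelKind.gastropod_system1, base, label


def _canonical_recipes() -> dict[str, Callable[..., tuple[ModelKind, dict, str]]]:
    return {
        # gastropod System 1 recipes (printed values)
        "cone_shell": lambda: _sys1("cone_shell", k=0.7, l=3.0, m=3.0, c=1.0,
                                    R_max=1.5, r_max=2.0),
        "volute": lambda: _sys1("volute", k=1.0, l=0.0, m=0.0, R_max=1.5, r_max=2.0),
        "olive": lambda: _sys1("olive", k=1.0, l=2.0, m=0.0, R_max=1.0, r_max=2.0),
        "melampus": lambda: _sys1("melampus", k=1.0, l=1.5, m=2.3, j=0.5,
                                  R_max=0.7, r_max=2.4),
        "sundial": lambda: _sys1("sundial", k=1.0, l=0.0, m=0.0, a=2.0, b=2.0,
                                 j=0.15, R_max=1.3, r_max=1.0),
        "bubble": lambda: _sys1("bubble", k=1.0, l=1.0, m=0.0, b=2.0, j=0.3,
                                R_max=1.0, r_max=2.0),
        # gastropod System 2 exemplar
        "moon_snail": lambda: (
            ModelKind.gastropod_system2,
            dict(a=1.0, b=2.5, c=1.0, j=0.25, k=1.2, R_max=1.0, r_max=1.6),
            "moon_snail",
        ),
        # high-spired family
        "turritellid": lambda n_whorls=8: (
            ModelKind.turritellid,
            dict(b=float(n_whorls), j=0.25, k=0.55, R_max=1.0, r_max=1.0),
            f"turritellid_{int(n_whorls)}",
        ),
        "vermicularia": lambda n_whorls=9, uncoil=2.5: (
            ModelKind.vermicularia,
            dict(b=-float(n_whorls), j=0.25, k=0.55, q=float(uncoil),
                 R_max=1.0, r_max=1.0),
            f"vermicularia_{int(n_whorls)}",
        ),
        "spiral": lambda n_coils=5: (
            ModelKind.spiral_curve,
            dict(b=float(n_coils), j=0.25, k=0.55, R_max=1.0, r_max=_SPIRAL_EPSILON),
            f"spiral_{int(n_coils)}",
        ),
        # bivalves, limpet, cephalopod, scaphopod, echinoid
        "clam": lambda: (ModelKind.clam, dict(a=2.5, b=0.3, j=1.4, R=1.0, r=1.0), "clam"),
        "oyster": lambda: (ModelKind.oyster, dict(c=1.8, R=1.0, r=1.0), "oyster"),
        "scallop": lambda: (
            ModelKind.scallop,
            dict(a=0.4, b=6.0, c=0.08, j=18.0, l=0.45, m=1.1, R=1.0, r=1.0),
            "scallop",
        ),
        "limpet": lambda: (ModelKind.limpet, dict(a=1.0, c=0.8, k=2.0, R=1.5, r=1.0), "limpet"),
        "ammonite": lambda l=3.0, q=8.0: (
            ModelKind.ammonite,
            dict(l=float(l), q=float(q), R=2.0, r=1.0),
            f"ammonite_l{l:g}_q{q:g}",
        ),
        "scaphopod": lambda: (
            ModelKind.scaphopod, dict(a=2.0, k=0.25, R=2.0, r=1.0), "scaphopod"
        ),
        "echinoid": lambda: (
            ModelKind.echinoid, dict(a=0.05, b=1.2, c=0.8, R=2.0, r=2.0), "echinoid"
        ),
        # basic geometric forms
        "torus": lambda: (ModelKind.torus, dict(R=2.0, r=1.0), "torus"),
        "cylinder": lambda: (ModelKind.cylinder, dict(R=2.0, r=1.0), "cylinder"),
        "cone": lambda: (ModelKind.cone, dict(R=2.0, r=1.0), "cone"),
        "dome": lambda: (ModelKind.dome, dict(r=1.0), "dome"),
        "sphere": lambda: (ModelKind.sphere, dict(r=1.0), "sphere"),
        "ellipsoid": lambda axis_ratio=1.5: (
            ModelKind.ellipsoid,
            dict(a=float(axis_ratio), r=1.0),
            f"ellipsoid_{axis_ratio:g}",
        ),
    }


_CANONICAL = _canonical_recipes()

_NAME_WITH_ARGS = re.compile(r"^\s*([A-Za-z_][\w]*)\s*(?:\(\s*([^)]*)\s*\))?\s*$")


def canonical_names() -> list[str]:
    """Names accepted by :func:`canonical_model`."""
    return sorted(_CANONICAL)


def canonical_model(name: str, **kwargs) -> SurfaceModel:
    """Build a registered model from its name.

    Arguments may be passed as keywords or inline, e.g. ``"turritellid(7)"``,
    ``"ammonite(3, 8)"`` or ``"ellipsoid(2.5)"``.  Unknown names raise
    :class:`RegistryError`.
    """
    match = _NAME_WITH_ARGS.match(name)
    if not match:
        raise RegistryError(f"malformed canonical-model name {name!r}")
    base, argtext = match.group(1), match.group(2)
    if base not in _CANONICAL:
        raise RegistryError(
            f"unknown canonical model {base!r}; known: {', '.join(canonical_names())}"
        )
    args: list[float] = []
    if argtext:
        args = [float(tok) for tok in argtext.split(",") if tok.strip()]
    kind, coeffs, label = _CANONICAL[base](*args, **kwargs)
    return make_model(kind, coeffs, label=label)
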