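"""Jacobian summaries, Hessian elements, curvatures and moving frames."""

import math

import numpy as np
import pytest
import sympy as sp

from morphosurf import (
    DegenerateCurveError,
    ModelKind,
    RegularityError,
    StepError,
    U,
    UnknownElementError,
    V,
    canonical_model,
    darboux_frame,
    frenet_frame,
    hessian_elements,
    jacobian,
    jacobian_minors,
    jacobians_identical,
    make_model,
    model_from_expressions,
    numeric_jacobian,
    principal_curvatures,
    scale_model,
)
from morphosurf.diffgeo import JacobianSummary


def unit_torus():
    return make_model(ModelKind.torus, {"R": 1.0, "r": 1.0})


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def test_unit_torus_jacobian_at_origin():
    J = jacobian(unit_torus())
    assert J.flat == (0.0, 0.0, 2.0, 0.0, 0.0, 1.0)
    assert J.matrix.shape == (3, 2)


def test_jacobian_scales_linearly_with_radii():
    m = unit_torus()
    J = np.array(jacobian(m).flat)
    for c in (0.5, 3.0):
        Jc = np.array(jacobian(scale_model(m, c)).flat)
        assert np.max(np.abs(Jc - c * J)) < 1e-12


def test_numeric_jacobian_agrees_with_symbolic():
    for name in ("torus", "volute", "scallop", "echinoid"):
        m = canonical_model(name)
        for u0, v0 in [(0.0, 0.0), (1.3, 4.1)]:
            sym = np.array(jacobian(m, u0, v0).flat)
            num = np.array(numeric_jacobian(m, u0, v0).flat)
            scale = max(1.0, np.max(np.abs(sym)))
            assert np.max(np.abs(sym - num)) < 1e-6 * scale, name


def test_nonpositive_step_rejected():
    with pytest.raises(StepError):
        numeric_jacobian(unit_torus(), 0.0, 0.0, h=0.0)


def test_jacobian_minors_examples():
    J = jacobian(unit_torus())
    assert jacobian_minors(J) == (0.0, 0.0, 2.0)
    zero = JacobianSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    assert jacobian_minors(zero) == (0.0, 0.0, 0.0)


def test_flat_model_minors_all_zero():
    # z identically 0 and x, y functions of u only: rank-deficient tangent map
    flat = model_from_expressions(sp.cos(U), sp.sin(U), sp.Integer(0), label="flat")
    minors = jacobian_minors(jacobian(flat, 1.0, 1.0))
    assert minors == (0.0, 0.0, 0.0)


def test_reflection_negates_only_z_row():
    m = unit_torus()
    reflected = model_from_expressions(m.x_expr, m.y_expr, -m.z_expr)
    a = jacobian(m, 1.0, 2.0)
    b = jacobian(reflected, 1.0, 2.0)
    assert (b.dx_du, b.dx_dv, b.dy_du, b.dy_dv) == (a.dx_du, a.dx_dv, a.dy_du, a.dy_dv)
    assert (b.dz_du, b.dz_dv) == (-a.dz_du, -a.dz_dv)


def test_rotation_swaps_jacobian_columns_predictably():
    # swapping sin u and cos u in x, y is a quarter-turn about the z-axis:
    # the new (x, y) rows are the old (y, x) rows up to sign
    m = unit_torus()
    rotated = model_from_expressions(
        m.y_expr, m.x_expr, m.z_expr  # (x, y) -> (y, x), a reflection-rotation
    )
    a = jacobian(m, 1.0, 2.0)
    b = jacobian(rotated, 1.0, 2.0)
    assert (b.dx_du, b.dx_dv) == (a.dy_du, a.dy_dv)
    assert (b.dy_du, b.dy_dv) == (a.dx_du, a.dx_dv)


def test_jacobians_identical_threshold():
    a = jacobian(unit_torus())
    b = JacobianSummary(*(x + 1e-12 for x in a.flat))
    c = JacobianSummary(*(x + 1e-6 for x in a.flat))
    assert jacobians_identical(a, b)
    assert not jacobians_identical(a, c)


# ---------------------------------------------------------------------------
# Hessian elements
# ---------------------------------------------------------------------------

def test_unit_torus_hessian_examples():
    h = hessian_elements(unit_torus(), 0.0, 0.0,
                         which=("d2x_du2", "d2z_dudv", "d2x_dv2"))
    assert h["d2x_du2"] == pytest.approx(-2.0, abs=1e-12)
    assert h["d2z_dudv"] == pytest.approx(0.0, abs=1e-12)
    assert h["d2x_dv2"] == pytest.approx(-1.0, abs=1e-12)


def test_unknown_hessian_element_rejected():
    with pytest.raises(UnknownElementError):
        hessian_elements(unit_torus(), 0.0, 0.0, which=("d2x_du3",))


def test_mixed_partials_are_symmetric():
    from morphosurf.surfaces import lambdify_uv

    for name in ("volute", "ammonite", "scallop", "echinoid"):
        m = canonical_model(name)
        for expr in m.expressions:
            uv = lambdify_uv(sp.diff(expr, U, V))(1.0, 2.0)
            vu = lambdify_uv(sp.diff(expr, V, U))(1.0, 2.0)
            assert abs(float(uv) - float(vu)) < 1e-9, name


# ---------------------------------------------------------------------------
# curvature and frames
# ---------------------------------------------------------------------------

def test_torus_principal_curvatures_match_closed_form():
    m = canonical_model("torus")  # R = 2, r = 1
    outer = principal_curvatures(m, 0.0, 0.0)
    assert outer.k1 == pytest.approx(1.0 / 3.0, abs=1e-9)
    assert outer.k2 == pytest.approx(1.0, abs=1e-9)
    top = principal_curvatures(m, 0.0, math.pi / 2)
    assert top.k1 == pytest.approx(0.0, abs=1e-9)
    assert top.k2 == pytest.approx(1.0, abs=1e-9)
    assert outer.gaussian == pytest.approx(1.0 / 3.0, abs=1e-9)
    assert outer.mean == pytest.approx(2.0 / 3.0, abs=1e-9)


def test_sphere_is_umbilic():
    m = canonical_model("sphere")
    for u0, v0 in [(0.0, 0.0), (1.0, 1.0), (4.0, 2.5), (2.0, 5.5)]:
        cs = principal_curvatures(m, u0, v0)
        assert cs.k1 == pytest.approx(cs.k2, abs=1e-8)


def test_degenerate_metric_raises_regularity_error():
    # the cone apex line v = 0 collapses the u-curve to a point
    with pytest.raises(RegularityError):
        principal_curvatures(canonical_model("cone"), 1.0, 0.0)


def test_darboux_frame_unit_torus_origin():
    fr = darboux_frame(unit_torus(), 0.0, 0.0, along="u_curve")
    assert np.allclose(fr.t, [0.0, 1.0, 0.0], atol=1e-12)
    assert abs(abs(fr.u_vec[0]) - 1.0) < 1e-12  # normal is +/-(1, 0, 0)
    # orthonormal triple
    M = np.stack([fr.t, fr.u_vec, fr.v_vec])
    assert np.max(np.abs(M @ M.T - np.eye(3))) < 1e-9


def test_torus_meridian_is_a_geodesic():
    m = canonical_model("torus")
    fr = darboux_frame(m, 1.0, 1.0, along="v_curve")
    assert fr.kappa_g == pytest.approx(0.0, abs=1e-9)
    assert fr.tau_g == pytest.approx(0.0, abs=1e-9)


def test_frenet_frame_of_meridian_circle():
    m = canonical_model("torus")  # meridian is a circle of radius r = 1
    ff = frenet_frame(m, 0.0, 1.0, along="v_curve")
    assert ff.kappa == pytest.approx(1.0, abs=1e-9)
    assert ff.tau == pytest.approx(0.0, abs=1e-9)
    df = darboux_frame(m, 0.0, 1.0, along="v_curve")
    assert np.allclose(ff.t, df.t, atol=1e-9)
    M = np.stack([ff.t, ff.n, ff.b])
    assert np.max(np.abs(M @ M.T - np.eye(3))) < 1e-9


def test_zero_speed_and_zero_curvature_curves_rejected():
    cone = canonical_model("cone")
    # at v = 0 the cone's u-curve collapses to the apex: the surface itself
    # is irregular there, which darboux_frame reports first
    with pytest.raises(RegularityError):
        darboux_frame(cone, 1.0, 0.0, along="u_curve")
    # the Frenet frame of that collapsed curve fails on zero speed
    with pytest.raises(DegenerateCurveError):
        frenet_frame(cone, 1.0, 0.0, along="u_curve")
    # a cylinder generator line is straight: zero curvature, no principal normal
    with pytest.raises(DegenerateCurveError):
        frenet_frame(canonical_model("cylinder"), 1.0, 1.0, along="v_curve")
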