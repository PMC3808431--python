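"""Surface construction, evaluation, sampling, scaling and the registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphosurf import (
    CoefficientSet,
    DegenerateRadiusError,
    DomainError,
    MissingCoefficientError,
    ModelKind,
    ParameterDomain,
    RegistryError,
    ResolutionError,
    ScaleError,
    canonical_model,
    canonical_names,
    evaluate_point,
    make_model,
    sample_grid,
    scale_model,
)

TWO_PI = 2.0 * math.pi


def unit_torus():
    return make_model(ModelKind.torus, {"R": 1.0, "r": 1.0})


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_unit_torus_reference_points():
    m = unit_torus()
    p = evaluate_point(m, 0.0, 0.0)
    assert (p.x, p.y, p.z) == pytest.approx((2.0, 0.0, 0.0), abs=1e-12)
    p = evaluate_point(m, math.pi / 2, 0.0)
    assert (p.x, p.y, p.z) == pytest.approx((0.0, 2.0, 0.0), abs=1e-12)
    p = evaluate_point(m, 0.0, math.pi)
    assert (p.x, p.y, p.z) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_evaluation_outside_domain_rejected():
    m = unit_torus()
    with pytest.raises(DomainError):
        evaluate_point(m, -1.0, 0.0)
    with pytest.raises(DomainError):
        evaluate_point(m, 0.0, TWO_PI + 1.0)


def test_torus_closure_at_period_boundaries():
    m = unit_torus()
    for v in (0.0, 1.0, 2.5):
        a = evaluate_point(m, 0.0, v).as_array()
        b = evaluate_point(m, TWO_PI, v).as_array()
        assert np.max(np.abs(a - b)) < 1e-12
    for u in (0.0, 1.0, 2.5):
        a = evaluate_point(m, u, 0.0).as_array()
        b = evaluate_point(m, u, TWO_PI).as_array()
        assert np.max(np.abs(a - b)) < 1e-12


# ---------------------------------------------------------------------------
# construction errors
# ---------------------------------------------------------------------------

def test_missing_coefficient_is_named():
    with pytest.raises(MissingCoefficientError) as exc:
        make_model(ModelKind.gastropod_system1,
                   {"c": 1.0, "l": 3.0, "m": 3.0, "R_max": 1.5, "r_max": 2.0})
    assert "k" in str(exc.value)


def test_zero_aperture_radius_rejected():
    with pytest.raises(DegenerateRadiusError):
        make_model(ModelKind.torus, {"R": 1.0, "r": 0.0})


def test_unknown_kind_rejected():
    with pytest.raises(RegistryError):
        make_model("snail", {"R": 1.0, "r": 1.0})


def test_unknown_coefficient_name_rejected():
    with pytest.raises(MissingCoefficientError):
        make_model(ModelKind.torus, {"R": 1.0, "r": 1.0, "wings": 3.0})


def test_domain_bounds_must_be_ordered():
    with pytest.raises(DomainError):
        ParameterDomain(u_range=(1.0, 1.0))


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def test_grid_count_and_periodic_corners():
    m = unit_torus()
    g = sample_grid(m, 3, 3)
    assert g.n_points == 9
    corners = [g.points[i, j] for i in (0, -1) for j in (0, -1)]
    for corner in corners:
        assert np.allclose(corner, [2.0, 0.0, 0.0], atol=1e-12)
    assert sample_grid(m, 4, 5).n_points == 20


def test_grid_resolution_minimum():
    with pytest.raises(ResolutionError):
        sample_grid(unit_torus(), 1, 3)


def test_sphere_grid_lies_on_unit_sphere():
    g = sample_grid(canonical_model("sphere"), 9, 9)
    norms = np.linalg.norm(g.flat_points(), axis=1)
    assert np.max(np.abs(norms - 1.0)) < 1e-12


# ---------------------------------------------------------------------------
# scaling / homogeneity
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=25, deadline=None)
@given(factor=st.floats(min_value=0.05, max_value=20.0,
                        allow_nan=False, allow_infinity=False))
def test_homogeneity_of_degree_one_in_radii(factor):
    m = canonical_model("volute")
    scaled = scale_model(m, factor)
    pts = [(0.0, 0.0), (1.0, 2.0), (5.0, 0.5), (TWO_PI, TWO_PI)]
    for u, v in pts:
        a = evaluate_point(m, u, v).as_array()
        b = evaluate_point(scaled, u, v).as_array()
        assert np.max(np.abs(b - factor * a)) <= 1e-9 * max(1.0, np.max(np.abs(b)))


def test_scale_examples_and_errors():
    m = unit_torus()
    doubled = scale_model(m, 2.0)
    p = evaluate_point(doubled, 0.0, 0.0)
    assert (p.x, p.y, p.z) == pytest.approx((4.0, 0.0, 0.0), abs=1e-12)
    same = scale_model(m, 1.0)
    assert evaluate_point(same, 1.0, 1.0).as_array() == pytest.approx(
        evaluate_point(m, 1.0, 1.0).as_array()
    )
    with pytest.raises(ScaleError):
        scale_model(m, 0.0)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def test_registry_completeness_all_names_evaluate_finitely():
    for name in canonical_names():
        model = canonical_model(name)
        grid = sample_grid(model, 7, 7)
        assert np.all(np.isfinite(grid.points)), name


def test_printed_recipe_coefficients():
    volute = canonical_model("volute")
    c = volute.coefficients
    assert (c.k, c.l, c.m, c.R_max, c.r_max) == (1.0, 0.0, 0.0, 1.5, 2.0)
    melampus = canonical_model("melampus")
    c = melampus.coefficients
    assert (c.l, c.m, c.R_max, c.r_max) == (1.5, 2.3, 0.7, 2.4)
    sundial = canonical_model("sundial")
    c = sundial.coefficients
    assert (c.a, c.b, c.R_max, c.r_max) == (2.0, 2.0, 1.3, 1.0)


def test_canonical_inline_arguments_and_labels():
    t7 = canonical_model("turritellid(7)")
    assert t7.label == "turritellid_7"
    assert t7.coefficients.b == 7.0
    amm = canonical_model("ammonite(3, 8)")
    assert amm.label == "ammonite_l3_q8"
    ell = canonical_model("ellipsoid(2.5)")
    assert ell.label == "ellipsoid_2.5"


def test_unknown_canonical_name_rejected():
    with pytest.raises(RegistryError):
        canonical_model("nonexistent")


def test_turritellid_matches_vermicularia_without_uncoiling():
    turr = canonical_model("turritellid(8)")
    verm = make_model(
        ModelKind.vermicularia,
        {"b": 8.0, "j": 0.25, "k": 0.55, "q": 0.0, "R_max": 1.0, "r_max": 1.0},
    )
    for u, v in [(0.0, 0.0), (1.0, 2.0), (3.0, 5.0), (TWO_PI, TWO_PI)]:
        a = evaluate_point(turr, u, v).as_array()
        b = evaluate_point(verm, u, v).as_array()
        assert np.max(np.abs(a - b)) < 1e-9


def test_coefficient_set_as_dict_only_reports_set_fields():
    c = CoefficientSet(R=2.0, r=1.0)
    d = c.as_dict()
    assert d["R"] == 2.0 and d["r"] == 1.0
    assert "k" not in d and d["z_offset"] == 0.0
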