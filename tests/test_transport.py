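"""Closed-form transport: dispersivity correlation, velocities, peak."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import nanospill as ns


def test_dispersivity_base10_anchor():
    assert ns.dispersivity_x(10.0) == pytest.approx(0.83, abs=1e-12)


@pytest.mark.parametrize(
    "x,expected",
    [(200.0, 6.20524), (600.0, 9.77923)],
)
def test_dispersivity_at_case_distances(x, expected):
    # frozen from a high-precision evaluation of 0.83*(log10 x)**2.414
    assert ns.dispersivity_x(x) == pytest.approx(expected, abs=5e-4)


def test_dispersivity_strictly_increasing_and_lateral_ratio():
    xs = np.linspace(1.5, 2000, 500)
    ax = ns.dispersivity_x(xs)
    assert np.all(np.diff(ax) > 0)
    np.testing.assert_allclose(ns.dispersivity_y(xs), ax / 10.0, rtol=1e-15)


def test_dispersivity_domain_error_at_or_below_1m():
    for x in (1.0, 0.5, -3.0):
        with pytest.raises(ValueError):
            ns.dispersivity_x(x)


def test_linear_velocity_darcy():
    assert ns.linear_velocity(1.0, 1.0, 0.999) == pytest.approx(1.0, rel=1e-2)
    assert ns.linear_velocity(244.7, 0.001, 0.15) == pytest.approx(1.631, abs=2e-3)
    assert ns.linear_velocity(2 * 244.7, 0.001, 0.15) == pytest.approx(
        2 * ns.linear_velocity(244.7, 0.001, 0.15)
    )
    with pytest.raises(ValueError):
        ns.linear_velocity(1.0, 1.0, 0.0)


def test_arrival_time():
    assert ns.arrival_time(1.0, 1.0, 1.0) == 1.0
    assert ns.arrival_time(200.0, 1.05, 1.631) == pytest.approx(128.8, abs=0.2)
    v = 1.7
    assert ns.arrival_time(50.0, 1.1, v) / ns.arrival_time(50.0, 1.0, v) == pytest.approx(1.1)
    with pytest.raises(ValueError):
        ns.arrival_time(1.0, 1.0, 0.0)


@pytest.mark.parametrize(
    "L,n,expected_mg_L",
    [(200.0, 0.15, 0.8587), (600.0, 0.25, 0.1089)],
)
def test_peak_concentration_case_medians(L, n, expected_mg_L):
    # plug-in arithmetic at the case-study central parameter values
    src = ns.SourceSpec(mass=2e9, source_length_b=3.0, distance_L=L)
    c = ns.peak_concentration(src, n=n, F=1.05)
    assert c / 1e6 == pytest.approx(expected_mg_L, abs=2e-3)


def test_peak_concentration_monotone_decreasing_in_b_n_F_L():
    base = dict(mass=2e9, b=3.0, L=200.0, n=0.15, F=1.05)

    def cmax(mass, b, L, n, F):
        return ns.peak_concentration(
            ns.SourceSpec(mass=mass, source_length_b=b, distance_L=L), n=n, F=F
        )

    c0 = cmax(base["mass"], base["b"], base["L"], base["n"], base["F"])
    assert cmax(base["mass"], 4.0, base["L"], base["n"], base["F"]) < c0
    assert cmax(base["mass"], base["b"], 300.0, base["n"], base["F"]) < c0
    assert cmax(base["mass"], base["b"], base["L"], 0.2, base["F"]) < c0
    assert cmax(base["mass"], base["b"], base["L"], base["n"], 1.1) < c0
    # linear in mass
    assert cmax(2 * base["mass"], base["b"], base["L"], base["n"], base["F"]) == pytest.approx(2 * c0)


@given(
    L=st.floats(10.0, 1500.0),
    n=st.floats(0.05, 0.45),
    g=st.floats(1e-4, 5e-3),
    k=st.floats(5.0, 2000.0),
    F=st.floats(1.0, 1.2),
    b=st.floats(0.5, 20.0),
    mass=st.floats(1e6, 1e11),
)
@settings(deadline=None, max_examples=100)
def test_field_at_peak_equals_closed_form(L, n, g, k, F, b, mass):
    """C(L, 0, t_max) must reproduce the closed-form peak to 1e-12."""
    src = ns.SourceSpec(mass=mass, source_length_b=b, distance_L=L)
    aq = ns.AquiferDraw(porosity_n=n, gradient_g=g, conductivity_k=k, retardation_F=F)
    sol = ns.solve_transport(src, aq)
    c_field = ns.concentration_field(L, 0.0, sol.t_max, src, aq)
    assert c_field == pytest.approx(sol.c_max, rel=1e-12)


def test_field_symmetry_and_decay_in_y():
    src = ns.SourceSpec(mass=2e9, source_length_b=3.0, distance_L=200.0)
    aq = ns.AquiferDraw(porosity_n=0.15, gradient_g=1e-3, conductivity_k=244.7, retardation_F=1.05)
    t = 100.0
    for y in (0.0, 3.0, 17.2):
        assert ns.concentration_field(150.0, y, t, src, aq) == ns.concentration_field(
            150.0, -y, t, src, aq
        )
    ys = np.array([0.0, 5.0, 20.0, 80.0, 400.0])
    c = ns.concentration_field(150.0, ys, t, src, aq)
    assert np.all(np.diff(c) < 0)
    assert c[-1] < 1e-12 * c[0]
    with pytest.raises(ValueError):
        ns.concentration_field(150.0, 0.0, 0.0, src, aq)


def test_peak_time_convention_close_to_true_temporal_maximum():
    """The closed-form peak evaluates the field at the plume-centre
    passage time; the true temporal maximum at fixed x is slightly
    earlier (the 1/t prefactor) but within a fraction of a percent."""
    src = ns.SourceSpec(mass=2e9, source_length_b=3.0, distance_L=200.0)
    aq = ns.AquiferDraw(porosity_n=0.15, gradient_g=1e-3, conductivity_k=244.7, retardation_F=1.05)
    sol = ns.solve_transport(src, aq)
    res = minimize_scalar(
        lambda t: -ns.concentration_field(200.0, 0.0, t, src, aq),
        bounds=(0.3 * sol.t_max, 2.0 * sol.t_max),
        method="bounded",
    )
    assert res.x < sol.t_max  # true max is earlier
    assert -res.fun >= sol.c_max
    assert (-res.fun - sol.c_max) / sol.c_max < 0.05


def test_solution_invariants():
    src = ns.SourceSpec(mass=2e9, source_length_b=3.0, distance_L=200.0)
    aq = ns.AquiferDraw(porosity_n=0.15, gradient_g=1e-3, conductivity_k=244.7, retardation_F=1.05)
    sol = ns.solve_transport(src, aq)
    assert sol.alpha_y == sol.alpha_x / 10.0
    assert sol.Dx == pytest.approx(sol.alpha_x * sol.velocity_Vfx)
    assert sol.Dy == pytest.approx(sol.alpha_y * sol.velocity_Vfx)
    assert sol.t_max == pytest.approx(200.0 * 1.05 / sol.velocity_Vfx)
    assert sol.darcy_q == pytest.approx(244.7 * 1e-3)
    assert sol.c_max > 0 and sol.t_max > 0


def test_invalid_source_and_aquifer_fields():
    with pytest.raises(ValueError):
        ns.SourceSpec(mass=-1.0, source_length_b=3.0, distance_L=200.0)
    with pytest.raises(ValueError):
        ns.AquiferDraw(porosity_n=1.2, gradient_g=1e-3, conductivity_k=100.0, retardation_F=1.0)
    with pytest.raises(ValueError):
        ns.AquiferDraw(porosity_n=0.2, gradient_g=1e-3, conductivity_k=100.0, retardation_F=0.9)
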