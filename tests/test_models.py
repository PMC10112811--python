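"""Unit and property tests for the three speed-mass curves and their
analytic properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allospeed as ap
from allospeed import LocomotionMode, ModelKind, ModelSpec
from allospeed.exceptions import ConfigurationError

METABOLIC = ModelSpec(kind="metabolic")
CONSTANT = ModelSpec(kind="constant_hd")
ALLOMETRIC = ModelSpec(kind="allometric_hd")


def table_params(sigma=0.3, **overrides):
    p = ap.reference_parameters(sigma=sigma)
    for key, val in overrides.items():
        setattr(p, key, val)
    return p


def direct_allometric(mass, v0, k, c, d):
    """Plain-arithmetic oracle for the hump-shaped curve (no log tricks)."""
    return (1.0 / k) * mass**c / (mass ** (c + d) + 1.0 / (v0 * k))


class TestRealisedSpeed:
    def test_metabolic_identity_at_unit_mass(self):
        params = table_params()
        for mode in LocomotionMode:
            assert ap.realised_speed(METABOLIC, 1.0, mode, params) == pytest.approx(
                params.v0_for(mode)
            )

    @pytest.mark.parametrize(
        "mode, mass",
        [("swimming", 74_000.0), ("flying", 1.0), ("running", 250.0), ("swimming", 1e-5)],
    )
    def test_allometric_matches_direct_arithmetic(self, mode, mass):
        params = table_params()
        expected = direct_allometric(mass, params.v0_for(mode), 0.033, 0.27, 0.24)
        assert ap.realised_speed(ALLOMETRIC, mass, mode, params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_fin_whale_mass_speed(self):
        # 74-tonne swimmer on the posterior-mean curve: ~1.64 m/s
        v = ap.realised_speed(ALLOMETRIC, 74_000.0, "swimming", table_params())
        assert v == pytest.approx(1.64, abs=0.01)

    def test_one_kg_flyer_speed(self):
        v = ap.realised_speed(ALLOMETRIC, 1.0, "flying", table_params())
        assert v == pytest.approx((1 / 0.033) / (1 + 1 / (30.54 * 0.033)), rel=1e-12)
        assert v == pytest.approx(15.2, abs=0.05)

    def test_constant_hd_saturates_below_speed_ceiling(self):
        params = table_params(k0=0.05, k_lambda=None)
        v_big = ap.realised_speed(CONSTANT, 1e12, "running", params)
        v_bigger = ap.realised_speed(CONSTANT, 1e20, "running", params)
        assert v_big < v_bigger < 1 / 0.05
        assert v_bigger == pytest.approx(1 / 0.05, rel=1e-3)

    def test_stable_over_extreme_masses(self):
        params = table_params()
        masses = np.logspace(-12, 12, 25)
        for spec in (METABOLIC, ALLOMETRIC):
            v = ap.realised_speed(spec, masses, "swimming", params)
            assert np.all(np.isfinite(v)) and np.all(v > 0)

    def test_vectorised_matches_scalar(self):
        params = table_params()
        masses = np.logspace(-8, 5, 7)
        vec = ap.realised_speed(ALLOMETRIC, masses, "running", params)
        scal = [ap.realised_speed(ALLOMETRIC, m, "running", params) for m in masses]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            ap.realised_speed(ALLOMETRIC, 0.0, "flying", table_params())
        with pytest.raises(ValueError, match="mass"):
            ap.realised_speed(ALLOMETRIC, -1.0, "flying", table_params())

    def test_missing_parameter_rejected(self):
        params = table_params(k_lambda=None)
        with pytest.raises(ConfigurationError):
            ap.realised_speed(ALLOMETRIC, 1.0, "flying", params)


class TestNesting:
    """The three models are nested limits of one another."""

    def test_allometric_with_zero_d_equals_constant(self):
        masses = np.logspace(-10, 8, 50)
        p_allo = table_params(d=0.0)
        p_const = table_params(k0=0.033, k_lambda=None, d=0.0)
        for mode in LocomotionMode:
            np.testing.assert_allclose(
                ap.realised_speed(ALLOMETRIC, masses, mode, p_allo),
                ap.realised_speed(CONSTANT, masses, mode, p_const),
                rtol=1e-12,
            )

    def test_constant_with_vanishing_k_approaches_metabolic(self):
        masses = np.logspace(-8, 6, 30)
        p_const = table_params(k0=1e-14, k_lambda=None)
        p_met = table_params(k_lambda=None)
        np.testing.assert_allclose(
            ap.realised_speed(CONSTANT, masses, "running", p_const),
            ap.realised_speed(METABOLIC, masses, "running", p_met),
            rtol=1e-6,
        )

    def test_small_mass_limit_is_power_law(self):
        # both heat-dissipation curves converge to v0*M^c as M -> 0
        params = table_params(k0=0.033)
        m = 1e-9
        expected = params.v0_for("running") * m**0.27
        for spec in (CONSTANT, ALLOMETRIC):
            assert ap.realised_speed(spec, m, "running", params) == pytest.approx(
                expected, rel=1e-3
            )


class TestShape:
    def test_metabolic_and_constant_strictly_increasing(self):
        masses = np.logspace(-10, 10, 200)
        params = table_params(k0=0.033)
        for spec in (METABOLIC, CONSTANT):
            v = ap.realised_speed(spec, masses, "swimming", params)
            assert np.all(np.diff(v) > 0)

    def test_allometric_unimodal_around_peak(self):
        params = table_params()
        for mode in LocomotionMode:
            m_star = ap.peak_mass(params, mode)
            grid = np.logspace(math.log10(m_star) - 6, math.log10(m_star) + 6, 400)
            v = ap.realised_speed(ALLOMETRIC, grid, mode, params)
            rising = grid < m_star
            assert np.all(np.diff(v[rising]) > 0)
            falling = grid > m_star
            assert np.all(np.diff(v[falling]) < 0)


class TestPeakMass:
    def test_flying_peak_near_one_kg(self):
        assert ap.peak_mass(table_params(), "flying") == pytest.approx(1.24, abs=0.01)

    def test_swimming_peak_thousands_of_kg(self):
        m_star = ap.peak_mass(table_params(), "swimming")
        assert m_star == pytest.approx(6.4e3, rel=0.01)

    def test_zero_d_has_no_interior_maximum(self):
        with pytest.raises(ConfigurationError, match="saturat"):
            ap.peak_mass(table_params(d=0.0), "flying")

    def test_v0_scaling_identity(self):
        # multiplying v0 by x scales the peak mass by x**(-1/(c+d))
        p1 = table_params()
        x = 7.3
        p2 = table_params()
        p2.v0 = {m: v * x for m, v in p1.v0.items()}
        ratio = ap.peak_mass(p2, "running") / ap.peak_mass(p1, "running")
        assert ratio == pytest.approx(x ** (-1 / (0.27 + 0.24)), rel=1e-10)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        v0=st.floats(0.05, 50.0),
        k=st.floats(1e-3, 1.0),
        c=st.floats(0.1, 0.45),
        d=st.floats(0.05, 0.45),
    )
    def test_closed_form_matches_grid_search(self, v0, k, c, d):
        params = ap.ParameterSet(
            v0={LocomotionMode.RUNNING: v0}, k_lambda=k, c=c, d=d, sigma=0.3
        )
        m_star = ap.peak_mass(params, "running")
        lg = math.log10(m_star)
        grid = np.logspace(lg - 2, lg + 2, 4001)  # resolution 1e-3 decades
        v = ap.realised_speed(ALLOMETRIC, grid, "running", params)
        argmax = grid[np.argmax(v)]
        assert abs(math.log10(argmax) - lg) <= 2 * (4.0 / 4000)


class TestExponentBounds:
    def test_empirical_aerobic_and_efficiency_exponents(self):
        lo, hi = ap.exponent_bounds((0.80, 0.97), -0.67)
        assert lo == pytest.approx(0.13, abs=1e-12)
        assert hi == pytest.approx(0.30, abs=1e-12)

    def test_degenerate_interval_cancels(self):
        assert ap.exponent_bounds((0.5, 0.5), -0.5) == pytest.approx((0.0, 0.0))

    def test_wider_metabolic_interval(self):
        assert ap.exponent_bounds((0.75, 1.00), -0.67) == pytest.approx(
            (0.08, 0.33), abs=1e-12
        )

    def test_unordered_interval_rejected(self):
        with pytest.raises(ValueError):
            ap.exponent_bounds((0.97, 0.80), -0.67)

    def test_theory_bounds_derives_c_range(self):
        tb = ap.TheoryBounds(a_range=(0.80, 0.97), b=-0.67, d_range=(0.01, 0.37))
        assert tb.c_range == pytest.approx((0.13, 0.30), abs=1e-12)
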