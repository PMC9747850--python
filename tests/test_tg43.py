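"""TG43U1 engine: geometry factor against a quadrature oracle, parameter
extraction identities, forward dose and round trips."""

import numpy as np
import pytest
from scipy.integrate import quad

from brachymc.tg43 import (
    TG43Parameters,
    anisotropy_function,
    consensus_dose_rate_constant,
    dose_rate_constant,
    extract_geometry_factor,
    geometry_factor_line,
    radial_dose_function,
    tg43_dose,
)

L = 0.35


def g_oracle(r, theta_deg, length):
    """Line-source geometry factor by direct quadrature of the defining
    line integral (1/L) int dl / d(l)^2."""
    th = np.deg2rad(theta_deg)
    x = r * np.sin(th)
    z = r * np.cos(th)
    val, _ = quad(lambda l: 1.0 / (x * x + (z - l) ** 2), -length / 2, length / 2)
    return val / length


class TestGeometryFactor:
    def test_point_source_limit(self):
        assert geometry_factor_line(2.0, 90.0, 1e-9) == pytest.approx(0.25, rel=1e-6)

    def test_transverse_value_matches_quadrature(self):
        got = geometry_factor_line(1.0, 90.0, L)
        assert got == pytest.approx(g_oracle(1.0, 90.0, L), rel=1e-10)
        assert got == pytest.approx(2 * np.arctan(L / 2) / L, rel=1e-12)

    def test_on_axis_closed_form(self):
        got = geometry_factor_line(1.0, 0.0, L)
        assert got == pytest.approx(1.0 / (1.0 - L**2 / 4.0), rel=1e-12)
        assert got == pytest.approx(1.031592, abs=1e-6)

    @pytest.mark.parametrize("r,theta", [(1.0, 30.0), (2.5, 120.0), (0.3, 90.0)])
    def test_general_points_match_quadrature(self, r, theta):
        assert geometry_factor_line(r, theta, L) == pytest.approx(
            g_oracle(r, theta, L), rel=1e-10)

    def test_continuity_into_axis(self):
        near = geometry_factor_line(1.0, 1e-5, L)
        axis = geometry_factor_line(1.0, 0.0, L)
        assert near == pytest.approx(axis, rel=1e-8)

    def test_far_field_r2_limit_monotone(self):
        r = np.array([5.0, 10.0, 50.0, 200.0])
        vals = geometry_factor_line(r, np.full_like(r, 90.0), L) * r**2
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-5)

    def test_point_on_segment_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            geometry_factor_line(0.1, 0.0, L)


class TestDoseRateConstant:
    def test_ratio_identity(self):
        lam, rel = dose_rate_constant(2.0e-13, 2.0e-13)
        assert lam == 1.0 and rel == 0.0

    def test_uncertainty_quadrature(self):
        _, rel = dose_rate_constant(1.0, 2.0, 0.03, 0.04)
        assert rel == pytest.approx(0.05)

    def test_normalization_mismatch_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            dose_rate_constant(1.0, 1.0, d_ref_per_history=True,
                               s_k_is_per_history=False)

    def test_consensus_average_rounds_half_up(self):
        # (1.118 + 1.115)/2 = 1.1165 -> 1.117 under half-up rounding
        assert consensus_dose_rate_constant() == 1.117


class TestRadialDoseFunction:
    r = np.array([0.5, 1.0, 2.0, 3.0, 5.0])

    def test_pure_geometry_falloff_gives_unity(self):
        d = geometry_factor_line(self.r, np.full_like(self.r, 90.0), L)
        assert np.allclose(radial_dose_function(self.r, d, L), 1.0, atol=1e-14)

    def test_analytic_exponential_recovered(self):
        d = geometry_factor_line(self.r, np.full_like(self.r, 90.0), L) * np.exp(
            -0.03 * self.r)
        g = radial_dose_function(self.r, d, L)
        assert np.allclose(g, np.exp(-0.03 * (self.r - 1.0)), rtol=1e-12)

    def test_missing_reference_radius_rejected(self):
        with pytest.raises(ValueError, match="r0"):
            radial_dose_function(np.array([0.5, 2.0]), np.array([1.0, 1.0]), L)

    def test_reference_value_exactly_one(self):
        d = np.array([3.0, 1.7, 0.4, 0.2, 0.07])
        g = radial_dose_function(self.r, d, L)
        assert g[1] == 1.0


class TestAnisotropyFunction:
    r = np.array([1.0, 2.0])
    th = np.array([10.0, 50.0, 90.0, 170.0])

    def test_pure_geometry_gives_unity(self):
        d = geometry_factor_line(self.r[:, None], self.th[None, :], L)
        f = anisotropy_function(self.r, self.th, d, L)
        assert np.allclose(f, 1.0, atol=1e-14)

    def test_halved_dose_at_ten_degrees(self):
        d = geometry_factor_line(self.r[:, None], self.th[None, :], L).copy()
        d[:, 0] *= 0.5
        f = anisotropy_function(self.r, self.th, d, L)
        # direct substitution into the defining formula
        expected = (d[0, 0] * geometry_factor_line(1.0, 90.0, L)
                    / (d[0, 2] * geometry_factor_line(1.0, 10.0, L)))
        assert f[0, 0] == pytest.approx(expected, rel=1e-12)
        assert f[0, 0] == pytest.approx(0.5, rel=1e-12)

    def test_reference_column_exactly_one(self):
        d = np.random.default_rng(0).uniform(0.5, 2.0, size=(2, 4))
        f = anisotropy_function(self.r, self.th, d, L)
        assert np.all(f[:, 2] == 1.0)

    def test_missing_theta0_rejected(self):
        with pytest.raises(ValueError, match="theta0|90"):
            anisotropy_function(self.r, np.array([10.0, 50.0]),
                                np.ones((2, 2)), L)


def _params(lam=1.12):
    g_r = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0])
    g_v = np.exp(-0.002 * (g_r - 1.0) ** 2)
    g_v[2] = 1.0
    f_r = np.array([0.5, 1.0, 2.0, 5.0])
    f_t = np.arange(0.0, 181.0, 10.0)
    f_t[9] = 90.0
    f_v = 1.0 - 0.25 * np.cos(np.deg2rad(f_t))[None, :] ** 2 * np.ones((4, 1))
    f_v[:, 9] = 1.0
    return TG43Parameters(dose_rate_constant=lam, active_length=L,
                          g_r=g_r, g_values=g_v, f_r=f_r, f_theta=f_t, f_values=f_v)


class TestForwardDose:
    def test_reference_point_returns_drc(self):
        p = _params(1.117)
        assert tg43_dose(p, 1.0, 1.0, 90.0) == pytest.approx(1.117, rel=1e-12)

    def test_inverse_square_in_point_limit(self):
        g_r = np.array([0.5, 1.0, 2.0, 5.0])
        p = TG43Parameters(
            dose_rate_constant=1.0, active_length=1e-9, g_r=g_r,
            g_values=np.ones(4), f_r=g_r, f_theta=np.array([0.0, 90.0, 180.0]),
            f_values=np.ones((4, 3)))
        assert tg43_dose(p, 2.0, 2.0, 45.0) == pytest.approx(0.5, rel=1e-6)

    def test_hand_substitution_of_five_factors(self):
        p = _params()
        r, th = 2.0, 40.0
        by_hand = (3.0 * p.dose_rate_constant
                   * geometry_factor_line(r, th, L)
                   / geometry_factor_line(1.0, 90.0, L)
                   * np.interp(r, p.g_r, p.g_values)
                   * p.f_values[np.searchsorted(p.f_r, r), 4])
        assert tg43_dose(p, 3.0, r, th) == pytest.approx(by_hand, rel=1e-12)

    def test_extrapolation_rejected_unless_edge_allowed(self):
        p = _params()
        with pytest.raises(ValueError):
            tg43_dose(p, 1.0, 20.0, 90.0)
        assert tg43_dose(p, 1.0, 20.0, 90.0, allow_edge=True) > 0

    def test_round_trip_through_extraction(self):
        """Forward dose -> extracted g_L and F -> forward dose again
        reproduces the map at tabulated nodes."""
        p = _params()
        r = p.g_r
        th = p.f_theta
        dose_t = np.array([tg43_dose(p, 1.0, ri, 90.0, allow_edge=True) for ri in r])
        g = radial_dose_function(r, dose_t, L)
        assert np.allclose(g, p.g_values, rtol=1e-10)
        grid = np.array([[tg43_dose(p, 1.0, ri, tj, allow_edge=True)
                          for tj in th] for ri in p.f_r])
        f = anisotropy_function(p.f_r, th, grid, L)
        assert np.allclose(f, p.f_values, rtol=1e-10)


class TestExtractGeometryFactor:
    def test_profile_proportional_to_g_becomes_constant(self):
        z = np.linspace(0.5, 5.0, 10)
        pos = np.column_stack([np.zeros_like(z), z, np.zeros_like(z)])
        doses = geometry_factor_line(z, np.full_like(z, 90.0), L)
        adj, mult, exc = extract_geometry_factor(pos, doses, L)
        assert not exc.any()
        assert np.allclose(adj, adj[0], rtol=1e-12)

    def test_reference_point_multiplier_is_one(self):
        _, mult, _ = extract_geometry_factor([[0.0, 1.0, 0.0]], [1.0], L)
        assert mult[0] == pytest.approx(1.0, rel=1e-12)

    def test_transverse_multiplier_at_two_cm(self):
        _, mult, _ = extract_geometry_factor([[0.0, 2.0, 0.0]], [1.0], L)
        expected = g_oracle(1.0, 90.0, L) / g_oracle(2.0, 90.0, L)
        assert mult[0] == pytest.approx(expected, rel=1e-10)

    def test_points_on_segment_excluded(self):
        adj, _, exc = extract_geometry_factor(
            [[0.0, 0.0, 0.1], [0.0, 1.0, 0.0]], [1.0, 1.0], L)
        assert exc[0] and not exc[1]
        assert np.isnan(adj[0])
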