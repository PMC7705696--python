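"""Model core against independent brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilsans import (
    WoodModelParams,
    bundle_diameter_from_sigma,
    bundle_term,
    cylinder_cs_amplitude,
    intensity_terms,
    paracrystal_sf,
    peak_position,
    size_averaged_P,
    total_intensity,
)


def j1_series(x: float, n_terms: int = 40) -> float:
    """Bessel J1 by its power series — independent of scipy.special."""
    total = 0.0
    for m in range(n_terms):
        total += (
            (-1.0) ** m
            / (math.factorial(m) * math.factorial(m + 1))
            * (x / 2.0) ** (2 * m + 1)
        )
    return total


class TestCylinderAmplitude:
    def test_continuous_limit_at_zero(self):
        assert cylinder_cs_amplitude(0.0) == 1.0
        assert cylinder_cs_amplitude(1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_value_at_one_from_series(self):
        assert cylinder_cs_amplitude(1.0) == pytest.approx(
            2.0 * j1_series(1.0), rel=1e-10
        )
        assert cylinder_cs_amplitude(1.0) == pytest.approx(0.880101, abs=1e-6)

    def test_first_zero_from_series_rootfind(self):
        # bisection on the independent series between 3 and 4.5
        lo, hi = 3.0, 4.5
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if j1_series(lo) * j1_series(mid) <= 0:
                hi = mid
            else:
                lo = mid
        root = 0.5 * (lo + hi)
        assert root == pytest.approx(3.8317, abs=1e-3)
        assert cylinder_cs_amplitude(root) == pytest.approx(0.0, abs=1e-8)


class TestSizeAveragedP:
    def test_degenerate_distribution(self):
        q = np.geomspace(0.002, 0.3, 30)
        np.testing.assert_allclose(
            size_averaged_P(q, 12.0, 0.0),
            cylinder_cs_amplitude(q * 12.0) ** 2,
            rtol=0,
        )

    def test_unity_at_zero_q(self):
        for r_sd in (0.0, 1.0, 3.0):
            assert size_averaged_P(np.array([1e-12]), 12.0, r_sd)[0] == \
                pytest.approx(1.0, abs=1e-8)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(2024)
        radii = rng.normal(12.0, 2.0, 10**6)
        radii = radii[radii > 0]
        mc = np.mean(cylinder_cs_amplitude(0.2 * radii) ** 2)
        assert size_averaged_P(np.array([0.2]), 12.0, 2.0)[0] == \
            pytest.approx(mc, rel=1e-3)


class TestParacrystal:
    def test_no_interference_for_single_plane(self):
        q = np.geomspace(0.002, 0.3, 50)
        np.testing.assert_array_equal(paracrystal_sf(q, 43.0, 0.2, 1),
                                      np.ones_like(q))

    def test_zero_q_equals_N(self):
        for n in (1, 2, 5, 8):
            assert paracrystal_sf(np.array([1e-15]), 43.0, 0.2, n)[0] == \
                pytest.approx(n, abs=1e-9)

    @pytest.mark.parametrize("n_planes", [2, 3, 5, 8])
    def test_closed_form_equals_double_sum(self, n_planes):
        # brute force over all site pairs of the cumulative-disorder stack
        q = np.geomspace(0.002, 0.3, 50)
        d = np.sqrt(3.0) / 2.0 * 43.0
        f = np.exp(-0.5 * q**2 * (0.2 * d) ** 2)
        brute = np.zeros_like(q)
        for j in range(n_planes):
            for k in range(n_planes):
                brute += f ** abs(j - k) * np.cos((j - k) * q * d)
        brute /= n_planes
        np.testing.assert_allclose(
            paracrystal_sf(q, 43.0, 0.2, n_planes), brute, rtol=1e-10
        )

    def test_principal_maximum_near_bragg(self):
        # grid-search oracle: argmax within 5% of 2 pi / d100
        q = np.linspace(0.05, 0.3, 20001)
        s = paracrystal_sf(q, 43.0, 0.2, 4)
        q_star = q[np.argmax(s)]
        assert q_star == pytest.approx(2 * np.pi / (np.sqrt(3) / 2 * 43.0),
                                       rel=0.05)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a_cc=st.floats(25.0, 60.0),
        g=st.floats(0.0, 0.45),
        n=st.integers(1, 8),
        q=st.floats(1e-4, 0.5),
    )
    def test_structure_factor_nonnegative(self, a_cc, g, n, q):
        # S = <|sum exp(i q x_j)|^2> / N is an averaged modulus squared
        assert paracrystal_sf(np.array([q]), a_cc, g, n)[0] >= -1e-12


class TestBundleTerm:
    def test_maximum_at_zero_and_width_definition(self):
        assert bundle_term(0.0, 3.0, 0.02) == 3.0
        assert bundle_term(0.02, 3.0, 0.02) == pytest.approx(
            3.0 * np.exp(-0.5), rel=1e-12
        )

    def test_monotone_decreasing(self):
        q = np.linspace(1e-4, 0.3, 200)
        assert np.all(np.diff(bundle_term(q, 1.0, 0.0157)) < 0)


class TestBundleDiameter:
    def test_reference_width_gives_18nm(self):
        # 2*sqrt(2)/0.0157 A = 180.15 A = 18.0 nm, inside the 12-19 nm
        # native range
        d = bundle_diameter_from_sigma(0.0157)
        assert d == pytest.approx(18.0, abs=0.05)
        assert 12.0 < d < 19.0

    def test_inverse_proportionality(self):
        assert bundle_diameter_from_sigma(0.00785) == pytest.approx(
            2.0 * bundle_diameter_from_sigma(0.0157), rel=1e-12
        )

    @pytest.mark.parametrize("d_nm", [8.0, 13.0, 18.5])
    def test_roundtrip_through_exact_disc_intensity(self, d_nm):
        """Fitting the Gaussian to the exact oriented-disc cross-section
        intensity over q R_c < 1 recovers the diameter within 3%."""
        radius = d_nm * 10.0 / 2.0  # A
        r_c = radius / np.sqrt(2.0)
        q = np.linspace(1e-3, 1.0 / r_c, 60)
        intensity = cylinder_cs_amplitude(q * radius) ** 2
        # log-linear regression against the Gaussian form
        slope = np.polyfit(q**2, np.log(intensity), 1)[0]
        sigma_fit = np.sqrt(-1.0 / (2.0 * slope))
        d_rec = bundle_diameter_from_sigma(sigma_fit)
        assert d_rec == pytest.approx(d_nm, rel=0.03)

    def test_guinier_slope_consistency(self):
        # ln I vs q^2 of the exact disc intensity is linear with slope
        # -R_c^2/2 in the window q R_c < 1
        radius = 90.0
        r_c = radius / np.sqrt(2.0)
        q = np.linspace(1e-4, 0.8 / r_c, 50)
        y = np.log(cylinder_cs_amplitude(q * radius) ** 2)
        slope, _ = np.polyfit(q**2, y, 1)
        assert slope == pytest.approx(-r_c**2 / 2.0, rel=0.05)

    def test_spherical_convention_and_errors(self):
        assert bundle_diameter_from_sigma(0.0157, "spherical") > \
            bundle_diameter_from_sigma(0.0157, "cross_section")
        with pytest.raises(ValueError):
            bundle_diameter_from_sigma(0.0)
        with pytest.raises(ValueError):
            bundle_diameter_from_sigma(0.01, "cubic")


class TestTotalIntensity:
    def test_background_only(self):
        p = WoodModelParams(A_mf=0.0, A_b=0.0, B_pl=0.0, C_bg=0.7)
        q = np.geomspace(0.002, 0.3, 40)
        np.testing.assert_allclose(total_intensity(q, p), 0.7)

    def test_pure_power_law_slope(self):
        p = WoodModelParams(A_mf=0.0, A_b=0.0, B_pl=1e-7, C_bg=0.0,
                            alpha=4.0)
        q = np.geomspace(0.01, 0.1, 60)
        slope = np.polyfit(np.log(q), np.log(total_intensity(q, p)), 1)[0]
        assert slope == pytest.approx(-4.0, abs=1e-3)

    def test_terms_sum_to_total_and_are_nonnegative(self):
        p = WoodModelParams()
        q = np.geomspace(0.002, 0.3, 80)
        terms = intensity_terms(q, p)
        np.testing.assert_allclose(
            sum(terms.values()), total_intensity(q, p), rtol=1e-14
        )
        for name, curve in terms.items():
            assert np.all(curve >= 0), name

    def test_linearity_in_amplitudes(self):
        q = np.geomspace(0.002, 0.3, 40)
        p = WoodModelParams(C_bg=0.02)
        p2 = p.replace(A_mf=3 * p.A_mf, A_b=3 * p.A_b, B_pl=3 * p.B_pl,
                       C_bg=3 * p.C_bg)
        np.testing.assert_allclose(
            total_intensity(q, p2), 3 * total_intensity(q, p), rtol=1e-12
        )

    def test_bundle_dominates_low_q_window(self):
        """With default parameters the bundle Gaussian carries > 50% of
        the non-background, non-power-law intensity over 0.01-0.05 A^-1."""
        p = WoodModelParams()
        q = np.geomspace(0.01, 0.05, 100)
        terms = intensity_terms(q, p)
        frac = terms["bundles"] / (terms["bundles"] + terms["microfibrils"])
        assert frac.min() > 0.5

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            WoodModelParams(sigma_b=-0.01)
        with pytest.raises(ValueError):
            WoodModelParams(g_distortion=0.6)
        with pytest.raises(ValueError):
            WoodModelParams(alpha=2.0)
        with pytest.raises(ValueError):
            total_intensity(np.array([-0.01]), WoodModelParams())


class TestPeakPosition:
    def test_bragg_limit(self):
        p = WoodModelParams(g_distortion=0.01, N_planes=8, R_sd=0.0)
        assert peak_position(p) == pytest.approx(2 * np.pi / p.d100,
                                                 rel=0.01)

    def test_monotone_in_spacing(self):
        peaks = [
            peak_position(WoodModelParams(a_cc=a)) for a in (32.0, 38.0, 43.0)
        ]
        assert peaks[0] > peaks[1] > peaks[2]

    @pytest.mark.parametrize("a_cc", [32.0, 43.0])
    def test_near_bragg_at_moderate_disorder(self, a_cc):
        # form-factor modulation shifts the peak a few percent below the
        # ideal lattice position at moderate disorder
        p = WoodModelParams(a_cc=a_cc, g_distortion=0.1, N_planes=6)
        assert peak_position(p) == pytest.approx(2 * np.pi / p.d100, rel=0.10)
        assert 0.1 < peak_position(WoodModelParams(a_cc=a_cc)) < 0.25

    def test_boundary_warning_without_interference(self):
        p = WoodModelParams(N_planes=1)
        with pytest.warns(UserWarning, match="no interior maximum"):
            peak_position(p)


def test_params_serialization_roundtrip():
    p = WoodModelParams(a_cc=38.5, sigma_b=0.021)
    assert WoodModelParams.from_dict(p.to_dict()) == p
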