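"""Reduction of 2D frames: q-mapping, sector separation, merge, rebin."""

import numpy as np
import pytest

from fibrilsans import (
    DetectorFrame,
    Geometry,
    Profile1D,
    SectorSpec,
    azimuthal_profile,
    build_qmap,
    merge_profiles,
    rebin_log,
    separate_anisotropic,
)
from fibrilsans.synthetic import (
    SyntheticSpec,
    _expected_counts,
    expected_reduced_profile,
    generate_frames,
)
from tests.conftest import FLAGSHIP_TRUTH


GEO = Geometry(wavelength=6.0, sdd=8000.0, beam_center=(63.5, 63.5),
               pixel_size=7.5)


class TestQMap:
    def test_beam_center_pixel(self):
        geo = Geometry(wavelength=6.0, sdd=8000.0, beam_center=(10, 20),
                       pixel_size=7.5)
        q, _ = build_qmap(geo, (32, 32))
        assert q[10, 20] == 0.0

    def test_two_degree_scattering_angle(self):
        # pixel exactly at 2theta = 2 deg: q = 4 pi sin(1 deg) / 6.0
        sdd = 8000.0
        r = sdd * np.tan(np.radians(2.0))
        geo = Geometry(wavelength=6.0, sdd=sdd, beam_center=(0, 0),
                       pixel_size=r)
        q, _ = build_qmap(geo, (1, 2))  # pixel (0,1) sits at distance r
        assert q[0, 1] == pytest.approx(
            4 * np.pi * np.sin(np.radians(1.0)) / 6.0, rel=1e-12
        )
        assert q[0, 1] == pytest.approx(0.03656, abs=2e-5)

    def test_radial_symmetry(self):
        q, _ = build_qmap(GEO, (128, 128))
        # pixels mirrored through the beam center share q exactly
        np.testing.assert_array_equal(q, q[::-1, ::-1])

    def test_q_decreases_with_sdd(self):
        q1, _ = build_qmap(GEO, (128, 128))
        geo2 = Geometry(wavelength=6.0, sdd=16000.0,
                        beam_center=(63.5, 63.5), pixel_size=7.5)
        q2, _ = build_qmap(geo2, (128, 128))
        assert np.all(q2 <= q1)

    def test_azimuth_convention(self):
        _, az = build_qmap(GEO, (128, 128))
        # along the row through the beam center: equator, azimuth ~ 0
        assert az[63, 100] == pytest.approx(0.0, abs=1.0)
        # along the column: meridian, azimuth ~ 90
        assert az[10, 63] == pytest.approx(90.0, abs=1.0)
        assert np.all((az >= 0) & (az < 180))


def _isotropic_frame(level=50.0, seed=0, shape=(128, 128)):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(level, shape).astype(float)
    return DetectorFrame(counts=counts, exposure=1.0, geometry=GEO)


class TestAzimuthalProfile:
    def test_isotropic_frame_is_flat(self):
        prof = azimuthal_profile(_isotropic_frame(), (0.01, 0.02))
        ok = ~prof["gap"]
        z = (prof["I"][ok] - 50.0) / prof["sigma"][ok]
        assert np.all(np.abs(z) < 4.0)

    def test_streak_frame_peaks_at_equator(self, flagship_frames):
        frames, _ = flagship_frames
        # at the packing peak the equatorial streak dominates
        prof = azimuthal_profile(frames[0], (0.14, 0.18), n_azimuth_bins=18)
        ok = ~prof["gap"]
        centers = prof["azimuth"][ok]
        best = centers[np.argmax(prof["I"][ok])]
        # maximum azimuth bin lies on the equator (0/180 wrap)
        assert min(best, 180.0 - best) < 15.0

    def test_fully_masked_bin_flags_gap(self):
        frame = _isotropic_frame()
        frame.mask[:] = True
        frame.mask[0, 0] = False  # keep frame usable
        with pytest.raises(ValueError):
            azimuthal_profile(frame, (0.5, 0.6))

    def test_bad_q_bin(self):
        with pytest.raises(ValueError):
            azimuthal_profile(_isotropic_frame(), (0.02, 0.01))


class TestSectorSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            SectorSpec(half_width_equator=0.0)
        with pytest.raises(ValueError):
            SectorSpec(half_width_equator=95.0)
        with pytest.raises(ValueError):
            # reference band touching the equator band
            SectorSpec(half_width_equator=30.0,
                       reference_azimuth_band=(20.0, 120.0))

    def test_band_membership(self):
        s = SectorSpec()
        az = np.array([0.0, 10.0, 20.0, 90.0, 170.0, 179.0])
        np.testing.assert_array_equal(
            s.in_equator(az), [True, True, False, False, True, True]
        )
        np.testing.assert_array_equal(
            s.in_reference(az), [False, False, False, True, False, False]
        )


class TestSeparateAnisotropic:
    def test_isotropic_frame_consistent_with_zero(self):
        prof = separate_anisotropic(_isotropic_frame(level=80.0, seed=5))
        frac = np.mean(np.abs(prof.I) < 3.0 * prof.sigma)
        assert frac >= 0.99

    def test_recovers_known_anisotropy_within_counting_noise(
        self, flagship_spec, flagship_frames
    ):
        """chi^2 per point against the exact expectation (reduction of
        the noise-free expected-counts map) must be ~1."""
        frames, _ = flagship_frames
        for i, frame in enumerate(frames):
            expected = expected_reduced_profile(flagship_spec, i)
            observed = separate_anisotropic(frame)
            np.testing.assert_allclose(observed.q, expected.q)
            chi2 = np.mean(((observed.I - expected.I) / observed.sigma) ** 2)
            assert 0.5 < chi2 < 2.0, f"frame {i}: chi2/point = {chi2}"

    def test_meridional_streak_leaves_equator_band_isotropic(
        self, flagship_spec
    ):
        """Rotating the streak onto the meridian: the equator band then
        sees only the isotropic level (orthogonality of the numerator);
        the subtracted reference band, which now contains the streak,
        drives the output strongly negative."""
        geometry = flagship_spec.geometries[1]
        expected, mask = _expected_counts(flagship_spec, geometry)
        rotated = DetectorFrame(
            counts=expected.T.copy(), exposure=1.0, geometry=geometry,
            mask=mask.T.copy(),
        )
        prof = separate_anisotropic(rotated)
        iso = flagship_spec.counts_scale * flagship_spec.isotropic_flat
        q, az = build_qmap(geometry, rotated.counts.shape)
        from fibrilsans.frames import solid_angle_weight

        sectors = SectorSpec()
        in_eq = sectors.in_equator(az) & ~rotated.mask
        w = solid_angle_weight(geometry, rotated.counts.shape)
        mid = (q > 0.01) & (q < 0.05)
        eq_level = np.mean((rotated.counts / w)[in_eq & mid])
        assert eq_level == pytest.approx(iso, rel=0.02)
        assert np.median(prof.I[(prof.q > 0.01) & (prof.q < 0.05)]) < 0

    def test_linearity_in_counts(self, flagship_spec):
        geometry = flagship_spec.geometries[1]
        expected, mask = _expected_counts(flagship_spec, geometry)
        f1 = DetectorFrame(counts=expected, exposure=1.0,
                           geometry=geometry, mask=mask)
        f3 = DetectorFrame(counts=3.0 * expected, exposure=1.0,
                           geometry=geometry, mask=mask)
        p1, p3 = separate_anisotropic(f1), separate_anisotropic(f3)
        np.testing.assert_allclose(p3.I, 3.0 * p1.I, rtol=1e-12)


def _power_law_profile(n=200, seed=0, q_lo=0.01, q_hi=0.3, scale=1.0):
    rng = np.random.default_rng(seed)
    q = np.geomspace(q_lo, q_hi, n)
    i_true = scale * 1e-6 * q**-4.0
    sigma = 0.01 * i_true
    return Profile1D(q=q, I=i_true + sigma * rng.standard_normal(n),
                     sigma=sigma)


class TestMerge:
    def test_single_profile_identity_up_to_rebinning(self):
        p = _power_law_profile()
        merged = merge_profiles([p], bins_per_decade=1000)
        np.testing.assert_allclose(merged.I, p.I)
        assert merged.meta["scale_factors"] == [1.0]

    def test_identical_copies_scale_unity(self):
        p = _power_law_profile()
        merged = merge_profiles([p, p])
        assert merged.meta["scale_factors"][1] == pytest.approx(1.0,
                                                                rel=1e-6)

    def test_rescaled_copy_recovered_within_one_percent(self):
        p1 = _power_law_profile(seed=1)
        p2 = _power_law_profile(seed=2, scale=2.5)
        merged = merge_profiles([p1, p2], scale_reference=0)
        # profile2 = 2.5 x profile1, so it is scaled back by 1/2.5
        assert merged.meta["scale_factors"][1] * 2.5 == pytest.approx(
            1.0, rel=0.01
        )

    def test_disjoint_ranges_raise(self):
        p1 = _power_law_profile(q_lo=0.001, q_hi=0.01)
        p2 = _power_law_profile(q_lo=0.1, q_hi=0.3)
        with pytest.raises(ValueError, match="overlap"):
            merge_profiles([p1, p2])


class TestRebinLog:
    def test_constant_profile_invariant(self):
        q = np.geomspace(0.01, 0.1, 300)
        p = Profile1D(q=q, I=np.full_like(q, 5.0),
                      sigma=np.full_like(q, 0.1))
        out = rebin_log(p, 20)
        np.testing.assert_allclose(out.I, 5.0)

    def test_power_law_slope_preserved(self):
        p = _power_law_profile(n=600, seed=3)
        out = rebin_log(p, 40)
        slope = np.polyfit(np.log(out.q), np.log(out.I), 1)[0]
        assert slope == pytest.approx(-4.0, abs=0.02)

    def test_sparse_input_returned_unchanged(self):
        q = np.geomspace(0.01, 0.1, 10)
        p = Profile1D(q=q, I=q**-1, sigma=0.01 * q**-1)
        out = rebin_log(p, 1000)
        np.testing.assert_allclose(out.q, p.q)
        np.testing.assert_allclose(out.I, p.I)

    def test_noise_free_sigma_zero_supported(self):
        q = np.geomspace(0.01, 0.1, 100)
        p = Profile1D(q=q, I=q**-2, sigma=np.zeros_like(q))
        out = rebin_log(p, 10)
        assert np.all(out.sigma == 0)
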