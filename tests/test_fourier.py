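"""Wedge masks, band-pass filtering and Fourier shell correlation."""

import numpy as np
import pytest
import scipy.fft as sf
from hypothesis import given, settings
from hypothesis import strategies as st

from stakit.fourier import (
    FSCCurve,
    ResolutionError,
    WedgeRangeError,
    apply_wedge,
    bandpass,
    build_wedge_mask,
    fsc_curve,
    full_wedge,
    radial_frequency_grid,
    resolution_at_threshold,
)
from stakit.volume import DensityVolume, VolumeError


def noise_volume(n, seed, voxel=1.0):
    return DensityVolume(np.random.default_rng(seed).normal(size=(n,) * 3), voxel)


class TestWedgeMask:
    @pytest.mark.parametrize(
        "box,half_range,expected",
        [(32, 60.0, 2 / 3), (32, 90.0, 1.0), (64, 45.0, 0.5), (48, 60.0, 2 / 3)],
    )
    def test_retained_fraction_matches_analytic(self, box, half_range, expected):
        wedge = build_wedge_mask(box, -half_range, half_range, softness=0.0)
        assert wedge.retained_fraction == pytest.approx(expected, abs=0.02)

    def test_retained_fraction_against_voxel_count_oracle(self):
        """Independent oracle: count voxels whose in-plane (kx, kz) angle
        from the x axis is ≤ 45°, inside the Nyquist ball, boundary voxels
        at half weight."""
        box = 64
        f = np.fft.fftfreq(box)
        fx, fy, fz = np.meshgrid(f, f, f, indexing="ij")
        ang = np.degrees(np.arctan2(np.abs(fz), np.abs(fx)))
        weight = np.where(np.isclose(ang, 45.0), 0.5, (ang < 45.0).astype(float))
        weight[(fx == 0) & (fz == 0)] = 1.0
        ball = np.sqrt(fx**2 + fy**2 + fz**2) <= 0.5
        expected = weight[ball].mean()
        wedge = build_wedge_mask(box, -45.0, 45.0, softness=0.0)
        assert wedge.retained_fraction == pytest.approx(expected, abs=1e-6)

    def test_mask_is_hermitian(self):
        m = build_wedge_mask(16, -60, 60, softness=1.0).mask
        flipped = m[
            np.ix_(*[np.r_[0, np.arange(15, 0, -1)] for _ in range(3)])
        ]  # index -k
        assert np.allclose(m, flipped, atol=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(WedgeRangeError):
            build_wedge_mask(16, -95.0, 60.0)
        with pytest.raises(WedgeRangeError):
            build_wedge_mask(16, 30.0, 30.0)


class TestApplyWedge:
    def test_full_mask_is_identity(self):
        v = noise_volume(16, 0)
        out = apply_wedge(v, full_wedge(16))
        assert np.allclose(out.data, v.data, atol=1e-5)

    def test_hard_mask_idempotent(self):
        v = noise_volume(32, 1)
        w = build_wedge_mask(32, -60, 60, softness=0.0)
        once = apply_wedge(v, w)
        twice = apply_wedge(once, w)
        assert np.allclose(twice.data, once.data, atol=1e-5)

    def test_impulse_psf_spectrum_equals_mask(self):
        n = 32
        data = np.zeros((n,) * 3)
        data[n // 2, n // 2, n // 2] = 1.0
        w = build_wedge_mask(n, -60, 60, softness=0.0)
        psf = apply_wedge(DensityVolume(data, 1.0), w)
        spec = np.abs(sf.fftn(psf.data.astype(float)))
        assert np.allclose(spec, w.mask, atol=1e-6)

    def test_box_mismatch_rejected(self):
        with pytest.raises(VolumeError):
            apply_wedge(noise_volume(16, 0), build_wedge_mask(32, -60, 60))


class TestBandpass:
    def test_near_nyquist_lowpass_keeps_power(self, scene32):
        out = bandpass(scene32, None, 2 * 5.4)
        assert np.var(out.data) >= 0.99 * np.var(scene32.data)

    def test_out_of_band_tone_suppressed(self):
        n, voxel = 64, 5.4
        z = np.arange(n) * voxel
        tone = np.broadcast_to(np.sin(2 * np.pi * z / 20.0), (n, n, n)).copy()
        out = bandpass(DensityVolume(tone, voxel), None, 36.0)
        assert np.var(out.data) < 0.01 * np.var(tone)

    def test_noise_power_fraction_matches_voxel_count(self):
        """Parseval oracle: retained white-noise power equals the fraction
        of Fourier voxels inside the band."""
        v = noise_volume(64, 3, voxel=5.4)
        out = bandpass(v, None, 22.0)
        frac_power = np.var(out.data) / np.var(v.data)
        frac_voxels = float((radial_frequency_grid(64, 5.4) <= 1 / 22.0).mean())
        assert frac_power == pytest.approx(frac_voxels, abs=0.02)

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ResolutionError):
            bandpass(noise_volume(16, 0, voxel=5.4), None, 5.0)
        with pytest.raises(ResolutionError):
            bandpass(noise_volume(16, 0, voxel=5.4), 20.0, 30.0)

    @given(st.integers(0, 2**31 - 1), st.floats(12.0, 40.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_never_increases_total_power(self, seed, high_res):
        v = noise_volume(24, seed, voxel=5.4)
        out = bandpass(v, None, high_res)
        p_in = float(np.sum(np.abs(sf.fftn(v.data.astype(float))) ** 2))
        p_out = float(np.sum(np.abs(sf.fftn(out.data.astype(float))) ** 2))
        assert p_out <= p_in * (1 + 1e-9)


class TestFSC:
    def test_self_correlation_is_one(self, scene32):
        curve = fsc_curve(scene32, scene32)
        assert np.all(curve.correlations[curve.n_voxels_per_shell > 0] > 0.999999)

    def test_negated_volume_gives_minus_one(self, scene32):
        curve = fsc_curve(scene32, scene32.with_data(-scene32.data))
        assert np.all(curve.correlations[curve.n_voxels_per_shell > 0] < -0.999999)

    def test_symmetric_and_bounded(self):
        a, b = noise_volume(32, 4), noise_volume(32, 5)
        cab, cba = fsc_curve(a, b), fsc_curve(b, a)
        assert np.allclose(cab.correlations, cba.correlations, atol=1e-12)
        assert np.all(np.abs(cab.correlations) <= 1.0)

    def test_frequencies_strictly_increasing_to_nyquist(self):
        v = noise_volume(32, 6, voxel=2.0)
        c = fsc_curve(v, v)
        assert np.all(np.diff(c.shell_frequencies) > 0)
        assert c.shell_frequencies[-1] == pytest.approx(1 / (2 * 2.0), rel=1e-9)

    def test_independent_noise_decorrelates(self):
        """|FSC| between independent noise stays within the 3/√n envelope in
        at least 95% of shells (20 seed pairs here; the full 100-pair check
        runs in the acceptance suite)."""
        hits = total = 0
        for seed in range(20):
            a, b = noise_volume(64, 1000 + seed), noise_volume(64, 2000 + seed)
            c = fsc_curve(a, b)
            bound = 3.0 / np.sqrt(np.maximum(c.n_voxels_per_shell, 1))
            hits += int(np.sum(np.abs(c.correlations) <= bound))
            total += len(c.correlations)
        assert hits / total >= 0.95


class TestResolutionAtThreshold:
    def test_perfect_curve_reports_nyquist(self):
        curve = FSCCurve(np.linspace(0.01, 0.1, 10), np.ones(10), np.ones(10))
        assert resolution_at_threshold(curve, 0.143, voxel_size=5.0) == 10.0

    def test_linear_interpolation_between_shells(self):
        """Step from 1 to 0 between 1/40 and 1/30 Å⁻¹: the 0.143 crossing
        interpolates to f = f1 + (1-0.143)·(f2-f1)."""
        f = np.array([1 / 40.0, 1 / 30.0])
        curve = FSCCurve(f, np.array([1.0, 0.0]), np.array([10, 10]))
        expected = 1.0 / (f[0] + (1.0 - 0.143) * (f[1] - f[0]))
        res = resolution_at_threshold(curve, 0.143)
        assert res == pytest.approx(expected, rel=1e-12)
        assert 30.0 < res < 40.0

    def test_all_zero_curve_warns_and_reports_first_shell(self):
        curve = FSCCurve(np.array([0.01, 0.02]), np.zeros(2), np.ones(2))
        with pytest.warns(UserWarning):
            res = resolution_at_threshold(curve, 0.143)
        assert res == pytest.approx(100.0)
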