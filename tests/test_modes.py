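"""Eigenvolume mode decomposition, half-maps and spatial statistics."""

import numpy as np
import pytest

from stakit import phantom as ph
from stakit.modes import (
    EigenvolumeAnalysis,
    ModeAnalysisError,
    align_class_averages,
    mode_halfmaps,
    mode_spatial_correlation,
)
from stakit.volume import DensityVolume, EulerTriplet, rotate_shift

from .conftest import correlation


@pytest.fixture(scope="module")
def mode_basis():
    """Base scene plus two orthonormal deformation fields and an
    amplitude (trivial) direction, mutually orthogonalised."""
    spec = ph.PhantomSpec.scaled(32)
    base = ph.make_scene(spec).data.astype(np.float64)
    va = ph.make_scene(ph.ClassDeformation("a", slab_scale=0.85).apply(spec)).data - base
    vb = ph.make_scene(ph.ClassDeformation("b", height_scale=1.3).apply(spec)).data - base

    def orth(v, *others):
        v = v.astype(np.float64)
        for o in others:
            v = v - (v.ravel() @ o.ravel()) / (o.ravel() @ o.ravel()) * o
        return v / np.linalg.norm(v)

    va_n = orth(va)
    vb_n = orth(vb, va_n)
    triv = orth(base.copy(), va_n, vb_n)
    return spec, base, triv, va_n, vb_n


def build_set(mode_basis, k=36, sd_trivial=6.0, sd_a=3.0, sd_b=1.8, seed=5):
    spec, base, triv, va_n, vb_n = mode_basis
    rng = np.random.default_rng(seed)
    s = sd_trivial * rng.normal(size=k)
    a = sd_a * rng.normal(size=k)
    b = sd_b * rng.normal(size=k)
    vols = [
        DensityVolume(base + s[i] * triv + a[i] * va_n + b[i] * vb_n, spec.voxel_size)
        for i in range(k)
    ]
    return vols, s, a, b


class TestAlignClassAverages:
    def test_identical_volumes_need_no_updates(self, scene32):
        aligned, mean, records = align_class_averages([scene32] * 4, rounds=2)
        for rec in records:
            assert rec.pose.geodesic_to(EulerTriplet(), c4=True) < 1e-6
            assert np.all(rec.shift == 0)
        assert correlation(mean, scene32) > 0.9999

    def test_planted_shift_recovered(self, scene32):
        shifted = rotate_shift(scene32, EulerTriplet(), (2 * 5.4, 0, 0))
        aligned, _, records = align_class_averages(
            [scene32, scene32, shifted, scene32], rounds=4
        )
        assert abs(records[2].shift[0] - (-2 * 5.4)) <= 0.5 * 5.4 or abs(
            records[2].shift[0] - 2 * 5.4
        ) <= 0.5 * 5.4
        assert correlation(aligned[2], scene32) > 0.98

    def test_mean_invariant_to_input_order(self, mode_basis):
        vols, *_ = build_set(mode_basis, k=5)
        _, mean_fwd, _ = align_class_averages(vols, rounds=2)
        _, mean_rev, _ = align_class_averages(vols[::-1], rounds=2)
        assert correlation(mean_fwd, mean_rev) > 0.9999

    def test_needs_three_volumes(self, scene32):
        with pytest.raises(ModeAnalysisError):
            align_class_averages([scene32, scene32])


class TestEigenvolumeDecomposition:
    def test_trivial_component_tracks_amplitude_and_is_dropped(self, mode_basis):
        vols, s, a, b = build_set(mode_basis)
        dec = EigenvolumeAnalysis(vols).fit()
        assert dec.dropped_trivial
        # the dropped component carries the planted amplitude variation
        assert abs(np.corrcoef(dec._trivial_coeffs, s)[0, 1]) > 0.98
        assert abs(correlation(dec.eigenvolumes[0].data, mode_basis[3])) > 0.90

    def test_amplitude_only_variation_flagged_as_trivial(self, mode_basis):
        spec, base, *_ = mode_basis
        rng = np.random.default_rng(3)
        vols = [
            DensityVolume((1 + 0.1 * rng.normal()) * base, spec.voxel_size)
            for _ in range(8)
        ]
        dec = EigenvolumeAnalysis(vols).fit()
        assert abs(dec.trivial_amplitude_corr) > 0.99

    def test_informativity_matches_planted_variance_ratio(self, mode_basis):
        vols, s, a, b = build_set(mode_basis)
        dec = EigenvolumeAnalysis(vols).fit()
        expected = np.var(b) / np.var(a)
        assert dec.informativity[0] == pytest.approx(1.0)
        assert dec.informativity[1] == pytest.approx(expected, rel=0.10)
        assert np.all(np.diff(dec.informativity) <= 1e-12)
        assert np.all(dec.eigenvalues >= 0)

    def test_reconstruction_reproduces_inputs(self, mode_basis):
        vols, *_ = build_set(mode_basis, k=8)
        dec = EigenvolumeAnalysis(vols).fit()
        for i in (0, 3, 7):
            rel = np.abs(dec.reconstruct(i).data - vols[i].data).max() / np.abs(
                vols[i].data
            ).max()
            assert rel < 1e-4

    def test_identical_inputs_give_empty_mode_list(self, scene32):
        dec = EigenvolumeAnalysis([scene32] * 5).fit()
        assert dec.n_modes == 0
        assert len(dec.informativity) == 0

    def test_coefficient_columns_orthogonal(self, mode_basis):
        vols, *_ = build_set(mode_basis, k=12)
        dec = EigenvolumeAnalysis(vols).fit()
        c = dec.eigencoefficients
        gram = c.T @ c
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-6 * np.diag(gram).max()


class TestModeHalfmaps:
    def test_partition_into_equal_groups_and_sign_symmetry(self, mode_basis):
        vols, s, a, b = build_set(mode_basis, k=10)
        dec = EigenvolumeAnalysis(vols).fit()
        lo, hi = mode_halfmaps(dec, 1)
        # flipping the eigenvector sign swaps the maps exactly
        dec.eigencoefficients[:, 0] *= -1
        dec.eigenvolumes[0] = dec.eigenvolumes[0].with_data(-dec.eigenvolumes[0].data)
        lo2, hi2 = mode_halfmaps(dec, 1)
        assert np.allclose(lo.data, hi2.data, atol=1e-5)
        assert np.allclose(hi.data, lo2.data, atol=1e-5)

    def test_odd_count_excludes_median_volume(self, mode_basis):
        vols, *_ = build_set(mode_basis, k=9)
        dec = EigenvolumeAnalysis(vols).fit()
        lo, hi = mode_halfmaps(dec, 1)
        order = np.argsort(dec.eigencoefficients[:, 0])
        manual_lo = np.mean([dec.reconstruct(i).data for i in order[:4]], axis=0)
        assert np.allclose(lo.data, manual_lo, atol=1e-5)

    def test_identical_volumes_give_equal_halfmaps(self, mode_basis):
        vols, s, a, b = build_set(mode_basis, sd_b=0.0)
        dec = EigenvolumeAnalysis(vols).fit()
        if dec.n_modes >= 2:
            lo, hi = mode_halfmaps(dec, 2)
            # mode 2 carries (numerically) no variance: halves nearly equal
            assert correlation(lo, hi) > 0.999

    def test_difference_power_concentrates_in_deformed_region(self, mode_basis):
        vols, *_ = build_set(mode_basis)
        spec = mode_basis[0]
        dec = EigenvolumeAnalysis(vols).fit()
        lo, hi = mode_halfmaps(dec, 1)
        diff = hi.data - lo.data
        mask = ph.deformation_mask(
            spec, ph.ClassDeformation("base"), ph.ClassDeformation("a", slab_scale=0.85)
        )
        assert (diff[mask] ** 2).sum() / (diff**2).sum() >= 0.70


class TestSpatialCorrelation:
    def test_random_coefficients_not_flagged(self):
        rng = np.random.default_rng(11)
        r = mode_spatial_correlation(
            rng.normal(size=50), rng.uniform(0, 1000, (50, 3)), seed=2
        )
        assert r.p_value > 0.01
        assert not r.degenerate

    def test_two_spatial_blocks_detected(self):
        rng = np.random.default_rng(12)
        pos = np.vstack([rng.uniform(0, 100, (25, 3)), rng.uniform(900, 1000, (25, 3))])
        coeff = np.r_[np.ones(25), -np.ones(25)] + 0.05 * rng.normal(size=50)
        r = mode_spatial_correlation(coeff, pos, seed=2)
        assert r.p_value < 0.01

    def test_constant_coefficients_degenerate(self):
        rng = np.random.default_rng(13)
        r = mode_spatial_correlation(np.ones(30), rng.uniform(0, 100, (30, 3)))
        assert r.degenerate

    def test_too_few_particles_rejected(self):
        with pytest.raises(ModeAnalysisError):
            mode_spatial_correlation(np.arange(5), np.zeros((5, 3)))

    def test_permutation_null_calibrated(self):
        """Under the null (randomly permuted labels) the one-sided p-value
        should exceed 5% in ≥ 90% of seeded trials."""
        rng = np.random.default_rng(21)
        pos = rng.uniform(0, 500, (40, 3))
        base = rng.normal(size=40)
        hits = 0
        trials = 30
        for t in range(trials):
            coeff = rng.permutation(base)
            r = mode_spatial_correlation(
                coeff, pos, n_permutations=199, seed=1000 + t
            )
            hits += int(r.p_value > 0.05)
        assert hits / trials >= 0.90
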