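"""Constrained correlation, alignment and wedge-compensated averaging."""

import numpy as np
import pytest

from stakit import phantom as ph
from stakit.align import (
    AlignmentConfig,
    AlignmentError,
    SubtomogramAlignment,
    align_particle,
    align_set,
    constrained_cc,
    weighted_average,
)
from stakit.fourier import apply_wedge, bandpass_mask, radial_frequency_grid
from stakit.particles import ParticleRecord, ParticleSet
from stakit.volume import EulerTriplet, unrotate_unshift

from .conftest import correlation, truth_particleset


class TestConstrainedCC:
    def test_self_and_negated(self, scene32):
        assert constrained_cc(scene32, scene32) == pytest.approx(1.0, abs=1e-9)
        neg = scene32.with_data(-scene32.data)
        assert constrained_cc(scene32, neg) == pytest.approx(-1.0, abs=1e-9)

    def test_wedge_constrained_score_removes_wedge_bias(self, scene32, spec32):
        """A wedge-filtered copy correlates ~1 with the clean volume when
        the correlation is restricted to the sampled region, but clearly
        below 1 on the full grid."""
        from stakit.fourier import build_wedge_mask

        wedge = build_wedge_mask(32, -60.0, 60.0, softness=0.0)
        filtered = apply_wedge(scene32, wedge)
        constrained = constrained_cc(filtered, scene32, wedge)
        unconstrained = constrained_cc(filtered, scene32, None)
        assert constrained == pytest.approx(1.0, abs=1e-3)
        assert unconstrained < constrained - 0.005

    def test_constrained_cc_equals_masked_inner_product_oracle(self, scene32, spec32):
        """Brute-force oracle: the same masked normalised inner product
        computed on the full (non-rfft) Fourier grid."""
        import scipy.fft as sf

        from stakit.fourier import build_wedge_mask

        wedge = build_wedge_mask(32, -60.0, 60.0, softness=0.0)
        other = apply_wedge(scene32, wedge)
        got = constrained_cc(other, scene32, wedge, band_limit_a=22.0)
        m = wedge.mask * bandpass_mask(32, spec32.voxel_size, None, 22.0)
        m[0, 0, 0] = 0.0
        fa = sf.fftn(other.data - other.data.mean())
        fb = sf.fftn(scene32.data - scene32.data.mean())
        num = float(np.sum(m * (fa * np.conj(fb)).real))
        den = np.sqrt(np.sum(m * np.abs(fa) ** 2) * np.sum(m * np.abs(fb) ** 2))
        assert got == pytest.approx(num / den, abs=1e-6)

    def test_empty_overlap_rejected(self, scene32):
        from stakit.fourier import WedgeMask

        empty = WedgeMask(-60, 60, 32, 0.0, np.zeros((32,) * 3))
        with pytest.raises(AlignmentError):
            constrained_cc(scene32, scene32, empty)


class TestAlignParticle:
    CFG = AlignmentConfig(
        cone_range=16, cone_step=8, inplane_step=8, shift_limit_a=12.0
    )

    def test_reference_aligns_to_itself_at_identity(self, scene32):
        rec = align_particle(scene32, ParticleRecord(id=0), scene32, self.CFG)
        assert rec.pose.geodesic_to(EulerTriplet(), c4=True) < 1e-6
        assert np.all(rec.shift == 0)
        assert rec.cc == pytest.approx(1.0, abs=1e-6)

    def test_recovers_planted_poses_within_grid_step(self, ensemble32_highsnr):
        ens = ensemble32_highsnr
        aligned = align_set(
            ens.volumes,
            ens.working,
            ens.class_volumes[0],
            self.CFG,
            ens.wedge,
            ens.phantom_spec.tilt_scheme,
        )
        errs = [
            a.pose.geodesic_to(t.pose, c4=True) for a, t in zip(aligned, ens.truth)
        ]
        shift_errs = [
            np.linalg.norm(a.shift - t.shift) for a, t in zip(aligned, ens.truth)
        ]
        assert np.median(errs) < 8.0
        assert np.median(shift_errs) < ens.phantom_spec.voxel_size

    def test_c4_poses_reported_in_canonical_sector(self, scene32):
        rotated, _ = ph.render_particle(
            scene32, EulerTriplet(tdrot=200.0), (0, 0, 0), None, None, None, 0
        )
        rec = align_particle(rotated, ParticleRecord(id=0), scene32, self.CFG)
        # tilt ~ 0: the two z angles merge and fold into [0, 90)
        assert 0.0 <= (rec.pose.tdrot + rec.pose.narot) % 360.0 < 90.0

    def test_shift_on_search_boundary_flagged(self, scene32):
        shifted, _ = ph.render_particle(
            scene32, EulerTriplet(), (30.0, 0, 0), None, None, None, 0
        )
        cfg = AlignmentConfig(
            cone_range=0, cone_step=8, inplane_range=0.0, inplane_step=8,
            shift_limit_a=12.0, local_refine=False,
        )
        rec = align_particle(shifted, ParticleRecord(id=0), scene32, cfg)
        assert rec.shift_on_boundary


class TestWeightedAverage:
    CFG = AlignmentConfig(symmetry_c4=False)

    def test_identical_copies_reproduce_the_particle(self, scene32, spec32):
        wedge = spec32.tilt_scheme.wedge_mask(32, softness=0.0)
        vol, _ = ph.render_particle(
            scene32, EulerTriplet(), (0, 0, 0), wedge, None, None, 0
        )
        recs = ParticleSet([ParticleRecord(id=i, cc=0.8) for i in range(3)])
        avg = weighted_average([vol] * 3, recs, self.CFG, wedge)
        assert correlation(avg, vol) > 0.995

    def test_nonpositive_cc_particles_are_excluded(self, ensemble32):
        ens = ensemble32
        parts = truth_particleset(ens, cc=0.8)
        junk = ens.volumes[0].with_data(
            np.random.default_rng(0).normal(size=(32,) * 3)
        )
        a = weighted_average(
            ens.volumes[:10], parts.subset(range(10)), self.CFG, ens.wedge
        )
        b = weighted_average(
            ens.volumes[:10] + [junk],
            ParticleSet(parts.records[:10] + [ParticleRecord(id=99, cc=-0.2)]),
            self.CFG,
            ens.wedge,
        )
        assert np.allclose(a.data, b.data, atol=1e-6)

    def test_zero_total_weight_rejected(self, ensemble32):
        parts = truth_particleset(ensemble32, cc=0.0)
        with pytest.raises(AlignmentError):
            weighted_average(ensemble32.volumes, parts, self.CFG, ensemble32.wedge)

    def test_average_beats_singles_and_improves_with_n(self, ensemble32):
        """At SNR 0.5 the compensated average correlates with the planted
        truth better than any raw particle, monotonically in n."""
        ens = ensemble32
        gt = ens.class_volumes[0]
        parts = truth_particleset(ens, cc=0.8)
        singles = [
            correlation(unrotate_unshift(v, t.pose, t.shift), gt)
            for v, t in zip(ens.volumes[:10], ens.truth)
        ]
        corrs = []
        for n in (10, 30):
            avg = weighted_average(
                ens.volumes[:n],
                parts.subset(range(n)),
                self.CFG,
                ens.wedge,
                ens.phantom_spec.tilt_scheme,
            )
            corrs.append(correlation(avg, gt))
        assert corrs[0] > max(singles)
        assert corrs[1] > corrs[0]

    def test_wedge_union_coverage_for_complementary_wedges(self, scene32, spec32):
        """Two particles whose wedges cover complementary orientations give
        an average whose Fourier support is (approximately) the union."""
        import scipy.fft as sf

        wedge = spec32.tilt_scheme.wedge_mask(32, softness=0.0)
        poses = [EulerTriplet(), EulerTriplet(0.0, 90.0, 0.0)]
        vols, recs = [], []
        for i, pose in enumerate(poses):
            v, _ = ph.render_particle(scene32, pose, (0, 0, 0), wedge, None, None, 0)
            vols.append(v)
            recs.append(ParticleRecord(id=i, pose=pose, cc=0.9))
        avg = weighted_average(vols, ParticleSet(recs), self.CFG, wedge)
        spec_power = np.abs(sf.fftn(avg.data.astype(float))) ** 2
        from stakit.align import _rotate_fourier_mask

        union = np.maximum(
            _rotate_fourier_mask(wedge.mask, poses[0].matrix()),
            _rotate_fourier_mask(wedge.mask, poses[1].matrix()),
        )
        ball = radial_frequency_grid(32, 1.0) <= 0.45
        outside = (union < 0.05) & ball
        inside = (union > 0.95) & ball
        assert spec_power[outside].sum() < 0.02 * spec_power[inside].sum()


class TestHalfsetBranchRule:
    def test_identical_noise_free_halves_reach_nyquist(self, scene32, spec32):
        wedge = spec32.tilt_scheme.wedge_mask(32)
        vol, _ = ph.render_particle(
            scene32, EulerTriplet(), (0, 0, 0), wedge, None, None, 0
        )
        parts = ParticleSet([ParticleRecord(id=i, cc=0.9) for i in range(4)])
        cfg = AlignmentConfig(
            cone_range=0, cone_step=4, inplane_range=0.0, inplane_step=4,
            shift_limit_a=6.0, iterations=1, local_refine=False,
        )
        model = SubtomogramAlignment(
            [vol] * 4, parts, reference=vol, wedge=wedge, config=cfg
        )
        res = model.fit("halfset")
        assert np.all(res.fsc.correlations > 0.999)
        assert res.resolution_a == pytest.approx(2 * spec32.voxel_size)

    def test_small_set_takes_band_limited_branch(self, ensemble32):
        ens = ensemble32
        cfg = AlignmentConfig(
            cone_range=4, cone_step=4, inplane_range=4.0, inplane_step=4,
            shift_limit_a=6.0, iterations=1, local_refine=False,
        )
        model = SubtomogramAlignment(
            ens.volumes,
            truth_particleset(ens, cc=0.5),
            reference=ens.class_volumes[0],
            wedge=ens.wedge,
            tilt_scheme=ens.phantom_spec.tilt_scheme,
            config=cfg,
        )
        res = model.fit("auto")
        assert res.branch == "single-36A"
        assert res.resolution_a == 36.0
        import scipy.fft as sf

        power = np.abs(sf.fftn(res.average.data.astype(float))) ** 2
        power[0, 0, 0] = 0.0
        beyond = radial_frequency_grid(32, ens.phantom_spec.voxel_size) > 1 / 36.0
        assert power[beyond].sum() < 0.01 * power.sum()
        assert "single-36A" in res.summary()


class TestEquivariance:
    def test_global_inplane_rotation_leaves_average_unchanged(self, ensemble32):
        """Composing every pose with one fixed in-plane rotation must leave
        the compensated average invariant within interpolation tolerance."""
        from stakit.volume import rotate_shift

        ens = ensemble32
        cfg = AlignmentConfig(symmetry_c4=False)
        parts = truth_particleset(ens, cc=0.8).subset(range(10))
        vols = ens.volumes[:10]
        avg0 = weighted_average(vols, parts, cfg, ens.wedge)
        fixed = EulerTriplet(20.0, 10.0, -15.0)
        # rotate(particle, fixed) = rotate_shift(gt, pose∘fixed, F·shift)
        rotated = ParticleSet(
            [
                ParticleRecord(
                    id=r.id,
                    pose=r.pose.then(fixed),
                    shift=fixed.matrix() @ r.shift,
                    cc=r.cc,
                )
                for r in parts
            ]
        )
        vols_rot = [rotate_shift(v, fixed) for v in vols]
        avg1 = weighted_average(vols_rot, rotated, cfg, ens.wedge)
        assert correlation(avg0, avg1) > 0.95
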