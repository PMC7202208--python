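"""Constrained alignment and weighted averaging of missing-wedge volumes.

The estimation problem: each subtomogram is an unknown rigid transform of a
common density, observed through a known Fourier wedge with dose-dependent
amplitude decay and noise.  Alignment maximises the *constrained*
cross-correlation — normalised only over Fourier voxels inside both the
particle's wedge and the band limit, which removes missing-wedge bias — over
a hierarchical angular grid (coarse cone + local refinement) and a
translation window.  Averaging compensates the anisotropic sampling by
accumulating per-voxel Fourier weights (rotated wedge × exposure profile ×
particle weight) and dividing the weighted Fourier sum by them; a particle's
weight is max(cc, 0), i.e. contribution proportional to its correlation to
the reference, with negative scorers excluded.

Refinement follows the half-set branch rule: datasets of more than 500
particles are refined as two fully independent halves whose FSC yields the
resolution; smaller sets are refined against a single reference and the
final map is restricted to 36 Å.

The :class:`SubtomogramAlignment` model / :class:`AlignmentResults` pair is
the object-oriented entry point; the module-level functions are the
primitive operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .fourier import (
    FSCCurve,
    WedgeMask,
    bandpass,
    bandpass_mask,
    fsc_curve,
    full_wedge,
    radial_frequency_grid,
    resolution_at_threshold,
)
from .particles import ParticleRecord, ParticleSet
from .phantom import TiltScheme
from .volume import (
    DensityVolume,
    EulerTriplet,
    rotate_shift,
    symmetrize_c4,
    unrotate_unshift,
)

logger = logging.getLogger(__name__)

SMALL_SET_MAX = 500  # half-set refinement requires more particles than this
SMALL_SET_BAND_A = 36.0  # band limit imposed on small-set reconstructions


class AlignmentError(RuntimeError):
    """Degenerate alignment input (empty mask overlap, zero total weight…)."""


@dataclass(frozen=True)
class AlignmentConfig:
    """Angular/translational search space and refinement policy.

    The angular grid is a cone of directions within ``cone_range`` degrees
    of the current pose's z axis sampled every ``cone_step`` degrees, crossed
    with in-plane rotations over ``inplane_range`` every ``inplane_step``.
    With C4 symmetry on, the in-plane range is quotiented to 90°.  A local
    half-step 3×3×3 refinement follows the coarse grid when
    ``local_refine`` is set.
    """

    cone_range: float = 16.0
    cone_step: float = 8.0
    inplane_range: float = 360.0
    inplane_step: float = 8.0
    shift_limit_a: float = 16.0
    band_limit_a: float | None = None  # low-pass (Å) for scoring & averaging
    symmetry_c4: bool = True
    iterations: int = 1
    local_refine: bool = True
    fsc_threshold: float = 0.143
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cone_step <= 0 or self.inplane_step <= 0:
            raise ValueError("angular steps must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def effective_inplane_range(self) -> float:
        return min(self.inplane_range, 90.0) if self.symmetry_c4 else self.inplane_range


def angular_grid(config: AlignmentConfig) -> list[EulerTriplet]:
    """Deterministic cone × in-plane rotation grid (delta rotations).

    The matrix composes as Rz(tdrot)·Rx(tilt)·Rz(narot): the rotated-z
    *direction* is set by (tdrot, tilt) — azimuth rings over the cone —
    while ``narot`` is the template-frame spin, the angle quotiented by C4.
    """
    directions: list[tuple[float, float]] = [(0.0, 0.0)]
    tilt = config.cone_step
    while tilt <= config.cone_range + 1e-9:
        n_ring = max(1, int(round(360.0 * np.sin(np.radians(tilt)) / config.cone_step)))
        for k in range(n_ring):
            directions.append((360.0 * k / n_ring, tilt))
        tilt += config.cone_step
    rng_ip = config.effective_inplane_range()
    if rng_ip >= 90.0 - 1e-9:
        # global search: cover the (possibly C4-quotiented) spin circle
        inplane = np.arange(0.0, rng_ip - 1e-9, config.inplane_step)
    else:
        # local search: symmetric spin offsets ± the configured half-range
        inplane = np.arange(-rng_ip, rng_ip + 1e-9, config.inplane_step)
    if len(inplane) == 0:
        inplane = np.array([0.0])
    return [
        EulerTriplet(float(td), float(ti), float(na))
        for td, ti in directions
        for na in inplane
    ]


def _local_grid(best: EulerTriplet, cone_step: float, inplane_step: float) -> list[EulerTriplet]:
    """Half-step 3x3x3 Euler neighbourhood around the best coarse rotation."""
    out = []
    for dtd in (-cone_step / 2, 0.0, cone_step / 2):
        for dti in (-cone_step / 2, 0.0, cone_step / 2):
            for dna in (-inplane_step / 2, 0.0, inplane_step / 2):
                out.append(
                    EulerTriplet(best.tdrot + dtd, best.tilt + dti, best.narot + dna)
                )
    return out


# ---------------------------------------------------------------------------
# Fourier bookkeeping on the rfft half-grid


class _Workspace:
    """Pre-sliced masks and weights on the rfft grid for one box/config."""

    def __init__(
        self,
        box: int,
        voxel_size: float,
        wedge: WedgeMask | None,
        band_limit_a: float | None,
        tilt_scheme: TiltScheme | None = None,
    ):
        self.box, self.voxel_size = box, voxel_size
        nz = box // 2 + 1
        self.wedge_full = wedge.mask if wedge is not None else np.ones((box, box, box))
        band_full = (
            bandpass_mask(box, voxel_size, None, band_limit_a)
            if band_limit_a is not None
            else np.ones((box, box, box))
        )
        self.mask_r = (self.wedge_full * band_full)[:, :, :nz].copy()
        self.mask_r[0, 0, 0] = 0.0  # exclude DC from correlation
        # multiplicity of each rfft voxel in the full-grid sum
        w = np.full((box, box, nz), 2.0)
        w[:, :, 0] = 1.0
        if box % 2 == 0:
            w[:, :, -1] = 1.0
        self.rmult = w
        if tilt_scheme is not None:
            freq_r = radial_frequency_grid(box, voxel_size)[:, :, :nz]
            self.dose_r = tilt_scheme.exposure_profile(freq_r)
        else:
            self.dose_r = np.ones((box, box, nz))

    def rfft(self, vol: DensityVolume) -> np.ndarray:
        d = vol.data.astype(np.float64)
        return sp_fft.rfftn(d - d.mean())

    def masked_power(self, f: np.ndarray) -> float:
        return float(np.sum(self.rmult * self.mask_r * np.abs(f) ** 2))


def constrained_cc(
    particle_vol: DensityVolume,
    reference: DensityVolume,
    wedge: WedgeMask | None = None,
    band_limit_a: float | None = None,
) -> float:
    """Normalised cross-correlation over the Fourier voxels inside both the
    particle's wedge and the band limit (zero shift)."""
    ws = _Workspace(particle_vol.box, particle_vol.voxel_size, wedge, band_limit_a)
    if not np.any(ws.mask_r > 1e-6):
        raise AlignmentError("empty wedge/band overlap: correlation undefined")
    fp, fr = ws.rfft(particle_vol), ws.rfft(reference)
    denom = np.sqrt(ws.masked_power(fp) * ws.masked_power(fr))
    if denom == 0:
        raise AlignmentError("zero power inside the constrained region")
    num = float(np.sum(ws.rmult * ws.mask_r * (fp * np.conj(fr)).real))
    return float(np.clip(num / denom, -1.0, 1.0))


def _shift_window(box: int, limit_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean window of allowed wrap-aware shifts and the shift vectors."""
    t = np.fft.fftfreq(box) * box  # 0..n/2-1, -n/2..-1
    tx, ty, tz = np.meshgrid(t, t, t, indexing="ij", sparse=True)
    ok = (np.abs(tx) <= limit_vox) & (np.abs(ty) <= limit_vox) & (np.abs(tz) <= limit_vox)
    return ok, t


def _score_rotation(
    fp: np.ndarray,
    fr_rot: np.ndarray,
    ws: _Workspace,
    window: np.ndarray,
    norm_p: float,
) -> tuple[float, np.ndarray, bool]:
    """Best translation (voxels) and cc for one candidate rotation."""
    prod = fp * np.conj(fr_rot) * ws.mask_r
    # irfftn reconstructs the conjugate half itself (the product is
    # Hermitian), so no multiplicity factor here; undo its 1/N^3 so
    # cc_map[t] is the full-grid masked inner product at shift t
    cc_map = sp_fft.irfftn(prod, s=(ws.box,) * 3) * ws.box**3
    norm_r = ws.masked_power(fr_rot)
    denom = np.sqrt(norm_p * norm_r)
    if denom == 0:
        return -np.inf, np.zeros(3), False
    masked = np.where(window, cc_map, -np.inf)
    idx = np.unravel_index(int(np.argmax(masked)), masked.shape)
    t = np.array([i if i <= ws.box // 2 else i - ws.box for i in idx], dtype=float)
    cc = float(cc_map[idx] / denom)
    return cc, t, False


def align_particle(
    particle_vol: DensityVolume,
    record: ParticleRecord,
    reference: DensityVolume,
    config: AlignmentConfig,
    wedge: WedgeMask | None = None,
    _ws: _Workspace | None = None,
    _bank: list[tuple[EulerTriplet, np.ndarray]] | None = None,
) -> ParticleRecord:
    """Grid-search pose and shift of one particle against the reference.

    The reference is rotated into candidate poses (the wedge stays on the
    particle), the constrained correlation is evaluated over the translation
    window via FFT, and the best coarse candidate is locally refined at half
    the angular step.  Deterministic given the config.
    """
    ws = _ws or _Workspace(
        particle_vol.box, particle_vol.voxel_size, wedge, config.band_limit_a
    )
    fp = ws.rfft(particle_vol)
    norm_p = ws.masked_power(fp)
    limit_vox = config.shift_limit_a / particle_vol.voxel_size
    window, _ = _shift_window(particle_vol.box, limit_vox)
    prior = record.pose

    def candidates_abs(deltas: list[EulerTriplet]) -> list[EulerTriplet]:
        if prior == EulerTriplet():
            return deltas
        return [prior.then(d) for d in deltas]

    best = (-np.inf, EulerTriplet(), np.zeros(3))
    if _bank is not None and prior == EulerTriplet():
        for pose, fr_rot in _bank:
            cc, t, _ = _score_rotation(fp, fr_rot, ws, window, norm_p)
            if cc > best[0]:
                best = (cc, pose, t)
    else:
        for pose in candidates_abs(angular_grid(config)):
            fr_rot = ws.rfft(rotate_shift(reference, pose))
            cc, t, _ = _score_rotation(fp, fr_rot, ws, window, norm_p)
            if cc > best[0]:
                best = (cc, pose, t)
    if config.local_refine:
        for pose in _local_grid(best[1], config.cone_step, config.inplane_step):
            fr_rot = ws.rfft(rotate_shift(reference, pose))
            cc, t, _ = _score_rotation(fp, fr_rot, ws, window, norm_p)
            if cc > best[0]:
                best = (cc, pose, t)
    cc, pose, t = best
    if config.symmetry_c4:
        pose = pose.canonical_c4()
    on_boundary = bool(np.any(np.abs(t) >= np.floor(limit_vox)) and limit_vox >= 1)
    return replace(
        record,
        pose=pose,
        shift=t * particle_vol.voxel_size,
        cc=float(cc),
        shift_on_boundary=on_boundary,
    )


def align_set(
    volumes: list[DensityVolume],
    particles: ParticleSet,
    reference: DensityVolume,
    config: AlignmentConfig,
    wedge: WedgeMask | None = None,
    tilt_scheme: TiltScheme | None = None,
) -> ParticleSet:
    """Align every particle; shares one rotated-reference bank when all
    particles start from the identity pose (a global search)."""
    if not len(particles):
        return particles
    vol0 = volumes[0]
    ws = _Workspace(vol0.box, vol0.voxel_size, wedge, config.band_limit_a, tilt_scheme)
    bank = None
    if all(r.pose == EulerTriplet() for r in particles):
        bank = [
            (pose, ws.rfft(rotate_shift(reference, pose)).astype(np.complex64))
            for pose in angular_grid(config)
        ]
    out = []
    for vol, rec in zip(volumes, particles):
        out.append(
            align_particle(vol, rec, reference, config, wedge, _ws=ws, _bank=bank)
        )
    return ParticleSet(out)


# ---------------------------------------------------------------------------
# averaging


def _rotate_fourier_mask(mask: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Resample an unshifted Fourier mask at rotated frequencies M(R k).

    The mask is fftshifted so signed frequencies are contiguous, rotated
    about the DC voxel (index N/2), and shifted back; frequencies rotated in
    from beyond the cube count as unsampled (0).
    """
    from scipy import ndimage

    n = mask.shape[0]
    c = np.full(3, n // 2, dtype=float)
    shifted = np.fft.fftshift(mask)
    rotated = ndimage.affine_transform(
        shifted, rot, offset=c - rot @ c, order=1, mode="constant", cval=0.0
    )
    return np.fft.ifftshift(rotated)


def weighted_average(
    volumes: list[DensityVolume],
    particles: ParticleSet,
    config: AlignmentConfig,
    wedge: WedgeMask | None = None,
    tilt_scheme: TiltScheme | None = None,
    use_cc_weights: bool = True,
) -> DensityVolume:
    """Wedge- and dose-compensated average in the reference frame.

    Each particle is moved back to the reference frame; its Fourier
    contribution is accumulated together with a per-voxel sampling weight
    (its wedge rotated into the reference frame × the exposure-decay profile
    × the particle weight).  The weighted Fourier sum is divided by the
    accumulated weight, floored at 1e-3 of its maximum so never-sampled
    voxels do not amplify noise.  Particle weight is max(cc, 0) — the
    contribution is proportional to the correlation to the reference — or
    uniform with ``use_cc_weights=False``.
    """
    if not len(particles):
        raise AlignmentError("no particles to average")
    vol0 = volumes[0]
    box, voxel = vol0.box, vol0.voxel_size
    weights = np.array(
        [max(r.cc, 0.0) if use_cc_weights else 1.0 for r in particles], dtype=float
    )
    if weights.sum() <= 0:
        raise AlignmentError("total particle weight is zero")
    wedge_mask = wedge.mask if wedge is not None else np.ones((box,) * 3)
    freqs = radial_frequency_grid(box, voxel)
    dose = (
        tilt_scheme.exposure_profile(freqs)
        if tilt_scheme is not None
        else np.ones((box,) * 3)
    )
    # matched-filter exposure compensation: the data are weighted by the
    # decay profile D and divided by the accumulated sampling ∑ w·M·D², so
    # the signal is restored where it was measured while noise at strongly
    # damped frequencies is suppressed rather than amplified
    num = np.zeros((box,) * 3, dtype=complex)
    den = np.zeros((box,) * 3)
    for vol, rec, w in zip(volumes, particles, weights):
        if w <= 0:
            continue
        aligned = unrotate_unshift(vol, rec.pose, rec.shift)
        d = aligned.data.astype(np.float64)
        num += w * dose * sp_fft.fftn(d - d.mean())
        rot_wedge = _rotate_fourier_mask(wedge_mask, rec.pose.matrix())
        den += w * rot_wedge * dose**2
    # Tikhonov-regularised division: well-sampled voxels are divided by
    # their accumulated weight, while voxels with weight ≪ ε are driven to
    # zero instead of being amplified (interpolation leakage into the
    # missing wedge would otherwise dominate the average)
    eps = 0.1 * den.max()
    avg = sp_fft.ifftn(num * den / (den**2 + eps**2)).real
    out = DensityVolume(avg, voxel)
    if config.symmetry_c4:
        out = symmetrize_c4(out)
    if config.band_limit_a is not None:
        out = bandpass(out, None, config.band_limit_a)
    return out


# ---------------------------------------------------------------------------
# model / results


@dataclass
class AlignmentResults:
    """Outcome of subtomogram refinement.

    ``branch`` is ``"halfset"`` (independent half-maps, FSC resolution at the
    configured threshold) or ``"single-36A"`` (≤500 particles: one reference,
    final map restricted to 36 Å, resolution reported as that band limit).
    """

    particles: ParticleSet
    average: DensityVolume
    config: AlignmentConfig
    branch: str
    map_a: DensityVolume | None = None
    map_b: DensityVolume | None = None
    fsc: FSCCurve | None = None
    resolution_a: float = np.nan
    n_iterations: int = 0

    @property
    def nobs(self) -> int:
        return len(self.particles)

    def cc_scores(self) -> np.ndarray:
        return np.array([r.cc for r in self.particles])

    def summary(self) -> str:
        cc = self.cc_scores()
        lines = [
            "Subtomogram alignment results",
            "=" * 46,
            f"particles                {self.nobs}",
            f"refinement branch        {self.branch}",
            f"iterations               {self.n_iterations}",
            f"C4 symmetry              {self.config.symmetry_c4}",
            f"band limit (Å)           {self.config.band_limit_a}",
            f"mean / median cc         {cc.mean():.3f} / {np.median(cc):.3f}",
            f"resolution (Å)           {self.resolution_a:.2f}"
            + (
                f"  (FSC {self.config.fsc_threshold})"
                if self.branch == "halfset"
                else "  (band-limited)"
            ),
        ]
        return "\n".join(lines)

    def plot_fsc(self, ax=None):
        """FSC curve with the threshold line; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if self.fsc is None:
            raise ValueError("no FSC available on this branch")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fsc.shell_frequencies, self.fsc.correlations, lw=1.5)
        ax.axhline(self.config.fsc_threshold, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("spatial frequency (1/Å)")
        ax.set_ylabel("FSC")
        return ax

    def save(self, outdir) -> None:
        from pathlib import Path

        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_volume(self.average, outdir / "average.mrc")
        if self.map_a is not None:
            sio.write_volume(self.map_a, outdir / "half_a.mrc")
            sio.write_volume(self.map_b, outdir / "half_b.mrc")
        self.particles.write(outdir / "particles.tsv")
        if self.fsc is not None:
            pd.DataFrame(
                {
                    "frequency_inv_A": self.fsc.shell_frequencies,
                    "fsc": self.fsc.correlations,
                    "n_voxels": self.fsc.n_voxels_per_shell,
                }
            ).to_csv(outdir / "fsc.tsv", sep="\t", index=False)


class SubtomogramAlignment:
    """Constrained refinement of a particle set against a reference.

    Parameters
    ----------
    volumes, particles
        The subtomograms and their current alignment state.
    reference
        Starting reference; defaults to the unweighted average under the
        current poses.
    wedge
        The particles' shared missing-wedge mask (``None`` = fully sampled).
    tilt_scheme
        Enables exposure-decay compensation in scoring-free averaging.
    config
        Search space and policy; see :class:`AlignmentConfig`.
    """

    def __init__(
        self,
        volumes: list[DensityVolume],
        particles: ParticleSet,
        reference: DensityVolume | None = None,
        wedge: WedgeMask | None = None,
        tilt_scheme: TiltScheme | None = None,
        config: AlignmentConfig | None = None,
    ):
        self.volumes = volumes
        self.particles = particles.copy()
        self.wedge = wedge
        self.tilt_scheme = tilt_scheme
        self.config = config or AlignmentConfig()
        if reference is None:
            reference = weighted_average(
                volumes, self.particles, replace(self.config, band_limit_a=None),
                wedge, tilt_scheme, use_cc_weights=False,
            )
        self.reference = reference

    def fit(self, method: str = "auto") -> AlignmentResults:
        """Run the refinement.

        ``method='auto'`` applies the branch rule (half-sets for >500
        particles, single-reference with a 36 Å limit otherwise);
        ``'single'`` and ``'halfset'`` force a branch.
        """
        n = len(self.particles)
        if method == "auto":
            method = "halfset" if n > SMALL_SET_MAX else "single"
        if method == "halfset":
            return self._fit_halfsets()
        return self._fit_single()

    def _refine(self, volumes, particles, reference, iterations) -> tuple[ParticleSet, DensityVolume]:
        ref = reference
        for _ in range(iterations):
            particles = align_set(
                volumes, particles, ref, self.config, self.wedge, self.tilt_scheme
            )
            ref = weighted_average(
                volumes, particles, self.config, self.wedge, self.tilt_scheme
            )
        return particles, ref

    def _fit_single(self) -> AlignmentResults:
        logger.info("single-reference refinement of %d particles", len(self.particles))
        particles, _ = self._refine(
            self.volumes, self.particles, self.reference, self.config.iterations
        )
        final_cfg = replace(self.config, band_limit_a=None)
        avg = weighted_average(
            self.volumes, particles, final_cfg, self.wedge, self.tilt_scheme
        )
        # hard restriction: no power beyond the small-set band limit
        avg = bandpass(avg, None, SMALL_SET_BAND_A, edge_inside=True)
        return AlignmentResults(
            particles=particles,
            average=avg,
            config=self.config,
            branch="single-36A",
            resolution_a=SMALL_SET_BAND_A,
            n_iterations=self.config.iterations,
        )

    def _fit_halfsets(self) -> AlignmentResults:
        n = len(self.particles)
        logger.info("independent half-set refinement of %d particles", n)
        particles = self.particles
        particles.assign_halfsets(self.config.seed)
        idx = {h: particles.halfset_indices(h) for h in "AB"}
        maps: dict[str, DensityVolume] = {}
        halves: dict[str, ParticleSet] = {}
        for h in "AB":
            vols_h = [self.volumes[i] for i in idx[h]]
            parts_h = particles.subset(idx[h])
            parts_h, map_h = self._refine(
                vols_h, parts_h, self.reference, self.config.iterations
            )
            maps[h], halves[h] = map_h, parts_h
        curve = fsc_curve(maps["A"], maps["B"])
        res = resolution_at_threshold(
            curve, self.config.fsc_threshold, self.volumes[0].voxel_size
        )
        merged = particles.copy()
        for h in "AB":
            for i, rec in zip(idx[h], halves[h]):
                merged.records[i] = rec
        combined = weighted_average(
            self.volumes, merged, self.config, self.wedge, self.tilt_scheme
        )
        return AlignmentResults(
            particles=merged,
            average=combined,
            config=self.config,
            branch="halfset",
            map_a=maps["A"],
            map_b=maps["B"],
            fsc=curve,
            resolution_a=res,
            n_iterations=self.config.iterations,
        )


def halfset_refine(
    volumes: list[DensityVolume],
    particles: ParticleSet,
    config: AlignmentConfig,
    reference: DensityVolume | None = None,
    wedge: WedgeMask | None = None,
    tilt_scheme: TiltScheme | None = None,
) -> AlignmentResults:
    """Functional wrapper: branch-rule refinement (half-sets when n > 500,
    single-reference with the 36 Å restriction otherwise)."""
    if len(particles) < 2:
        raise AlignmentError("half-set refinement needs at least 2 particles")
    model = SubtomogramAlignment(volumes, particles, reference, wedge, tilt_scheme, config)
    return model.fit("auto")
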