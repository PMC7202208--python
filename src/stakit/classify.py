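"""Multireference alignment classification.

Particles keep their refined poses; K references are seeded by randomised
phase jitter of the global average, and the algorithm alternates
assignment-by-best-constrained-cc with per-class wedge-compensated
averaging at the classification band limit (22 Å in the reference
protocol, C4 applied).  Iteration stops when fewer than 1% of assignments
change, when the objective (sum of best-class correlations) would decrease,
or at the iteration cap.  Class pruning moves low-abundance or flagged
classes (gold-bead-like artefacts are flagged manually via an exclusion
list) into an excluded set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .align import _rotate_fourier_mask
from .fourier import WedgeMask, bandpass_mask, radial_frequency_grid
from .particles import ParticleSet
from .phantom import TiltScheme
from .volume import DensityVolume, symmetrize_c4, unrotate_unshift

logger = logging.getLogger(__name__)


class ClassificationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassificationConfig:
    """Multireference classification policy."""

    band_limit_a: float = 22.0
    symmetry_c4: bool = True
    max_iter: int = 10
    assign_tol: float = 0.01  # stop when < this fraction of labels change
    seed_jitter: float = 0.25  # rad, phase-jitter scale for reference seeding
    n_restarts: int = 5  # independent seedings; best final objective wins
    seed: int = 0


@dataclass
class ClassificationResults:
    """Assignments, class averages and occupancies of one classification run.

    ``occupancies`` are fractions of *all* classified particles and sum to 1
    over retained + excluded classes."""

    assignments: dict[int, int]  # particle id -> class index
    class_averages: list[DensityVolume | None]
    occupancies: np.ndarray
    particles: ParticleSet
    retained: list[int] = field(default_factory=list)
    excluded: dict[int, str] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    config: ClassificationConfig | None = None

    @property
    def k(self) -> int:
        return len(self.occupancies)

    @property
    def n_retained_particles(self) -> int:
        counts = self.class_counts()
        return int(sum(counts[c] for c in self.retained))

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(self.k, dtype=int)
        for c in self.assignments.values():
            counts[c] += 1
        return counts

    def occupancy_table(self) -> pd.DataFrame:
        """Per-class counts and fractions, sorted by descending count;
        fractions re-derived from counts and summing to 1."""
        counts = self.class_counts()
        total = counts.sum()
        df = pd.DataFrame(
            {
                "class_id": np.arange(self.k),
                "count": counts,
                "fraction": counts / total if total else 0.0,
                "status": [
                    "excluded" if c in self.excluded else "retained"
                    for c in range(self.k)
                ],
            }
        )
        return df.sort_values("count", ascending=False, kind="stable").reset_index(
            drop=True
        )

    def summary(self) -> str:
        tab = self.occupancy_table()
        lines = [
            "Multireference classification results",
            "=" * 46,
            f"classes (retained/total)  {len(self.retained)}/{self.k}",
            f"particles                 {len(self.assignments)}",
            f"iterations                {self.n_iterations}",
            "",
            tab.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        from pathlib import Path

        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c, avg in enumerate(self.class_averages):
            if avg is not None:
                sio.write_volume(avg, outdir / f"class_{c:02d}.mrc")
        self.occupancy_table().to_csv(outdir / "occupancies.tsv", sep="\t", index=False)
        self.particles.write(outdir / "assignments.tsv")


class MultireferenceClassification:
    """K-class multireference classification of aligned particles.

    Parameters
    ----------
    volumes, particles
        Subtomograms and their refined alignment state (poses are kept
        fixed during classification).
    k
        Number of classes; 2 ≤ k ≤ n/2.
    wedge, tilt_scheme
        Sampling model shared by the particles.
    global_average
        Reference used for seeding; computed from the particles when absent.
    """

    def __init__(
        self,
        volumes: list[DensityVolume],
        particles: ParticleSet,
        k: int,
        wedge: WedgeMask | None = None,
        tilt_scheme: TiltScheme | None = None,
        global_average: DensityVolume | None = None,
        config: ClassificationConfig | None = None,
    ):
        n = len(particles)
        if k < 1:
            raise ClassificationError("k must be >= 1")
        if k > 1 and (k < 2 or k > n // 2):
            raise ClassificationError(f"need 2 <= k <= n/2, got k={k}, n={n}")
        self.volumes = volumes
        self.particles = particles.copy()
        self.k = k
        self.wedge = wedge
        self.tilt_scheme = tilt_scheme
        self.config = config or ClassificationConfig()
        self._global_average = global_average

    # -- Fourier caches ----------------------------------------------------

    def _prepare(self):
        box = self.volumes[0].box
        voxel = self.volumes[0].voxel_size
        nz = box // 2 + 1
        band = bandpass_mask(box, voxel, None, self.config.band_limit_a)[:, :, :nz]
        band[0, 0, 0] = 0.0
        rmult = np.full((box, box, nz), 2.0)
        rmult[:, :, 0] = 1.0
        rmult[:, :, -1] = 1.0
        freqs = radial_frequency_grid(box, voxel)[:, :, :nz]
        dose = (
            self.tilt_scheme.exposure_profile(freqs)
            if self.tilt_scheme is not None
            else np.ones_like(freqs)
        )
        wedge_full = (
            self.wedge.mask if self.wedge is not None else np.ones((box,) * 3)
        )
        spectra, masks = [], []
        for vol, rec in zip(self.volumes, self.particles):
            aligned = unrotate_unshift(vol, rec.pose, rec.shift)
            d = aligned.data.astype(np.float64)
            spectra.append(sp_fft.rfftn(d - d.mean()).astype(np.complex64))
            rot = _rotate_fourier_mask(wedge_full, rec.pose.matrix())[:, :, :nz]
            masks.append(rot.astype(np.float32))
        return dict(
            box=box,
            voxel=voxel,
            band=band,
            rmult=rmult,
            dose=dose,
            spectra=spectra,
            masks=masks,
        )

    def _class_average_f(self, ctx, members, weights):
        """Wedge/dose-compensated class average spectrum (rfft grid)."""
        box = ctx["box"]
        num = np.zeros_like(ctx["spectra"][0], dtype=np.complex128)
        den = np.zeros_like(ctx["masks"][0], dtype=np.float64)
        for i in members:
            w = weights[i]
            if w <= 0:
                continue
            num += w * ctx["dose"] * ctx["spectra"][i]
            den += w * ctx["masks"][i] * ctx["dose"] ** 2
        if den.max() <= 0:
            return None
        eps = 0.1 * den.max()
        return num * den / (den**2 + eps**2)

    def _to_reference(self, ctx, avg_f) -> tuple[DensityVolume, np.ndarray]:
        """Real-space class average (C4, band-limited) and its spectrum."""
        box = ctx["box"]
        vol = DensityVolume(
            sp_fft.irfftn(avg_f, s=(box,) * 3), ctx["voxel"]
        )
        if self.config.symmetry_c4:
            vol = symmetrize_c4(vol)
        d = vol.data.astype(np.float64)
        return vol, sp_fft.rfftn(d - d.mean())

    def _cc(self, ctx, i, ref_f, ref_sq_cache) -> float:
        m = ctx["masks"][i] * ctx["band"] * ctx["rmult"]
        num = float(np.sum(m * (ctx["spectra"][i] * np.conj(ref_f)).real))
        np_i = float(np.sum(m * np.abs(ctx["spectra"][i]) ** 2))
        nr = float(np.sum(m * ref_sq_cache))
        if np_i <= 0 or nr <= 0:
            return -1.0
        return float(np.clip(num / np.sqrt(np_i * nr), -1.0, 1.0))

    # -- main loop ---------------------------------------------------------

    def fit(self) -> ClassificationResults:
        """Run the classification; the alternation is restarted from
        ``n_restarts`` independent reference seedings (the local optima of
        multireference alignment depend on the seeding) and the run with
        the best final objective is returned."""
        n = len(self.particles)
        ctx = self._prepare()
        weights0 = np.array([max(r.cc, 0.0) for r in self.particles])
        if weights0.sum() <= 0:
            weights0 = np.ones(n)  # unscored particles weigh equally

        glob_f = self._class_average_f(ctx, range(n), weights0)
        if glob_f is None:
            raise ClassificationError("no usable particles")
        if self.k == 1:
            avg, _ = self._to_reference(ctx, glob_f)
            labels = np.zeros(n, dtype=int)
            return self._package(labels, [avg], [], 0)

        best = None
        for restart_seed in np.random.SeedSequence(self.config.seed).spawn(
            max(1, self.config.n_restarts)
        ):
            run = self._fit_once(ctx, glob_f, weights0.copy(), restart_seed)
            if best is None or run[0] > best[0]:
                best = run
        _, labels, refs, trace, it, _ = best
        for rec, lab, c_i in zip(self.particles, labels, best[5]):
            rec.class_id = int(lab)
            rec.cc = float(c_i)
        averages = [refs[c][0] if np.any(labels == c) else None for c in range(self.k)]
        return self._package(labels, averages, trace, it)

    def _fit_once(self, ctx, glob_f, weights, seed_seq):
        n = len(self.particles)
        rng = np.random.default_rng(seed_seq)
        # seed K references by smooth random phase jitter of the global average
        refs_f = []
        for _ in range(self.k):
            phase = rng.normal(0.0, self.config.seed_jitter, glob_f.shape)
            refs_f.append(glob_f * np.exp(1j * phase))
        refs = [self._to_reference(ctx, f) for f in refs_f]

        labels = np.full(n, -1, dtype=int)
        objective_trace: list[float] = []
        reseeded = set()
        it = 0
        for it in range(1, self.config.max_iter + 1):
            ref_sq = [np.abs(rf) ** 2 for _, rf in refs]
            cc = np.empty((n, self.k))
            for i in range(n):
                for c in range(self.k):
                    cc[i, c] = self._cc(ctx, i, refs[c][1], ref_sq[c])
            new_labels = np.argmax(cc, axis=1)
            objective = float(cc[np.arange(n), new_labels].sum())
            if objective_trace and objective < objective_trace[-1]:
                logger.info("objective would decrease; stopping at iter %d", it)
                break
            # rescue empty classes once from the largest class's worst members
            counts = np.bincount(new_labels, minlength=self.k)
            for c in np.nonzero(counts == 0)[0]:
                if c in reseeded:
                    continue  # allowed to die after one rescue
                reseeded.add(c)
                big = int(np.argmax(counts))
                members = np.nonzero(new_labels == big)[0]
                worst = members[np.argsort(cc[members, big])][: max(1, len(members) // 10)]
                new_labels[worst] = c
                counts = np.bincount(new_labels, minlength=self.k)
            changed = float(np.mean(new_labels != labels)) if it > 1 else 1.0
            labels = new_labels
            objective_trace.append(objective)
            final_cc = cc[np.arange(n), labels]
            if changed < self.config.assign_tol and it > 1:
                break
            weights = np.array([max(c_i, 0.0) for c_i in final_cc])
            new_refs = []
            for c in range(self.k):
                members = np.nonzero(labels == c)[0]
                f = self._class_average_f(ctx, members, weights) if len(members) else None
                new_refs.append(refs[c] if f is None else self._to_reference(ctx, f))
            refs = new_refs
        return (
            objective_trace[-1] if objective_trace else -np.inf,
            labels,
            refs,
            objective_trace,
            it,
            final_cc,
        )

    def _package(self, labels, averages, trace, n_iter) -> ClassificationResults:
        n = len(self.particles)
        counts = np.bincount(labels, minlength=self.k)
        for rec, lab in zip(self.particles, labels):
            rec.class_id = int(lab)
        return ClassificationResults(
            assignments={r.id: int(l) for r, l in zip(self.particles, labels)},
            class_averages=averages,
            occupancies=counts / n,
            particles=self.particles,
            retained=list(range(len(averages))),
            excluded={},
            objective_trace=trace,
            n_iterations=n_iter,
            config=self.config,
        )


def multireference_classify(
    volumes,
    particles,
    k,
    wedge=None,
    tilt_scheme=None,
    config=None,
    seed=0,
) -> ClassificationResults:
    """Functional wrapper over :class:`MultireferenceClassification`."""
    cfg = config or ClassificationConfig(seed=seed)
    if config is not None and seed:
        cfg = replace(cfg, seed=seed)
    model = MultireferenceClassification(
        volumes, particles, k, wedge, tilt_scheme, config=cfg
    )
    return model.fit()


def prune_classes(
    result: ClassificationResults,
    min_fraction: float = 0.01,
    artifact_flags: list[int] | None = None,
) -> ClassificationResults:
    """Exclude classes below ``min_fraction`` (strictly) or manually flagged
    (e.g. gold-bead contamination); occupancies still sum to 1 over
    retained + excluded."""
    flags = set(artifact_flags or [])
    counts = result.class_counts()
    total = counts.sum()
    retained, excluded = [], {}
    for c in range(result.k):
        frac = counts[c] / total if total else 0.0
        if c in flags:
            excluded[c] = "flagged artifact"
        elif frac < min_fraction:
            excluded[c] = f"low abundance ({frac:.3%} < {min_fraction:.1%})"
        else:
            retained.append(c)
    if not retained:
        raise ClassificationError("pruning removed every class")
    return replace_result(result, retained=retained, excluded=excluded)


def replace_result(result: ClassificationResults, **kw) -> ClassificationResults:
    from dataclasses import replace as _replace

    return _replace(result, **kw)


def occupancy_table(result: ClassificationResults) -> pd.DataFrame:
    return result.occupancy_table()
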