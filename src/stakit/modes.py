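"""Eigenvolume analysis of conformational heterogeneity.

Class averages (fully sampled in Fourier space, so no wedge bookkeeping is
needed at this stage) are aligned to a common average and decomposed by
voxel-wise PCA on the class-count-sized Gram matrix.  The first raw
principal component of such sets is typically "trivial" — it tracks global
amplitude/normalisation differences between class averages rather than a
conformational motion — and is dropped, with the reported modes renumbered
from the second raw component; a diagnostic records its correlation with
global amplitude so the triviality can be verified.  Mode *informativity*
is the mode's variance divided by mode 1's variance.  Per-mode half-maps
are built by splitting the class averages into two equal-sized groups by
their eigencoefficients.  A Moran's-I statistic over a k-nearest-neighbour
graph of particle positions tests whether eigencoefficients cluster
spatially in the tomograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentConfig, align_particle
from .particles import ParticleRecord
from .volume import DensityVolume, EulerTriplet, rotate_shift, unrotate_unshift

logger = logging.getLogger(__name__)


class ModeAnalysisError(RuntimeError):
    pass


def align_class_averages(
    class_averages: list[DensityVolume],
    rounds: int = 5,
    cone_range: float = 8.0,
    cone_step: float = 4.0,
    inplane_range: float = 8.0,
    shift_limit_a: float = 12.0,
    symmetry_c4: bool = True,
) -> tuple[list[DensityVolume], DensityVolume, list[ParticleRecord]]:
    """Iteratively align class averages to their evolving common mean.

    Full-band small local search (the inputs are fully sampled volumes).
    Returns the aligned volumes, the common average, and the per-volume
    alignment records.  Non-convergence after ``rounds`` proceeds with a
    warning.
    """
    if len(class_averages) < 3:
        raise ModeAnalysisError("need at least 3 class averages")
    cfg = AlignmentConfig(
        cone_range=cone_range,
        cone_step=cone_step,
        inplane_range=inplane_range,
        inplane_step=cone_step,
        shift_limit_a=shift_limit_a,
        band_limit_a=None,
        symmetry_c4=symmetry_c4,
        local_refine=True,
    )
    records = [ParticleRecord(id=i) for i in range(len(class_averages))]
    aligned = list(class_averages)
    converged = False
    for _ in range(rounds):
        mean = class_averages[0].with_data(
            np.mean([v.data for v in aligned], axis=0)
        )
        new_records, moved = [], 0.0
        for vol, rec in zip(class_averages, records):
            new = align_particle(vol, rec, mean, cfg)
            moved = max(moved, new.pose.geodesic_to(rec.pose, c4=symmetry_c4))
            moved = max(moved, float(np.linalg.norm(new.shift - rec.shift)))
            new_records.append(new)
        records = new_records
        aligned = [
            unrotate_unshift(vol, rec.pose, rec.shift)
            for vol, rec in zip(class_averages, records)
        ]
        if moved < 1e-3:
            converged = True
            break
    if not converged:
        logger.warning("class-average alignment did not fully settle in %d rounds", rounds)
    mean = class_averages[0].with_data(np.mean([v.data for v in aligned], axis=0))
    return aligned, mean, records


@dataclass
class ModeDecomposition:
    """Eigenvolume decomposition of a set of aligned class averages.

    Modes are numbered 1.. after removal of the trivial first raw component;
    ``informativity`` is normalised so mode 1 ≡ 1.  ``eigencoefficients``
    has one row per class average, one column per mode.
    """

    mean_volume: DensityVolume
    eigenvolumes: list[DensityVolume]
    eigencoefficients: np.ndarray
    eigenvalues: np.ndarray
    informativity: np.ndarray
    trivial_component: DensityVolume | None
    trivial_amplitude_corr: float
    dropped_trivial: bool
    n_inputs: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvolumes)

    def reconstruct(self, index: int) -> DensityVolume:
        """Input volume ``index`` rebuilt from mean + all retained components
        (including the trivial one, if it was separated out)."""
        data = self.mean_volume.data.astype(np.float64).copy()
        if self.trivial_component is not None:
            data += self._trivial_coeffs[index] * self.trivial_component.data
        for m in range(self.n_modes):
            data += self.eigencoefficients[index, m] * self.eigenvolumes[m].data
        return self.mean_volume.with_data(data)

    _trivial_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def summary(self) -> str:
        lines = [
            "Eigenvolume mode decomposition",
            "=" * 46,
            f"class averages           {self.n_inputs}",
            f"modes retained           {self.n_modes}",
            f"trivial PC dropped       {self.dropped_trivial}"
            f" (|corr with amplitude| = {abs(self.trivial_amplitude_corr):.3f})",
            "",
            self.informativity_table().to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def informativity_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": np.arange(1, self.n_modes + 1),
                "variance": self.eigenvalues,
                "informativity": self.informativity,
            }
        )

    def plot_informativity(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(1, self.n_modes + 1), self.informativity)
        ax.set_xlabel("mode")
        ax.set_ylabel("informativity (var / var mode 1)")
        return ax


class EigenvolumeAnalysis:
    """Voxel-wise PCA over aligned class averages.

    The covariance is computed on the class-count-sized Gram matrix (far
    smaller than the voxel count).  ``drop_trivial`` removes the first raw
    principal component and renumbers modes from the second, per the
    standard treatment of the trivial amplitude component;
    ``occupancy_weights`` optionally weights classes by particle count
    (off by default: each class average counts once).
    """

    def __init__(
        self,
        aligned_volumes: list[DensityVolume],
        drop_trivial: bool = True,
        occupancy_weights: np.ndarray | None = None,
    ):
        if len(aligned_volumes) < 3:
            raise ModeAnalysisError("need at least 3 volumes for a mode analysis")
        self.volumes = aligned_volumes
        self.drop_trivial = drop_trivial
        self.weights = occupancy_weights

    def fit(self) -> ModeDecomposition:
        k = len(self.volumes)
        x = np.stack([v.data.ravel().astype(np.float64) for v in self.volumes])
        w = np.ones(k) if self.weights is None else np.asarray(self.weights, float)
        w = w / w.sum()
        mean = (w[:, None] * x).sum(axis=0)
        xc = (x - mean) * np.sqrt(w[:, None] * k)  # weighted, scaled to k rows
        gram = xc @ xc.T / (k - 1)
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        # variance below float round-off of the data scale counts as zero
        scale = float(np.mean(x**2)) + 1e-300
        nonzero = evals > 1e-12 * scale
        if not np.any(nonzero):
            logger.warning("all inputs identical: no variance to decompose")
            return ModeDecomposition(
                mean_volume=self.volumes[0].with_data(mean.reshape(self.volumes[0].data.shape)),
                eigenvolumes=[],
                eigencoefficients=np.zeros((k, 0)),
                eigenvalues=np.zeros(0),
                informativity=np.zeros(0),
                trivial_component=None,
                trivial_amplitude_corr=0.0,
                dropped_trivial=False,
                n_inputs=k,
            )
        evals, evecs = evals[nonzero], evecs[:, nonzero]
        # eigenvolumes (unit voxel norm) and per-class coefficients
        shape = self.volumes[0].data.shape
        comps, coeffs = [], []
        for j in range(len(evals)):
            v = xc.T @ evecs[:, j]
            norm = np.linalg.norm(v)
            v = v / norm if norm > 0 else v
            comps.append(v)
            coeffs.append(xc @ v)
        coeffs = np.array(coeffs).T  # k × modes
        # triviality diagnostic: correlation of PC1 coefficients with the
        # global amplitude (voxel sum) of each input
        amp = x.sum(axis=1)
        c0 = coeffs[:, 0]
        denom = np.std(amp) * np.std(c0)
        amp_corr = float(np.corrcoef(amp, c0)[0, 1]) if denom > 0 else 0.0
        start = 1 if (self.drop_trivial and len(evals) > 1) else 0
        mode_vals = evals[start:]
        informativity = mode_vals / mode_vals[0] if len(mode_vals) else mode_vals
        return ModeDecomposition(
            mean_volume=self.volumes[0].with_data(mean.reshape(shape)),
            eigenvolumes=[
                self.volumes[0].with_data(comps[j].reshape(shape))
                for j in range(start, len(evals))
            ],
            eigencoefficients=coeffs[:, start:],
            eigenvalues=mode_vals,
            informativity=informativity,
            trivial_component=(
                self.volumes[0].with_data(comps[0].reshape(shape)) if start else None
            ),
            trivial_amplitude_corr=amp_corr,
            dropped_trivial=bool(start),
            n_inputs=k,
            _trivial_coeffs=coeffs[:, 0] if start else np.zeros(k),
        )


def eigenvolume_decompose(
    aligned_volumes: list[DensityVolume], drop_trivial: bool = True
) -> ModeDecomposition:
    """Functional wrapper over :class:`EigenvolumeAnalysis`."""
    return EigenvolumeAnalysis(aligned_volumes, drop_trivial=drop_trivial).fit()


def mode_halfmaps(
    decomposition: ModeDecomposition, mode_index: int
) -> tuple[DensityVolume, DensityVolume]:
    """Average of the lower-coefficient half vs the upper-coefficient half of
    the class averages for one mode (1-based).  With an odd number of
    volumes the median-coefficient volume is excluded so the two groups stay
    equal-sized."""
    if not 1 <= mode_index <= decomposition.n_modes:
        raise ModeAnalysisError(f"mode {mode_index} does not exist")
    if decomposition.n_inputs < 4:
        raise ModeAnalysisError("half-maps need at least 4 volumes")
    coeff = decomposition.eigencoefficients[:, mode_index - 1]
    order = np.argsort(coeff, kind="stable")
    k = len(order)
    half = k // 2
    if k % 2:
        lower, upper = order[:half], order[half + 1 :]
    else:
        lower, upper = order[:half], order[half:]

    def _avg(idx):
        data = np.mean([decomposition.reconstruct(i).data for i in idx], axis=0)
        return decomposition.mean_volume.with_data(data)

    return _avg(lower), _avg(upper)


@dataclass(frozen=True)
class SpatialCorrelation:
    """Moran's I of eigencoefficients over a particle-position kNN graph."""

    mode: int
    moran_i: float
    null_mean: float
    null_std: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def mode_spatial_correlation(
    coefficients: np.ndarray,
    positions: np.ndarray,
    mode: int = 1,
    k_neighbors: int = 6,
    n_permutations: int = 999,
    seed: int = 0,
) -> SpatialCorrelation:
    """Test whether per-particle eigencoefficients cluster in space.

    ``coefficients`` is (n,) for the chosen mode (e.g. each particle carries
    its class's coefficient); ``positions`` is (n, 3) in Å.  The statistic is
    Moran's I on a symmetrised k-nearest-neighbour graph with a seeded
    permutation null and a one-sided (clustering) p-value.
    """
    coeff = np.asarray(coefficients, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = len(coeff)
    if n < 10:
        raise ModeAnalysisError("need at least 10 positioned particles")
    if np.std(coeff) == 0:
        return SpatialCorrelation(mode, np.nan, np.nan, np.nan, np.nan, 0, degenerate=True)
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    _, nbr = tree.query(pos, k=k_neighbors + 1)
    w = np.zeros((n, n))
    for i in range(n):
        for j in nbr[i, 1:]:
            w[i, j] = 1.0
    w = np.maximum(w, w.T)  # symmetrise
    s0 = w.sum()

    def moran(z):
        zc = z - z.mean()
        return n / s0 * float(zc @ w @ zc) / float(zc @ zc)

    observed = moran(coeff)
    rng = np.random.default_rng(seed)
    null = np.array(
        [moran(rng.permutation(coeff)) for _ in range(n_permutations)]
    )
    p = (1 + np.sum(null >= observed)) / (1 + n_permutations)
    return SpatialCorrelation(
        mode, observed, float(null.mean()), float(null.std()), float(p), n_permutations
    )
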