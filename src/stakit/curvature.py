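"""Membrane-curvature estimation by spherical-coordinate flatness
optimisation.

A density map whose membrane lies on a sphere of radius R becomes a
constant-radius sheet when resampled in spherical coordinates about the
sphere's centre.  The centre is constrained to the particle's symmetry
axis (the average is C4-symmetric, so the osculating sphere's centre lies
on the axis) at distance R from the membrane apex, on the lumenal side for
a membrane bulging toward the cytoplasm.  The flatness functional is the
variance across angular columns of the per-column membrane radial centroid
(in voxels²), with the receptor-stem footprint excluded; R is scanned over
a grid and refined by golden-section search, and a flat-sheet model
(curvature 0) competes with the spherical family.  Curvature is reported
as 1/R; for membrane-only patches the sign is positive when the centre of
curvature lies on the cytoplasmic (+z) side, i.e. the membrane is concave
seen from the cytoplasm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import DensityVolume

logger = logging.getLogger(__name__)


class CurvatureError(RuntimeError):
    pass


class MembraneDetectionError(CurvatureError):
    """No usable membrane band in most angular columns."""


@dataclass(frozen=True)
class CurvatureConfig:
    """Parameters of the flatness fit (lengths in physical units as noted)."""

    r_min_nm: float = 20.0
    r_max_nm: float = 200.0
    r_step_nm: float = 10.0
    near_flat_nm: float = 150.0  # |R| above this counts as near-flat
    membrane_z_a: float | None = None  # apex height; None = auto-detect
    smooth_sigma_vox: float = 1.0  # pre-smoothing for band detection
    z_refine_a: float = 15.0  # joint apex-height refinement half-window
    search_window_a: float = 80.0  # radial half-window around the probe sphere
    stem_exclusion_nm: float = 10.0  # central mask radius (receptor footprint)
    polar_step_deg: float = 2.0
    azimuth_step_deg: float = 6.0
    radial_step_vox: float = 0.5
    detect_fraction: float = 0.30  # column peak must exceed this × global peak
    min_detected_fraction: float = 0.5


def membrane_surface(
    vol: DensityVolume, config: CurvatureConfig, membrane_z_a: float
) -> tuple[np.ndarray, np.ndarray]:
    """Membrane surface samples (ρ_i, z_i) in Å from per-(x, y)-column
    lowest-band centroids within the window around ``membrane_z_a``."""
    n, a = vol.box, vol.voxel_size
    idx = np.arange(n)
    x = (idx[:, None] - n / 2.0) * a
    y = (idx[None, :] - n / 2.0) * a
    rho = np.sqrt(x**2 + y**2)
    zmask = np.abs(idx * a - membrane_z_a) <= config.search_window_a
    cols = (rho > config.stem_exclusion_nm * 10.0) & (rho < (n / 2 - 2) * a)
    profiles = vol.data[:, :, zmask][cols, :].astype(np.float64).T
    z_vals = idx[zmask].astype(float) * a
    cent = _lowest_band_centroids(profiles, z_vals, config.detect_fraction)
    good = np.isfinite(cent)
    return rho[cols][good], cent[good]


def estimate_apex(
    vol: DensityVolume, config: CurvatureConfig
) -> tuple[float, float | None]:
    """Apex height (Å) and a rough radius (nm) from an algebraic circle fit
    to the membrane surface z(ρ); radius is None when the surface is flat
    within half a voxel."""
    z_band = estimate_membrane_z(vol, config)
    rho, z = membrane_surface(vol, config, z_band)
    if len(z) < 20:
        raise MembraneDetectionError("too few membrane surface samples")
    if np.std(z) < 0.5 * vol.voxel_size:
        return float(np.mean(z)), None
    # sphere centred on the axis: rho² + (z − z0)² = R²  →  linear LS in z
    u = rho**2 + z**2
    A = np.stack([2.0 * z, np.ones_like(z)], axis=1)
    (z0, d), *_ = np.linalg.lstsq(A, u, rcond=None)
    r2 = d + z0**2
    if r2 <= 0:
        return float(np.mean(z)), None
    r_a = float(np.sqrt(r2))
    apex = float(z0 + r_a) if z0 < np.mean(z) else float(z0 - r_a)
    return apex, r_a / 10.0


def estimate_membrane_z(vol: DensityVolume, config: CurvatureConfig) -> float:
    """Nominal membrane apex height (Å): the density-richest plane in the
    lower half of the box, measured over an annulus outside the stem."""
    n, a = vol.box, vol.voxel_size
    idx = np.arange(n)
    x = (idx[:, None] - n / 2.0) * a
    y = (idx[None, :] - n / 2.0) * a
    rho = np.sqrt(x**2 + y**2)
    annulus = (rho > config.stem_exclusion_nm * 10.0) & (rho < (n / 2 - 2) * a)
    if not np.any(annulus):
        raise MembraneDetectionError(
            "stem exclusion radius leaves no membrane annulus in this box"
        )
    profile = vol.data[annulus, :].mean(axis=0)[: int(n * 0.6)]
    if not np.any(profile > 0):
        raise MembraneDetectionError("no positive density in the membrane annulus")
    # first strong band from the lumenal (low-z) side — the membrane — not
    # the global maximum, which can be the receptor's cytoplasmic domain
    strong = np.nonzero(profile > 0.5 * profile.max())[0]
    start = strong[0]
    stop = start
    while stop + 1 < len(profile) and profile[stop + 1] > 0.5 * profile.max():
        stop += 1
    band = profile[start : stop + 1]
    centroid = float((np.arange(start, stop + 1) * band).sum() / band.sum())
    return centroid * a


def spherical_resample(
    vol: DensityVolume,
    radius_nm: float,
    membrane_z_a: float,
    config: CurvatureConfig | None = None,
    center_side: str = "lumenal",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample the map on spherical shells about the candidate centre.

    The origin sits on the box (C4) axis at distance R from the membrane
    apex, below it for ``center_side='lumenal'`` (membrane bulging toward
    +z) or above for ``'cytoplasmic'``.  Returns ``(grid, r_vox, theta)``
    where ``grid[i_r, i_theta, i_phi]`` samples radius ``r_vox[i_r]``
    (voxels) at polar angle ``theta[i_theta]`` from the membrane apex
    direction.  A membrane lying on the sphere of radius R maps to a
    constant-radius sheet.
    """
    config = config or CurvatureConfig()
    n, a = vol.box, vol.voxel_size
    r_a = radius_nm * 10.0
    sign = 1.0 if center_side == "lumenal" else -1.0
    # apex direction is +z for a lumenal centre, -z for a cytoplasmic one
    cz = (membrane_z_a - sign * r_a) / a
    cx = cy = n / 2.0
    reach = (n / 2.0 - 2.0) * a
    if r_a < reach:
        warnings.warn(
            "candidate radius smaller than the box half-extent: shell leaves "
            "the box at large polar angles",
            stacklevel=2,
        )
    theta_max = np.arcsin(min(reach / r_a, 1.0))
    theta_min = np.arcsin(min(config.stem_exclusion_nm * 10.0 / r_a, 1.0))
    theta = np.arange(
        theta_min, theta_max, np.radians(config.polar_step_deg)
    )
    if len(theta) == 0:
        raise MembraneDetectionError(
            "stem exclusion and box reach leave no polar range at this radius"
        )
    phi = np.arange(0.0, 2 * np.pi, np.radians(config.azimuth_step_deg))
    win = config.search_window_a / a
    r_vox = np.arange(r_a / a - win, r_a / a + win, config.radial_step_vox)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), sign * np.cos(tt)]
    )  # (3, n_theta, n_phi)
    coords = (
        np.array([cx, cy, cz])[:, None, None, None]
        + r_vox[None, :, None, None] * dirs[:, None, :, :]
    )
    grid = ndimage.map_coordinates(
        vol.data.astype(np.float64), coords.reshape(3, -1), order=1, cval=0.0
    ).reshape(len(r_vox), len(theta), len(phi))
    return grid, r_vox, theta


def _lowest_band_centroids(
    profiles: np.ndarray, axis_values: np.ndarray, detect_fraction: float
) -> np.ndarray:
    """Centroid of the *lowest* strong density band of each column.

    ``profiles`` is (n_samples, n_columns) ordered from the lumenal side
    upward.  The membrane is the deepest band above the detection threshold;
    picking the global maximum instead would lock onto the receptor's
    cytoplasmic domain wherever it overhangs the membrane.  Returns NaN for
    columns without a band.
    """
    n_s, n_c = profiles.shape
    global_peak = profiles.max()
    out = np.full(n_c, np.nan)
    if global_peak <= 0:
        return out
    thresh = detect_fraction * global_peak
    above = profiles > thresh
    for j in range(n_c):
        idx = np.nonzero(above[:, j])[0]
        if idx.size == 0:
            continue
        # first contiguous run from the bottom
        stop = idx[0]
        while stop + 1 < n_s and above[stop + 1, j]:
            stop += 1
        run = slice(idx[0], stop + 1)
        band = profiles[run, j]
        w = np.clip(band - 0.5 * band.max(), 0.0, None)
        if w.sum() <= 0:
            continue
        out[j] = float((axis_values[run] * w).sum() / w.sum())
    return out


def _column_centroids(
    grid: np.ndarray, r_vox: np.ndarray, detect_fraction: float
) -> np.ndarray:
    """Per-column radial centroid of the membrane band (NaN = undetected)."""
    nr, nt, np_ = grid.shape
    cent = _lowest_band_centroids(grid.reshape(nr, -1), r_vox, detect_fraction)
    return cent.reshape(nt, np_)


def flatness_score(
    grid: np.ndarray,
    r_vox: np.ndarray,
    detect_fraction: float = 0.30,
    min_detected_fraction: float = 0.5,
) -> float:
    """Variance (voxels²) of the membrane radial centroid across angular
    columns; lower is flatter.  Raises when most columns lack a band."""
    cent = _column_centroids(grid, r_vox, detect_fraction)
    valid = np.isfinite(cent)
    if valid.mean() < min_detected_fraction:
        raise MembraneDetectionError(
            f"membrane band detected in only {valid.mean():.0%} of columns"
        )
    return float(np.var(cent[valid]))


def _flat_sheet_score(vol: DensityVolume, membrane_z_a: float, config: CurvatureConfig) -> float:
    """The R→∞ competitor: variance of the per-(x, y)-column z centroid of
    the membrane band, same units (voxels²) as the spherical score."""
    n, a = vol.box, vol.voxel_size
    idx = np.arange(n)
    x = (idx[:, None] - n / 2.0) * a
    y = (idx[None, :] - n / 2.0) * a
    rho = np.sqrt(x**2 + y**2)
    zmask = np.abs(idx * a - membrane_z_a) <= config.search_window_a
    sub = vol.data[:, :, zmask].astype(np.float64)
    z_vox = idx[zmask].astype(float)
    cols = (rho > config.stem_exclusion_nm * 10.0) & (rho < (n / 2 - 2) * a)
    flat = sub[cols, :].T  # (nz, n_cols), z ascending = lumenal side first
    if flat.max() <= 0:
        raise MembraneDetectionError("no density in the membrane window")
    cent = _lowest_band_centroids(flat, z_vox, config.detect_fraction)
    valid = np.isfinite(cent)
    if valid.mean() < config.min_detected_fraction:
        raise MembraneDetectionError("membrane band missing in most columns")
    return float(np.var(cent[valid]))


@dataclass
class CurvatureFit:
    """Flatness profile over candidate radii and the optimum.

    ``radius_nm`` is NaN and ``curvature_inv_nm`` 0 when the flat sheet wins.
    """

    radius_nm: float
    curvature_inv_nm: float
    scores: pd.DataFrame  # columns: radius_nm, score (NaN radius = flat)
    flat_score: float
    membrane_z_a: float
    center_side: str
    boundary_warning: bool = False
    is_flat: bool = False

    def summary(self) -> str:
        lines = [
            "Membrane curvature fit",
            "=" * 46,
            f"optimal radius (nm)      {'flat' if self.is_flat else f'{self.radius_nm:.1f}'}",
            f"curvature (1/nm)         {self.curvature_inv_nm:.4f}",
            f"membrane apex z (Å)      {self.membrane_z_a:.1f}",
            f"flat-sheet score         {self.flat_score:.3f} voxel²",
            f"centre side              {self.center_side}",
        ]
        if self.boundary_warning:
            lines.append("warning: optimum at the edge of the scanned radius grid")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sph = self.scores.dropna()
        ax.plot(sph["radius_nm"], sph["score"], "o-", ms=3)
        ax.axhline(self.flat_score, color="grey", ls="--", lw=0.8, label="flat sheet")
        if not self.is_flat:
            ax.axvline(self.radius_nm, color="crimson", lw=0.8)
        ax.set_xlabel("candidate radius R (nm)")
        ax.set_ylabel("flatness score (voxel²)")
        ax.legend()
        return ax


class MembraneCurvatureModel:
    """Fit the membrane osculating-sphere radius of a density map.

    The flatness score is evaluated over a radius grid (default
    20–200 nm in 10 nm steps plus a flat-sheet sentinel), the apex height
    is refined jointly over a small window, and the best grid radius is
    polished by golden-section search to 1 nm.
    """

    def __init__(
        self,
        vol: DensityVolume,
        config: CurvatureConfig | None = None,
        center_side: str = "lumenal",
    ):
        self.config = config or CurvatureConfig()
        self.center_side = center_side
        if self.config.smooth_sigma_vox > 0:
            vol = vol.with_data(
                ndimage.gaussian_filter(
                    vol.data.astype(np.float64), self.config.smooth_sigma_vox
                )
            )
        self.vol = vol

    def _score(self, radius_nm: float, membrane_z_a: float) -> float:
        grid, r_vox, _ = spherical_resample(
            self.vol, radius_nm, membrane_z_a, self.config, self.center_side
        )
        return flatness_score(
            grid, r_vox, self.config.detect_fraction, self.config.min_detected_fraction
        )

    def _score_zopt(self, radius_nm: float, z_candidates: np.ndarray) -> tuple[float, float]:
        best = (np.inf, z_candidates[0])
        for z in z_candidates:
            try:
                s = self._score(radius_nm, z)
            except MembraneDetectionError:
                continue
            if s < best[0]:
                best = (s, z)
        return best

    def fit(self) -> CurvatureFit:
        cfg = self.config
        if cfg.membrane_z_a is not None:
            z0 = cfg.membrane_z_a
            z_cands = z0 + np.linspace(-cfg.z_refine_a, cfg.z_refine_a, 7)
        else:
            # pin the sphere-apex height first from an algebraic circle fit
            # to the membrane surface; the flatness scan then only needs a
            # small local z refinement
            try:
                z0, _ = estimate_apex(self.vol, cfg)
            except MembraneDetectionError:
                z0 = estimate_membrane_z(self.vol, cfg)
            z_cands = z0 + np.linspace(-6.0, 6.0, 5)
        radii = np.arange(cfg.r_min_nm, cfg.r_max_nm + 1e-9, cfg.r_step_nm)
        rows, zbest = [], {}
        for r in radii:
            s, zb = self._score_zopt(r, z_cands)
            if np.isfinite(s):
                rows.append((float(r), s))
                zbest[float(r)] = zb
        if not rows:
            raise MembraneDetectionError("no candidate radius produced a usable fit")
        flat_s = _flat_sheet_score(self.vol, z0, cfg)
        scanned = pd.DataFrame(rows, columns=["radius_nm", "score"])
        i_best = int(scanned["score"].idxmin())
        r_best = float(scanned.loc[i_best, "radius_nm"])
        boundary = i_best in (0, len(scanned) - 1)
        # golden-section polish between the neighbours of the grid optimum
        lo = float(scanned["radius_nm"].iloc[max(i_best - 1, 0)])
        hi = float(scanned["radius_nm"].iloc[min(i_best + 1, len(scanned) - 1)])
        z_r = zbest[r_best]

        def f(r):
            try:
                return self._score(r, z_r)
            except MembraneDetectionError:
                return np.inf

        invphi = (np.sqrt(5.0) - 1) / 2
        a_, b_ = lo, hi
        c_ = b_ - invphi * (b_ - a_)
        d_ = a_ + invphi * (b_ - a_)
        fc, fd = f(c_), f(d_)
        while b_ - a_ > 1.0:
            if fc < fd:
                b_, d_, fd = d_, c_, fc
                c_ = b_ - invphi * (b_ - a_)
                fc = f(c_)
            else:
                a_, c_, fc = c_, d_, fd
                d_ = a_ + invphi * (b_ - a_)
                fd = f(d_)
        r_ref = (a_ + b_) / 2
        s_ref = f(r_ref)
        if s_ref > scanned.loc[i_best, "score"]:
            r_ref, s_ref = r_best, float(scanned.loc[i_best, "score"])
        profile = pd.concat(
            [scanned, pd.DataFrame([(np.nan, flat_s)], columns=["radius_nm", "score"])],
            ignore_index=True,
        )
        if flat_s <= s_ref:
            return CurvatureFit(
                radius_nm=np.nan,
                curvature_inv_nm=0.0,
                scores=profile,
                flat_score=flat_s,
                membrane_z_a=z0,
                center_side=self.center_side,
                boundary_warning=False,
                is_flat=True,
            )
        if boundary:
            warnings.warn("flatness optimum at the radius-grid boundary", stacklevel=2)
        return CurvatureFit(
            radius_nm=float(r_ref),
            curvature_inv_nm=1.0 / float(r_ref),
            scores=profile,
            flat_score=flat_s,
            membrane_z_a=float(zbest[r_best]),
            center_side=self.center_side,
            boundary_warning=boundary,
        )


def fit_membrane_radius(
    vol: DensityVolume,
    config: CurvatureConfig | None = None,
    center_side: str = "lumenal",
) -> CurvatureFit:
    """Functional wrapper over :class:`MembraneCurvatureModel`."""
    return MembraneCurvatureModel(vol, config, center_side).fit()


@dataclass(frozen=True)
class PatchClassification:
    """Signed curvature of receptor-free membrane patches."""

    table: pd.DataFrame  # patch, radius_nm, signed_curvature_inv_nm, category
    fractions: dict[str, float]


def classify_membrane_patches(
    patches: list[DensityVolume], config: CurvatureConfig | None = None
) -> PatchClassification:
    """Classify membrane-only patches as concave / near-flat / convex.

    Both centre placements are fitted; the better-scoring side gives the
    sign (positive = centre on the cytoplasmic side = cytoplasm-concave).
    ``|R| > near_flat_nm`` and flat-sheet winners count as near-flat.
    """
    config = config or CurvatureConfig()
    rows = []
    for i, patch in enumerate(patches):
        fits = {}
        for side in ("lumenal", "cytoplasmic"):
            try:
                fits[side] = MembraneCurvatureModel(patch, config, side).fit()
            except MembraneDetectionError:
                continue
        if not fits:
            raise MembraneDetectionError(f"patch {i}: no membrane found")

        def best_score(fit):
            return fit.flat_score if fit.is_flat else fit.scores["score"].min()

        side = min(fits, key=lambda s: best_score(fits[s]))
        fit = fits[side]
        if fit.is_flat or fit.radius_nm > config.near_flat_nm:
            cat, curv = "near-flat", 0.0 if fit.is_flat else 1.0 / fit.radius_nm
        else:
            cat = "concave" if side == "cytoplasmic" else "convex"
            curv = 1.0 / fit.radius_nm
        signed = curv if side == "cytoplasmic" else -curv
        rows.append((i, fit.radius_nm, signed, cat))
    table = pd.DataFrame(
        rows, columns=["patch", "radius_nm", "signed_curvature_inv_nm", "category"]
    )
    counts = table["category"].value_counts()
    fractions = {
        c: float(counts.get(c, 0)) / len(table)
        for c in ("concave", "near-flat", "convex")
    }
    return PatchClassification(table, fractions)
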