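"""Fourier-space primitives: missing-wedge masks, band-pass filtering and
Fourier shell correlation.

All masks live on the *unshifted* FFT grid (DC at index ``[0, 0, 0]``),
matching ``scipy.fft.fftn`` output, and are Hermitian-symmetric so that
masked spectra invert to real volumes.

Geometry convention: the tilt axis is y and the electron beam is z.  A
single-axis tilt series spanning ``[tilt_min, tilt_max]`` degrees samples the
central sections whose normals are the beam rotated about y; the unsampled
region is the familiar missing wedge around the k_z axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .volume import DensityVolume, VolumeError, require_same_grid


class WedgeRangeError(ValueError):
    """Tilt range outside [-90, 90] or empty."""


class ResolutionError(ValueError):
    """Requested band limit beyond Nyquist."""


def _freq_axes(box: int):
    """Centered-at-DC frequency axes in cycles/voxel (unshifted layout)."""
    f = np.fft.fftfreq(box)
    return np.meshgrid(f, f, f, indexing="ij", sparse=True)


def radial_frequency_grid(box: int, voxel_size: float) -> np.ndarray:
    """|k| in 1/Å on the unshifted FFT grid."""
    fx, fy, fz = _freq_axes(box)
    return np.sqrt(fx**2 + fy**2 + fz**2) / voxel_size


def radial_shell_index(box: int) -> np.ndarray:
    """Integer Fourier-shell index (radius in Fourier voxels, rounded)."""
    fx, fy, fz = _freq_axes(box)
    r = np.sqrt(fx**2 + fy**2 + fz**2) * box
    return np.rint(r).astype(np.int64)


@dataclass(frozen=True)
class WedgeMask:
    """Fourier-space sampling mask of a limited single-axis tilt range.

    ``mask`` holds values in [0, 1] on the unshifted FFT grid; a hard mask is
    binary, ``softness`` > 0 applies a Gaussian edge of that width in Fourier
    voxels.
    """

    tilt_min: float
    tilt_max: float
    box: int
    softness: float
    mask: np.ndarray

    @property
    def retained_fraction(self) -> float:
        """Mean mask value over the Nyquist sphere (the corner voxels of the
        FFT cube lie beyond Nyquist and would bias a plain voxel count)."""
        ball = radial_frequency_grid(self.box, 1.0) <= 0.5
        return float(self.mask[ball].mean())

    def is_full(self) -> bool:
        return bool(np.all(self.mask >= 0.999))


def build_wedge_mask(
    box: int, tilt_min: float, tilt_max: float, softness: float = 1.0
) -> WedgeMask:
    """Build the missing-wedge mask for a tilt series covering
    ``[tilt_min, tilt_max]`` degrees about the y axis.

    A Fourier voxel with in-plane (k_x, k_z) direction is sampled by the tilt
    whose central section contains it; the retained set is the double wedge
    ``tilt_min <= -atan2(k_z, k_x) <= tilt_max`` (folded to (-90, 90] for
    Hermitian symmetry).  For a hard mask the retained fraction equals
    span/180.
    """
    if not (-90.0 <= tilt_min < tilt_max <= 90.0):
        raise WedgeRangeError(
            f"tilt range must satisfy -90 <= min < max <= 90, got [{tilt_min}, {tilt_max}]"
        )
    fx, fy, fz = _freq_axes(box)
    # tilt angle that samples this voxel; fold into (-90, 90]
    psi = np.degrees(np.arctan2(-fz, fx)) + 0.0 * fy
    psi = (psi + 90.0) % 180.0 - 90.0
    hard = ((psi >= tilt_min) & (psi <= tilt_max)).astype(np.float64)
    # voxels exactly on a wedge boundary plane (e.g. the grid diagonals at
    # ±45°) belong half to each side; full weight would bias the count
    on_edge = np.zeros(psi.shape, dtype=bool)
    for edge in (tilt_min, tilt_max):
        if abs(edge) < 90.0:  # a ±90° boundary is fully sampled, not shared
            on_edge |= np.isclose(psi, edge, atol=1e-9)
    hard[on_edge & (hard > 0)] = 0.5
    # the k_y axis (k_x = k_z = 0) is present in every tilt image
    hard[0, :, 0] = 1.0
    if softness > 0:
        # mask is periodic on the FFT grid, so wrap-mode smoothing is exact
        soft = ndimage.gaussian_filter(hard, sigma=softness, mode="wrap")
    else:
        soft = hard
    return WedgeMask(tilt_min, tilt_max, box, softness, soft)


def full_wedge(box: int) -> WedgeMask:
    """Fully sampled Fourier space (tilt range ±90°)."""
    return WedgeMask(-90.0, 90.0, box, 0.0, np.ones((box, box, box)))


def apply_wedge(vol: DensityVolume, wedge: WedgeMask) -> DensityVolume:
    """Filter a volume by a wedge mask: IFFT(mask * FFT(vol))."""
    if wedge.box != vol.box:
        raise VolumeError(f"wedge box {wedge.box} != volume box {vol.box}")
    spec = sp_fft.fftn(vol.data.astype(np.float64))
    out = sp_fft.ifftn(spec * wedge.mask).real
    return vol.with_data(out)


def bandpass_mask(
    box: int,
    voxel_size: float,
    low_res: float | None,
    high_res: float | None,
    edge_width: float = 2.0,
    edge_inside: bool = False,
) -> np.ndarray:
    """Radial band-pass mask in [0, 1] on the unshifted grid.

    ``low_res``/``high_res`` are resolutions in Å (low_res > high_res); the
    edge is a raised cosine of ``edge_width`` Fourier voxels so total power
    can only decrease.  By default the roll-off starts *at* the cutoff
    (frequencies up to the cutoff pass untouched); ``edge_inside`` ends the
    roll-off at the cutoff instead, guaranteeing (numerically) zero power
    beyond it — the convention used for a hard frequency restriction.
    """
    if high_res is not None:
        if high_res < 2.0 * voxel_size:
            raise ResolutionError(
                f"high_res {high_res} Å is beyond Nyquist {2 * voxel_size} Å"
            )
        if low_res is not None and low_res <= high_res:
            raise ResolutionError("low_res must be a coarser resolution than high_res")
    r = radial_frequency_grid(box, voxel_size)  # 1/Å
    ew = edge_width / (box * voxel_size)  # Fourier-voxel width in 1/Å
    mask = np.ones_like(r)

    def _soft_step(x):  # 1 up to the cutoff, raised-cosine roll-off beyond
        t = np.clip(x / max(ew, 1e-12), 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))

    if high_res is not None:
        shift = ew if edge_inside else 0.0
        mask *= _soft_step(r - 1.0 / high_res + shift)
    if low_res is not None:
        mask *= 1.0 - _soft_step(r - 1.0 / low_res)
        mask[0, 0, 0] = 0.0
    return mask


def bandpass(
    vol: DensityVolume,
    low_res: float | None,
    high_res: float | None,
    edge_width: float = 2.0,
    edge_inside: bool = False,
) -> DensityVolume:
    """Soft radial band-pass filter between ``low_res`` and ``high_res`` (Å)."""
    mask = bandpass_mask(vol.box, vol.voxel_size, low_res, high_res, edge_width, edge_inside)
    spec = sp_fft.fftn(vol.data.astype(np.float64))
    return vol.with_data(sp_fft.ifftn(spec * mask).real)


@dataclass(frozen=True)
class FSCCurve:
    """Fourier shell correlation between two volumes.

    ``shell_frequencies`` are shell-centre spatial frequencies in 1/Å
    (strictly increasing, up to Nyquist); ``correlations`` the per-shell
    normalised cross-correlations; ``n_voxels_per_shell`` the shell sizes.
    """

    shell_frequencies: np.ndarray
    correlations: np.ndarray
    n_voxels_per_shell: np.ndarray


def fsc_curve(a: DensityVolume, b: DensityVolume, shell_width: int = 1) -> FSCCurve:
    """Per-shell normalised correlation of the Fourier coefficients of two
    volumes on the same grid.  Shells are ``shell_width`` Fourier voxels wide;
    an all-zero shell reports correlation 0.
    """
    require_same_grid(a, b)
    n = a.box
    fa = sp_fft.fftn(a.data.astype(np.float64))
    fb = sp_fft.fftn(b.data.astype(np.float64))
    shell = radial_shell_index(n) // int(shell_width)
    nshell = n // 2 // int(shell_width)
    keep = shell.ravel() <= nshell  # drop corner shells beyond Nyquist
    idx = shell.ravel()[keep]
    cross = np.bincount(
        idx, weights=(fa * np.conj(fb)).real.ravel()[keep], minlength=nshell + 1
    )
    pa = np.bincount(idx, weights=(np.abs(fa.ravel()) ** 2)[keep], minlength=nshell + 1)
    pb = np.bincount(idx, weights=(np.abs(fb.ravel()) ** 2)[keep], minlength=nshell + 1)
    counts = np.bincount(idx, minlength=nshell + 1)
    # shell 0 is DC; report shells 1..nshell
    sl = slice(1, nshell + 1)
    denom = np.sqrt(pa[sl] * pb[sl])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross[sl] / np.where(denom > 0, denom, 1.0), 0.0)
    freqs = (np.arange(1, nshell + 1) * shell_width + (shell_width - 1) / 2.0) / (
        n * a.voxel_size
    )
    return FSCCurve(freqs, np.clip(corr, -1.0, 1.0), counts[sl])


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = 0.143, voxel_size: float | None = None
) -> float:
    """Resolution (Å) where the FSC first drops below ``threshold``.

    The crossing frequency is linearly interpolated between shells.  A curve
    that never crosses reports the Nyquist resolution (2 * voxel_size, taken
    from the last shell when ``voxel_size`` is not given); a curve starting
    below the threshold reports 1/f of the first shell with a warning.
    """
    c = np.asarray(curve.correlations, dtype=float)
    f = np.asarray(curve.shell_frequencies, dtype=float)
    if c.size == 0:
        raise ValueError("empty FSC curve")
    if c[0] < threshold:
        warnings.warn(
            "FSC below threshold already in the lowest shell; resolution is "
            "worse than the first shell frequency",
            stacklevel=2,
        )
        return float(1.0 / f[0])
    below = np.nonzero(c < threshold)[0]
    if below.size == 0:
        if voxel_size is not None:
            return 2.0 * voxel_size
        return float(1.0 / f[-1])
    i = int(below[0])
    f_cross = f[i - 1] + (c[i - 1] - threshold) / (c[i - 1] - c[i]) * (f[i] - f[i - 1])
    return float(1.0 / f_cross)


def power(vol: DensityVolume) -> float:
    """Total variance-like power: mean squared deviation from the mean."""
    d = vol.data.astype(np.float64)
    return float(np.mean((d - d.mean()) ** 2))
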