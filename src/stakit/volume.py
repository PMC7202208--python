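"""Density volumes and real-space geometric primitives.

A :class:`DensityVolume` is a cubic voxel grid with a physical voxel size in
ångström — the common currency of every pipeline stage.  Orientations are
parameterised as intrinsic Z–X–Z Euler triplets in degrees (``tdrot``,
``tilt``, ``narot``), the convention used by subtomogram-averaging particle
tables, and applied about the geometric box centre (voxel ``N/2``, 0-based).

Array axis order is ``(x, y, z)``: ``data[ix, iy, iz]`` is the voxel at
physical position ``origin + voxel_size * (ix, iy, iz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


class VolumeError(ValueError):
    """Invalid volume geometry or incompatible volume pair."""


@dataclass(frozen=True)
class DensityVolume:
    """Real-valued cubic density grid.

    Parameters
    ----------
    data
        Cubic ``(N, N, N)`` array, axes ordered (x, y, z).  ``N`` must be
        even and at least 8.
    voxel_size
        Edge length of a voxel in Å.
    origin
        Physical coordinate (Å) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        object.__setattr__(self, "data", data)
        if data.ndim != 3 or len(set(data.shape)) != 1:
            raise VolumeError(f"volume must be cubic, got shape {data.shape}")
        n = data.shape[0]
        if n < 8 or n % 2:
            raise VolumeError(f"box size must be even and >= 8, got {n}")
        if not self.voxel_size > 0:
            raise VolumeError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(data)):
            raise VolumeError("volume contains non-finite values")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    @property
    def center(self) -> float:
        """Rotation centre in voxel units (index N/2, 0-based)."""
        return self.box / 2.0

    @property
    def nyquist_resolution(self) -> float:
        """Best representable resolution, 2 * voxel_size (Å)."""
        return 2.0 * self.voxel_size

    def with_data(self, data: np.ndarray) -> "DensityVolume":
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def physical_extent(self) -> float:
        """Box edge length in Å."""
        return self.box * self.voxel_size

    def background_level(self) -> float:
        """Mean of the one-voxel boundary shell — the local background used
        as the out-of-grid fill, so resampling adds neither mass nor edges."""
        d = self.data
        shell_sum = float(d.sum() - d[1:-1, 1:-1, 1:-1].sum())
        n = self.box
        return shell_sum / (n**3 - (n - 2) ** 3)


@dataclass(frozen=True)
class EulerTriplet:
    """Intrinsic Z–X–Z Euler angles in degrees (tdrot, tilt, narot)."""

    tdrot: float = 0.0
    tilt: float = 0.0
    narot: float = 0.0

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix R with v_rotated = R @ v."""
        return Rotation.from_euler(
            "ZXZ", [self.tdrot, self.tilt, self.narot], degrees=True
        ).as_matrix()

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "EulerTriplet":
        td, ti, na = Rotation.from_matrix(mat).as_euler("ZXZ", degrees=True)
        return cls(float(td), float(ti), float(na))

    def then(self, other: "EulerTriplet") -> "EulerTriplet":
        """Composition: apply ``self`` first, then ``other``."""
        return EulerTriplet.from_matrix(other.matrix() @ self.matrix())

    def inverse(self) -> "EulerTriplet":
        return EulerTriplet.from_matrix(self.matrix().T)

    def geodesic_to(self, other: "EulerTriplet", c4: bool = False) -> float:
        """Geodesic angular distance in degrees; with ``c4`` the distance is
        taken modulo the 4-fold rotation group about z."""
        r_self = self.matrix()
        best = np.inf
        ks = range(4) if c4 else (0,)
        for k in ks:
            rz = Rotation.from_euler("z", 90.0 * k, degrees=True).as_matrix()
            delta = r_self @ rz @ other.matrix().T
            cos = (np.trace(delta) - 1.0) / 2.0
            ang = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
            best = min(best, ang)
        return best

    def canonical_c4(self) -> "EulerTriplet":
        """Equivalent triplet with the template-frame spin folded into
        [0, 90) under C4.

        The matrix composes as Rz(tdrot)·Rx(tilt)·Rz(narot), so
        right-multiplying by a C4 symmetry rotation shifts ``narot``; at
        tilt ≈ 0 the two z angles merge and the fold applies to their sum.
        """
        if abs(self.tilt % 180.0) < 1e-9:
            return EulerTriplet((self.tdrot + self.narot) % 90.0, self.tilt, 0.0)
        return replace(self, narot=self.narot % 90.0)


IDENTITY = EulerTriplet()


def _affine_resample(
    data: np.ndarray, rot: np.ndarray, shift_vox: np.ndarray, cval: float
) -> np.ndarray:
    """out(x) = in(R^-1 (x - c - s) + c) with trilinear interpolation."""
    n = data.shape[0]
    c = np.full(3, n / 2.0)
    rinv = rot.T
    offset = c - rinv @ (c + shift_vox)
    return ndimage.affine_transform(
        data, rinv, offset=offset, order=1, mode="constant", cval=cval
    )


def rotate_shift(
    vol: DensityVolume,
    pose: EulerTriplet,
    shift: tuple[float, float, float] | np.ndarray = (0.0, 0.0, 0.0),
) -> DensityVolume:
    """Rotate a volume by ``pose`` about the box centre, then shift by
    ``shift`` (Å).

    Resampling is trilinear; samples falling outside the source grid take the
    volume's background level (boundary-shell mean) so no artificial
    low-frequency edge is introduced and compact content keeps its mass.
    """
    shift = np.asarray(shift, dtype=float)
    if float(np.linalg.norm(shift)) >= vol.box * vol.voxel_size / 2.0:
        raise VolumeError("shift magnitude exceeds half the box extent")
    if pose == IDENTITY and not shift.any():
        return vol
    out = _affine_resample(
        vol.data.astype(np.float64),
        pose.matrix(),
        shift / vol.voxel_size,
        cval=vol.background_level(),
    )
    return vol.with_data(out)


def unrotate_unshift(vol: DensityVolume, pose: EulerTriplet, shift) -> DensityVolume:
    """Exact inverse of :func:`rotate_shift` for the same (pose, shift)."""
    shift = np.asarray(shift, dtype=float)
    inv_pose = pose.inverse()
    inv_shift = -(inv_pose.matrix() @ shift)
    return rotate_shift(vol, inv_pose, inv_shift)


def symmetrize_c4(vol: DensityVolume) -> DensityVolume:
    """Impose 4-fold rotational symmetry about the box-centre z axis.

    Returns the mean over in-plane rotations {0°, 90°, 180°, 270°}.  The 90°
    rotations are exact index permutations whenever density is clear of the
    first row/column (index 0 has no partner under rotation about voxel N/2);
    trilinear resampling handles the general case identically because a 90°
    rotation lands on grid points.
    """
    data = vol.data.astype(np.float64)
    acc = data.copy()
    c = np.full(3, vol.box / 2.0)
    for k in (1, 2, 3):
        rot = Rotation.from_euler("z", 90.0 * k, degrees=True).as_matrix()
        # periodic boundaries make a 90° rotation about voxel N/2 an exact
        # grid permutation (index N/2 wraps to its partner at index 0)
        acc += ndimage.affine_transform(
            data, rot.T, offset=c - rot.T @ c, order=1, mode="grid-wrap"
        )
    return vol.with_data(acc / 4.0)


def require_same_grid(a: DensityVolume, b: DensityVolume) -> None:
    if a.box != b.box:
        raise VolumeError(f"box mismatch: {a.box} vs {b.box}")
    if not np.isclose(a.voxel_size, b.voxel_size, rtol=1e-6):
        raise VolumeError(f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}")
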