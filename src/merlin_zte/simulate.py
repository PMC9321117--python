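"""Synthetic segmented ZTE acquisitions under piecewise-constant rigid motion.

The simulator provides ground truth for every downstream stage.  Motion is
injected *in k-space*: for a segment during which the head pose (relative to
the reference position) is the rigid transform ``T = (R, delta)``, the
acquired sample at nominal coordinate ``k`` equals the static object's
spectrum evaluated at the rotated coordinate ``R^T k`` times the phase ramp
``exp(-i 2 pi k . delta / FOV)``.  This is the exact k-space image of the
moved object (rotation theorem + Fourier shift theorem), involves no image
interpolation, and is by construction the inverse of the retrospective
correction applied by the moco stage — giving round-trip tests a
machine-precision oracle.

Image-domain resampling (:func:`apply_rigid_image`) exists only to build
reference images for comparison, never to generate data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .nufft import NufftOperator
from .trajectory import KSpaceSamples

__all__ = [
    "Image3D",
    "CoilMaps",
    "RigidTransform",
    "MotionTrace",
    "RawData",
    "shepp_logan_3d",
    "synth_coil_maps",
    "apply_rigid_image",
    "simulate_acquisition",
    "motion_paradigm",
]


@dataclass
class Image3D:
    """Cubic voxel volume with isotropic spacing, center-of-volume origin.

    Voxel ``(N/2, N/2, N/2)`` sits at the physical center; axes are aligned
    with the scanner frame.  Voxels may be real or complex.
    """

    voxels: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ConfigurationError(f"Image3D must be cubic, got shape {v.shape}")
        self.voxels = v

    @property
    def mat(self) -> int:
        return self.voxels.shape[0]

    @property
    def fov_mm(self) -> float:
        return self.mat * self.spacing_mm

    def magnitude(self) -> np.ndarray:
        return np.abs(self.voxels)


@dataclass
class CoilMaps:
    """Per-channel complex receive sensitivities on the image grid."""

    maps: np.ndarray  # (C, N, N, N) complex
    spacing_mm: float

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def mat(self) -> int:
        return self.maps.shape[1]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


class RigidTransform:
    """Centered rotation followed by a translation, ``T(p) = R p + delta``.

    ``p`` and ``delta`` are in mm relative to the image center.  The rotation
    is composed intrinsically as ``R = Rz(az) @ Ry(ay) @ Rx(ax)``; only the
    matrix form is exchanged between modules, the angle decomposition is a
    reporting convention.
    """

    __slots__ = ("matrix", "translation_mm")

    def __init__(self, matrix: Optional[np.ndarray] = None, translation_mm: Optional[np.ndarray] = None):
        self.matrix = np.eye(3) if matrix is None else np.asarray(matrix, dtype=np.float64)
        self.translation_mm = (
            np.zeros(3) if translation_mm is None else np.asarray(translation_mm, dtype=np.float64)
        )
        err = np.abs(self.matrix @ self.matrix.T - np.eye(3)).max()
        if err > 1e-8 or np.linalg.det(self.matrix) < 0:
            raise ConfigurationError("rotation matrix must be orthogonal with det +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_angles(
        cls,
        angles_deg: Sequence[float] = (0.0, 0.0, 0.0),
        translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        ax, ay, az = np.radians(angles_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation_mm, dtype=np.float64))

    @property
    def angles_deg(self) -> np.ndarray:
        """Euler angles ``(ax, ay, az)`` of the Rz@Ry@Rx decomposition."""
        r = self.matrix
        ay = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
        return np.degrees([ax, ay, az])

    def inverse(self) -> "RigidTransform":
        rt = self.matrix.T
        return RigidTransform(rt, -rt @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation_mm + self.translation_mm,
        )

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return points_mm @ self.matrix.T + self.translation_mm

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.abs(self.matrix - np.eye(3)).max() <= tol
            and np.abs(self.translation_mm).max() <= tol
        )

    def __repr__(self) -> str:  # pragma: no cover
        a = ", ".join(f"{v:.3f}" for v in self.angles_deg)
        t = ", ".join(f"{v:.3f}" for v in self.translation_mm)
        return f"RigidTransform(angles_deg=({a}), translation_mm=({t}))"


@dataclass
class MotionTrace:
    """One head pose per acquisition segment, in acquisition order."""

    transforms: list[RigidTransform]
    start_times_s: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.transforms)

    def __getitem__(self, i: int) -> RigidTransform:
        return self.transforms[i]

    @classmethod
    def identity(cls, n_segments: int) -> "MotionTrace":
        return cls([RigidTransform.identity() for _ in range(n_segments)])

    @property
    def translations_mm(self) -> np.ndarray:
        return np.array([t.translation_mm for t in self.transforms])

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([t.angles_deg for t in self.transforms])

    def with_times(self, segment_duration_s: float) -> "MotionTrace":
        times = np.arange(len(self)) * segment_duration_s
        return MotionTrace(list(self.transforms), times)


@dataclass
class RawData:
    """Complex multi-channel k-space measurements, ``(C, n_spokes, n_readout)``.

    Deadtime-gap samples are stored as zero and excluded via the sample
    validity mask of the linked :class:`~merlin_zte.trajectory.KSpaceSamples`.
    """

    y: np.ndarray
    samples: KSpaceSamples
    noise_sd: float = 0.0
    seed: Optional[int] = None

    @property
    def n_channels(self) -> int:
        return self.y.shape[0]


# Modified 3D Shepp-Logan ellipsoids: (intensity, a, b, c, x0, y0, z0, phi_deg)
# Semi-axes and centers in [-1, 1] normalized coordinates; phi rotates about z.
_SHEPP_LOGAN = np.array(
    [
        [1.00, 0.6900, 0.920, 0.810, 0.00, 0.000, 0.00, 0],
        [-0.80, 0.6624, 0.874, 0.780, 0.00, -0.0184, 0.00, 0],
        [-0.20, 0.1100, 0.310, 0.220, 0.22, 0.000, 0.00, -18],
        [-0.20, 0.1600, 0.410, 0.280, -0.22, 0.000, 0.00, 18],
        [0.10, 0.2100, 0.250, 0.410, 0.00, 0.350, -0.15, 0],
        [0.10, 0.0460, 0.046, 0.050, 0.00, 0.100, 0.25, 0],
        [0.10, 0.0460, 0.046, 0.050, 0.00, -0.100, 0.25, 0],
        [0.10, 0.0460, 0.023, 0.050, -0.08, -0.605, 0.00, 0],
        [0.10, 0.0230, 0.023, 0.020, 0.00, -0.606, 0.00, 0],
        [0.10, 0.0230, 0.046, 0.020, 0.06, -0.605, 0.00, 0],
    ]
)


def shepp_logan_3d(mat: int, fov_mm: float = 192.0) -> Image3D:
    """Modified 3D Shepp-Logan ellipsoid phantom, intensities in [0, 1]."""
    if mat < 8:
        raise ConfigurationError(f"matrix size must be >= 8, got {mat}")
    n = (np.arange(mat) - mat / 2) / (mat / 2)
    x, y, z = np.meshgrid(n, n, n, indexing="ij")
    vol = np.zeros((mat, mat, mat))
    for inten, a, b, c, x0, y0, z0, phi in _SHEPP_LOGAN:
        p = np.radians(phi)
        xr = (x - x0) * np.cos(p) + (y - y0) * np.sin(p)
        yr = -(x - x0) * np.sin(p) + (y - y0) * np.cos(p)
        inside = (xr / a) ** 2 + (yr / b) ** 2 + ((z - z0) / c) ** 2 <= 1.0
        vol[inside] += inten
    return Image3D(np.clip(vol, 0.0, None), spacing_mm=fov_mm / mat)


def synth_coil_maps(mat: int, n_channels: int, fov_mm: float = 192.0) -> CoilMaps:
    """Smooth complex Gaussian-profile sensitivities, RSS-normalized to 1.

    Channel centers sit on a ring around the volume (alternating slightly
    above/below the axial midplane), emulating a receive array; each channel
    carries a gentle linear phase so the maps are genuinely complex.
    """
    if n_channels < 1:
        raise ConfigurationError("n_channels must be >= 1")
    n = (np.arange(mat) - mat / 2) / mat  # FOV-normalized [-0.5, 0.5)
    x, y, z = np.meshgrid(n, n, n, indexing="ij")
    maps = np.empty((n_channels, mat, mat, mat), dtype=np.complex128)
    sigma = 0.45
    for c in range(n_channels):
        ang = 2 * np.pi * c / n_channels
        cx, cy = 0.55 * np.cos(ang), 0.55 * np.sin(ang)
        cz = 0.25 if c % 2 else -0.25
        if n_channels == 1:
            cx = cy = cz = 0.0
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        mag = np.exp(-r2 / (2 * sigma**2))
        phase = 2 * np.pi * 0.3 * (np.cos(ang) * x + np.sin(ang) * y) + ang / 3.0
        if n_channels == 1:
            phase = np.zeros_like(x)
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return CoilMaps(maps=maps, spacing_mm=fov_mm / mat)


def apply_rigid_image(img: Image3D, transform: RigidTransform) -> Image3D:
    """Resample the image of an object moved by ``transform`` (linear interp).

    The output at physical point ``p`` equals the input at ``T^{-1}(p)``:
    material points are transported by ``T``.  Zero-filled outside.
    """
    n, sp = img.mat, img.spacing_mm
    inv = transform.inverse()
    c = np.full(3, n / 2.0)
    matrix = inv.matrix
    # index mapping: q_idx = R^T (idx - c) + c + t_inv / spacing
    offset = -matrix @ c + c + inv.translation_mm / sp

    def _warp(a: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(a, matrix, offset=offset, order=1, cval=0.0)

    v = img.voxels
    if np.iscomplexobj(v):
        out = _warp(v.real) + 1j * _warp(v.imag)
    else:
        out = _warp(v)
    return Image3D(out, spacing_mm=sp)


def simulate_acquisition(
    phantom: Image3D,
    maps: CoilMaps,
    samples: KSpaceSamples,
    trace: MotionTrace,
    noise_sd: float = 0.0,
    seed: int = 0,
    oversampling: float = 2.0,
    kernel_width: int = 6,
) -> RawData:
    """Forward-simulate multi-channel radial data under segment-wise motion.

    Defaults use a high-accuracy gridding kernel so the simulator is a
    trustworthy oracle for the reconstruction (which typically runs with a
    cheaper kernel).
    """
    if phantom.mat != maps.mat:
        raise ConfigurationError("phantom and coil maps must share the same grid")
    seg = samples.spokes.segment_index
    seg = np.where(seg < 0, 0, seg)
    n_seg = int(seg.max()) + 1
    if len(trace) < n_seg:
        raise ConfigurationError(
            f"motion trace has {len(trace)} transforms but the acquisition "
            f"spans {n_seg} segments"
        )
    mat = phantom.mat
    fov = phantom.fov_mm
    coil_imgs = maps.maps * phantom.voxels[None]
    nc = maps.n_channels
    ns, nr = samples.coords.shape[:2]
    y = np.zeros((nc, ns, nr), dtype=np.complex128)

    # The FFT grid depends only on the image, not on sample coordinates:
    # compute it once and reuse it for every segment's rotated coordinates.
    planner = NufftOperator(
        np.zeros((1, 3)), mat, oversampling=oversampling, kernel_width=kernel_width
    )
    grid_data = planner._to_grid(coil_imgs)

    for s in range(n_seg):
        spk = np.nonzero(seg == s)[0]
        if spk.size == 0:
            continue
        t = trace[s]
        k = samples.coords[spk].reshape(-1, 3)
        op = NufftOperator(
            k @ t.matrix, mat, oversampling=oversampling, kernel_width=kernel_width
        )  # rows are R^T k
        vals = op._interp @ grid_data.reshape(nc, -1).T  # (m, C)
        vals = vals.T.reshape(nc, spk.size, nr)
        phase = np.exp(-2j * np.pi * (k @ (t.translation_mm / fov))).reshape(spk.size, nr)
        y[:, spk, :] = vals * phase[None]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        y = y + noise * (noise_sd / np.sqrt(2.0))

    y[:, ~samples.valid] = 0.0
    return RawData(y=y, samples=samples, noise_sd=noise_sd, seed=seed)


_PARADIGMS = ("static", "step_rotation", "nodding", "continuous")


def motion_paradigm(
    name: str,
    amplitude_deg: float = 20.0,
    n_segments: int = 39,
    seed: int = 0,
    n_reference_segments: int = 3,
) -> MotionTrace:
    """Instructed-motion paradigms as piecewise-constant segment poses.

    ``static`` is all-identity; ``step_rotation`` makes abrupt axial (z)
    rotations up to exactly +-``amplitude_deg`` with small accompanying
    translations; ``nodding`` makes transient sagittal-plane (x) excursions
    that return to rest; ``continuous`` oscillates smoothly within the middle
    third of the scan.  Pose changes occur only at segment boundaries, and
    the first ``n_reference_segments`` (covering the reference navigator)
    are always identity.
    """
    if n_segments < 1:
        raise ConfigurationError("n_segments must be >= 1")
    if name not in _PARADIGMS:
        raise ConfigurationError(f"unknown paradigm {name!r}; choose from {_PARADIGMS}")
    rng = np.random.default_rng(seed)
    az = np.zeros(n_segments)
    ax = np.zeros(n_segments)
    trans = np.zeros((n_segments, 3))
    n0 = min(n_reference_segments, n_segments)

    if name == "step_rotation":
        n_steps = 4
        bounds = np.sort(rng.choice(np.arange(n0, n_segments), size=n_steps, replace=False))
        levels = rng.uniform(-1.0, 1.0, n_steps)
        levels *= amplitude_deg / np.abs(levels).max()
        for b, lv in zip(bounds, levels):
            az[b:] = lv
    elif name == "nodding":
        n_nods = 3
        starts = np.sort(rng.choice(np.arange(n0, max(n0 + 1, n_segments - 2)), size=min(n_nods, n_segments - n0), replace=False))
        for s0 in starts:
            dur = int(rng.integers(1, 3))
            ax[s0 : s0 + dur] = rng.uniform(0.4, 1.0) * amplitude_deg / 2.0
            trans[s0 : s0 + dur, 1] = rng.uniform(-1.0, 1.0) * amplitude_deg / 10.0
    elif name == "continuous":
        lo = max(n0, n_segments // 3)
        hi = min(n_segments, 2 * n_segments // 3 + 1)
        t = np.arange(lo, hi)
        if t.size:
            period = max(4.0, (hi - lo) / 3.0)
            osc = np.sin(2 * np.pi * (t - lo) / period)
            az[lo:hi] = 0.4 * amplitude_deg * osc
            trans[lo:hi, 0] = 0.15 * amplitude_deg * osc
    # static: all zeros

    transforms = [
        RigidTransform.from_angles((ax[s], 0.0, az[s]), trans[s]) for s in range(n_segments)
    ]
    for s in range(n0):
        transforms[s] = RigidTransform.identity()
    return MotionTrace(transforms)
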