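"""Interleaved 3D spiral-phyllotaxis ZTE trajectory design.

A silent ZTE acquisition reads one center-out radial spoke per repetition and
changes the gradient only slightly between repetitions.  The spoke directions
are arranged on a spiral phyllotaxis: azimuths advance by the golden angle
``phi_G = 360/g^2`` while the z-coordinate of the spoke tip sweeps linearly
from the north to the south pole (acos polar modulation, which yields uniform
sampling density for an isotropic field of view).  Subsampling the sequential
golden-angle set with a Fibonacci stride ``k = F(s)`` splits it into ``Ni``
smooth interleaves whose internal azimuthal step is ``360/g^s`` degrees — the
"smoothness factor" ``s`` therefore directly controls gradient switching and
thus acoustic noise.

The module also builds the companion WASPI spoke set (a short low-gradient
acquisition densely covering central k-space, used downstream for coil
sensitivity maps) and provides design diagnostics: spherical Voronoi cell
areas as a sampling-density measure and an angular-step surrogate for the
acoustic footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import SphericalVoronoi

from .errors import ConfigurationError, GeometryError

__all__ = [
    "GOLDEN_RATIO",
    "GOLDEN_ANGLE_DEG",
    "SequenceParams",
    "TrajectorySpec",
    "SpokeSet",
    "KSpaceSamples",
    "StepSummary",
    "fibonacci",
    "golden_constants",
    "azimuthal_increment_deg",
    "nyquist_spoke_count",
    "undersampling_factor",
    "make_phyllotaxis",
    "make_waspi",
    "sample_spokes",
    "partition_segments",
    "gradient_step_metric",
    "voronoi_density",
]

#: Golden ratio g = (1 + sqrt(5)) / 2 ~= 1.618.
GOLDEN_RATIO: float = (1.0 + np.sqrt(5.0)) / 2.0

#: Golden angle in degrees, 360 / g^2 ~= 137.5.
GOLDEN_ANGLE_DEG: float = 360.0 / GOLDEN_RATIO**2


def fibonacci(n: int) -> int:
    """Return the n-th Fibonacci number with F(1) = F(2) = 1."""
    if n < 1:
        raise ConfigurationError(f"Fibonacci index must be >= 1, got {n}")
    a, b = 1, 1
    for _ in range(n - 1):
        a, b = b, a + b
    return a


def golden_constants() -> tuple[float, float]:
    """Return ``(g, phi_G)``: the golden ratio and golden angle in degrees."""
    return GOLDEN_RATIO, GOLDEN_ANGLE_DEG


def azimuthal_increment_deg(s: int) -> float:
    """Azimuthal step within an interleaf, ``360 / g^s`` degrees.

    ``s`` is the smoothness factor: the interleaving stride is the s-th
    Fibonacci number, and the resulting within-interleaf azimuthal increment
    shrinks geometrically with ``s`` (e.g. 7.7 degrees for ``s=8``).
    """
    if s < 1:
        raise ConfigurationError(f"smoothness factor must be >= 1, got {s}")
    return 360.0 / GOLDEN_RATIO**s


def nyquist_spoke_count(mat: int) -> int:
    """Number of radial spokes for full Nyquist coverage, ``ceil(pi * mat^2)``."""
    return int(np.ceil(np.pi * mat**2))


def undersampling_factor(mat: int, nt: int) -> float:
    """Effective angular undersampling ``pi * mat^2 / nt`` of an ``nt``-spoke scan."""
    if nt < 1:
        raise ConfigurationError(f"spoke count must be >= 1, got {nt}")
    return np.pi * mat**2 / nt


@dataclass(frozen=True)
class SequenceParams:
    """Readout and timing parameters of a segmented ZTE acquisition.

    Parameters
    ----------
    fov_mm : isotropic field of view in mm.
    mat : isotropic matrix size (even).
    bw_khz : readout half-bandwidth in +-kHz.
    tr_ms : repetition time per spoke in ms.
    ti_ms : inversion time in ms (0 means native, non-prepared ZTE).
    fa_deg : excitation flip angle in degrees.
    n_readout : samples per spoke.
    gap_samples : deadtime-gap radius in samples (missing at the spoke start
        due to transmit-receive switching; 2-3 at +-31.25 kHz).
    spokes_per_segment : spokes acquired after each magnetization preparation.
    """

    fov_mm: float = 192.0
    mat: int = 64
    bw_khz: float = 31.25
    tr_ms: float = 1.8
    ti_ms: float = 0.0
    fa_deg: float = 3.0
    n_readout: int = 32
    gap_samples: int = 2
    spokes_per_segment: int = 384

    def __post_init__(self) -> None:
        if self.mat < 2 or self.mat % 2:
            raise ConfigurationError(f"matrix size must be even and >= 2, got {self.mat}")
        if not 0 <= self.gap_samples < self.n_readout:
            raise ConfigurationError(
                f"gap_samples must lie in [0, n_readout), got {self.gap_samples} "
                f"with n_readout={self.n_readout}"
            )
        if self.fov_mm <= 0 or self.tr_ms <= 0 or self.spokes_per_segment < 1:
            raise ConfigurationError("fov_mm, tr_ms must be positive; spokes_per_segment >= 1")

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.mat

    @property
    def segment_duration_s(self) -> float:
        """Wall time of one segment: TI delay plus its readout train."""
        return (self.ti_ms + self.spokes_per_segment * self.tr_ms) / 1000.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Geometry of an interleaved phyllotaxis trajectory plus its WASPI companion."""

    smoothness_s: int = 7
    n_spokes_per_interleaf: int = 384
    n_interleaves: int = 13
    waspi_scale: float = 0.125
    waspi_n_spokes: int = 512

    def __post_init__(self) -> None:
        if self.smoothness_s < 1:
            raise ConfigurationError("smoothness_s must be >= 1")
        if self.n_spokes_per_interleaf < 1 or self.n_interleaves < 1:
            raise ConfigurationError("interleaf dimensions must be >= 1")
        if self.n_spokes_per_interleaf * self.n_interleaves < 2:
            raise ConfigurationError("need at least 2 spokes in total")
        if not 0.0 < self.waspi_scale <= 1.0:
            raise ConfigurationError(f"waspi_scale must be in (0, 1], got {self.waspi_scale}")

    @property
    def subsample_k(self) -> int:
        """Fibonacci interleaving stride ``k = F(s)``."""
        return fibonacci(self.smoothness_s)

    @property
    def n_total(self) -> int:
        return self.n_spokes_per_interleaf * self.n_interleaves


@dataclass
class SpokeSet:
    """Ordered unit spoke directions with interleaf/segment bookkeeping.

    ``directions`` is ``(n, 3)`` in acquisition order (interleaf-major).
    ``segment_index`` is -1 until :func:`partition_segments` assigns it.
    """

    directions: np.ndarray
    interleaf_index: np.ndarray
    within_interleaf_index: np.ndarray
    is_waspi: np.ndarray
    segment_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    spec: Optional[TrajectorySpec] = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=np.float64)
        if self.segment_index is None:
            self.segment_index = np.full(len(self.directions), -1, dtype=np.int64)

    @property
    def n_spokes(self) -> int:
        return len(self.directions)

    @property
    def z(self) -> np.ndarray:
        return self.directions[:, 2]

    @property
    def azimuth_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.directions[:, 1], self.directions[:, 0]))

    @property
    def polar_deg(self) -> np.ndarray:
        return np.degrees(np.arccos(np.clip(self.z, -1.0, 1.0)))

    @property
    def n_segments(self) -> int:
        return 0 if self.segment_index.max(initial=-1) < 0 else int(self.segment_index.max()) + 1


def make_phyllotaxis(spec: TrajectorySpec) -> SpokeSet:
    """Build the interleaved phyllotaxis spoke set in acquisition order.

    Spoke ``i`` of interleaf ``j`` has azimuth ``(i*k + j) * phi_G`` and
    ``z = 1 - (i*Ni + j) * dz`` with ``dz = 2/(Ns*Ni - 1)``, so the first and
    last spokes sit exactly on the north and south pole and the union of all
    interleaves, re-sorted by z, is the sequential golden-angle set.
    """
    ns, ni = spec.n_spokes_per_interleaf, spec.n_interleaves
    k = spec.subsample_k
    i = np.arange(ns)[None, :]  # within-interleaf index
    j = np.arange(ni)[:, None]  # interleaf index (outer loop)
    phi = np.radians((i * k + j) * GOLDEN_ANGLE_DEG)
    dz = 2.0 / (ns * ni - 1)
    z = 1.0 - (i * ni + j) * dz
    z = np.clip(z, -1.0, 1.0)
    sin_theta = np.sqrt(1.0 - z**2)
    directions = np.stack(
        [np.cos(phi) * sin_theta, np.sin(phi) * sin_theta, np.broadcast_to(z, phi.shape)],
        axis=-1,
    ).reshape(-1, 3)
    return SpokeSet(
        directions=directions,
        interleaf_index=np.repeat(np.arange(ni), ns),
        within_interleaf_index=np.tile(np.arange(ns), ni),
        is_waspi=np.zeros(ns * ni, dtype=bool),
        spec=spec,
    )


def make_waspi(spec: TrajectorySpec) -> SpokeSet:
    """Build the WASPI spoke set: a near-uniform spherical Fibonacci lattice.

    The WASPI pre-scan runs at reduced gradient amplitude (``waspi_scale`` of
    the nominal, 0.125 by default) and therefore only covers central k-space;
    its directions need not be smooth, just uniform.
    """
    n = spec.waspi_n_spokes
    if n < 4:
        raise ConfigurationError(f"waspi_n_spokes must be >= 4, got {n}")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.radians(i * GOLDEN_ANGLE_DEG)
    sin_theta = np.sqrt(1.0 - z**2)
    directions = np.stack([np.cos(phi) * sin_theta, np.sin(phi) * sin_theta, z], axis=-1)
    return SpokeSet(
        directions=directions,
        interleaf_index=np.zeros(n, dtype=np.int64),
        within_interleaf_index=i,
        is_waspi=np.ones(n, dtype=bool),
        spec=spec,
    )


@dataclass
class KSpaceSamples:
    """Per-sample k-space coordinates of a spoke set, in cycles per FOV.

    ``coords`` has shape ``(n_spokes, n_readout, 3)``; sample ``r`` of spoke
    ``d`` sits at ``radius(r) * d`` with the outermost sample on the Nyquist
    shell ``|k| = mat/2`` (scaled by ``waspi_scale`` for WASPI spokes).
    ``valid`` is False inside the deadtime gap.
    """

    coords: np.ndarray
    valid: np.ndarray
    spokes: SpokeSet
    seq: SequenceParams

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_readout(self) -> int:
        return self.coords.shape[1]

    @property
    def radius_index(self) -> np.ndarray:
        return np.broadcast_to(np.arange(self.n_readout), self.coords.shape[:2])

    def flat_coords(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Return coordinates as ``(m, 3)``, optionally restricted to a mask."""
        if mask is None:
            return self.coords.reshape(-1, 3)
        return self.coords[mask]

    def select_spokes(self, spoke_mask: np.ndarray) -> "KSpaceSamples":
        """Restrict to a subset of spokes, keeping bookkeeping consistent."""
        sp = self.spokes
        sub_spokes = SpokeSet(
            directions=sp.directions[spoke_mask],
            interleaf_index=sp.interleaf_index[spoke_mask],
            within_interleaf_index=sp.within_interleaf_index[spoke_mask],
            is_waspi=sp.is_waspi[spoke_mask],
            segment_index=sp.segment_index[spoke_mask],
            spec=sp.spec,
        )
        return KSpaceSamples(
            coords=self.coords[spoke_mask],
            valid=self.valid[spoke_mask],
            spokes=sub_spokes,
            seq=self.seq,
        )


def sample_spokes(spokes: SpokeSet, seq: SequenceParams) -> KSpaceSamples:
    """Place readout samples along each spoke and mask the deadtime gap.

    The gap is set by the transmit-receive switching time, so the same
    number of initial *samples* is lost on every spoke regardless of
    gradient amplitude.  WASPI spokes advance through k-space at
    ``waspi_scale`` of the nominal rate, so their absolute k-space hole is
    ``waspi_scale`` times smaller — which is what lets the WASPI data cover
    the central region the nominal-gradient spokes miss.
    """
    nr, gap = seq.n_readout, seq.gap_samples
    if nr < gap + 2:
        raise ConfigurationError(f"n_readout={nr} must be >= gap_samples+2={gap + 2}")
    scale = np.where(spokes.is_waspi, _waspi_scale(spokes), 1.0)
    r = np.arange(nr, dtype=np.float64)
    k_step = (seq.mat / 2.0) / (nr - 1)  # nominal k advance per sample
    radius = r[None, :] * k_step * scale[:, None]
    coords = radius[..., None] * spokes.directions[:, None, :]
    valid = np.broadcast_to(np.arange(nr) >= gap, radius.shape).copy()
    return KSpaceSamples(coords=coords, valid=valid, spokes=spokes, seq=seq)


def _waspi_scale(spokes: SpokeSet) -> float:
    if spokes.spec is None:
        return 0.125
    return spokes.spec.waspi_scale


def partition_segments(spokes: SpokeSet, spokes_per_segment: int) -> SpokeSet:
    """Assign each spoke to an acquisition segment.

    Each interleaf is split into ``Nseg = Ns / spokes_per_segment`` contiguous
    segments; the segment index increases monotonically in acquisition order
    across the whole scan.
    """
    within = spokes.within_interleaf_index
    ns = int(within.max()) + 1
    if ns % spokes_per_segment:
        raise ConfigurationError(
            f"spokes_per_segment={spokes_per_segment} does not divide the "
            f"interleaf length Ns={ns}"
        )
    nseg = ns // spokes_per_segment
    segment = spokes.interleaf_index * nseg + within // spokes_per_segment
    return replace(spokes, segment_index=segment.astype(np.int64))


@dataclass(frozen=True)
class StepSummary:
    """Great-circle angular steps between consecutive spokes, in degrees."""

    within_deg: np.ndarray
    boundary_deg: np.ndarray

    @property
    def mean_within(self) -> float:
        return float(np.mean(self.within_deg)) if self.within_deg.size else float("nan")

    @property
    def max_within(self) -> float:
        return float(np.max(self.within_deg)) if self.within_deg.size else float("nan")

    @property
    def mean_boundary(self) -> float:
        return float(np.mean(self.boundary_deg)) if self.boundary_deg.size else float("nan")


def gradient_step_metric(spokes: SpokeSet) -> StepSummary:
    """Angular step between consecutive spokes — a surrogate acoustic metric.

    Gradient switching (and hence acoustic noise) scales with the directional
    change between successive spokes.  Interleaf-boundary transitions are
    reported separately because the scanner ramps gradients down and up again
    between segments, keeping those transitions silent regardless of size.
    """
    if spokes.n_spokes < 2:
        return StepSummary(np.empty(0), np.empty(0))
    d = spokes.directions
    dots = np.clip(np.sum(d[:-1] * d[1:], axis=1), -1.0, 1.0)
    steps = np.degrees(np.arccos(dots))
    boundary = spokes.interleaf_index[:-1] != spokes.interleaf_index[1:]
    return StepSummary(within_deg=steps[~boundary], boundary_deg=steps[boundary])


def voronoi_density(spokes: SpokeSet) -> np.ndarray:
    """Spherical Voronoi cell area (solid angle) per spoke direction.

    The areas partition the sphere (they sum to ``4*pi``); their coefficient
    of variation measures how uniformly the trajectory samples angular
    k-space.
    """
    pts = spokes.directions
    if len(pts) < 4:
        raise GeometryError("need at least 4 spokes for a spherical Voronoi diagram")
    try:
        sv = SphericalVoronoi(pts, radius=1.0, threshold=1e-9)
        return sv.calculate_areas()
    except ValueError as exc:  # coplanar / duplicate input
        raise GeometryError(f"degenerate spoke geometry: {exc}") from exc
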