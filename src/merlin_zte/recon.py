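"""Non-Cartesian reconstruction: density compensation, coil maps, cgSENSE.

The reconstruction solves the coil-sensitivity-weighted least-squares problem

    argmin_x  sum_c || W^1/2 (F S_c x - y_c) ||^2 + lambda ||x||^2

by conjugate gradients on the normal equations ``(A^H W A + lambda I) x =
A^H W y``, where ``F`` is the gridding NUFFT restricted to valid (non-gap)
samples, ``S_c`` the coil sensitivities and ``W`` the Pipe sample-density
weights.  Because the deadtime-gap samples are simply absent from the data
term (not zero-filled), the regularized solution extrapolates the k-space
center — the implicit gap filling that makes navigator images usable without
re-acquiring low frequencies.

Sensitivity maps come from the WASPI pre-scan alone: each channel's gridded
low-resolution image divided by the root-sum-of-squares combination, with a
Hann apodization over the WASPI k-radius to suppress ringing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .nufft import NufftOperator
from .simulate import CoilMaps, Image3D, RawData
from .trajectory import KSpaceSamples

__all__ = [
    "ReconParams",
    "DensityWeights",
    "pipe_density_weights",
    "estimate_sens_maps",
    "cg_sense",
    "CgInfo",
    "SenseOperator",
    "truncate_to_resolution",
]


@dataclass(frozen=True)
class ReconParams:
    """Settings of the iterative reconstruction.

    ``lambda_tikhonov`` may be an absolute value or None, in which case it is
    set to ``lambda_rel`` times a power-iteration estimate of the largest
    eigenvalue of the normal operator (so regularization strength is
    independent of data scaling and sample count).
    """

    lambda_tikhonov: Optional[float] = None
    lambda_rel: float = 1e-2
    n_cg_iter: int = 12
    cg_tolerance: float = 1e-6
    grid_oversampling: float = 1.25
    kernel_width: int = 4
    n_pipe_iter: int = 40
    pipe_tolerance: float = 1e-3
    target_resolution_mm: float = 3.0
    n_power_iter: int = 10
    single_precision: bool = True

    def __post_init__(self) -> None:
        if self.lambda_tikhonov is not None and self.lambda_tikhonov < 0:
            raise ConfigurationError("lambda_tikhonov must be >= 0")
        if self.n_cg_iter < 1:
            raise ConfigurationError("n_cg_iter must be >= 1")
        if self.grid_oversampling < 1.25:
            raise ConfigurationError("grid_oversampling must be >= 1.25")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.complex64 if self.single_precision else np.complex128)


@dataclass
class DensityWeights:
    """Non-negative Pipe sample-density weights, one per valid sample."""

    weights: np.ndarray
    converged: bool
    n_iter: int


def pipe_density_weights(
    coords: np.ndarray,
    mat: int,
    params: ReconParams = ReconParams(),
    operator: Optional[NufftOperator] = None,
) -> DensityWeights:
    """Iterative sample-density compensation (fixed point of w / (w (*) psf)).

    Each weight is divided by the kernel-convolved weight field evaluated at
    the sample itself, normalized so an isolated sample keeps weight 1; the
    fixed point flattens the gridded point-spread function.  Converged when
    the largest relative update drops below ``pipe_tolerance``.
    """
    coords = np.atleast_2d(coords)
    if coords.shape[0] < 1:
        raise ConfigurationError("need at least one sample")
    op = operator or NufftOperator(
        coords, mat, params.grid_oversampling, params.kernel_width, dtype=np.complex128
    )
    p = op._interp
    pt = op._interp_t
    row_norm = np.asarray(p.multiply(p).sum(axis=1)).ravel()  # isolated-sample response
    w = np.ones(p.shape[0])
    n_done = params.n_pipe_iter
    converged = False
    for it in range(params.n_pipe_iter):
        denom = (p @ (pt @ w)) / row_norm
        w_new = w / np.maximum(denom, 1e-30)
        update = np.abs(w_new - w).max() / max(w.max(), 1e-30)
        w = w_new
        if update < params.pipe_tolerance:
            converged, n_done = True, it + 1
            break
    if not converged:
        warnings.warn(
            f"Pipe density iteration did not reach tolerance "
            f"{params.pipe_tolerance} in {params.n_pipe_iter} iterations",
            stacklevel=2,
        )
    return DensityWeights(weights=w, converged=converged, n_iter=n_done)


def estimate_sens_maps(
    waspi_raw: RawData,
    waspi_samples: Optional[KSpaceSamples] = None,
    grid: Optional[int] = None,
    params: ReconParams = ReconParams(),
) -> CoilMaps:
    """Coil sensitivity maps from the WASPI pre-scan (channel / RSS images).

    The WASPI data are gridded per channel onto the target grid with Pipe
    density weights and a Hann window over the WASPI k-radius (apodization
    against low-resolution ringing); dividing each channel image by the
    root-sum-of-squares combination cancels the object and leaves smooth
    maps with unit RSS everywhere.
    """
    samples = waspi_samples or waspi_raw.samples
    if not np.any(np.abs(waspi_raw.y) > 0):
        raise DegenerateInputError("WASPI data are identically zero")
    grid = grid or samples.seq.mat
    valid = samples.valid
    coords = samples.coords[valid]
    y = waspi_raw.y[:, valid]
    dw = pipe_density_weights(coords, grid, params)
    kr = np.linalg.norm(coords, axis=1)
    kmax = kr.max()
    apod = 0.5 * (1.0 + np.cos(np.pi * kr / kmax))
    op = NufftOperator(coords, grid, params.grid_oversampling, params.kernel_width, params.dtype)
    imgs = op.adjoint(y * (dw.weights * apod)[None])
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    maps = imgs / np.maximum(rss, 1e-12 * rss.max())[None]
    fov = samples.seq.fov_mm
    return CoilMaps(maps=maps.astype(np.complex128), spacing_mm=fov / grid)


class SenseOperator:
    """Per-channel map-weighted NUFFT ``A`` and its weighted normal operator."""

    def __init__(
        self,
        coords: Optional[np.ndarray],
        maps: CoilMaps,
        weights: np.ndarray,
        params: ReconParams = ReconParams(),
        operator: Optional[NufftOperator] = None,
    ) -> None:
        self.maps = maps.maps.astype(params.dtype)
        self.weights = weights.astype(np.float64)
        self.op = operator or NufftOperator(
            coords, maps.mat, params.grid_oversampling, params.kernel_width, params.dtype
        )
        self.params = params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Image -> per-channel samples, shape (C, M)."""
        return self.op.forward(self.maps * x[None])

    def adjoint_weighted(self, y: np.ndarray) -> np.ndarray:
        """Samples (C, M) -> image, applying W and combining channels."""
        imgs = self.op.adjoint(y * self.weights[None])
        return np.sum(np.conj(self.maps) * imgs, axis=0)

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint_weighted(self.forward(x))

    def max_eig(self, n_iter: int = 10, seed: int = 0) -> float:
        """Power-iteration estimate of the largest eigenvalue of A^H W A."""
        rng = np.random.default_rng(seed)
        n = self.maps.shape[1]
        x = (rng.standard_normal((n, n, n)) + 1j * rng.standard_normal((n, n, n))).astype(
            self.params.dtype
        )
        x /= np.linalg.norm(x)
        lam = 1.0
        for _ in range(n_iter):
            y = self.normal(x)
            lam = float(np.linalg.norm(y))
            x = y / max(lam, 1e-30)
        return lam


@dataclass
class CgInfo:
    """Convergence diagnostics of one conjugate-gradient solve."""

    residual_norms: np.ndarray
    objective: np.ndarray
    n_iter: int
    lambda_used: float
    converged: bool


def cg_sense(
    raw: RawData,
    samples: Optional[KSpaceSamples] = None,
    maps: Optional[CoilMaps] = None,
    params: ReconParams = ReconParams(),
    weights: Optional[np.ndarray] = None,
    return_info: bool = False,
    operator: Optional[NufftOperator] = None,
):
    """Tikhonov-regularized cgSENSE reconstruction of radial data.

    Only valid (non-gap) samples enter the data term; the k-space center is
    extrapolated by the regularized solution rather than zero-filled.
    Returns the complex :class:`Image3D` (optionally with :class:`CgInfo`).
    """
    samples = samples or raw.samples
    if maps is None:
        raise ConfigurationError("coil sensitivity maps are required")
    valid = samples.valid
    coords = None if operator is not None else samples.coords[valid]
    y = raw.y[:, valid]
    if weights is None:
        weights = pipe_density_weights(
            coords if coords is not None else samples.coords[valid], maps.mat, params
        ).weights
    A = SenseOperator(coords, maps, weights, params, operator=operator)
    lam = params.lambda_tikhonov
    if lam is None:
        lam = params.lambda_rel * A.max_eig(params.n_power_iter)

    b = A.adjoint_weighted(y.astype(params.dtype))
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.real(np.vdot(r, r)))
    b_norm = np.sqrt(float(np.real(np.vdot(b, b))))
    res_norms = [np.sqrt(rs)]
    objective = []
    tol2 = (params.cg_tolerance * b_norm) ** 2
    converged = False
    n_done = 0
    for it in range(params.n_cg_iter):
        ap = A.normal(p) + lam * p
        alpha = rs / float(np.real(np.vdot(p, ap)))
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.real(np.vdot(r, r)))
        res_norms.append(np.sqrt(rs_new))
        # quadratic objective 0.5 x^H M x - Re b^H x, strictly decreasing for CG
        objective.append(float(-0.5 * np.real(np.vdot(b + r, x))))
        n_done = it + 1
        if rs_new < tol2:
            converged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    img = Image3D(x, spacing_mm=maps.spacing_mm)
    info = CgInfo(
        residual_norms=np.array(res_norms),
        objective=np.array(objective),
        n_iter=n_done,
        lambda_used=float(lam),
        converged=converged,
    )
    return (img, info) if return_info else img


def truncate_to_resolution(
    samples: KSpaceSamples, raw: Optional[RawData], target_res_mm: float
):
    """Crop radial readouts to the k-radius of a coarser target resolution.

    Keeps samples with ``|k| <= fov / (2 * target_res)``; the matching
    reconstruction grid is ``fov / target_res`` voxels.  Returns
    ``(samples, raw, mat_target)`` with readouts shortened in place along the
    sample axis.
    """
    seq = samples.seq
    acquired_res = seq.fov_mm / seq.mat
    if target_res_mm < acquired_res - 1e-9:
        raise ConfigurationError(
            f"target resolution {target_res_mm} mm is finer than acquired "
            f"{acquired_res} mm"
        )
    kmax = seq.fov_mm / (2.0 * target_res_mm)
    mat_t = int(round(seq.fov_mm / target_res_mm / 2.0)) * 2
    radii = np.linalg.norm(samples.coords, axis=2).max(axis=0)  # per readout index
    n_keep = int(np.searchsorted(radii, kmax + 1e-9, side="right"))
    n_keep = max(n_keep, 2)
    if n_keep == samples.n_readout and mat_t == seq.mat:
        return samples, raw, seq.mat
    new_samples = KSpaceSamples(
        coords=samples.coords[:, :n_keep],
        valid=samples.valid[:, :n_keep],
        spokes=samples.spokes,
        seq=dc_replace(seq, mat=mat_t, n_readout=n_keep),
    )
    new_raw = None
    if raw is not None:
        new_raw = RawData(
            y=raw.y[:, :, :n_keep],
            samples=new_samples,
            noise_sd=raw.noise_sd,
            seed=raw.seed,
        )
    return new_samples, new_raw, mat_t
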