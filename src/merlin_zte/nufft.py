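"""Gridding non-uniform FFT for 3D radial reconstruction.

Implements the standard interpolation-based NUFFT: samples at arbitrary
k-space locations are related to an oversampled Cartesian FFT grid through a
compact Kaiser-Bessel interpolation kernel, with the kernel's analytic
Fourier transform divided out of the image (deapodization).  The forward
(type-2) transform evaluates

    s(k) = sum_n x[n] * exp(-i 2 pi k . (n - N/2) / N)

for k in cycles per FOV, i.e. the image is supported on FOV-normalized
coordinates [-0.5, 0.5) with the center voxel at index N/2.  The adjoint is
the exact conjugate transpose of the forward map, so the pair passes a
dot-product test to machine precision by construction of the sparse
interpolator.

Accuracy is controlled by the kernel width and grid oversampling factor:
width 4 at oversampling 1.25 gives ~1e-3 relative error (sufficient for
iterative reconstruction), width 8 at oversampling 2 reaches ~1e-9.

The interpolator is stored as a scipy CSR matrix so repeated applications
(CG iterations, multi-channel data) amortize the setup cost; columns of a
multi-channel right-hand side are transformed in a single sparse product.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as spfft
import scipy.sparse as sp

from .errors import GeometryError

__all__ = ["NufftOperator", "kaiser_bessel", "kaiser_bessel_ft"]


def _beatty_beta(width: int, oversampling: float) -> float:
    # Kernel shape parameter minimizing aliasing error for given width/oversampling.
    w, s = width, oversampling
    return np.pi * np.sqrt((w / s) ** 2 * (s - 0.5) ** 2 - 0.8)


def kaiser_bessel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel value at offset ``u`` grid cells from the center."""
    arg = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=np.float64)
    ok = arg > 0
    out[ok] = np.i0(beta * np.sqrt(arg[ok]))
    return out


def kaiser_bessel_ft(tau: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the kernel at frequency ``tau`` (cycles/cell)."""
    z2 = beta**2 - (np.pi * width * tau) ** 2
    z = np.sqrt(np.abs(z2).astype(np.float64))
    out = np.empty_like(z)
    pos = z2 > 0
    out[pos] = np.sinh(z[pos]) / z[pos]
    out[~pos] = np.sinc(z[~pos] / np.pi)
    return width * out


class NufftOperator:
    """Type-2/type-1 NUFFT between an ``N^3`` image and fixed sample locations.

    Parameters
    ----------
    coords : (M, 3) array
        Sample locations in cycles per FOV; each component must satisfy
        ``|k| <= N/2`` (the oversampled grid cannot represent more).
    mat : int
        Image matrix size N (isotropic).
    oversampling : float
        Grid oversampling factor sigma >= 1.25.
    kernel_width : int
        Interpolation kernel width in oversampled grid cells.
    dtype : complex dtype
        Working precision of the FFT grid and sparse interpolator.
    """

    def __init__(
        self,
        coords: np.ndarray,
        mat: int,
        oversampling: float = 1.25,
        kernel_width: int = 4,
        dtype: np.dtype = np.complex128,
    ) -> None:
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (M, 3), got {coords.shape}")
        if oversampling < 1.25:
            raise GeometryError("oversampling must be >= 1.25")
        limit = mat / 2 + 1e-9
        if coords.size and np.abs(coords).max() > limit:
            raise GeometryError(
                f"coordinate magnitude {np.abs(coords).max():.3f} exceeds the "
                f"representable range +-{mat / 2} cycles/FOV"
            )
        self.mat = int(mat)
        self.n_samples = coords.shape[0]
        self.dtype = np.dtype(dtype)
        real_dtype = np.float32 if self.dtype == np.complex64 else np.float64
        grid = int(np.ceil(mat * oversampling / 2.0)) * 2
        self.grid = grid
        self.width = int(kernel_width)
        self.beta = _beatty_beta(self.width, grid / mat)

        # Separable kernel weights and wrapped grid indices per axis.
        w = self.width
        g = coords * (grid / mat) + grid / 2  # position in oversampled grid units
        base = np.floor(g - w / 2.0).astype(np.int64) + 1  # support (g-w/2, g+w/2]
        offsets = np.arange(w)
        idx = base[:, :, None] + offsets  # (M, 3, w)
        u = idx - g[:, :, None]
        wts = kaiser_bessel(u, w, self.beta)  # (M, 3, w)
        idx %= grid

        m = self.n_samples
        vals = (wts[:, 0, :, None, None] * wts[:, 1, None, :, None] * wts[:, 2, None, None, :]).reshape(m, -1)
        flat = (
            idx[:, 0, :, None, None] * grid * grid
            + idx[:, 1, None, :, None] * grid
            + idx[:, 2, None, None, :]
        ).reshape(m, -1)
        rows = np.repeat(np.arange(m), w**3)
        self._interp = sp.csr_matrix(
            (vals.ravel().astype(real_dtype), (rows, flat.ravel())),
            shape=(m, grid**3),
        )
        self._interp_t = self._interp.T.tocsr()

        # Deapodization: divide out the kernel's image-domain profile.
        n = np.arange(mat) - mat / 2
        d1 = kaiser_bessel_ft(n / grid, w, self.beta)
        self._deapod = (d1[:, None, None] * d1[None, :, None] * d1[None, None, :]).astype(real_dtype)
        self._pad = (grid - mat) // 2

    @classmethod
    def stacked(cls, ops: "list[NufftOperator]") -> "NufftOperator":
        """Concatenate operators sharing one grid into a single operator.

        The sample axis of the result is the concatenation of the parts (in
        order); grid geometry, kernel and precision must match.  Used to
        assemble sliding-window operators from per-segment pieces without
        rebuilding the interpolator.
        """
        first = ops[0]
        if any(
            (o.mat, o.grid, o.width, o.dtype) != (first.mat, first.grid, first.width, first.dtype)
            for o in ops[1:]
        ):
            raise GeometryError("stacked operators must share grid, kernel and dtype")
        new = object.__new__(cls)
        new.mat = first.mat
        new.grid = first.grid
        new.width = first.width
        new.beta = first.beta
        new.dtype = first.dtype
        new._deapod = first._deapod
        new._pad = first._pad
        new._interp = sp.vstack([o._interp for o in ops], format="csr")
        new._interp_t = new._interp.T.tocsr()
        new.n_samples = new._interp.shape[0]
        return new

    # -- helpers -----------------------------------------------------------

    def _to_grid(self, img: np.ndarray) -> np.ndarray:
        """Deapodize, zero-pad and centered-FFT an (..., N, N, N) image."""
        n, g, p = self.mat, self.grid, self._pad
        x = np.asarray(img, dtype=self.dtype) / self._deapod
        shape = x.shape[:-3] + (g, g, g)
        pad = np.zeros(shape, dtype=self.dtype)
        pad[..., p : p + n, p : p + n, p : p + n] = x
        axes = (-3, -2, -1)
        return spfft.fftshift(spfft.fftn(spfft.ifftshift(pad, axes=axes), axes=axes), axes=axes)

    def _from_grid(self, grid_data: np.ndarray) -> np.ndarray:
        n, g, p = self.mat, self.grid, self._pad
        axes = (-3, -2, -1)
        x = spfft.fftshift(spfft.ifftn(spfft.ifftshift(grid_data, axes=axes), axes=axes), axes=axes)
        x = x[..., p : p + n, p : p + n, p : p + n] * (g**3)
        return x / self._deapod

    # -- public API --------------------------------------------------------

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Evaluate the image's Fourier transform at the sample locations.

        ``img`` may carry leading batch axes (e.g. coil channels); the
        result has shape ``batch + (n_samples,)``.
        """
        img = np.asarray(img)
        batch = img.shape[:-3]
        grid_data = self._to_grid(img).reshape(-1, self.grid**3)
        out = self._interp @ grid_data.T  # (M, B)
        return np.ascontiguousarray(out.T).reshape(batch + (self.n_samples,))

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (gridding reconstruction)."""
        samples = np.asarray(samples, dtype=self.dtype)
        batch = samples.shape[:-1]
        y = samples.reshape(-1, self.n_samples)
        grid_data = (self._interp_t @ y.T).T.reshape(batch + (self.grid,) * 3)
        return self._from_grid(grid_data)
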