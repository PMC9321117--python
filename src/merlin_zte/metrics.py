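"""Image-quality metrics: masked mSSIM and average edge strength (AES).

mSSIM compares a test volume against a reference within a mask (1 = perfect
agreement); with a static scan as reference it is expected to increase after
motion correction.  AES measures sharpness of a single volume — the mean
gradient magnitude over detected edge voxels — and decreases with motion
blur, so correction should raise it.  Both are evaluated only within an
object mask, as scanner-frame structures (headrest, coil housing) would
otherwise dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold
from skimage.metrics import structural_similarity

from .errors import ConfigurationError, DegenerateInputError
from .simulate import Image3D

__all__ = ["MetricsReport", "mssim", "aes", "aes_percent_change", "metrics_report"]

#: SSIM constants (standard choice).
SSIM_K1, SSIM_K2 = 0.01, 0.03
#: Gaussian window sigma for the local SSIM statistics.
SSIM_SIGMA = 1.5
#: Canny-style hysteresis thresholds, as fractions of the in-mask gradient range.
AES_LOW_FRAC, AES_HIGH_FRAC = 0.1, 0.2


def _as_magnitude(img) -> np.ndarray:
    if isinstance(img, Image3D):
        return img.magnitude()
    return np.abs(np.asarray(img))


def mssim(test, ref, mask: np.ndarray | None = None) -> float:
    """Mean structural similarity of ``test`` vs ``ref`` over ``mask``.

    The local SSIM map uses a 3D Gaussian window (sigma 1.5, 11 voxels wide)
    with K1=0.01, K2=0.03; the dynamic range is the reference's robust
    maximum (99.9th percentile) so single hot voxels cannot deflate the
    score.  Symmetric in its arguments apart from that range convention.
    """
    a, b = _as_magnitude(test), _as_magnitude(ref)
    if a.shape != b.shape:
        raise ConfigurationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    if not np.any(mask):
        raise DegenerateInputError("empty metric mask")
    data_range = float(np.percentile(b, 99.9))
    if data_range <= 0:
        raise DegenerateInputError("reference image has no positive dynamic range")
    _, ssim_map = structural_similarity(
        b,
        a,
        data_range=data_range,
        gaussian_weights=True,
        sigma=SSIM_SIGMA,
        use_sample_covariance=False,
        K1=SSIM_K1,
        K2=SSIM_K2,
        full=True,
    )
    return float(np.mean(ssim_map[mask]))


def aes(img, mask: np.ndarray | None = None, normalize: bool = True) -> float:
    """Average edge strength: mean gradient magnitude over edge voxels.

    Edges are found by hysteresis thresholding of the Sobel gradient
    magnitude at 0.1/0.2 of its in-mask range (a 3D analogue of the Canny
    criterion, without thinning).  With ``normalize`` the image is first
    divided by its mean in-mask intensity, making the score invariant to
    global scaling.  Returns 0 (with a warning) if no edges are detected.
    """
    v = _as_magnitude(img).astype(np.float64)
    if mask is None:
        mask = np.ones(v.shape, dtype=bool)
    if not np.any(mask):
        raise DegenerateInputError("empty metric mask")
    if normalize:
        mean = v[mask].mean()
        if mean > 0:
            v = v / mean
    grad = np.sqrt(sum(ndimage.sobel(v, axis=ax) ** 2 for ax in range(3)))
    g = grad * mask
    gmax = g.max()
    if gmax <= 0:
        warnings.warn("image is flat within the mask; AES = 0", stacklevel=2)
        return 0.0
    edges = apply_hysteresis_threshold(g, AES_LOW_FRAC * gmax, AES_HIGH_FRAC * gmax)
    edges &= mask
    if not np.any(edges):
        warnings.warn("no edges detected within the mask; AES = 0", stacklevel=2)
        return 0.0
    return float(grad[edges].mean())


def aes_percent_change(test, ref, mask: np.ndarray | None = None) -> float:
    """Percentage change in AES of ``test`` relative to ``ref``."""
    a_ref = aes(ref, mask)
    if a_ref <= 0:
        raise DegenerateInputError("reference AES is zero")
    return 100.0 * (aes(test, mask) - a_ref) / a_ref


@dataclass
class MetricsReport:
    """Bundle of quality metrics with the parameters that produced them."""

    mssim: float
    aes: float
    aes_reference: float
    aes_percent_change: float
    mask_voxels: int
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mssim": self.mssim,
            "aes": self.aes,
            "aes_reference": self.aes_reference,
            "aes_percent_change": self.aes_percent_change,
            "mask_voxels": self.mask_voxels,
            "parameters": self.parameters,
        }


def metrics_report(test, ref, mask: np.ndarray | None = None) -> MetricsReport:
    """Compute the full quality report of ``test`` against ``ref``."""
    a_ref = aes(ref, mask)
    a_test = aes(test, mask)
    pct = 100.0 * (a_test - a_ref) / a_ref if a_ref > 0 else float("nan")
    n_mask = int(np.count_nonzero(mask)) if mask is not None else int(np.prod(_as_magnitude(test).shape))
    return MetricsReport(
        mssim=mssim(test, ref, mask),
        aes=a_test,
        aes_reference=a_ref,
        aes_percent_change=pct,
        mask_voxels=n_mask,
        parameters={
            "ssim_sigma": SSIM_SIGMA,
            "ssim_k1": SSIM_K1,
            "ssim_k2": SSIM_K2,
            "aes_thresholds": [AES_LOW_FRAC, AES_HIGH_FRAC],
            "aes_normalized": True,
        },
    )
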