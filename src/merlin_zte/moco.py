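"""Self-navigated retrospective motion estimation and correction.

The correction loop: reconstruct low-resolution navigator images from a
sliding window of acquisition segments, rigidly register each navigator to
the first one (the reference position), assign each window's pose estimate
to its middle segment, and undo the motion in k-space — rotating each
segment's trajectory coordinates by the transpose of its pose rotation and
multiplying its data by the translation phase ramp — before a single final
reconstruction of the combined corrected data.

Pose convention: a trace transform ``T = (R, delta)`` is the head pose
relative to the reference, i.e. a material point at ``p`` (mm, centered)
has moved to ``R p + delta``.  The acquired sample at nominal coordinate
``k`` then equals the static spectrum at ``R^T k`` times
``exp(-i 2 pi k . delta / FOV)``; the correction below inverts exactly
that, and the registration (moving navigator onto the reference) returns
``T`` directly in the same convention.  A round-trip test against the
simulator, not this docstring, is the source of truth for the signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DegenerateInputError, MerlinError
from .nufft import NufftOperator
from .recon import ReconParams, cg_sense, estimate_sens_maps, pipe_density_weights, truncate_to_resolution
from .simulate import CoilMaps, Image3D, MotionTrace, RawData, RigidTransform
from .trajectory import KSpaceSamples

__all__ = [
    "NavigatorWindow",
    "MocoConfig",
    "MoCoResult",
    "sliding_windows",
    "reconstruct_navigators",
    "make_registration_mask",
    "register_rigid",
    "assign_to_segments",
    "correct_kspace",
    "merlin_pipeline",
    "detrend_trace",
    "trace_stats",
    "trace_spectrum",
    "TraceSpectrum",
]


@dataclass(frozen=True)
class NavigatorWindow:
    """A block of ``n_segments`` consecutive segments reconstructed together."""

    first_segment: int
    n_segments: int

    @property
    def segments(self) -> list[int]:
        return list(range(self.first_segment, self.first_segment + self.n_segments))

    @property
    def middle_segment(self) -> int:
        return self.first_segment + (self.n_segments - 1) // 2


def sliding_windows(n_interleaves: int, n_seg_per_interleaf: int) -> list[NavigatorWindow]:
    """All sliding navigator windows, stepping forward by one segment.

    A window spans one interleaf's worth of segments; stepping by a single
    segment yields ``(Ni - 1) * Nseg + 1`` windows over ``Ni * Nseg``
    segments.
    """
    if n_interleaves < 1 or n_seg_per_interleaf < 1:
        raise ConfigurationError("Ni and Nseg must be >= 1")
    n_win = (n_interleaves - 1) * n_seg_per_interleaf + 1
    return [NavigatorWindow(w, n_seg_per_interleaf) for w in range(n_win)]


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _to_sitk(img: Image3D) -> sitk.Image:
    """Magnitude image in physical coordinates with the volume center at 0."""
    mag = np.ascontiguousarray(img.magnitude().transpose(2, 1, 0).astype(np.float64))
    out = sitk.GetImageFromArray(mag)
    sp = float(img.spacing_mm)
    out.SetSpacing((sp, sp, sp))
    o = -img.mat / 2.0 * sp
    out.SetOrigin((o, o, o))
    return out


def make_registration_mask(reference_nav: Image3D, n_dilations: int = 2) -> np.ndarray:
    """Object mask for the registration metric.

    Otsu threshold on the magnitude, keep the largest connected component,
    fill holes, then dilate (twice by default, 3x3x3 structuring element) so
    the mask covers the object boundary but still excludes distant static
    structures such as a headrest.
    """
    mag = reference_nav.magnitude()
    if not np.any(mag > 0) or np.ptp(mag) == 0:
        raise DegenerateInputError("reference navigator is empty or flat")
    thr = threshold_otsu(mag)
    binary = mag > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise DegenerateInputError("no foreground found in reference navigator")
    largest = np.argmax(ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    if n_dilations:
        mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3)), iterations=n_dilations)
    return mask


@dataclass
class RegistrationDiagnostics:
    metric_value: float
    converged: bool
    n_iterations: int
    stop_description: str = ""


def register_rigid(
    moving: Image3D,
    fixed: Image3D,
    mask: Optional[np.ndarray] = None,
    initial: Optional[RigidTransform] = None,
    seed: int = 1,
) -> tuple[RigidTransform, RegistrationDiagnostics]:
    """Estimate the rigid pose mapping ``moving`` onto ``fixed``.

    Mattes mutual information evaluated within the fixed-image mask,
    two-level multi-resolution, regular-step gradient descent with physical
    shift scaling.  Deterministic for a fixed sampling seed.  Returns the
    head pose in this package's convention together with diagnostics; on
    non-convergence the best transform found is returned and flagged.
    """
    if moving.mat != fixed.mat or moving.spacing_mm != fixed.spacing_mm:
        raise ConfigurationError("moving and fixed images must share grid and spacing")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=150,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    if mask is not None:
        m = sitk.GetImageFromArray(np.ascontiguousarray(mask.transpose(2, 1, 0).astype(np.uint8)))
        m.CopyInformation(f_img)
        reg.SetMetricFixedMask(m)

    tx = sitk.Euler3DTransform()
    tx.SetComputeZYX(True)
    tx.SetCenter((0.0, 0.0, 0.0))
    if initial is not None:
        tx.SetMatrix(tuple(initial.matrix.ravel()))
        tx.SetTranslation(tuple(initial.translation_mm))
    reg.SetInitialTransform(tx, inPlace=True)

    try:
        reg.Execute(f_img, m_img)
        stop = reg.GetOptimizerStopConditionDescription()
        converged = "Maximum number of iterations" not in stop
        metric_value = float(reg.GetMetricValue())
        n_iter = int(reg.GetOptimizerIteration())
    except RuntimeError as exc:  # optimizer failure: keep best-found transform
        stop, converged, metric_value, n_iter = str(exc), False, float("nan"), 0
    matrix = np.array(tx.GetMatrix()).reshape(3, 3)
    translation = np.array(tx.GetTranslation())
    diag = RegistrationDiagnostics(
        metric_value=metric_value,
        converged=converged,
        n_iterations=n_iter,
        stop_description=stop,
    )
    return RigidTransform(matrix, translation), diag


# ---------------------------------------------------------------------------
# navigators, assignment, correction
# ---------------------------------------------------------------------------


def reconstruct_navigators(
    raw: RawData,
    samples: KSpaceSamples,
    windows: Sequence[NavigatorWindow],
    maps: CoilMaps,
    params: ReconParams = ReconParams(),
    weights: Optional[np.ndarray] = None,
    lambda_abs: Optional[float] = None,
) -> tuple[list[Image3D], list]:
    """One low-resolution cgSENSE image per sliding window.

    ``samples``/``raw`` must already be truncated to navigator resolution.
    The gridding interpolator is built once per segment and sliding windows
    reuse the segment blocks; all windows share the sampling-density
    weights and regularization weight calibrated on the first window (their
    radial geometry is identical — only the azimuthal pattern rotates), so
    the expensive setup runs once.
    """
    seg = samples.spokes.segment_index
    if seg.min() < 0:
        raise ConfigurationError("samples must carry segment indices (partition_segments)")
    p = params
    needed = sorted({s for w in windows for s in w.segments})
    seg_ops: dict[int, NufftOperator] = {}
    seg_y: dict[int, np.ndarray] = {}
    for s in needed:
        spk = seg == s
        if not np.any(spk):
            raise ConfigurationError(f"segment {s} selects no spokes")
        sub = samples.select_spokes(spk)
        coords = sub.coords[sub.valid]
        seg_ops[s] = NufftOperator(
            coords, maps.mat, p.grid_oversampling, p.kernel_width, p.dtype
        )
        seg_y[s] = raw.y[:, spk][:, sub.valid]

    navs: list[Image3D] = []
    infos = []
    from .recon import SenseOperator

    for w in windows:
        op = NufftOperator.stacked([seg_ops[s] for s in w.segments])
        y = np.concatenate([seg_y[s] for s in w.segments], axis=1)
        if weights is None:
            weights = pipe_density_weights(None, maps.mat, p, operator=op).weights
        if lambda_abs is None:
            A = SenseOperator(None, maps, weights, p, operator=op)
            lambda_abs = p.lambda_rel * A.max_eig(p.n_power_iter)
        flat_samples = KSpaceSamples(
            coords=np.zeros((1, y.shape[1], 3)),
            valid=np.ones((1, y.shape[1]), dtype=bool),
            spokes=samples.spokes,
            seq=samples.seq,
        )
        flat_raw = RawData(y=y[:, None, :], samples=flat_samples, noise_sd=raw.noise_sd, seed=raw.seed)
        img, info = cg_sense(
            flat_raw,
            samples=flat_samples,
            maps=maps,
            params=dc_replace(p, lambda_tikhonov=lambda_abs),
            weights=weights,
            return_info=True,
            operator=op,
        )
        navs.append(img)
        infos.append(info)
    return navs, infos


def assign_to_segments(
    windows: Sequence[NavigatorWindow],
    transforms: Sequence[RigidTransform],
    n_segments_total: int,
) -> MotionTrace:
    """Assign each window's pose to its middle segment.

    The window estimate represents the average position over the window, so
    it is attributed to the central segment.  Segments before the first
    middle (the not-motion-corrected start of the scan: dummies, WASPI and
    the reference region) keep the identity pose; segments after the last
    middle inherit the final estimate; any interior segment without a direct
    estimate takes the nearest one.
    """
    if len(windows) != len(transforms):
        raise ConfigurationError(
            f"got {len(transforms)} transforms for {len(windows)} windows"
        )
    out: list[Optional[RigidTransform]] = [None] * n_segments_total
    middles = []
    for w, t in zip(windows, transforms):
        if w.middle_segment >= n_segments_total:
            raise ConfigurationError("window middle exceeds segment count")
        out[w.middle_segment] = t
        middles.append(w.middle_segment)
    first, last = min(middles), max(middles)
    for s in range(first):
        out[s] = RigidTransform.identity()
    for s in range(last + 1, n_segments_total):
        out[s] = transforms[-1]
    for s in range(first, last + 1):
        if out[s] is None:  # nearest-neighbor fill (absent when the step is one segment)
            near = min(middles, key=lambda m: abs(m - s))
            out[s] = transforms[middles.index(near)]
    return MotionTrace(out)  # type: ignore[arg-type]


def correct_kspace(
    samples: KSpaceSamples, raw: RawData, trace: MotionTrace
) -> tuple[KSpaceSamples, RawData]:
    """Undo per-segment rigid motion on the trajectory and raw data.

    Rotation: each segment's coordinates become ``R^T k`` (sample radii are
    preserved; rotated samples may leave the original Nyquist ball and are
    kept — they carry valid high-frequency information).  Translation: the
    data gain the unit-magnitude phase ramp ``exp(+i 2 pi k . delta / FOV)``
    evaluated at the *acquired* coordinates.  An identity trace returns
    bitwise-identical output.
    """
    seg = samples.spokes.segment_index
    seg = np.where(seg < 0, 0, seg)
    if int(seg.max()) + 1 > len(trace):
        raise ConfigurationError(
            f"trace covers {len(trace)} segments, acquisition has {int(seg.max()) + 1}"
        )
    fov = samples.seq.fov_mm
    coords = samples.coords.copy()
    y = raw.y.copy()
    for s in np.unique(seg):
        t = trace[int(s)]
        if t.is_identity():
            continue
        spk = np.nonzero(seg == s)[0]
        k = samples.coords[spk]  # (n, nr, 3), acquired coordinates
        coords[spk] = k @ t.matrix  # rows become R^T k
        phase = np.exp(2j * np.pi * (k @ (t.translation_mm / fov)))
        y[:, spk, :] = y[:, spk, :] * phase[None]
    new_samples = KSpaceSamples(coords=coords, valid=samples.valid, spokes=samples.spokes, seq=samples.seq)
    new_raw = RawData(y=y, samples=new_samples, noise_sd=raw.noise_sd, seed=raw.seed)
    return new_samples, new_raw


# ---------------------------------------------------------------------------
# trace analysis
# ---------------------------------------------------------------------------


def _trace_params(trace: MotionTrace) -> np.ndarray:
    """(n_segments, 6) array: translations (mm) then rotation angles (deg)."""
    return np.hstack([trace.translations_mm, trace.angles_deg])


def detrend_trace(trace: MotionTrace, window: int = 51) -> MotionTrace:
    """Residual motion after subtracting a uniform moving average.

    Slow positional drift is removed by convolving each of the six motion
    parameters with a uniform window (reflect padding at the edges); the
    returned trace holds the residuals, suitable for stability statistics
    and frequency analysis.
    """
    n = len(trace)
    if window % 2 == 0 or window > n:
        raise ConfigurationError(
            f"detrend window must be odd and <= trace length, got {window} for {n} segments"
        )
    p = _trace_params(trace)
    pad = window // 2
    padded = np.pad(p, ((pad, pad), (0, 0)), mode="reflect")
    kernel = np.ones(window) / window
    smooth = np.stack([np.convolve(padded[:, i], kernel, mode="valid") for i in range(6)], axis=1)
    resid = p - smooth
    transforms = [
        RigidTransform.from_angles(resid[s, 3:], resid[s, :3]) for s in range(n)
    ]
    return MotionTrace(transforms, trace.start_times_s)


def trace_stats(trace: MotionTrace) -> dict[str, float]:
    """Mean and SD of the translation- and rotation-vector magnitudes."""
    if len(trace) < 1:
        raise ConfigurationError("trace must contain at least one segment")
    t_mag = np.linalg.norm(trace.translations_mm, axis=1)
    a_mag = np.linalg.norm(trace.angles_deg, axis=1)
    return {
        "mean_translation_mm": float(t_mag.mean()),
        "sd_translation_mm": float(t_mag.std()),
        "mean_rotation_deg": float(a_mag.mean()),
        "sd_rotation_deg": float(a_mag.std()),
    }


@dataclass
class TraceSpectrum:
    """Amplitude spectra of the six motion parameters.

    ``amplitudes`` is ``(6, n_freq)`` with Parseval scaling
    ``|FFT| / sqrt(n)``, so the squared spectrum sums to the squared
    residuals.  ``golden_frequency_hz`` marks the rate at which the
    phyllotaxis sampling pattern rotates by one golden angle (one interleaf
    period) — static-scan traces show a spurious peak there because the
    residual streaking pattern rotates with the trajectory.
    """

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray
    golden_frequency_hz: Optional[float] = None


def trace_spectrum(
    trace: MotionTrace,
    segment_duration_s: float,
    n_segments_per_interleaf: Optional[int] = None,
) -> TraceSpectrum:
    """Discrete amplitude spectrum of each motion parameter.

    Requires uniform segment timing.  The input should normally be
    detrended first (see :func:`detrend_trace`).
    """
    n = len(trace)
    if n < 8:
        raise ConfigurationError("need at least 8 segments for a spectrum")
    if trace.start_times_s is not None:
        dt = np.diff(trace.start_times_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ConfigurationError("trace timing is not uniform")
    p = _trace_params(trace)
    spec = np.abs(np.fft.fft(p, axis=0)).T / np.sqrt(n)  # (6, n)
    freqs = np.fft.fftfreq(n, d=segment_duration_s)
    golden = None
    if n_segments_per_interleaf is not None:
        golden = 1.0 / (n_segments_per_interleaf * segment_duration_s)
    return TraceSpectrum(frequencies_hz=freqs, amplitudes=spec, golden_frequency_hz=golden)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class MocoConfig:
    """Settings of the end-to-end correction pipeline."""

    recon: ReconParams = field(default_factory=ReconParams)
    nav_resolution_mm: float = 3.0
    n_cg_nav: int = 8
    n_cg_final: int = 10
    n_pipe_iter_final: int = 15
    registration_seed: int = 1
    chain_initialization: bool = True
    keep_navigators: bool = True


@dataclass
class MoCoResult:
    """Everything the correction loop produces."""

    corrected: Image3D
    uncorrected: Image3D
    trace: MotionTrace
    navigators: list[Image3D]
    diagnostics: list[RegistrationDiagnostics]
    mask: np.ndarray
    windows: list[NavigatorWindow]


def merlin_pipeline(container, config: Optional[MocoConfig] = None) -> MoCoResult:
    """Run the full self-navigated correction on an acquisition container.

    Stages: WASPI sensitivity maps -> sliding-window navigators -> masked
    rigid registration to the first navigator -> middle-segment assignment
    -> k-space correction -> final reconstruction (the uncorrected image is
    reconstructed with identical settings for comparison).  The WASPI data
    join the final data set uncorrected: they are acquired immediately
    before the reference navigator and assumed to share its position.
    """
    cfg = config or MocoConfig()
    stage = "setup"
    try:
        seq = container.seq
        samples = container.samples
        raw = container.raw
        spec = container.spec
        n_seg_total = int(samples.spokes.segment_index.max()) + 1
        nseg = n_seg_total // spec.n_interleaves

        stage = "navigator truncation"
        nav_samples, nav_raw, mat_nav = truncate_to_resolution(
            samples, raw, cfg.nav_resolution_mm
        )

        stage = "sensitivity maps"
        maps_nav = estimate_sens_maps(container.waspi_raw, grid=mat_nav, params=cfg.recon)

        stage = "navigator reconstruction"
        windows = sliding_windows(spec.n_interleaves, nseg)
        nav_params = dc_replace(cfg.recon, n_cg_iter=cfg.n_cg_nav)
        navs, _ = reconstruct_navigators(nav_raw, nav_samples, windows, maps_nav, nav_params)

        stage = "registration mask"
        mask = make_registration_mask(navs[0])

        stage = "registration"
        transforms = [RigidTransform.identity()]
        diagnostics = [RegistrationDiagnostics(0.0, True, 0, "reference")]
        prev = None
        for nav in navs[1:]:
            t, diag = register_rigid(
                nav, navs[0], mask=mask, initial=prev, seed=cfg.registration_seed
            )
            transforms.append(t)
            diagnostics.append(diag)
            if cfg.chain_initialization:
                prev = t

        stage = "segment assignment"
        trace = assign_to_segments(windows, transforms, n_seg_total)
        trace = trace.with_times(seq.segment_duration_s)

        stage = "k-space correction"
        corr_samples, corr_raw = correct_kspace(samples, raw, trace)

        stage = "final reconstruction"
        maps_full = estimate_sens_maps(container.waspi_raw, grid=seq.mat, params=cfg.recon)
        final_params = dc_replace(
            cfg.recon, n_cg_iter=cfg.n_cg_final, n_pipe_iter=cfg.n_pipe_iter_final
        )
        uncorrected, calib = _final_recon(samples, raw, container, maps_full, final_params)
        corrected, _ = _final_recon(
            corr_samples, corr_raw, container, maps_full, final_params, calibration=calib
        )
    except MerlinError:
        raise
    except Exception as exc:
        raise MerlinError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return MoCoResult(
        corrected=corrected,
        uncorrected=uncorrected,
        trace=trace,
        navigators=navs if cfg.keep_navigators else [],
        diagnostics=diagnostics,
        mask=mask,
        windows=windows,
    )


def _final_recon(samples, raw, container, maps, params, calibration=None):
    """Full-resolution cgSENSE of the phyllotaxis data plus (uncorrected) WASPI.

    ``calibration`` is an optional ``(weights, lambda)`` pair; the corrected
    reconstruction reuses the uncorrected one's calibration (per-segment
    rotations leave the sample-density profile essentially unchanged) so the
    two images are directly comparable and the expensive Pipe/power
    iterations run once.
    """
    w_samples = container.waspi_samples
    w_raw = container.waspi_raw
    coords = np.concatenate([samples.coords[samples.valid], w_samples.coords[w_samples.valid]])
    y = np.concatenate(
        [raw.y[:, samples.valid], w_raw.y[:, w_samples.valid]], axis=1
    )
    from .recon import SenseOperator

    op = NufftOperator(coords, maps.mat, params.grid_oversampling, params.kernel_width, params.dtype)
    if calibration is None:
        weights = pipe_density_weights(None, maps.mat, params, operator=op).weights
        lam = params.lambda_tikhonov
        if lam is None:
            A = SenseOperator(None, maps, weights, params, operator=op)
            lam = params.lambda_rel * A.max_eig(params.n_power_iter)
        calibration = (weights, lam)
    weights, lam = calibration
    # flat container mimicking a KSpaceSamples/RawData pair for cg_sense
    flat_samples = KSpaceSamples(
        coords=coords[None],
        valid=np.ones((1, coords.shape[0]), dtype=bool),
        spokes=samples.spokes,
        seq=samples.seq,
    )
    flat_raw = RawData(y=y[:, None, :], samples=flat_samples, noise_sd=raw.noise_sd, seed=raw.seed)
    img = cg_sense(
        flat_raw,
        samples=flat_samples,
        maps=maps,
        params=dc_replace(params, lambda_tikhonov=lam),
        weights=weights,
        operator=op,
    )
    return img, calibration
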