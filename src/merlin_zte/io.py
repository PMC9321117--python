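"""Acquisition container I/O, run configuration and scenario fixtures.

A single HDF5 layout carries everything one acquisition produces:
trajectory, sequence parameters, multi-channel raw data, the WASPI
pre-scan, and (for simulated data) an optional ground-truth group with the
phantom and the injected motion trace.  Sample coordinates are derived
quantities and are rebuilt from the stored spoke directions on read, so the
round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .errors import ConfigurationError, ContainerError
from .simulate import (
    Image3D,
    MotionTrace,
    RawData,
    RigidTransform,
    motion_paradigm,
    shepp_logan_3d,
    simulate_acquisition,
    synth_coil_maps,
)
from .trajectory import (
    KSpaceSamples,
    SequenceParams,
    SpokeSet,
    TrajectorySpec,
    make_phyllotaxis,
    make_waspi,
    partition_segments,
    sample_spokes,
)

__all__ = [
    "FORMAT_VERSION",
    "AcquisitionContainer",
    "RunConfig",
    "read_container",
    "write_container",
    "scenario_fixture",
    "SCENARIOS",
]

FORMAT_VERSION = "1"


@dataclass
class AcquisitionContainer:
    """In-memory form of one (possibly simulated) segmented ZTE acquisition."""

    spec: TrajectorySpec
    seq: SequenceParams
    spokes: SpokeSet
    samples: KSpaceSamples
    raw: RawData
    waspi_spokes: SpokeSet
    waspi_samples: KSpaceSamples
    waspi_raw: RawData
    truth_phantom: Optional[Image3D] = None
    truth_trace: Optional[MotionTrace] = None
    meta: dict = field(default_factory=dict)


def write_container(container: AcquisitionContainer, path) -> None:
    """Write the acquisition to HDF5 (see module docstring for the layout)."""
    c = container
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["waspi_scheme"] = "spherical-fibonacci"
        p = f.create_group("params")
        for fld in dataclasses.fields(c.seq):
            p.attrs[fld.name] = getattr(c.seq, fld.name)
        t = f.create_group("trajectory")
        t.create_dataset("directions", data=c.spokes.directions)
        t.create_dataset("interleaf", data=c.spokes.interleaf_index)
        t.create_dataset("within_interleaf", data=c.spokes.within_interleaf_index)
        t.create_dataset("segment", data=c.spokes.segment_index)
        for fld in dataclasses.fields(c.spec):
            t.attrs[fld.name] = getattr(c.spec, fld.name)
        t.attrs["subsample_k"] = c.spec.subsample_k
        d = f.create_group("data")
        d.create_dataset("y", data=c.raw.y)
        d.attrs["noise_sd"] = c.raw.noise_sd
        d.attrs["seed"] = -1 if c.raw.seed is None else c.raw.seed
        w = f.create_group("waspi")
        w.create_dataset("directions", data=c.waspi_spokes.directions)
        w.create_dataset("y", data=c.waspi_raw.y)
        w.attrs["noise_sd"] = c.waspi_raw.noise_sd
        w.attrs["seed"] = -1 if c.waspi_raw.seed is None else c.waspi_raw.seed
        if c.truth_phantom is not None or c.truth_trace is not None:
            g = f.create_group("truth")
            if c.truth_phantom is not None:
                g.create_dataset("phantom", data=c.truth_phantom.voxels)
                g.attrs["phantom_spacing_mm"] = c.truth_phantom.spacing_mm
            if c.truth_trace is not None:
                g.create_dataset(
                    "rotations", data=np.array([t.matrix for t in c.truth_trace.transforms])
                )
                g.create_dataset("translations_mm", data=c.truth_trace.translations_mm)
                if c.truth_trace.start_times_s is not None:
                    g.create_dataset("start_times_s", data=c.truth_trace.start_times_s)
        for k, v in c.meta.items():
            f.attrs[k] = v


def read_container(path) -> AcquisitionContainer:
    """Read an acquisition written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise ContainerError(f"{path}: missing format_version attribute")
        if str(version) != FORMAT_VERSION:
            raise ContainerError(
                f"{path}: container format version {version!r} != supported "
                f"{FORMAT_VERSION!r}; re-export the acquisition with this package version"
            )
        for group in ("params", "trajectory", "data", "waspi"):
            if group not in f:
                raise ContainerError(f"{path}: missing required group /{group}")
        p = dict(f["params"].attrs)
        seq = SequenceParams(**{k: _native(v) for k, v in p.items()})
        t = f["trajectory"]
        spec_fields = {fld.name for fld in dataclasses.fields(TrajectorySpec)}
        spec = TrajectorySpec(
            **{k: _native(v) for k, v in t.attrs.items() if k in spec_fields}
        )
        spokes = SpokeSet(
            directions=t["directions"][()],
            interleaf_index=t["interleaf"][()],
            within_interleaf_index=t["within_interleaf"][()],
            is_waspi=np.zeros(t["directions"].shape[0], dtype=bool),
            segment_index=t["segment"][()],
            spec=spec,
        )
        samples = sample_spokes(spokes, seq)
        d = f["data"]
        raw = RawData(
            y=d["y"][()],
            samples=samples,
            noise_sd=float(d.attrs["noise_sd"]),
            seed=None if int(d.attrs["seed"]) < 0 else int(d.attrs["seed"]),
        )
        w = f["waspi"]
        wdirs = w["directions"][()]
        waspi_spokes = SpokeSet(
            directions=wdirs,
            interleaf_index=np.zeros(len(wdirs), dtype=np.int64),
            within_interleaf_index=np.arange(len(wdirs)),
            is_waspi=np.ones(len(wdirs), dtype=bool),
            spec=spec,
        )
        waspi_samples = sample_spokes(waspi_spokes, seq)
        waspi_raw = RawData(
            y=w["y"][()],
            samples=waspi_samples,
            noise_sd=float(w.attrs["noise_sd"]),
            seed=None if int(w.attrs["seed"]) < 0 else int(w.attrs["seed"]),
        )
        phantom = trace = None
        if "truth" in f:
            g = f["truth"]
            if "phantom" in g:
                phantom = Image3D(g["phantom"][()], float(g.attrs["phantom_spacing_mm"]))
            if "rotations" in g:
                rots = g["rotations"][()]
                trans = g["translations_mm"][()]
                times = g["start_times_s"][()] if "start_times_s" in g else None
                trace = MotionTrace(
                    [RigidTransform(r, tr) for r, tr in zip(rots, trans)], times
                )
        meta = {
            k: _native(v)
            for k, v in f.attrs.items()
            if k not in ("format_version", "waspi_scheme")
        }
        meta["waspi_scheme"] = str(f.attrs["waspi_scheme"])
    return AcquisitionContainer(
        spec=spec,
        seq=seq,
        spokes=spokes,
        samples=samples,
        raw=raw,
        waspi_spokes=waspi_spokes,
        waspi_samples=waspi_samples,
        waspi_raw=waspi_raw,
        truth_phantom=phantom,
        truth_trace=trace,
        meta=meta,
    )


def write_trajectory(spokes: SpokeSet, spec: TrajectorySpec, seq: SequenceParams, path) -> None:
    """Write a trajectory-only file (groups /trajectory and /params)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["waspi_scheme"] = "spherical-fibonacci"
        p = f.create_group("params")
        for fld in dataclasses.fields(seq):
            p.attrs[fld.name] = getattr(seq, fld.name)
        t = f.create_group("trajectory")
        t.create_dataset("directions", data=spokes.directions)
        t.create_dataset("interleaf", data=spokes.interleaf_index)
        t.create_dataset("within_interleaf", data=spokes.within_interleaf_index)
        t.create_dataset("segment", data=spokes.segment_index)
        for fld in dataclasses.fields(spec):
            t.attrs[fld.name] = getattr(spec, fld.name)
        t.attrs["subsample_k"] = spec.subsample_k


def read_trajectory(path) -> tuple[SpokeSet, TrajectorySpec, SequenceParams]:
    """Read a file written by :func:`write_trajectory`."""
    with h5py.File(path, "r") as f:
        for group in ("params", "trajectory"):
            if group not in f:
                raise ContainerError(f"{path}: missing required group /{group}")
        seq = SequenceParams(**{k: _native(v) for k, v in f["params"].attrs.items()})
        t = f["trajectory"]
        spec_fields = {fld.name for fld in dataclasses.fields(TrajectorySpec)}
        spec = TrajectorySpec(
            **{k: _native(v) for k, v in t.attrs.items() if k in spec_fields}
        )
        spokes = SpokeSet(
            directions=t["directions"][()],
            interleaf_index=t["interleaf"][()],
            within_interleaf_index=t["within_interleaf"][()],
            is_waspi=np.zeros(t["directions"].shape[0], dtype=bool),
            segment_index=t["segment"][()],
            spec=spec,
        )
    return spokes, spec, seq


def save_nifti(img: Image3D, path) -> None:
    """Write a volume as NIfTI-1, RAS-aligned, spacing from the image.

    Complex volumes are written as a magnitude file plus a ``*_phase``
    companion.
    """
    import nibabel as nib

    sp = float(img.spacing_mm)
    affine = np.diag([sp, sp, sp, 1.0])
    affine[:3, 3] = -img.mat / 2.0 * sp
    v = img.voxels
    path = Path(path)
    if np.iscomplexobj(v):
        nib.save(nib.Nifti1Image(np.abs(v).astype(np.float32), affine), str(path))
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        phase_path = path.with_name(stem + "_phase.nii.gz")
        nib.save(nib.Nifti1Image(np.angle(v).astype(np.float32), affine), str(phase_path))
    else:
        nib.save(nib.Nifti1Image(v.astype(np.float32), affine), str(path))


def load_nifti(path) -> Image3D:
    """Read a NIfTI volume written by :func:`save_nifti` (magnitude only)."""
    import nibabel as nib

    ni = nib.load(str(path))
    spacing = float(ni.header.get_zooms()[0])
    return Image3D(np.asanyarray(ni.dataobj).astype(np.float64), spacing)


def _native(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, bytes):
        return v.decode()
    return v


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: provenance of each configuration default: stated by the method's protocol
#: ("paper") or chosen by this package ("decision").
CONFIG_PROVENANCE = {
    "seed": "decision",
    "nav_resolution_mm": "paper",
    "detrend_window": "paper",
    "waspi_scale": "paper",
    "lambda_rel": "decision",
    "n_cg_nav": "decision",
    "n_cg_final": "decision",
    "grid_oversampling": "decision",
    "kernel_width": "decision",
    "n_pipe_iter": "decision",
    "registration_seed": "decision",
    "noise_fraction": "decision",
}


@dataclass
class RunConfig:
    """Serializable bundle of pipeline defaults (TOML round trip)."""

    seed: int = 0
    nav_resolution_mm: float = 3.0
    detrend_window: int = 51
    waspi_scale: float = 0.125
    lambda_rel: float = 1e-2
    n_cg_nav: int = 8
    n_cg_final: int = 10
    grid_oversampling: float = 1.25
    kernel_width: int = 4
    n_pipe_iter: int = 40
    registration_seed: int = 1
    noise_fraction: float = 0.01

    def to_toml(self, path) -> None:
        lines = ["[merlin]"]
        for fld in dataclasses.fields(self):
            v = getattr(self, fld.name)
            rendered = repr(v) if not isinstance(v, str) else f'"{v}"'
            prov = CONFIG_PROVENANCE.get(fld.name, "decision")
            lines.append(f"{fld.name} = {rendered}  # provenance: {prov}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())["merlin"]
        return cls(**data)


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

SCENARIOS = {
    "static64": "static",
    "steprot20_64": "step_rotation",
    "nodding64": "nodding",
    "continuous64": "continuous",
}


def scenario_fixture(name: str, seed: int = 0) -> AcquisitionContainer:
    """Deterministic desk-scale end-to-end test acquisition.

    All scenarios share the same geometry — 64 matrix over a 192 mm FOV
    (3 mm voxels), 13 interleaves of 1152 spokes (3 segments of 384),
    smoothness factor 7, 8 receive channels, a 2-sample deadtime gap and a
    512-spoke WASPI pre-scan — and differ only in the injected motion
    paradigm.  Complex noise is added at 1% of the peak signal magnitude.
    The phantom is a lightly smoothed Shepp-Logan (1-voxel Gaussian,
    emulating the finite acquisition point-spread function).
    """
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    mat, fov = 64, 192.0
    spec = TrajectorySpec(
        smoothness_s=7,
        n_spokes_per_interleaf=1152,
        n_interleaves=13,
        waspi_scale=0.125,
        waspi_n_spokes=512,
    )
    seq = SequenceParams(
        fov_mm=fov,
        mat=mat,
        bw_khz=31.25,
        tr_ms=1.8,
        ti_ms=450.0,
        fa_deg=3.0,
        n_readout=32,
        gap_samples=2,
        spokes_per_segment=384,
    )
    from scipy import ndimage as _ndi

    phantom = shepp_logan_3d(mat, fov)
    phantom = Image3D(_ndi.gaussian_filter(phantom.voxels, 1.0), phantom.spacing_mm)
    maps = synth_coil_maps(mat, 8, fov)

    spokes = partition_segments(make_phyllotaxis(spec), seq.spokes_per_segment)
    samples = sample_spokes(spokes, seq)
    n_seg = int(spokes.segment_index.max()) + 1
    trace = motion_paradigm(SCENARIOS[name], amplitude_deg=20.0, n_segments=n_seg, seed=seed)
    trace = trace.with_times(seq.segment_duration_s)

    clean = simulate_acquisition(phantom, maps, samples, trace, noise_sd=0.0)
    noise_sd = 0.01 * float(np.abs(clean.y[:, samples.valid]).max())
    raw = _add_noise(clean, noise_sd, seed=(seed * 7919 + 101) % (2**31))

    waspi_spokes = make_waspi(spec)
    waspi_samples = sample_spokes(waspi_spokes, seq)
    waspi_clean = simulate_acquisition(
        phantom, maps, waspi_samples, MotionTrace.identity(1), noise_sd=0.0
    )
    waspi_raw = _add_noise(waspi_clean, noise_sd, seed=(seed * 7919 + 202) % (2**31))

    return AcquisitionContainer(
        spec=spec,
        seq=seq,
        spokes=spokes,
        samples=samples,
        raw=raw,
        waspi_spokes=waspi_spokes,
        waspi_samples=waspi_samples,
        waspi_raw=waspi_raw,
        truth_phantom=phantom,
        truth_trace=trace,
        meta={"scenario": name, "scenario_seed": seed, "noise_fraction": 0.01},
    )


def _add_noise(raw: RawData, noise_sd: float, seed: int) -> RawData:
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(raw.y.shape) + 1j * rng.standard_normal(raw.y.shape)
    y = raw.y + noise * (noise_sd / np.sqrt(2.0))
    y[:, ~raw.samples.valid] = 0.0
    return RawData(y=y, samples=raw.samples, noise_sd=noise_sd, seed=seed)
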