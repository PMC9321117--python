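"""Shared fixtures: small phantoms, trajectories and an independent NDFT oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from merlin_zte import (
    Image3D,
    MotionTrace,
    SequenceParams,
    TrajectorySpec,
    make_phyllotaxis,
    make_waspi,
    partition_segments,
    sample_spokes,
    shepp_logan_3d,
    simulate_acquisition,
    synth_coil_maps,
)


# --- independent brute-force nonuniform DFT oracle -------------------------


def ndft_forward(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct evaluation of sum_n x[n] exp(-2 pi i k . (n - N/2) / N)."""
    n = img.shape[0]
    ax = np.arange(n) - n / 2
    r = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3) / n
    return np.exp(-2j * np.pi * (coords @ r.T)) @ img.ravel()


def ndft_adjoint(samples: np.ndarray, coords: np.ndarray, n: int) -> np.ndarray:
    """Exact conjugate transpose of :func:`ndft_forward`."""
    ax = np.arange(n) - n / 2
    r = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3) / n
    return (np.exp(2j * np.pi * (r @ coords.T)) @ samples).reshape(n, n, n)


# --- shared small-scale objects --------------------------------------------


@pytest.fixture(scope="session")
def smooth_phantom32() -> Image3D:
    """PSF-smoothed Shepp-Logan at 32^3 over a 96 mm FOV (3 mm voxels)."""
    ph = shepp_logan_3d(32, 96.0)
    return Image3D(ndimage.gaussian_filter(ph.voxels, 1.0), ph.spacing_mm)


@pytest.fixture(scope="session")
def smooth_phantom64() -> Image3D:
    ph = shepp_logan_3d(64, 192.0)
    return Image3D(ndimage.gaussian_filter(ph.voxels, 1.0), ph.spacing_mm)


@pytest.fixture(scope="session")
def small_acq(smooth_phantom32):
    """Tiny segmented acquisition: 5 interleaves of 96 spokes, 4 channels.

    Returns a dict with every piece a test might need; static and
    noise-free so it can serve as an exact oracle.
    """
    spec = TrajectorySpec(
        smoothness_s=7, n_spokes_per_interleaf=96, n_interleaves=5, waspi_n_spokes=128
    )
    seq = SequenceParams(
        fov_mm=96.0, mat=32, n_readout=16, gap_samples=2, spokes_per_segment=48
    )
    spokes = partition_segments(make_phyllotaxis(spec), seq.spokes_per_segment)
    samples = sample_spokes(spokes, seq)
    maps = synth_coil_maps(32, 4, 96.0)
    n_seg = int(spokes.segment_index.max()) + 1
    raw = simulate_acquisition(
        smooth_phantom32, maps, samples, MotionTrace.identity(n_seg), noise_sd=0.0
    )
    waspi_spokes = make_waspi(spec)
    waspi_samples = sample_spokes(waspi_spokes, seq)
    waspi_raw = simulate_acquisition(
        smooth_phantom32, maps, waspi_samples, MotionTrace.identity(1), noise_sd=0.0
    )
    return {
        "spec": spec,
        "seq": seq,
        "spokes": spokes,
        "samples": samples,
        "maps": maps,
        "raw": raw,
        "waspi_spokes": waspi_spokes,
        "waspi_samples": waspi_samples,
        "waspi_raw": waspi_raw,
        "phantom": smooth_phantom32,
        "n_segments": n_seg,
    }


# --- desk-scale scenario containers (shared across io and acceptance tests) --


@pytest.fixture(scope="session")
def container_static():
    from merlin_zte import scenario_fixture

    return scenario_fixture("static64", seed=0)


@pytest.fixture(scope="session")
def container_steprot():
    from merlin_zte import scenario_fixture

    return scenario_fixture("steprot20_64", seed=0)


@pytest.fixture(scope="session")
def container_nodding():
    from merlin_zte import scenario_fixture

    return scenario_fixture("nodding64", seed=0)


@pytest.fixture(scope="session")
def container_continuous():
    from merlin_zte import scenario_fixture

    return scenario_fixture("continuous64", seed=0)
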