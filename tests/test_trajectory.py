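"""Trajectory design: phyllotaxis geometry, WASPI lattice, diagnostics."""

import numpy as np
import pytest

from merlin_zte import (
    GOLDEN_ANGLE_DEG,
    GOLDEN_RATIO,
    ConfigurationError,
    GeometryError,
    SequenceParams,
    SpokeSet,
    TrajectorySpec,
    azimuthal_increment_deg,
    fibonacci,
    golden_constants,
    gradient_step_metric,
    make_phyllotaxis,
    make_waspi,
    nyquist_spoke_count,
    partition_segments,
    sample_spokes,
    undersampling_factor,
    voronoi_density,
)


@pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 2), (8, 21), (12, 144)])
def test_fibonacci(n, expected):
    assert fibonacci(n) == expected


def test_fibonacci_rejects_nonpositive():
    with pytest.raises(ConfigurationError):
        fibonacci(0)


def test_golden_constants():
    g, phi = golden_constants()
    assert round(g, 3) == 1.618
    assert round(phi, 1) == 137.5
    assert g**2 == pytest.approx(g + 1, abs=1e-14)  # defining equation


def test_azimuthal_increment():
    assert round(azimuthal_increment_deg(8), 1) == 7.7
    assert round(azimuthal_increment_deg(10), 2) == 2.93
    assert round(azimuthal_increment_deg(1), 2) == 222.49  # golden-angle complement
    steps = [azimuthal_increment_deg(s) for s in range(1, 13)]
    assert np.all(np.diff(steps) < 0)  # strictly decreasing in s
    with pytest.raises(ConfigurationError):
        azimuthal_increment_deg(0)


@pytest.mark.parametrize("mat,expected", [(192, 115812), (64, 12868), (1, 4)])
def test_nyquist_spoke_count(mat, expected):
    assert nyquist_spoke_count(mat) == expected


def test_undersampling_factor():
    assert round(undersampling_factor(192, 37376), 1) == 3.1
    assert round(undersampling_factor(192, 93312), 2) == 1.24
    mat = 96
    assert undersampling_factor(mat, nyquist_spoke_count(mat)) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ConfigurationError):
        undersampling_factor(192, 0)


class TestPhyllotaxis:
    def test_tiny_z_multiset(self):
        spokes = make_phyllotaxis(TrajectorySpec(1, 2, 2))
        assert sorted(spokes.z) == pytest.approx([-1.0, -1 / 3, 1 / 3, 1.0], abs=1e-14)

    def test_poles_and_unit_norm(self):
        spokes = make_phyllotaxis(TrajectorySpec(7, 96, 5))
        np.testing.assert_allclose(spokes.directions[0], [0, 0, 1], atol=1e-14)
        assert spokes.z[-1] == pytest.approx(-1.0, abs=1e-14)
        norms = np.linalg.norm(spokes.directions, axis=1)
        assert np.abs(norms - 1).max() < 1e-12

    def test_z_values_form_arithmetic_grid(self):
        ns, ni = 24, 7
        spokes = make_phyllotaxis(TrajectorySpec(5, ns, ni))
        dz = 2.0 / (ns * ni - 1)
        expected = 1.0 - np.arange(ns * ni) * dz
        assert np.allclose(np.sort(spokes.z)[::-1], expected, atol=1e-12)

    def test_within_interleaf_steps_constant(self):
        ns, ni, s = 48, 8, 7
        k = fibonacci(s)
        spokes = make_phyllotaxis(TrajectorySpec(s, ns, ni))
        one = spokes.directions[spokes.interleaf_index == 3]
        dz = 2.0 / (ns * ni - 1)
        np.testing.assert_allclose(np.diff(one[:, 2]), -ni * dz, atol=1e-12)
        az = np.degrees(np.arctan2(one[:, 1], one[:, 0]))
        step = (np.diff(az) + 360) % 360
        expected = (k * GOLDEN_ANGLE_DEG) % 360
        assert np.abs(step - expected).max() < 1e-9

    def test_interleaving_identity(self):
        # with Ni = k, sorting all spokes by descending z recovers the
        # sequential golden-angle azimuths m * phi_G
        s = 7
        k = fibonacci(s)
        spokes = make_phyllotaxis(TrajectorySpec(s, 96, k))
        order = np.argsort(-spokes.z, kind="stable")
        az = spokes.azimuth_deg[order] % 360
        m = np.arange(spokes.n_spokes)
        expected = (m * GOLDEN_ANGLE_DEG) % 360
        interior = np.abs(spokes.z[order]) < 1.0 - 1e-15  # azimuth undefined at poles
        mismatch = np.abs((az - expected + 180) % 360 - 180)
        assert mismatch[interior].max() < 1e-9


class TestWaspi:
    def test_counts_and_flags(self):
        for n in (2048, 1536):
            w = make_waspi(TrajectorySpec(waspi_n_spokes=n))
            assert w.n_spokes == n
            assert w.is_waspi.all()
            assert np.abs(np.linalg.norm(w.directions, axis=1) - 1).max() < 1e-12

    def test_near_uniform_nearest_neighbor_spacing(self):
        from scipy.spatial import cKDTree

        w = make_waspi(TrajectorySpec(waspi_n_spokes=512))
        dist, _ = cKDTree(w.directions).query(w.directions, k=2)
        ang = np.degrees(2 * np.arcsin(dist[:, 1] / 2))
        assert ang.std() / ang.mean() < 0.25

    def test_too_few_spokes(self):
        with pytest.raises(ConfigurationError):
            make_waspi(TrajectorySpec(waspi_n_spokes=3))


class TestSampleSpokes:
    def test_no_gap_keeps_center(self):
        spokes = make_phyllotaxis(TrajectorySpec(5, 24, 3))
        seq = SequenceParams(mat=32, n_readout=16, gap_samples=0, fov_mm=96)
        ks = sample_spokes(spokes, seq)
        assert ks.valid.all()
        assert np.abs(ks.coords[:, 0, :]).max() == 0.0  # k = 0 sample present
        assert np.abs(np.linalg.norm(ks.coords, axis=2)).max() == pytest.approx(16.0)

    def test_gap_masks_exact_radius_indices(self):
        spokes = make_phyllotaxis(TrajectorySpec(5, 24, 3))
        seq = SequenceParams(mat=32, n_readout=16, gap_samples=3, fov_mm=96)
        ks = sample_spokes(spokes, seq)
        assert not ks.valid[:, :3].any()
        assert ks.valid[:, 3:].all()

    def test_waspi_radius_scaled(self):
        spec = TrajectorySpec(waspi_n_spokes=64, waspi_scale=0.125)
        seq = SequenceParams(mat=64, n_readout=32, gap_samples=2)
        ks = sample_spokes(make_waspi(spec), seq)
        assert np.linalg.norm(ks.coords, axis=2).max() == pytest.approx(0.125 * 32)
        # same sample-index gap; absolute k hole is 8x smaller than nominal
        assert not ks.valid[:, :2].any() and ks.valid[:, 2:].all()

    def test_readout_too_short(self):
        spokes = make_phyllotaxis(TrajectorySpec(5, 24, 3))
        with pytest.raises(ConfigurationError):
            sample_spokes(spokes, SequenceParams(mat=32, n_readout=3, gap_samples=2))


class TestSegments:
    @pytest.mark.parametrize("ns,size,nseg", [(1152, 384, 3), (768, 384, 2), (1536, 384, 4)])
    def test_segments_per_interleaf(self, ns, size, nseg):
        spokes = make_phyllotaxis(TrajectorySpec(7, ns, 2))
        out = partition_segments(spokes, size)
        assert out.n_segments == 2 * nseg
        assert np.all(np.diff(out.segment_index) >= 0)  # monotone in acquisition order

    def test_non_divisible_raises_with_context(self):
        spokes = make_phyllotaxis(TrajectorySpec(7, 1000, 2))
        with pytest.raises(ConfigurationError, match="1000"):
            partition_segments(spokes, 384)


class TestStepMetric:
    def test_within_interleaf_step_equals_azimuthal_increment(self):
        s, ns, ni = 9, 256, 8
        spokes = make_phyllotaxis(TrajectorySpec(s, ns, ni))
        summary = gradient_step_metric(spokes)
        # polar sweep adds a small constant; azimuthal step dominates
        assert summary.mean_within == pytest.approx(azimuthal_increment_deg(s), rel=0.25)
        assert len(summary.boundary_deg) == ni - 1

    def test_smoother_trajectory_has_smaller_steps(self):
        base = dict(n_spokes_per_interleaf=256, n_interleaves=8)
        m9 = gradient_step_metric(make_phyllotaxis(TrajectorySpec(9, **base)))
        m11 = gradient_step_metric(make_phyllotaxis(TrajectorySpec(11, **base)))
        assert m11.mean_within < m9.mean_within

    def test_single_spoke_empty(self):
        one = SpokeSet(
            directions=np.array([[0.0, 0.0, 1.0]]),
            interleaf_index=np.zeros(1, dtype=int),
            within_interleaf_index=np.zeros(1, dtype=int),
            is_waspi=np.zeros(1, dtype=bool),
        )
        summary = gradient_step_metric(one)
        assert summary.within_deg.size == 0 and summary.boundary_deg.size == 0


class TestVoronoi:
    def test_octahedron(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        spokes = SpokeSet(
            directions=pts,
            interleaf_index=np.zeros(6, dtype=int),
            within_interleaf_index=np.arange(6),
            is_waspi=np.zeros(6, dtype=bool),
        )
        areas = voronoi_density(spokes)
        np.testing.assert_allclose(areas, 2 * np.pi / 3, rtol=1e-9)

    def test_phyllotaxis_uniformity(self):
        spokes = make_phyllotaxis(TrajectorySpec(7, 384, 13))
        areas = voronoi_density(spokes)
        assert abs(areas.sum() - 4 * np.pi) / (4 * np.pi) < 1e-6
        interior = np.ones(len(areas), bool)
        interior[[0, -1]] = False  # the two polar spokes
        assert areas[interior].std() / areas[interior].mean() < 0.15

    def test_acos_modulation_beats_sqrt_modulation(self):
        # same azimuths, polar angle from sqrt-modulated z (non-uniform density)
        spec = TrajectorySpec(7, 96, 13)
        acos_set = make_phyllotaxis(spec)
        nt = acos_set.n_spokes
        m = np.arange(nt)
        phi = np.radians(m * GOLDEN_ANGLE_DEG)
        # square-root polar modulation of the original phyllotaxis design
        theta = 0.5 * np.pi * np.sqrt((m + 0.5) / nt)
        both = np.concatenate([theta, np.pi - theta[::-1]])[:nt]  # cover both hemispheres
        d = np.stack(
            [np.cos(phi) * np.sin(both), np.sin(phi) * np.sin(both), np.cos(both)], -1
        )
        sqrt_set = SpokeSet(
            directions=d,
            interleaf_index=np.zeros(nt, dtype=int),
            within_interleaf_index=m,
            is_waspi=np.zeros(nt, dtype=bool),
        )

        def cv(s):
            a = voronoi_density(s)
            keep = np.ones(len(a), bool)
            keep[[np.argmax(s.z), np.argmin(s.z)]] = False
            return a[keep].std() / a[keep].mean()

        assert cv(acos_set) < cv(sqrt_set)

    def test_coplanar_rejected(self):
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.stack([np.cos(phi), np.sin(phi), np.zeros(8)], -1)
        spokes = SpokeSet(
            directions=pts,
            interleaf_index=np.zeros(8, dtype=int),
            within_interleaf_index=np.arange(8),
            is_waspi=np.zeros(8, dtype=bool),
        )
        with pytest.raises(GeometryError):
            voronoi_density(spokes)


def test_sequence_params_validation():
    with pytest.raises(ConfigurationError):
        SequenceParams(mat=63)
    with pytest.raises(ConfigurationError):
        SequenceParams(gap_samples=40, n_readout=32)
    with pytest.raises(ConfigurationError):
        TrajectorySpec(waspi_scale=0.0)
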