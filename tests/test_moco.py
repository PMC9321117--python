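"""Motion-correction loop: windows, registration, assignment, trace analysis."""

import numpy as np
import pytest
from scipy import ndimage

from merlin_zte import (
    ConfigurationError,
    DegenerateInputError,
    Image3D,
    MotionTrace,
    RigidTransform,
    apply_rigid_image,
    assign_to_segments,
    correct_kspace,
    detrend_trace,
    make_registration_mask,
    register_rigid,
    shepp_logan_3d,
    sliding_windows,
    trace_spectrum,
    trace_stats,
)
from merlin_zte.moco import NavigatorWindow
from merlin_zte.simulate import motion_paradigm, simulate_acquisition


class TestSlidingWindows:
    def test_count_identity_exhaustive(self):
        for ni in range(1, 7):
            for nseg in range(1, 7):
                windows = sliding_windows(ni, nseg)
                # direct enumeration: windows of nseg consecutive segments
                # stepping by one inside ni*nseg segments
                expected = ni * nseg - nseg + 1
                assert len(windows) == expected == (ni - 1) * nseg + 1

    def test_windows_are_contiguous_and_step_one(self):
        windows = sliding_windows(3, 3)
        assert [w.first_segment for w in windows] == list(range(7))
        assert windows[0].segments == [0, 1, 2]

    def test_middle_segment(self):
        assert NavigatorWindow(4, 3).middle_segment == 5
        assert NavigatorWindow(4, 4).middle_segment == 5  # earlier of the two central
        assert NavigatorWindow(4, 1).middle_segment == 4


class TestAssignment:
    def test_middle_gets_window_estimate(self):
        windows = sliding_windows(3, 3)
        tx = [RigidTransform.from_angles((0, 0, i)) for i in range(len(windows))]
        trace = assign_to_segments(windows, tx, 9)
        for w, t in zip(windows, tx):
            assert trace[w.middle_segment].angles_deg[2] == pytest.approx(
                t.angles_deg[2]
            )

    def test_boundary_rules(self):
        windows = sliding_windows(3, 3)  # middles cover segments 1..7 of 9
        tx = [RigidTransform.from_angles((0, 0, 5 + i)) for i in range(7)]
        trace = assign_to_segments(windows, tx, 9)
        assert trace[0].is_identity()  # before the first middle: not corrected
        assert trace[8].angles_deg[2] == pytest.approx(tx[-1].angles_deg[2])

    def test_all_identity(self):
        windows = sliding_windows(4, 2)
        tx = [RigidTransform.identity() for _ in windows]
        trace = assign_to_segments(windows, tx, 8)
        assert all(t.is_identity() for t in trace.transforms)

    def test_count_mismatch(self):
        with pytest.raises(ConfigurationError):
            assign_to_segments(sliding_windows(3, 3), [RigidTransform.identity()], 9)


class TestCorrectKspace:
    def test_identity_is_bitwise_noop(self, small_acq):
        a = small_acq
        cs, cr = correct_kspace(
            a["samples"], a["raw"], MotionTrace.identity(a["n_segments"])
        )
        assert np.array_equal(cs.coords, a["samples"].coords)
        assert np.array_equal(cr.y, a["raw"].y)

    def test_rotation_preserves_radii(self, small_acq):
        a = small_acq
        trace = MotionTrace(
            [RigidTransform.from_angles((10, -5, 20))] * a["n_segments"]
        )
        cs, _ = correct_kspace(a["samples"], a["raw"], trace)
        r0 = np.linalg.norm(a["samples"].coords, axis=2)
        r1 = np.linalg.norm(cs.coords, axis=2)
        assert np.abs(r1 - r0).max() < 1e-12 * r0.max()

    def test_translation_preserves_magnitude(self, small_acq):
        a = small_acq
        trace = MotionTrace(
            [RigidTransform.from_angles((0, 0, 0), (2.5, -1, 4))] * a["n_segments"]
        )
        _, cr = correct_kspace(a["samples"], a["raw"], trace)
        assert np.abs(np.abs(cr.y) - np.abs(a["raw"].y)).max() < 1e-10 * np.abs(
            a["raw"].y
        ).max()

    def test_inverse_trace_restores(self, small_acq):
        a = small_acq
        trace = motion_paradigm("step_rotation", 12.0, a["n_segments"], seed=1)
        cs, cr = correct_kspace(a["samples"], a["raw"], trace)
        inv = MotionTrace([t.inverse() for t in trace.transforms])
        cs2, cr2 = correct_kspace(cs, cr, inv)
        assert np.abs(cs2.coords - a["samples"].coords).max() < 1e-10
        assert np.abs(cr2.y - a["raw"].y).max() < 1e-10 * np.abs(a["raw"].y).max()

    def test_missing_segment_transform(self, small_acq):
        a = small_acq
        with pytest.raises(ConfigurationError):
            correct_kspace(a["samples"], a["raw"], MotionTrace.identity(3))


@pytest.fixture(scope="module")
def nav_like_image(smooth_phantom64):
    return smooth_phantom64


class TestRegistration:
    def test_identity_recovery(self, nav_like_image):
        mask = make_registration_mask(nav_like_image)
        t, diag = register_rigid(nav_like_image, nav_like_image, mask=mask)
        assert np.abs(t.translation_mm).max() < 0.05
        assert np.abs(t.angles_deg).max() < 0.05

    def test_translation_recovery(self, nav_like_image):
        true = RigidTransform.from_angles((0, 0, 0), (4.0, 0, 0))
        moved = apply_rigid_image(nav_like_image, true)
        mask = make_registration_mask(nav_like_image)
        t, _ = register_rigid(moved, nav_like_image, mask=mask)
        assert np.abs(t.translation_mm - [4, 0, 0]).max() < 0.3

    def test_rotation_recovery(self, nav_like_image):
        true = RigidTransform.from_angles((0, 0, 10.0))
        moved = apply_rigid_image(nav_like_image, true)
        mask = make_registration_mask(nav_like_image)
        t, _ = register_rigid(moved, nav_like_image, mask=mask)
        assert np.abs(t.angles_deg - [0, 0, 10]).max() < 0.3

    def test_sign_convention_matches_pose(self, nav_like_image):
        # the registration returns the head pose in the package convention:
        # registering the image of an object moved by T recovers T itself
        true = RigidTransform.from_angles((3, -2, 6), (2, 1, -3))
        moved = apply_rigid_image(nav_like_image, true)
        mask = make_registration_mask(nav_like_image)
        t, _ = register_rigid(moved, nav_like_image, mask=mask)
        assert np.abs(t.angles_deg - true.angles_deg).max() < 0.3
        assert np.abs(t.translation_mm - true.translation_mm).max() < 0.3

    def test_grid_mismatch_rejected(self, nav_like_image, smooth_phantom32):
        with pytest.raises(ConfigurationError):
            register_rigid(smooth_phantom32, nav_like_image)


class TestRegistrationMask:
    def test_covers_phantom_support(self, smooth_phantom64):
        mask = make_registration_mask(smooth_phantom64)
        support = smooth_phantom64.voxels > 0.05
        assert (mask & support).sum() / support.sum() >= 0.99

    def test_excludes_distant_structure(self, smooth_phantom64):
        # a small bright static blob away from the object (headrest stand-in)
        v = smooth_phantom64.voxels.copy()
        v[2:6, 2:6, 2:6] = 1.0
        mask = make_registration_mask(Image3D(v, 3.0))
        assert not mask[:7, :7, :7].any()

    def test_flat_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_registration_mask(Image3D(np.zeros((16, 16, 16)), 3.0))


def _trace_from(params):
    return MotionTrace(
        [RigidTransform.from_angles(p[3:], p[:3]) for p in params]
    )


class TestDetrend:
    def test_constant_trace_zero_residual(self):
        trace = _trace_from(np.tile([1.0, 2, 3, 0.5, -0.5, 1], (60, 1)))
        out = detrend_trace(trace, window=11)
        assert np.abs(out.translations_mm).max() < 1e-12
        assert np.abs(out.angles_deg).max() < 1e-12

    def test_linear_drift_removed_in_interior(self):
        n = 101
        drift = np.outer(np.linspace(0, 5, n), [1, 0, 0, 0, 0, 1])
        out = detrend_trace(_trace_from(drift), window=21)
        interior = slice(10, n - 10)
        assert np.abs(out.translations_mm[interior]).max() < 1e-10
        assert np.abs(out.angles_deg[interior]).max() < 1e-10

    def test_fast_sinusoid_retained(self):
        n = 255
        t = np.arange(n)
        sig = np.zeros((n, 6))
        sig[:, 2] = np.sin(2 * np.pi * t / 8)  # period 8 << window 51
        out = detrend_trace(_trace_from(sig), window=51)
        assert np.abs(out.translations_mm[:, 2]).max() >= 0.9

    def test_window_validation(self):
        trace = _trace_from(np.zeros((20, 6)))
        with pytest.raises(ConfigurationError):
            detrend_trace(trace, window=10)  # even
        with pytest.raises(ConfigurationError):
            detrend_trace(trace, window=21)  # longer than trace


class TestTraceStats:
    def test_identity(self):
        s = trace_stats(MotionTrace.identity(5))
        assert s["mean_translation_mm"] == 0 and s["sd_translation_mm"] == 0
        assert s["mean_rotation_deg"] == 0 and s["sd_rotation_deg"] == 0

    def test_pythagorean_offset(self):
        trace = _trace_from(np.tile([3.0, 4, 0, 0, 0, 0], (7, 1)))
        s = trace_stats(trace)
        assert s["mean_translation_mm"] == pytest.approx(5.0)
        assert s["sd_translation_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_magnitudes_match_generator(self):
        rng = np.random.default_rng(11)
        n = 500
        p = np.zeros((n, 6))
        p[:, :3] = rng.normal(0, 1.0, (n, 3))
        s = trace_stats(_trace_from(p))
        # |N(0,1)^3| has mean sqrt(2/pi)*... = 1.5958, sd ~ 0.6734
        assert s["mean_translation_mm"] == pytest.approx(1.5958, rel=0.08)
        assert s["sd_translation_mm"] == pytest.approx(0.6734, rel=0.15)


class TestTraceSpectrum:
    def test_pure_sinusoid_peak(self):
        n = 64
        dt = 2.0
        f0 = 1.0 / 16.0
        p = np.zeros((n, 6))
        p[:, 5] = np.sin(2 * np.pi * f0 * np.arange(n) * dt)
        spec = trace_spectrum(_trace_from(p), segment_duration_s=dt)
        az = spec.amplitudes[5]
        peak = np.abs(spec.frequencies_hz[np.argmax(az)])
        assert peak == pytest.approx(f0, abs=1e-12)

    def test_parseval(self):
        rng = np.random.default_rng(3)
        p = rng.normal(0, 1, (32, 6))
        spec = trace_spectrum(_trace_from(p), segment_duration_s=1.0)
        for i in range(6):
            assert np.sum(spec.amplitudes[i] ** 2) == pytest.approx(
                np.sum(p[:, i] ** 2), rel=1e-8
            )

    def test_white_noise_has_no_dominant_peak(self):
        rng = np.random.default_rng(7)
        p = rng.normal(0, 0.1, (128, 6))
        spec = trace_spectrum(_trace_from(p), segment_duration_s=1.0)
        nonzero = np.abs(spec.frequencies_hz) > 1e-12
        for i in range(6):
            a = spec.amplitudes[i][nonzero]
            assert a.max() < 5 * np.median(a)

    def test_golden_angle_marker(self):
        p = np.zeros((16, 6))
        spec = trace_spectrum(
            _trace_from(p), segment_duration_s=1.1412, n_segments_per_interleaf=3
        )
        assert spec.golden_frequency_hz == pytest.approx(1 / (3 * 1.1412))

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            trace_spectrum(_trace_from(np.zeros((4, 6))), 1.0)

    def test_nonuniform_timing_rejected(self):
        trace = _trace_from(np.zeros((10, 6)))
        trace.start_times_s = np.array([0, 1, 2, 3, 4, 5.5, 6, 7, 8, 9])
        with pytest.raises(ConfigurationError):
            trace_spectrum(trace, 1.0)
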