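import numpy as np
import pytest

from cafi.core_io import ImageSequence
from cafi.interpolate import (
    FlowField,
    cafi_midframe,
    consistency_weights,
    downsample_axis,
    estimate_flow,
    held_out_frames,
    icafi,
    interp_blend,
    interp_cubic,
    interp_duplicate,
    interpolate_sequence,
    make_velocity_series,
    warp_frame,
)
from cafi.metrics import rmse
from cafi.simulate import SimulationConfig, render_frame
from cafi.tracking import detect_spots_log

from conftest import make_texture, translating_sequence


class TestClassicalInterpolators:
    def test_duplicate_returns_copy_of_earlier_frame(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        out = interp_duplicate(a, b)
        np.testing.assert_array_equal(out, a)
        out[0, 0] = 99  # must be a copy, not a view
        assert a[0, 0] != 99

    @pytest.mark.parametrize("t,expected", [(0.5, 0.5), (0.25, 0.25)])
    def test_blend_of_constants(self, t, expected):
        a, b = np.zeros((4, 4)), np.ones((4, 4))
        np.testing.assert_allclose(interp_blend(a, b, t), expected)

    def test_blend_idempotent_on_equal_frames(self, rng):
        a = rng.random((6, 6))
        np.testing.assert_allclose(interp_blend(a, a.copy()), a)

    def test_cubic_reproduces_constants_and_linear_ramps(self):
        c = np.full((4, 4), 2.5)
        np.testing.assert_allclose(interp_cubic(c, c, c, c), c)
        ramp = [np.full((4, 4), float(v)) for v in (0, 1, 2, 3)]
        np.testing.assert_allclose(interp_cubic(*ramp, 0.5), 1.5)

    def test_cubic_exact_on_quadratic_signal(self):
        # pixel value q(s) = s^2 at s = -1, 0, 1, 2; expect q(0.5) = 0.25
        frames = [np.full((3, 3), float(s**2)) for s in (-1, 0, 1, 2)]
        np.testing.assert_allclose(interp_cubic(*frames, 0.5), 0.25, atol=1e-12)


class TestFlowAndWarp:
    @pytest.mark.parametrize("shift", [(0, 3), (-5, 8), (0, 12), (7, -12)])
    def test_flow_recovers_global_translation(self, shift):
        seq = translating_sequence(1.0, n_frames=1, size=160)
        a = seq.frames[0]
        from scipy.ndimage import fourier_shift

        b = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(a), shift)))
        flow = estimate_flow(a, b)
        # forward flow: b(x+u, y+v) ≈ a(x, y)
        assert np.median(flow.v) == pytest.approx(shift[0], abs=0.5)
        assert np.median(flow.u) == pytest.approx(shift[1], abs=0.5)
        interior = (slice(20, -20),) * 2
        mee = np.hypot(flow.u - shift[1], flow.v - shift[0])[interior].mean()
        assert mee <= 0.5

    def test_identical_frames_give_zero_flow(self):
        a = make_texture(64)
        flow = estimate_flow(a, a.copy())
        assert np.abs(flow.u).max() < 0.1 and np.abs(flow.v).max() < 0.1

    def test_constant_image_warns_and_returns_zero_flow(self):
        a = np.full((32, 32), 2.0)
        with pytest.warns(UserWarning):
            flow = estimate_flow(a, a)
        assert (flow.u == 0).all() and (flow.v == 0).all()

    def test_zero_flow_warp_is_identity(self, rng):
        frame = rng.random((16, 16))
        flow = FlowField(u=np.zeros((16, 16)), v=np.zeros((16, 16)))
        np.testing.assert_allclose(warp_frame(frame, flow), frame, atol=1e-10)

    def test_zero_t_scale_is_identity(self, rng):
        frame = rng.random((16, 16))
        flow = FlowField(u=rng.random((16, 16)), v=rng.random((16, 16)))
        np.testing.assert_allclose(
            warp_frame(frame, flow, t_scale=0.0), frame, atol=1e-10
        )

    def test_uniform_flow_shifts_ramp_one_column(self):
        frame = np.tile(np.arange(16.0), (16, 1))
        flow = FlowField(u=np.ones((16, 16)), v=np.zeros((16, 16)))
        out = warp_frame(frame, flow, t_scale=1.0)
        np.testing.assert_allclose(out[:, :-1], frame[:, 1:])


class TestConsistencyWeights:
    def test_inverse_flows_reach_maximum_weight(self):
        u = np.full((8, 8), 2.0)
        f_ab = FlowField(u=u, v=np.zeros_like(u))
        f_ba = FlowField(u=-u, v=np.zeros_like(u))
        w = consistency_weights(f_ab, f_ba)
        np.testing.assert_allclose(w, 1.0)

    def test_inconsistent_pixels_get_smaller_weight(self):
        u = np.zeros((8, 8))
        u_bad = u.copy()
        u_bad[4, 4] = 3.0  # forward flow not cancelled by backward flow
        f_ab = FlowField(u=u_bad, v=np.zeros_like(u))
        f_ba = FlowField(u=np.zeros_like(u), v=np.zeros_like(u))
        w = consistency_weights(f_ab, f_ba)
        assert w[4, 4] < w[0, 0] == 1.0

    def test_weight_value_matches_declared_kernel(self):
        # inconsistency of 3 px with scale 2 → exp(-(3/2)^2)
        u = np.zeros((4, 4))
        u[1, 1] = 3.0
        f_ab = FlowField(u=u, v=np.zeros_like(u))
        f_ba = FlowField(u=np.zeros_like(u), v=np.zeros_like(u))
        w = consistency_weights(f_ab, f_ba, scale=2.0)
        assert w[1, 1] == pytest.approx(np.exp(-2.25), rel=1e-9)


class TestCafiMidframe:
    def test_static_scene_returns_input(self):
        a = make_texture(64)
        out = cafi_midframe(a, a.copy())
        assert rmse(out, a) < 1e-3

    def test_translating_texture_recovers_analytic_midframe(self):
        # scene translated 2Δ between anchors → midframe = translation by Δ
        seq = translating_sequence(3.0, n_frames=3, size=160)
        a, gt_mid, b = seq.frames
        mid = cafi_midframe(a, b)
        err_cafi = rmse(mid, gt_mid)
        err_blend = rmse(interp_blend(a, b), gt_mid)
        assert err_cafi <= 0.02
        assert err_cafi < err_blend

    def test_opposite_moving_particles_land_at_mean_positions(self):
        cfg = SimulationConfig(width=96, height=96)
        a = render_frame(np.array([[30.0, 30.0], [70.0, 70.0]]), cfg)
        b = render_frame(np.array([[34.0, 30.0], [66.0, 70.0]]), cfg)
        mid = cafi_midframe(a * 255, b * 255)
        spots = detect_spots_log(
            ImageSequence(frames=mid[None]), diameter=15, threshold=5
        )[0]
        found = sorted([(s.x, s.y) for s in spots])
        assert len(found) == 2
        assert found[0] == pytest.approx((32.0, 30.0), abs=0.5)
        assert found[1] == pytest.approx((68.0, 70.0), abs=0.5)

    def test_invalid_t_rejected(self, rng):
        a = rng.random((32, 32))
        with pytest.raises(ValueError):
            cafi_midframe(a, a, t=1.0)


class TestSequenceOps:
    @pytest.mark.parametrize("method", ["none", "bil", "bic"])
    def test_two_times_upsampling_length_and_anchors(self, rng, method):
        seq = ImageSequence(frames=rng.random((9, 16, 16)))
        out = interpolate_sequence(seq, method)
        assert len(out) == 17
        np.testing.assert_array_equal(out.frames[::2], seq.frames)

    def test_axis_z_equals_axis_t_after_relabel(self, rng):
        frames = rng.random((5, 16, 16))
        out_t = interpolate_sequence(ImageSequence(frames=frames), "bil", axis="t")
        out_z = interpolate_sequence(
            ImageSequence(frames=frames, axis_label="z"), "bil", axis="z"
        )
        np.testing.assert_array_equal(out_t.frames, out_z.frames)

    def test_axis_mismatch_rejected(self, rng):
        seq = ImageSequence(frames=rng.random((4, 8, 8)))
        with pytest.raises(ValueError):
            interpolate_sequence(seq, "bil", axis="z")

    @pytest.mark.parametrize("factor", [2, 4, 8, 16])
    def test_icafi_length_law_and_anchor_preservation(self, rng, factor):
        seq = ImageSequence(frames=rng.random((3, 16, 16)))
        out = icafi(seq, "bil", factor)
        assert len(out) == factor * 2 + 1
        np.testing.assert_array_equal(out.frames[::factor], seq.frames)

    def test_icafi_sixteen_fold_from_fifteen_frames_gives_225(self, rng):
        seq = ImageSequence(frames=rng.random((15, 16, 16)))
        assert len(icafi(seq, "none", 16)) == 225

    def test_icafi_factor_two_equals_single_interpolation(self, rng):
        seq = ImageSequence(frames=rng.random((4, 16, 16)))
        np.testing.assert_array_equal(
            icafi(seq, "bil", 2).frames, interpolate_sequence(seq, "bil").frames
        )

    def test_invalid_factor_rejected(self, rng):
        seq = ImageSequence(frames=rng.random((4, 8, 8)))
        with pytest.raises(ValueError):
            icafi(seq, "bil", 3)


class TestDownsampling:
    def test_stride_16_of_225_gives_15_frames(self, rng):
        seq = ImageSequence(frames=rng.random((225, 4, 4)))
        assert len(downsample_axis(seq, 16)) == 15

    def test_89_frames_stride_4_gives_23(self, rng):
        seq = ImageSequence(frames=rng.random((89, 4, 4)))
        assert len(downsample_axis(seq, 4)) == 23

    def test_stride_2_twice_equals_stride_4(self, rng):
        seq = ImageSequence(frames=rng.random((33, 4, 4)))
        twice = downsample_axis(downsample_axis(seq, 2), 2)
        np.testing.assert_array_equal(twice.frames, downsample_axis(seq, 4).frames)

    def test_held_out_complements_kept_frames(self, rng):
        seq = ImageSequence(frames=rng.random((11, 4, 4)))
        idx, frames = held_out_frames(seq, 2)
        np.testing.assert_array_equal(idx, [1, 3, 5, 7, 9])
        np.testing.assert_array_equal(frames, seq.frames[1::2])

    def test_velocity_series_stride_5_truncates_to_17(self, rng):
        dense = ImageSequence(frames=rng.random((225, 4, 4)))
        out = make_velocity_series(dense, 5)
        assert len(out) == 17
        np.testing.assert_array_equal(out.frames, dense.frames[0:85:5])

    def test_velocity_13_ends_at_frame_208(self, rng):
        dense = ImageSequence(frames=rng.random((225, 4, 4)))
        out = make_velocity_series(dense, 13)
        assert len(out) == 17
        np.testing.assert_array_equal(out.frames[-1], dense.frames[208])

    def test_too_short_dense_sequence_rejected(self, rng):
        dense = ImageSequence(frames=rng.random((40, 4, 4)))
        with pytest.raises(ValueError):
            make_velocity_series(dense, 5)
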