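"""Flow-period accumulation, trend interpolation and full-sequence tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendontrack import (
    MotionProfile,
    PhantomSpec,
    Region,
    TrackerConfig,
    accumulate_until_threshold,
    interpolate_period,
    render_sequence,
    track,
    track_comparator,
)


def _static_sequence(n=12, seed=4):
    spec = PhantomSpec(
        motion=MotionProfile.constant_velocity(n, 0.0),
        width=260, height=130, seed=seed,
    )
    return render_sequence(spec)[0]


def _const_flow(dx, dy=0.0):
    return lambda seq, t, region, cfg: (dx, dy)


class TestAccumulateUntilThreshold:
    def test_constant_two_px_with_lambda_ten_gives_five_frames(self):
        seq = _static_sequence(30)
        period = accumulate_until_threshold(
            seq, 0, Region(70, 40, 101, 41), TrackerConfig(lambda_px=10),
            flow_fn=_const_flow(2.0),
        )
        assert period.n == 5
        assert period.da == pytest.approx(10.0)
        assert period.d_of.shape == (6, 2)
        assert np.allclose(period.d_of[:, 0], [0, 2, 4, 6, 8, 10])

    def test_sequence_end_terminates_below_threshold(self):
        seq = _static_sequence(7)
        period = accumulate_until_threshold(
            seq, 0, Region(70, 40, 101, 41), TrackerConfig(lambda_px=10),
            flow_fn=_const_flow(1.0),
        )
        assert period.end == 6
        assert period.da == pytest.approx(6.0) and abs(period.da) < 10

    def test_zero_motion_spans_whole_sequence(self):
        seq = _static_sequence(9)
        period = accumulate_until_threshold(
            seq, 0, Region(70, 40, 101, 41), TrackerConfig(lambda_px=10),
        )
        assert period.start == 0 and period.end == 8
        assert period.da == 0.0

    def test_signed_cancellation_does_not_trigger(self):
        # back-and-forth flow cancels in the signed sum Da
        seq = _static_sequence(9)
        vals = iter([6.0, -6.0, 6.0, -6.0, 6.0, -6.0, 6.0, -6.0])

        def flow(sequence, t, region, cfg):
            return (next(vals), 0.0)

        period = accumulate_until_threshold(
            seq, 0, Region(70, 40, 101, 41), TrackerConfig(lambda_px=10), flow_fn=flow,
        )
        assert period.end == 8  # ran to sequence end
        assert abs(period.da) < 10

    def test_start_at_last_frame_rejected(self):
        seq = _static_sequence(5)
        with pytest.raises(ValueError):
            accumulate_until_threshold(seq, 4, Region(70, 40, 101, 41))


class TestInterpolatePeriod:
    def test_endpoints_exact(self):
        out, fb = interpolate_period(np.array([0.0, 0.7, 1.3, 2.1]), 0.3, 2.9)
        assert out[0] == 0.3 and out[-1] == 2.9
        assert not fb

    def test_hand_example(self):
        out, _ = interpolate_period(np.array([0.0, 1.0, 2.0]), 0.0, 3.0)
        assert out[1] == pytest.approx(1.5)

    def test_degenerate_flow_falls_back_to_linear(self):
        out, fb = interpolate_period(np.array([0.0, 0.0, 0.0]), 1.0, 3.0)
        assert fb
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_linear_mode(self):
        out, fb = interpolate_period(np.array([0.0, 0.2, 1.8, 2.0]), 0.0, 3.0, "linear")
        assert np.allclose(out, [0.0, 1.0, 2.0, 3.0])
        assert not fb

    def test_flow_trend_differs_from_linear_interior(self):
        d_of = np.array([0.0, 0.2, 1.8, 2.0])
        trend, _ = interpolate_period(d_of, 0.0, 3.0, "flow_trend")
        linear, _ = interpolate_period(d_of, 0.0, 3.0, "linear")
        assert trend[0] == linear[0] and trend[-1] == linear[-1]
        assert not np.allclose(trend[1:-1], linear[1:-1])
        assert trend[1] == pytest.approx(0.2 * 3.0 / 2.0)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 2.0), min_size=1, max_size=10),
        st.floats(-5, 5), st.floats(-20, 20),
    )
    def test_monotone_flow_gives_monotone_interpolation(self, steps, start, delta):
        d_of = np.concatenate([[0.0], np.cumsum(steps)])
        out, fb = interpolate_period(d_of, start, start + delta)
        assert not fb
        diffs = np.diff(out)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)


class TestTrack:
    def test_static_sequence_stays_put(self, default_config):
        seq = _static_sequence(12)
        traj = track(seq, Region(70, 40, 101, 41), default_config)
        assert traj.n_frames == 12
        assert np.allclose(traj.cumulative, 0.0)
        assert traj.is_anchor[0] and traj.is_anchor[-1]
        assert len(traj.periods) == 1

    def test_constant_velocity_tracked_within_5_percent(self, default_config):
        spec = PhantomSpec(
            motion=MotionProfile.constant_velocity(120, 0.5),
            width=300, height=130, noise_sigma=0.01, rho=0.0, seed=11,
        )
        seq, motion = render_sequence(spec)
        traj = track(seq, Region(70, 40, 101, 41), default_config)
        assert traj.n_frames == 120
        total = traj.total_displacement_x
        assert abs(total - 59.5) <= 0.05 * 59.5

    def test_anchor_endpoint_consistency(self, default_config):
        spec = PhantomSpec(
            motion=MotionProfile.constant_velocity(80, 0.6),
            width=300, height=130, noise_sigma=0.01, rho=0.0, seed=2,
        )
        seq, _ = render_sequence(spec)
        traj = track(seq, Region(70, 40, 101, 41), default_config)
        cum_mkbm = 0.0
        for p in traj.periods:
            cum_mkbm += p["mkbm_dx"]
            assert traj.dx[p["end"]] == pytest.approx(cum_mkbm, abs=1e-12)
            assert traj.is_anchor[p["end"]]

    def test_lambda_to_zero_degenerates_to_per_frame_mkbm(self, default_config):
        spec = PhantomSpec(
            motion=MotionProfile.constant_velocity(30, 1.5),
            width=300, height=130, noise_sigma=0.005, rho=0.0, seed=9,
        )
        seq, _ = render_sequence(spec)
        region = Region(60, 40, 101, 41)
        oftb = track(seq, region, default_config.replace(lambda_px=1e-9))
        mkbm = track_comparator(seq, region, default_config, "mkbm_only")
        assert np.array_equal(oftb.cumulative, mkbm.cumulative)
        assert oftb.total_displacement_x != 0.0  # equality is not vacuous

    def test_determinism_bit_identical(self, default_config):
        spec = PhantomSpec(
            motion=MotionProfile.constant_velocity(40, 0.5),
            width=260, height=130, noise_sigma=0.02, rho=0.02, seed=5,
        )
        seq, _ = render_sequence(spec)
        t1 = track(seq, Region(60, 40, 101, 41), default_config)
        t2 = track(seq, Region(60, 40, 101, 41), default_config)
        assert np.array_equal(t1.cumulative, t2.cumulative)
        assert np.array_equal(t1.is_anchor, t2.is_anchor)

    def test_drift_to_border_truncates_with_warning(self, default_config):
        # fast rightward motion with the region started near the right edge
        spec = PhantomSpec(
            motion=MotionProfile.constant_velocity(40, 3.0),
            width=300, height=130, seed=8,
        )
        seq, _ = render_sequence(spec)
        with pytest.warns(UserWarning):
            traj = track(seq, Region(170, 40, 101, 41), default_config)
        assert traj.truncated
        assert traj.n_frames < 40


class TestComparators:
    def test_static_sequence_all_methods_zero(self, default_config):
        seq = _static_sequence(10)
        region = Region(70, 40, 101, 41)
        for method in ("of_only", "mkbm_only", "adaptive_mkbm"):
            traj = track_comparator(seq, region, default_config, method)
            assert np.allclose(traj.cumulative, 0.0), method

    def test_adaptive_matches_oftb_at_anchors_only(self, default_config):
        spec = PhantomSpec(
            motion=MotionProfile.sinusoidal(60, 20.0, 60.0),
            width=300, height=130, noise_sigma=0.01, rho=0.0, seed=6,
        )
        seq, _ = render_sequence(spec)
        region = Region(100, 40, 101, 41)
        oftb = track(seq, region, default_config)
        adaptive = track_comparator(seq, region, default_config, "adaptive_mkbm")
        anchors = np.flatnonzero(oftb.is_anchor)
        assert np.allclose(oftb.cumulative[anchors], adaptive.cumulative[anchors])
        interior = ~oftb.is_anchor
        assert not np.allclose(oftb.dx[interior], adaptive.dx[interior])

    def test_unknown_method_rejected(self, default_config):
        seq = _static_sequence(4)
        with pytest.raises(ValueError, match="unknown comparator"):
            track_comparator(seq, Region(70, 40, 101, 41), default_config, "kalman")
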