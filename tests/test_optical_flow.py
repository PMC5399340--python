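"""Lucas-Kanade flow, direction voting, Va-N averaging and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendontrack import (
    FlowField,
    Region,
    TrackerConfig,
    VaNTable,
    calibrate_va_n,
    classify_direction,
    compute_flow_field,
    lucas_kanade_point,
    region_displacement,
)
from tendontrack.optical_flow import grid_positions

from conftest import smooth_image


def _field_from_vx(vx_values, vy_values=None) -> FlowField:
    """Hand-built 1-row flow field with given velocities."""
    vx = np.asarray(vx_values, dtype=float)[None, :]
    vy = (
        np.asarray(vy_values, dtype=float)[None, :]
        if vy_values is not None
        else np.zeros_like(vx)
    )
    n = vx.shape[1]
    return FlowField(0, np.arange(n), np.array([0]), vx, vy, np.isfinite(vx))


class TestLucasKanadePoint:
    def test_identical_frames_give_exact_zero(self):
        f = smooth_image((60, 60))
        fp = lucas_kanade_point(f, f, (30, 30), 17)
        assert fp.valid
        assert fp.vx == 0.0 and fp.vy == 0.0

    def test_unit_shift_recovered(self):
        f0 = smooth_image((60, 80))
        f1 = smooth_image((60, 80), shift_x=1.0)
        fp = lucas_kanade_point(f0, f1, (40, 30), 17)
        assert fp.valid
        assert abs(fp.vx - 1.0) < 0.05
        assert abs(fp.vy) < 0.05

    def test_textureless_window_is_invalid(self):
        f = np.full((40, 40), 0.5)
        fp = lucas_kanade_point(f, f, (20, 20), 17)
        assert not fp.valid
        assert np.isnan(fp.vx) and np.isnan(fp.vy)

    def test_center_outside_frame(self):
        f = smooth_image((40, 40))
        with pytest.raises(IndexError):
            lucas_kanade_point(f, f, (3, 20), 17)

    def test_even_window_rejected(self):
        f = smooth_image((40, 40))
        with pytest.raises(ValueError):
            lucas_kanade_point(f, f, (20, 20), 16)


class TestComputeFlowField:
    def test_default_grid_is_43_by_13(self, speckle_frame, centered_region, default_config):
        ff = compute_flow_field(speckle_frame, speckle_frame, centered_region, default_config)
        assert ff.grid_shape == (13, 43)
        assert ff.n_points == 559

    def test_identical_frames_all_zero(self, speckle_frame, centered_region, default_config):
        ff = compute_flow_field(speckle_frame, speckle_frame, centered_region, default_config)
        vx, vy = ff.valid_velocities()
        assert np.all(vx == 0.0) and np.all(vy == 0.0)

    def test_matches_pointwise_reference(self, shifted_speckle_pair, default_config):
        f0, f1 = shifted_speckle_pair(0.7, 0.2)
        region = Region(100, 60, 41, 31)
        ff = compute_flow_field(f0, f1, region, default_config)
        for iy in (0, 5):
            for ix in (0, 7):
                fp = lucas_kanade_point(
                    f0, f1, (int(ff.xs[ix]), int(ff.ys[iy])), default_config.of_window
                )
                assert fp.valid == bool(ff.valid[iy, ix])
                if fp.valid:
                    assert np.isclose(fp.vx, ff.vx[iy, ix], atol=1e-8)
                    assert np.isclose(fp.vy, ff.vy[iy, ix], atol=1e-8)

    def test_translation_equivariance(self, shifted_speckle_pair, default_config):
        f0, f1 = shifted_speckle_pair(0.5)
        r1 = Region(80, 50, 101, 41)
        r2 = r1.translated(6, 4)
        g0 = np.roll(np.roll(f0, 4, axis=0), 6, axis=1)
        g1 = np.roll(np.roll(f1, 4, axis=0), 6, axis=1)
        ff1 = compute_flow_field(f0, f1, r1, default_config)
        ff2 = compute_flow_field(g0, g1, r2, default_config)
        # interior nodes see identical data, so velocities match exactly
        assert np.allclose(
            ff1.vx[ff1.valid & ff2.valid], ff2.vx[ff1.valid & ff2.valid], atol=1e-10
        )

    def test_speckle_shift_two_px(self, shifted_speckle_pair, centered_region, default_config):
        f0, f1 = shifted_speckle_pair(2.0)
        ff = compute_flow_field(f0, f1, centered_region, default_config)
        rd = region_displacement(ff, config=default_config)
        assert abs(rd.dx - 2.0) < 0.2

    def test_underestimation_regime_at_large_shift(
        self, shifted_speckle_pair, centered_region, default_config
    ):
        # motivation for interval-based matching: single-step flow saturates
        for s in (5.0, 6.0):
            f0, f1 = shifted_speckle_pair(s)
            ff = compute_flow_field(f0, f1, centered_region, default_config)
            rd = region_displacement(ff, config=default_config)
            assert 0 < rd.dx < s

    def test_region_too_small(self, speckle_frame, default_config):
        with pytest.raises(ValueError):
            grid_positions(Region(0, 0, 10, 10), 17, 2)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "vx,expected",
        [(-0.3, "left"), (0.0, "ignored"), (0.7, "right"), (-1e-12, "left")],
    )
    def test_sign_rule(self, vx, expected):
        assert classify_direction(vx) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(float("nan"))


class TestRegionDisplacement:
    def test_identical_velocities_mean_is_identity(self):
        ff = _field_from_vx([0.8] * 12)
        rd = region_displacement(ff)
        assert rd.dx == pytest.approx(0.8)
        assert rd.direction == "right"

    def test_top_30_percent_of_ten(self):
        vals = [2.0, 1.8, 1.6, 1.4, 1.2, 1.0, 0.8, 0.6, 0.4, 0.2]
        table = VaNTable(((0.1, 30.0),))  # constant N = 30%
        rd = region_displacement(_field_from_vx(vals), va_n_table=table)
        assert rd.n_points_used == 3
        assert rd.dx == pytest.approx(np.mean([2.0, 1.8, 1.6]))  # = 1.8

    def test_va_1p5_maps_to_n_20_with_default_table(self):
        # 20 points whose top-5% (one point) magnitude is exactly 1.5
        vals = [1.5] + [0.5] * 19
        rd = region_displacement(_field_from_vx(vals))
        assert rd.va == pytest.approx(1.5)
        assert rd.n_percent == pytest.approx(20.0)
        assert rd.n_points_used == 4  # ceil(20 * 0.20)

    def test_majority_direction_wins(self):
        rd = region_displacement(_field_from_vx([1.0, 1.2, 0.9, -5.0]))
        assert rd.direction == "right"
        assert rd.dx > 0

    def test_tie_uses_previous_direction_else_none(self):
        ff = _field_from_vx([1.0, -1.0])
        rd = region_displacement(ff, prev_direction="left")
        assert rd.direction == "left" and rd.dx == -1.0
        rd2 = region_displacement(ff)
        assert rd2.direction == "none" and rd2.dx == 0.0

    def test_all_invalid_flagged_none(self):
        vx = np.full((1, 4), np.nan)
        ff = FlowField(0, np.arange(4), np.array([0]), vx, vx.copy(),
                       np.zeros_like(vx, dtype=bool))
        rd = region_displacement(ff)
        assert rd.direction == "none"
        assert rd.dx == 0.0 and rd.dy == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.permutations(list(range(8))))
    def test_invariant_under_point_reordering(self, perm):
        vals = np.array([1.9, 1.4, 1.1, 0.9, 0.7, 0.5, 0.3, 0.1])
        base = region_displacement(_field_from_vx(vals))
        shuffled = region_displacement(_field_from_vx(vals[perm]))
        assert shuffled.dx == pytest.approx(base.dx)
        assert shuffled.va == pytest.approx(base.va)


class TestCalibration:
    def _fields(self, rng, n_pairs=30, n_points=100, scale=1.0):
        fields = []
        for _ in range(n_pairs):
            vals = np.abs(rng.normal(scale, 0.4 * scale, n_points)) + 0.05
            fields.append(_field_from_vx(vals))
        return fields

    def test_truth_equal_to_top5_mean_gives_constant_5(self):
        rng = np.random.default_rng(0)
        records = []
        for ff in self._fields(rng):
            vx, _ = ff.valid_velocities()
            order = np.argsort(-np.abs(vx), kind="stable")
            k = max(1, int(np.ceil(0.05 * vx.size)))
            records.append((ff, float(vx[order[:k]].mean())))
        table = calibrate_va_n(records, gt_tolerance=1e-9)
        assert np.all(table.n == 5.0)

    def test_truth_equal_to_top50_mean_gives_about_50(self):
        rng = np.random.default_rng(1)
        records = []
        for ff in self._fields(rng):
            vx, _ = ff.valid_velocities()
            order = np.argsort(-np.abs(vx), kind="stable")
            k = max(1, int(np.ceil(0.50 * vx.size)))
            records.append((ff, float(vx[order[:k]].mean())))
        table = calibrate_va_n(records, gt_tolerance=1e-9)
        assert np.all(np.abs(table.n - 50.0) <= 2.0)

    def test_knots_strictly_increasing_in_va(self):
        rng = np.random.default_rng(2)
        records = []
        for scale in np.linspace(0.5, 3.0, 40):
            ff = self._fields(rng, n_pairs=1, scale=scale)[0]
            vx, _ = ff.valid_velocities()
            records.append((ff, float(np.median(vx))))
        table = calibrate_va_n(records)
        assert np.all(np.diff(table.va) > 0)
        assert np.all(np.diff(table.n) <= 0)  # monotone non-increasing N

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            calibrate_va_n([( _field_from_vx([1.0]), 1.0)] * 5)
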