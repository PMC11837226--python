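import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarekit.core import FeatureSeries
from flarekit.kinematics import (KeypointTable, clean_keypoints,
                                 compute_features, median_smooth,
                                 tail_geometry)


def table_from_arrays(x, y, conf, part="nose", fps=40.0, px_per_cm=1.0):
    return KeypointTable(
        data=pd.DataFrame({f"{part}_x": x, f"{part}_y": y,
                           f"{part}_likelihood": conf}),
        frame_rate=fps, px_per_cm=px_per_cm)


class TestCleanKeypoints:
    def test_low_confidence_interpolated(self):
        # confidence 0.79 between valid neighbors at (0,0) and (2,2) -> (1,1)
        t = table_from_arrays([0.0, 5.0, 2.0], [0.0, 5.0, 2.0],
                              [1.0, 0.79, 1.0])
        out = clean_keypoints(t)
        assert out.data.loc[1, "nose_x"] == pytest.approx(1.0)
        assert out.data.loc[1, "nose_y"] == pytest.approx(1.0)

    def test_confidence_exactly_at_threshold_retained(self):
        t = table_from_arrays([0.0, 5.0, 2.0], [0.0, 5.0, 2.0],
                              [1.0, 0.8, 1.0])
        out = clean_keypoints(t)
        assert out.data.loc[1, "nose_x"] == 5.0

    def test_jump_rule_16px_dropped_14px_retained(self):
        t16 = table_from_arrays([0.0, 16.0, 0.0], [0.0, 0.0, 0.0],
                                [1.0, 1.0, 1.0])
        out16 = clean_keypoints(t16)
        assert out16.data.loc[1, "nose_x"] == pytest.approx(0.0)
        t14 = table_from_arrays([0.0, 14.0, 0.0], [0.0, 0.0, 0.0],
                                [1.0, 1.0, 1.0])
        out14 = clean_keypoints(t14)
        assert out14.data.loc[1, "nose_x"] == 14.0

    def test_jump_compared_to_previous_retained_sample(self):
        # one outlier must not mask subsequent good points near the track
        t = table_from_arrays([0.0, 100.0, 1.0, 2.0], [0.0] * 4, [1.0] * 4)
        out = clean_keypoints(t)
        assert out.data.loc[2, "nose_x"] == 1.0
        assert out.data.loc[3, "nose_x"] == 2.0

    def test_clean_is_noop_on_good_data(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 1, 50))
        t = table_from_arrays(x, x * 0.5, np.ones(50))
        out = clean_keypoints(t)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_leading_trailing_fill_nearest(self):
        t = table_from_arrays([9.0, 1.0, 2.0, 9.0], [0.0] * 4,
                              [0.1, 1.0, 1.0, 0.1])
        out = clean_keypoints(t)
        assert out.data.loc[0, "nose_x"] == 1.0
        assert out.data.loc[3, "nose_x"] == 2.0

    def test_all_invalid_keypoint_errors_with_name(self):
        t = table_from_arrays([0.0, 1.0], [0.0, 0.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="nose"):
            clean_keypoints(t)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = np.cumsum(rng.normal(0, 4, n))
        y = np.cumsum(rng.normal(0, 4, n))
        conf = rng.choice([0.5, 0.85, 1.0], size=n)
        conf[rng.integers(0, n)] = 1.0    # ensure at least one valid sample
        t = table_from_arrays(x, y, conf)
        once = clean_keypoints(t)
        twice = clean_keypoints(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


def rectangle_contour(length=100.0, width=10.0, n_side=150):
    """Closed rectangle polygon along +x, nose at (length, 0)."""
    top = np.column_stack([np.linspace(0, length, n_side),
                           np.full(n_side, width / 2)])
    bot = np.column_stack([np.linspace(length, 0, n_side),
                           np.full(n_side, -width / 2)])
    return np.vstack([top, bot])


class TestTailGeometry:
    def test_straight_fish_zero_angle_and_deviation(self):
        contour = rectangle_contour(width=1.0)
        g = tail_geometry(contour, head_kp=(100.0, 0.0), tail_kp=(0.0, 0.0))
        assert g.tail_angle == pytest.approx(0.0, abs=0.5)
        assert g.tail_deviation == pytest.approx(0.0, abs=0.75)  # half-width

    def test_rotated_tail_recovers_angle(self):
        # bend the last 30% of a thin contour by 30 degrees about the peduncle
        n = 300
        xs = np.linspace(0, 100, n)
        ys = np.zeros(n)
        pivot = 70.0
        bend = xs > pivot
        ang = np.deg2rad(30.0)
        # rotate bent section about (pivot, 0); tail extends away from head
        xr = pivot + (xs[bend] - pivot) * np.cos(ang)
        yr = (xs[bend] - pivot) * np.sin(ang)
        upper = np.column_stack([np.concatenate([xs[~bend], xr]),
                                 np.concatenate([ys[~bend], yr]) + 0.5])
        lower = upper[::-1].copy()
        lower[:, 1] -= 1.0
        contour = np.vstack([upper, lower])
        tail_tip = contour[np.argmax(contour[:, 0] * 0 + contour[:, 1])]
        g = tail_geometry(contour, head_kp=(0.0, 0.0),
                          tail_kp=(xr[-1], yr[-1]))
        assert g.tail_angle == pytest.approx(30.0, abs=2.0)

    def test_marker_on_vertex_is_nearest_point(self):
        contour = rectangle_contour()
        g = tail_geometry(contour, head_kp=tuple(contour[3]),
                          tail_kp=(0.0, 0.0))
        np.testing.assert_array_equal(g.contour_head, contour[3])


def straight_track_table(n=30, fps=40.0, px_per_cm=10.0):
    parts = {}
    x = np.linspace(0, 10, n)
    layout = {"nose": (20.0, 0.0), "spine1": (10.0, 0.0), "spine2": (0.0, 0.0),
              "spine3": (-10.0, 0.0), "tail": (-20.0, 0.0),
              "left_operculum": (12.0, 6.0), "right_operculum": (12.0, -6.0)}
    for part, (dx, dy) in layout.items():
        parts[f"{part}_x"] = x + dx
        parts[f"{part}_y"] = np.zeros(n) + dy
        parts[f"{part}_likelihood"] = np.ones(n)
    return KeypointTable(data=pd.DataFrame(parts), frame_rate=fps,
                         px_per_cm=px_per_cm)


class TestComputeFeatures:
    def test_stationary_speed_zero(self):
        t = straight_track_table()
        t.data.loc[:, [c for c in t.data.columns if c.endswith("_x")]] = \
            t.data.iloc[0][[c for c in t.data.columns if c.endswith("_x")]].values
        fs = compute_features(t)
        assert np.allclose(fs.channel("speed")[1:], 0.0)

    def test_hand_kinematics_speed(self):
        # centroid displacement (3, 4) px/frame, 10 px/cm, 40 fps -> 20 cm/s
        n = 10
        parts = {}
        for part in ("nose", "spine1", "spine2", "spine3"):
            dx = {"nose": 20.0, "spine1": 10.0, "spine2": 0.0, "spine3": -10.0}
            parts[f"{part}_x"] = 3.0 * np.arange(n) + dx[part]
            parts[f"{part}_y"] = 4.0 * np.arange(n)
            parts[f"{part}_likelihood"] = np.ones(n)
        t = KeypointTable(data=pd.DataFrame(parts), frame_rate=40.0,
                          px_per_cm=10.0)
        fs = compute_features(t)
        assert np.allclose(fs.channel("speed")[1:], 20.0)

    def test_orientation_against_stimulus_normal(self):
        t = straight_track_table()
        fs = compute_features(t, stimulus_normal=(1.0, 0.0))
        assert np.allclose(fs.channel("orientation"), 0.0, atol=1e-9)
        fs90 = compute_features(t, stimulus_normal=(0.0, 1.0))
        assert np.allclose(fs90.channel("orientation"), 90.0)

    def test_operculum_angle_flare_ordering(self, dyad_trial, rendered_table):
        from flarekit.simulate import classify_operculum_angle
        fs = compute_features(rendered_table)
        truth = dyad_trial.agents[0].flare_class
        ang = fs.channel("operculum_angle")
        full = ang[truth == 2]
        partial = ang[truth == 1]
        if len(full) and len(partial):
            assert full.min() > partial.max()
        # fixed thresholds recover the ground-truth class on all clean frames
        assert (classify_operculum_angle(ang) == truth).mean() >= 0.99

    def test_z_channels_absent_without_side_view(self):
        fs = compute_features(straight_track_table())
        assert "elevation" not in fs.channels
        assert "elevation" in fs.meta["absent_channels"]

    def test_elevation_from_side_view(self):
        t = straight_track_table()
        side = straight_track_table(px_per_cm=10.0)
        side.data.loc[:, "nose_y"] = 80.0    # 80 px above floor at y=180
        fs = compute_features(t, side_table=side, tank_floor_y=180.0)
        assert np.allclose(fs.channel("elevation"), 10.0)

    def test_translation_invariance(self):
        t = straight_track_table()
        shifted = KeypointTable(data=t.data.copy(), frame_rate=t.frame_rate,
                                px_per_cm=t.px_per_cm)
        for c in shifted.data.columns:
            if c.endswith("_x"):
                shifted.data[c] += 123.0
            elif c.endswith("_y"):
                shifted.data[c] -= 45.0
        a = compute_features(t)
        b = compute_features(shifted)
        for ch in ("orientation", "speed", "turning_angle", "operculum_angle"):
            np.testing.assert_allclose(a.channel(ch), b.channel(ch), atol=1e-9)


class TestKeypointIO:
    def test_flat_csv_round_trip(self, tmp_path):
        t = straight_track_table()
        t.to_csv(tmp_path / "kp.csv")
        back = KeypointTable.from_csv(tmp_path / "kp.csv", px_per_cm=10.0)
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_multirow_pose_tracker_header(self, tmp_path):
        # scorer / bodyparts / coords header rows are collapsed
        lines = ["scorer,m,m,m,m,m,m",
                 "bodyparts,nose,nose,nose,tail,tail,tail",
                 "coords,x,y,likelihood,x,y,likelihood",
                 "0,1.0,2.0,0.9,3.0,4.0,0.8",
                 "1,1.5,2.5,0.95,3.5,4.5,0.85"]
        p = tmp_path / "dlc.csv"
        p.write_text("\n".join(lines))
        t = KeypointTable.from_csv(p)
        assert t.bodyparts == ["nose", "tail"]
        assert t.n_frames == 2
        np.testing.assert_allclose(t.xy("tail")[1], [3.5, 4.5])
        np.testing.assert_allclose(t.confidence("nose"), [0.9, 0.95])


class TestMedianSmooth:
    def make_series(self, values, fps=40.0):
        return FeatureSeries(data=pd.DataFrame({"ch": values}), frame_rate=fps)

    def test_window_span_seconds(self):
        fs = median_smooth(self.make_series(np.zeros(20)), 11)
        assert fs.meta["smoothing_window_s"] == pytest.approx(0.275)

    def test_constant_unchanged(self):
        fs = median_smooth(self.make_series(np.full(30, 7.0)))
        assert np.allclose(fs.channel("ch"), 7.0)

    def test_spike_removed_matches_direct_sliding_median(self):
        x = np.zeros(31)
        x[15] = 1.0
        out = median_smooth(self.make_series(x), 11).channel("ch")
        # independent direct sliding median with shrunken edge windows
        expected = np.array([np.median(x[max(0, i - 5):i + 6])
                             for i in range(31)])
        np.testing.assert_allclose(out, expected)
        assert out[15] == 0.0

    def test_even_window_errors(self):
        with pytest.raises(ValueError):
            median_smooth(self.make_series(np.zeros(5)), 4)
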