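"""Spout-distance geometry, path length, histograms, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from waterreach import (
    GeometryError,
    WindowError,
    bin_distances,
    build_timeline,
    lift_trace,
    path_length,
    per_mouse_stats,
    spout_distance,
    trajectory_stats,
)
from waterreach.trials import REWARDED

from conftest import make_tracks

RATE = 60.0


def _rest_xy(n, geometry, x=100.0):
    return np.column_stack([np.full(n, x), np.full(n, geometry.platform_y)])


class TestSpoutDistance:
    def test_constant_landmarks(self, geometry, resting_tracks):
        geom = spout_distance(resting_tracks)
        assert geom.spout_distance_px == pytest.approx(40.0)

    def test_median_robust_to_jitter(self, geometry):
        rng = np.random.default_rng(7)
        n = 960
        tracks = make_tracks(_rest_xy(n, geometry), geometry)
        df = tracks.data.copy()
        for kp in ("platform", "spout"):
            df[(kp, "y")] = df[(kp, "y")].to_numpy() + rng.uniform(-1, 1, n)
        from waterreach import PoseTracks

        jittered = PoseTracks(df, RATE)
        assert spout_distance(jittered).spout_distance_px == pytest.approx(
            40.0, abs=1.0
        )

    def test_zero_distance_rejected(self, geometry):
        n = 100
        tracks = make_tracks(_rest_xy(n, geometry), geometry)
        df = tracks.data.copy()
        df[("spout", "y")] = geometry.platform_y  # spout at platform height
        from waterreach import PoseTracks

        with pytest.raises(GeometryError):
            spout_distance(PoseTracks(df, RATE))

    def test_too_few_confident_frames(self, geometry):
        n = 100
        tracks = make_tracks(_rest_xy(n, geometry), geometry)
        df = tracks.data.copy()
        conf = np.full(n, 0.1)
        conf[:5] = 1.0
        df[("spout", "confidence")] = conf
        from waterreach import PoseTracks

        with pytest.raises(GeometryError):
            spout_distance(PoseTracks(df, RATE))


class TestPathLength:
    def test_stationary_paw_zero(self, geometry):
        tracks = make_tracks(_rest_xy(960, geometry), geometry)
        tl = build_timeline(REWARDED, None)
        assert path_length(tracks, tl, geometry).value == 0.0

    def test_straight_vertical_reach_is_one(self, geometry):
        """A lift of exactly one spout distance inside the window -> 1.0."""
        n = 960
        xy = _rest_xy(n, geometry)
        i0, i1 = 360, 425  # frames inside [6.0, 7.1)
        ramp = np.linspace(0.0, geometry.spout_distance_px, i1 - i0 + 1)
        xy[i0 : i1 + 1, 1] = geometry.platform_y - ramp
        xy[i1 + 1 :, 1] = xy[i1, 1]
        tracks = make_tracks(xy, geometry)
        tl = build_timeline(REWARDED, None)
        res = path_length(tracks, tl, geometry)
        assert res.value == pytest.approx(1.0, rel=1e-12)
        assert not res.flagged

    def test_zigzag_matches_bruteforce(self, geometry):
        """Hand-listed 10-point zigzag equals direct segment summation."""
        pts = np.array(
            [
                [100.0, 200.0],
                [103.0, 195.0],
                [99.0, 188.0],
                [104.5, 181.0],
                [101.2, 174.3],
                [106.0, 168.8],
                [102.3, 162.0],
                [108.0, 158.5],
                [105.1, 153.0],
                [110.0, 150.0],
            ]
        )
        n = 960
        xy = _rest_xy(n, geometry)
        xy[360:370] = pts
        xy[370:] = pts[-1]
        tracks = make_tracks(xy, geometry)
        tl = build_timeline(REWARDED, None)
        got = path_length(tracks, tl, geometry).value
        # oracle: explicit pairwise segment sum over the window frames
        window = xy[360:426]
        expected = sum(
            float(np.hypot(*(window[i + 1] - window[i])))
            for i in range(len(window) - 1)
        ) / geometry.spout_distance_px
        assert got == pytest.approx(expected, rel=1e-9)

    def test_window_not_covered(self, geometry):
        tracks = make_tracks(_rest_xy(420, geometry), geometry)  # 7.0 s
        tl = build_timeline(REWARDED, None)
        with pytest.raises(WindowError):
            path_length(tracks, tl, geometry)

    def test_long_gap_flags_result(self, geometry):
        xy = _rest_xy(960, geometry)
        conf = np.ones(960)
        conf[380:395] = 0.1  # 15-frame dropout inside the window
        tracks = make_tracks(xy, geometry, confidence=conf)
        tl = build_timeline(REWARDED, None)
        assert path_length(tracks, tl, geometry).flagged

    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        zoom=st.floats(0.5, 2.0),
    )
    @settings(derandomize=True, max_examples=25)
    def test_translation_and_zoom_invariance(self, dx, dy, zoom, geometry):
        """Normalization by spout distance cancels global shifts and zoom."""
        rng = np.random.default_rng(11)
        xy = _rest_xy(960, geometry)
        xy[360:426] += np.cumsum(rng.normal(0, 1.5, (66, 2)), axis=0)
        tl = build_timeline(REWARDED, None)
        base = path_length(
            make_tracks(xy, geometry), tl, spout_distance(make_tracks(xy, geometry))
        ).value
        moved_xy = xy * zoom + np.array([dx, dy])
        from waterreach import SpoutGeometry

        moved = make_tracks(
            moved_xy,
            SpoutGeometry(
                spout_distance_px=geometry.spout_distance_px * zoom,
                platform_y=geometry.platform_y * zoom + dy,
                spout_y=geometry.spout_y * zoom + dy,
                platform_x=geometry.platform_x * zoom + dx,
                spout_x=geometry.spout_x * zoom + dx,
            ),
        )
        got = path_length(moved, tl, spout_distance(moved)).value
        assert got == pytest.approx(base, rel=1e-9)

    def test_exceeds_net_displacement(self, geometry):
        """Path length >= straight-line displacement (triangle inequality)."""
        rng = np.random.default_rng(13)
        xy = _rest_xy(960, geometry)
        xy[360:426] += np.cumsum(rng.normal(0, 2.0, (66, 2)), axis=0)
        tracks = make_tracks(xy, geometry)
        tl = build_timeline(REWARDED, None)
        total = path_length(tracks, tl, geometry).value
        net = float(np.hypot(*(xy[425] - xy[360]))) / geometry.spout_distance_px
        assert total >= net - 1e-12


class TestBinDistances:
    def test_worked_example_bin_four(self):
        hist = bin_distances([4.0, 4.2, 4.9])
        assert list(hist.index) == [4]
        assert hist.loc[4] == pytest.approx(100.0)

    def test_empty_input(self):
        assert bin_distances([]).empty

    def test_mass_sums_to_100(self):
        rng = np.random.default_rng(5)
        hist = bin_distances(rng.uniform(0, 8, 500))
        assert hist.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_truncated_normal_cdf(self):
        """1000 truncated-normal draws: bins 1-3 match analytic masses."""
        rng = np.random.default_rng(17)
        draws = rng.normal(2.1, 0.6, 4000)
        draws = draws[draws >= 0][:1000]
        assert len(draws) == 1000
        hist = bin_distances(draws)
        norm = stats.norm(2.1, 0.6)
        z = 1.0 - norm.cdf(0.0)  # truncation renormalization
        for k in (1, 2, 3):
            analytic = (norm.cdf(k + 1) - norm.cdf(k)) / z * 100.0
            assert hist.get(k, 0.0) == pytest.approx(analytic, abs=3.0)


class TestTrajectoryStats:
    def test_single_mouse_mean_and_sample_sd(self):
        out = per_mouse_stats({"m1": [1.0, 3.0]})
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(2.0))

    def test_genotype_mean_ignores_trial_counts(self):
        """Mice averaging 2 and 4 give a genotype mean of 3 even with
        wildly unequal trial counts (hierarchy is never pooled)."""
        stats_ = trajectory_stats(
            {"m1": [2.0] * 3, "m2": [4.0] * 200}
        )
        assert stats_["mean_of_means"] == pytest.approx(3.0)

    def test_recovers_configured_mean(self):
        """6 mice x 50 draws at N(2.1, 0.6): group mean within 3 SEM."""
        rng = np.random.default_rng(23)
        lengths = {
            f"m{i}": list(rng.normal(2.1, 0.6, 50)) for i in range(6)
        }
        out = trajectory_stats(lengths)
        assert abs(out["mean_of_means"] - 2.1) <= 3 * out["sem_of_means"] + 1e-12


class TestLiftTrace:
    def test_resting_paw_near_zero(self, geometry, resting_tracks):
        trace = lift_trace(resting_tracks, geometry)
        assert np.nanmax(np.abs(trace)) < 1e-9

    def test_success_trial_peak_inside_reach_window(self, synth_geometry):
        from waterreach import build_timeline, simulate_trajectory

        rng = np.random.default_rng(3)
        tl = build_timeline(REWARDED, 6.8)
        tracks = simulate_trajectory(
            "success", synth_geometry, 2.0, rng, timeline=tl, reach_onset_s=6.2
        )
        trace = lift_trace(tracks.truncate(10.0), synth_geometry)
        t_peak = np.nanargmax(trace) / tracks.rate
        assert 6.0 <= t_peak < 7.1

    def test_early_reach_bump_before_reward(self, synth_geometry):
        from waterreach import build_timeline, simulate_trajectory

        rng = np.random.default_rng(3)
        tl = build_timeline(REWARDED, 6.8)
        tracks = simulate_trajectory(
            "success",
            synth_geometry,
            2.0,
            rng,
            timeline=tl,
            reach_onset_s=6.2,
            early_reach_time_s=4.0,
        )
        trace = lift_trace(tracks, synth_geometry)
        pre = trace[: int(6.0 * tracks.rate)]
        lift_threshold_px = 0.10 * synth_geometry.spout_distance_px
        assert np.nanmax(pre) > lift_threshold_px
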