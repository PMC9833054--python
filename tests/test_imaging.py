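"""Demultiplexing, dF/F, hemodynamic correction, atlas, peaks, areas."""

import logging

import numpy as np
import pytest

from waterreach import (
    ChannelMovie,
    DFFMovie,
    ImagingError,
    RegistrationError,
    StrobedStack,
    WindowError,
    area_activated,
    build_timeline,
    compute_dff,
    default_atlas,
    demultiplex,
    extract_trace,
    hemodynamic_correct,
    peak_amplitude,
    register_atlas,
    search_window,
)
from waterreach.imaging import FLUORESCENCE, REFLECTANCE, ROITrace
from waterreach.trials import NONREWARDED, REWARDED


def _stack(n, h=4, w=4, even=1000, odd=2000):
    frames = np.empty((n, h, w), np.uint16)
    frames[0::2] = even
    frames[1::2] = odd
    return StrobedStack(frames)


class TestDemultiplex:
    def test_even_split(self):
        fluo, refl = demultiplex(_stack(1920))
        assert fluo.frames.shape[0] == refl.frames.shape[0] == 960
        assert fluo.rate == refl.rate == 60.0
        assert fluo.channel == FLUORESCENCE
        assert refl.channel == REFLECTANCE

    def test_channel_values_separated(self):
        fluo, refl = demultiplex(_stack(20, even=1111, odd=3333))
        assert np.all(fluo.frames == 1111)
        assert np.all(refl.frames == 3333)

    def test_odd_frame_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="waterreach.imaging"):
            fluo, refl = demultiplex(_stack(21))
        assert fluo.frames.shape[0] == refl.frames.shape[0] == 10
        assert any("unpaired" in r.message for r in caplog.records)

    def test_single_frame_rejected(self):
        with pytest.raises(ImagingError):
            demultiplex(_stack(1))

    def test_reversed_channel_order(self):
        stack = _stack(20, even=500, odd=900)
        stack.channel_order = (REFLECTANCE, FLUORESCENCE)
        fluo, refl = demultiplex(stack)
        assert np.all(fluo.frames == 900)
        assert np.all(refl.frames == 500)


def _movie(frames, rate=60.0):
    return ChannelMovie(np.asarray(frames, np.float32), rate, FLUORESCENCE)


class TestComputeDff:
    def test_constant_movie_is_zero(self):
        dff = compute_dff(_movie(np.full((600, 3, 3), 1000.0)), (0.0, 6.0))
        assert np.all(dff.values == 0.0)

    def test_five_percent_step(self):
        frames = np.full((600, 2, 2), 1000.0)
        frames[360:] = 1050.0  # +5% after the 6-s baseline
        dff = compute_dff(_movie(frames), (0.0, 6.0))
        assert dff.values[:360] == pytest.approx(0.0)
        assert dff.values[360:] == pytest.approx(5.0)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(2)
        frames = 1000.0 + rng.normal(0, 5, (600, 4, 4))
        dff = compute_dff(_movie(frames), (0.0, 6.0))
        assert np.abs(dff.values[:360].mean(axis=0)).max() < 1e-4

    def test_dark_pixels_masked(self):
        frames = np.full((600, 2, 2), 1000.0)
        frames[:, 0, 0] = 0.0  # dead pixel
        dff = compute_dff(_movie(frames), (0.0, 6.0))
        assert not dff.valid_mask[0, 0]
        assert np.all(dff.values[:, 0, 0] == 0.0)

    def test_all_dark_rejected(self):
        with pytest.raises(ImagingError):
            compute_dff(_movie(np.zeros((600, 2, 2))), (0.0, 6.0))

    def test_baseline_beyond_movie_rejected(self):
        with pytest.raises(WindowError):
            compute_dff(_movie(np.full((100, 2, 2), 1000.0)), (0.0, 6.0))


class TestHemodynamicCorrect:
    def _dff(self, values):
        v = np.asarray(values, np.float32)
        return DFFMovie(v, 60.0, (0.0, 6.0), valid_mask=np.ones(v.shape[1:], bool))

    def test_identical_channels_cancel(self):
        v = np.random.default_rng(3).normal(0, 1, (100, 3, 3))
        out = hemodynamic_correct(self._dff(v), self._dff(v))
        assert np.abs(out.values).max() == 0.0
        assert out.corrected

    def test_shared_artifact_removed_signal_kept(self):
        t = np.arange(600) / 60.0
        artifact = np.sin(2 * np.pi * 0.1 * t)[:, None, None] * np.ones((1, 2, 2))
        signal = np.zeros((600, 2, 2))
        signal[400:, 0, 0] = 3.0
        out = hemodynamic_correct(
            self._dff(signal + artifact), self._dff(artifact)
        )
        assert out.values == pytest.approx(signal.astype(np.float32), abs=1e-5)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ImagingError):
            hemodynamic_correct(
                self._dff(np.zeros((10, 2, 2))), self._dff(np.zeros((10, 3, 3)))
            )

    def test_mismatched_baselines_rejected(self):
        a = self._dff(np.zeros((10, 2, 2)))
        b = self._dff(np.zeros((10, 2, 2)))
        b.baseline_window_s = (0.0, 5.0)
        with pytest.raises(ImagingError):
            hemodynamic_correct(a, b)


class TestAtlasRegistration:
    def test_default_atlas_complete(self):
        atlas = default_atlas((128, 128))
        assert len(atlas.names) == 24
        for name in atlas.names:
            assert atlas.mask(name).any()

    def test_identity_landmarks(self):
        atlas = default_atlas((64, 64))
        out = register_atlas(atlas.landmarks, atlas)
        assert out.residual_px == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(out.label_image, atlas.label_image)

    def test_pure_translation(self):
        atlas = default_atlas((96, 96))
        shifted = {k: (x + 5.0, y - 3.0) for k, (x, y) in atlas.landmarks.items()}
        out = register_atlas(shifted, atlas, output_shape=(96, 96))
        assert out.residual_px == pytest.approx(0.0, abs=1e-6)
        # recovered affine is [I | t] with t = (+5, -3)
        assert out.affine[:, :2] == pytest.approx(np.eye(2), abs=1e-9)
        assert out.affine[:, 2] == pytest.approx([5.0, -3.0], abs=1e-6)

    def test_rotation_scale_recovered(self):
        atlas = default_atlas((128, 128))
        theta, s = np.deg2rad(8.0), 1.05
        rot = s * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([4.0, 2.0])
        moved = {
            k: tuple(rot @ np.array(v) + shift)
            for k, v in atlas.landmarks.items()
        }
        out = register_atlas(moved, atlas)
        assert out.residual_px < 1e-6
        assert out.affine[:, :2] == pytest.approx(rot, abs=1e-9)

    def test_collinear_landmarks_rejected(self):
        atlas = default_atlas((64, 64))
        collinear = {
            "bregma": (10.0, 10.0),
            "lambda": (20.0, 20.0),
            "anchor_left": (30.0, 30.0),
            "anchor_right": (40.0, 40.0),
        }
        with pytest.raises(RegistrationError):
            register_atlas(collinear, atlas)

    def test_too_few_landmarks_rejected(self):
        atlas = default_atlas((64, 64))
        with pytest.raises(RegistrationError):
            register_atlas({"bregma": (1.0, 1.0), "lambda": (2.0, 5.0)}, atlas)


class TestExtractTrace:
    def test_uniform_movie(self):
        atlas = default_atlas((64, 64))
        dff = DFFMovie(np.full((30, 64, 64), 3.0, np.float32), 60.0, (0.0, 0.5))
        trace = extract_trace(dff, atlas, "M1_contra")
        assert trace.values == pytest.approx(3.0)

    def test_center_delta_weighted_by_window(self):
        """A single bright pixel at the centroid contributes 1/25 of its value."""
        atlas = default_atlas((64, 64))
        from waterreach.imaging import _round_half_down

        cr, cc = atlas.centroid("M1_contra")
        r, c = _round_half_down(cr), _round_half_down(cc)
        values = np.zeros((10, 64, 64), np.float32)
        values[:, r, c] = 25.0
        dff = DFFMovie(values, 60.0, (0.0, 0.1))
        trace = extract_trace(dff, atlas, "M1_contra")
        assert trace.values == pytest.approx(1.0)

    def test_unknown_roi(self):
        atlas = default_atlas((64, 64))
        dff = DFFMovie(np.zeros((10, 64, 64), np.float32), 60.0, (0.0, 0.1))
        with pytest.raises(KeyError):
            extract_trace(dff, atlas, "cerebellum_contra")


class TestPeakAmplitude:
    def _trace(self, values):
        return ROITrace(np.asarray(values, float), 60.0, "M1_contra")

    def test_flat_trace_zero(self):
        tl = build_timeline(REWARDED, 6.5)
        res = peak_amplitude(self._trace(np.zeros(600)), tl, "success")
        assert res.amplitude == 0.0

    def test_plateau_above_baseline(self):
        tl = build_timeline(REWARDED, 6.5)
        v = np.zeros(600)
        v[60:300] = 1.0  # baseline window [1, 5) sits at 1.0
        v[380:420] = 7.0  # response plateau inside [6, 10)
        res = peak_amplitude(self._trace(v), tl, "success")
        assert res.amplitude == pytest.approx(6.0)
        assert res.baseline_mean == pytest.approx(1.0)
        assert res.peak_time_s == pytest.approx(380 / 60.0)

    def test_success_window_excludes_precue_peak(self):
        """A pre-reward bump is invisible to the success search window but
        found by the full-trial unrewarded window."""
        v = np.zeros(600)
        v[200] = 9.0  # bump at 3.33 s, before the reward
        v[400] = 2.0  # smaller response after the reward
        rew = build_timeline(REWARDED, 6.5)
        non = build_timeline(NONREWARDED)
        assert peak_amplitude(self._trace(v), rew, "success").amplitude < 9.0
        got = peak_amplitude(self._trace(v), non, "unrewarded_reach")
        assert got.amplitude == pytest.approx(9.0 - 9.0 / 240.0)  # bump in baseline

    def test_no_window_for_no_reach(self):
        tl = build_timeline(REWARDED, None)
        with pytest.raises(WindowError):
            search_window(tl, "no_reach")

    def test_earliest_tie_wins(self):
        tl = build_timeline(REWARDED, 6.5)
        v = np.zeros(600)
        v[390] = 5.0
        v[450] = 5.0
        res = peak_amplitude(self._trace(v), tl, "success")
        assert res.peak_time_s == pytest.approx(390 / 60.0)


class TestAreaActivated:
    def _dff(self, values):
        v = np.asarray(values, np.float32)
        return DFFMovie(v, 60.0, (0.0, 6.0), valid_mask=np.ones(v.shape[1:], bool))

    def test_quiet_noise_floor(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 0.2, (600, 16, 16))
        tl = build_timeline(REWARDED, 6.5)
        out = area_activated(self._dff(v), tl, "success", np.ones((16, 16), bool))
        # max of 240 N(0, sd) draws exceeding 4 sd-hat is rare; allow a few
        assert out.pixel_count <= 10
        assert out.n_eligible == 256

    def test_exact_blob_recovered(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 0.2, (600, 16, 16))
        v[380:420, 4:9, 4:9] += 10.0  # 25-pixel response at 50 x noise SD
        tl = build_timeline(REWARDED, 6.5)
        out = area_activated(self._dff(v), tl, "success", np.ones((16, 16), bool))
        blob = np.zeros((16, 16), bool)
        blob[4:9, 4:9] = True
        assert out.pixel_count >= 25
        assert out.area_mm2 == pytest.approx(out.pixel_count * 0.068**2)

    def test_zero_variance_pixels_excluded(self):
        v = np.zeros((600, 8, 8))
        v[400, 2, 2] = 1.0  # response without any baseline variance
        tl = build_timeline(REWARDED, 6.5)
        out = area_activated(self._dff(v), tl, "success", np.ones((8, 8), bool))
        assert out.pixel_count == 0
        assert out.n_zero_variance == 64

    def test_brain_mask_respected(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 0.2, (600, 8, 8))
        v[380:420] += 10.0  # everything responds
        tl = build_timeline(REWARDED, 6.5)
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        out = area_activated(self._dff(v), tl, "success", mask)
        assert out.pixel_count == 32
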