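"""Synthetic water-reaching sessions with recorded ground truth.

Emulates the three acquisition streams of the task — trial event log, 60-Hz
pose tracks, and 120-Hz strobed two-channel widefield movies — with the
statistical structure of the real experiment: strictly alternating
rewarded/nonrewarded trials starting rewarded, per-category behavioral
repertoires (success, partial fail, complete fail, no reach, groom,
unrewarded reach), reach path lengths in spout-distance multiples, and
ROI-localized GCaMP transients riding on a shared hemodynamic artifact that
appears in both channels.  Every sampled latent is recorded per trial so
downstream stages can be validated against known truth.

All randomness flows from one session seed; each trial uses the substream
``default_rng([seed, trial_index])``, so outputs are bit-reproducible and
independent of how many trials are generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .atlas import AtlasROIMap, default_atlas
from .errors import ConfigError
from .imaging import FLUORESCENCE, MAX_12BIT, REFLECTANCE, StrobedStack
from .kinematics import REACH_WINDOW_S, SpoutGeometry
from .pose import PoseTracks, frame_window
from .trials import (
    NONREWARDED,
    REWARDED,
    TONE_S,
    TrialTimeline,
    build_timeline,
)

REWARDED_CATEGORIES = ("success", "partial_fail", "complete_fail", "no_reach", "groom")
NONREWARDED_CATEGORIES = ("unrewarded_reach", "no_reach")
REACH_CATEGORIES = ("success", "partial_fail", "complete_fail", "unrewarded_reach")

# GCaMP6s-like transient kernel (difference of exponentials), seconds
KERNEL_RISE_S = 0.1
KERNEL_DECAY_S = 1.0

# hemodynamic/movement artifact: slow sinusoid plus a causal reach-locked
# bump (movement artifacts are instantaneous with the reach; blood-volume
# changes lag slightly) -- zero before reach onset so the pre-reward F0
# baseline stays uncontaminated
HEMO_SINE_HZ = 0.1
HEMO_SINE_AMP = 0.3  # relative to unit gain
HEMO_BUMP_AMP = 1.0
HEMO_BUMP_RISE_S = 0.15
HEMO_BUMP_DECAY_S = 1.2

CONTACT_DELAY_S = 0.8  # reward -> spout contact for contact categories


def _default_rewarded_probs() -> dict[str, float]:
    return {
        "success": 0.70,
        "partial_fail": 0.10,
        "complete_fail": 0.05,
        "no_reach": 0.10,
        "groom": 0.05,
    }


def _default_nonrewarded_probs() -> dict[str, float]:
    return {"unrewarded_reach": 0.30, "no_reach": 0.70}


def _default_roi_amplitudes() -> dict[str, float]:
    # percent dF/F; plausible mesoscale GCaMP6s transient sizes (2-8%)
    return {
        "M1_contra": 5.0,
        "M2_contra": 4.0,
        "sspfl_contra": 4.5,
        "M1_ipsi": 3.0,
        "rspd_contra": 2.0,
    }


@dataclass
class SynthConfig:
    """Session-level generator parameters (the study conditions)."""

    n_trials: int = 120
    frame_rate_behavior: float = 60.0
    frame_rate_imaging_combined: float = 120.0
    image_shape: tuple[int, int] = (128, 128)
    spout_distance_px: float = 40.0
    rewarded_category_probs: dict[str, float] = field(
        default_factory=_default_rewarded_probs
    )
    nonrewarded_category_probs: dict[str, float] = field(
        default_factory=_default_nonrewarded_probs
    )
    early_reach_probability: float = 0.2
    trajectory_length_mean: float = 2.1
    trajectory_length_sd: float = 0.6
    roi_peak_amplitudes: dict[str, float] = field(
        default_factory=_default_roi_amplitudes
    )
    hemodynamic_gain_fluo: float = 2.0  # percent on the unit waveform
    hemodynamic_gain_reflect: float = 2.0
    noise_sd: float = 0.2  # percent dF/F, per pixel per frame
    baseline_intensity: float = 2000.0  # mean fluorescence counts
    pose_dropout_probability: float = 0.02
    pose_jitter_px: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0 or self.n_trials % 2:
            raise ConfigError(
                f"n_trials must be a positive even number, got {self.n_trials}"
            )
        for name, probs, legal in (
            ("rewarded_category_probs", self.rewarded_category_probs, REWARDED_CATEGORIES + ("disregard",)),
            ("nonrewarded_category_probs", self.nonrewarded_category_probs, NONREWARDED_CATEGORIES + ("disregard",)),
        ):
            unknown = set(probs) - set(legal)
            if unknown:
                raise ConfigError(f"{name}: unknown categories {sorted(unknown)}")
            vals = np.array(list(probs.values()), float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ConfigError(f"{name}: probabilities must be in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities sum to {vals.sum()}, not 1")
        for name in (
            "early_reach_probability",
            "pose_dropout_probability",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("trajectory_length_sd", "noise_sd", "pose_jitter_px"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.spout_distance_px <= 0:
            raise ConfigError("spout_distance_px must be positive")
        if self.trajectory_length_mean < 1.0:
            raise ConfigError("trajectory_length_mean must be >= 1 spout distance")


@dataclass
class TrialGroundTruth:
    """Hidden latents of one simulated trial."""

    index: int
    trial_type: str
    category: str
    early_reach: bool = False
    reach_onset_s: float | None = None
    early_reach_time_s: float | None = None
    target_path_length: float | None = None  # spout-distance multiples
    touch_s: float | None = None
    roi_amplitudes: dict[str, float] | None = None
    hemo_phase: float | None = None


@dataclass
class SessionGroundTruth:
    seed: int
    trials: list[TrialGroundTruth]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "trials": [asdict(t) for t in self.trials]},
                fh,
                indent=1,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.trials]).drop(
            columns=["roi_amplitudes"]
        )


@dataclass
class Session:
    """One complete synthetic session."""

    log: pd.DataFrame
    pose: list[PoseTracks]
    stacks: list[StrobedStack] | None
    truth: SessionGroundTruth
    roi_map: AtlasROIMap
    geometry: SpoutGeometry
    timelines: list[TrialTimeline]


def default_geometry(config: SynthConfig) -> SpoutGeometry:
    """Platform/spout layout in behavior-camera pixels (y grows downward)."""
    d = config.spout_distance_px
    platform_y = 220.0
    rest_x = 160.0
    return SpoutGeometry(
        spout_distance_px=d,
        platform_y=platform_y,
        spout_y=platform_y - d,
        platform_x=rest_x - 0.25 * d,
        spout_x=rest_x + 0.3 * d,
    )


def _polyline(n_frames: int, waypoints: list[tuple[int, float, float]]):
    """Piecewise-linear x/y sampled at integer frames through waypoints."""
    frames = np.array([w[0] for w in waypoints], float)
    xs = np.array([w[1] for w in waypoints], float)
    ys = np.array([w[2] for w in waypoints], float)
    t = np.arange(n_frames, dtype=float)
    return np.interp(t, frames, xs), np.interp(t, frames, ys)


def _discrete_length(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def _ascent(
    f0: int,
    f1: int,
    start: tuple[float, float],
    end: tuple[float, float],
    target_px: float,
    n_cycles: int,
):
    """Rise from ``start`` to ``end`` over frames [f0, f1] with a lateral
    oscillation whose amplitude is solved so the discrete polyline length
    equals ``target_px`` (sub-reach exploration of the configured extent)."""
    u = np.linspace(0.0, 1.0, f1 - f0 + 1)
    base_x = start[0] + u * (end[0] - start[0])
    base_y = start[1] + u * (end[1] - start[1])
    wiggle = np.sin(2 * np.pi * n_cycles * u) * np.sin(np.pi * u)

    def length(amp: float) -> float:
        return _discrete_length(base_x + amp * wiggle, base_y)

    straight = length(0.0)
    if target_px < straight - 1e-9:
        raise ConfigError(
            f"target path {target_px:.1f} px shorter than the direct route "
            f"{straight:.1f} px"
        )
    if target_px <= straight + 1e-9:
        amp = 0.0
    else:
        hi = 1.0
        while length(hi) < target_px:
            hi *= 2.0
        amp = brentq(lambda a: length(a) - target_px, 0.0, hi, xtol=1e-10)
    return base_x + amp * wiggle, base_y


def simulate_trajectory(
    category: str,
    geometry: SpoutGeometry,
    target_length: float | None,
    rng: np.random.Generator,
    *,
    timeline: TrialTimeline,
    rate: float = 60.0,
    reach_onset_s: float | None = None,
    early_reach_time_s: float | None = None,
) -> PoseTracks:
    """Noise-free keypoint trajectories for one trial of a given category.

    Successful trials traverse rest-on-platform, lift, spout approach,
    mouth return and back-to-rest phases; the path length over the
    reward -> +1.1 s window is solved to match ``target_length`` (in
    spout-distance multiples) exactly on the 60-Hz frame grid.  Categories
    that contact the spout require ``target_length >= 1``.
    """
    d = geometry.spout_distance_px
    n = frame_window(0.0, timeline.end_s, rate)[1]
    py = geometry.platform_y
    rest = (geometry.spout_x - 0.3 * d, py)
    rx = rest[0]
    mouth = (rx + 0.18 * d, py - 0.8 * d)
    contact_pt = (geometry.spout_x, geometry.spout_y + 0.08 * d)
    short_pt = (geometry.spout_x, geometry.spout_y + 0.3 * d)

    if category in ("success", "partial_fail") and (
        target_length is None or target_length < 1.0
    ):
        raise ConfigError(
            f"target_length must be >= 1 for spout-contact category "
            f"{category!r}, got {target_length}"
        )

    t_all = np.arange(n) / rate
    x = np.full(n, rx)
    y = np.full(n, py)

    def place(waypoints):
        nonlocal x, y
        x, y = _polyline(n, waypoints)

    reward = timeline.reward_s if timeline.reward_s is not None else TONE_S

    if category in ("success", "partial_fail", "complete_fail"):
        onset = reach_onset_s if reach_onset_s is not None else reward + 0.15
        f_on = int(round(onset * rate))
        f_contact = int(round((reward + CONTACT_DELAY_S) * rate))
        w1 = frame_window(reward, reward + REACH_WINDOW_S, rate)[1]
        end_pt = short_pt if category == "complete_fail" else contact_pt
        cycles = max(2, int(round(target_length or 1)))
        ax, ay = _ascent(f_on, f_contact, rest, end_pt, (target_length or 1) * d, cycles)
        x[f_on : f_contact + 1] = ax
        y[f_on : f_contact + 1] = ay
        # hold at the apex through the end of the measurement window
        x[f_contact:w1] = end_pt[0]
        y[f_contact:w1] = end_pt[1]
        if category == "success":
            tail = [
                (w1, end_pt[0], end_pt[1]),
                (w1 + 12, mouth[0], mouth[1]),  # grasp-to-drink
                (w1 + 42, mouth[0], mouth[1]),  # drinking hold
                (w1 + 78, rx, py),
            ]
        elif category == "partial_fail":
            tail = [  # drop lost; outward bow back to rest, away from mouth
                (w1, end_pt[0], end_pt[1]),
                (w1 + 18, rx + 0.45 * d, py - 0.5 * d),
                (w1 + 36, rx, py),
            ]
        else:
            tail = [(w1, end_pt[0], end_pt[1]), (w1 + 30, rx, py)]
        tx, ty = _polyline(n, [(0, x[w1 - 1], y[w1 - 1])] + tail + [(n - 1, rx, py)])
        x[w1:], y[w1:] = tx[w1:], ty[w1:]
    elif category == "groom" or (
        category == "unrewarded_reach" and reach_onset_s is not None and rng.random() < 0.5
    ):
        onset = reach_onset_s if reach_onset_s is not None else reward + 0.3
        f0 = int(round(onset * rate))
        near = (mouth[0] + 0.03 * d, mouth[1] + 0.03 * d)
        pts = [(max(f0 - 1, 0), rx, py)]
        for c in range(4):  # paw-mouth oscillation cycles
            pts.append((f0 + 60 * c + 30, near[0], near[1]))
            pts.append((f0 + 60 * c + 60, rx, py))
        place([(0, rx, py)] + pts + [(n - 1, rx, py)])
    elif category == "unrewarded_reach":
        onset = reach_onset_s if reach_onset_s is not None else 3.0
        f0 = int(round(onset * rate))
        f1 = f0 + int(round(CONTACT_DELAY_S * rate))
        length = max((target_length or 1.2), 0.80) * d
        ax, ay = _ascent(f0, f1, rest, short_pt, length, 2)
        x[f0 : f1 + 1] = ax
        y[f0 : f1 + 1] = ay
        tx, ty = _polyline(
            n, [(0, rx, py), (f1, short_pt[0], short_pt[1]), (f1 + 30, rx, py), (n - 1, rx, py)]
        )
        x[f1:], y[f1:] = tx[f1:], ty[f1:]
    elif category in ("no_reach", "disregard"):
        x = rx + 0.015 * d * np.sin(2 * np.pi * 0.4 * t_all + rng.uniform(0, 2 * np.pi))
        y = py - 0.03 * d * 0.5 * (
            1 + np.sin(2 * np.pi * 0.3 * t_all + rng.uniform(0, 2 * np.pi))
        )
    else:
        raise ConfigError(f"unknown trajectory category {category!r}")

    if early_reach_time_s is not None:
        f0 = int(round(early_reach_time_s * rate))
        ex, ey = _polyline(
            n,
            [
                (max(f0 - 1, 0), rx, py),
                (f0 + 15, rx + 0.2 * d, py - 0.4 * d),
                (f0 + 30, rx, py),
            ],
        )
        sl = slice(f0, f0 + 30)
        x[sl], y[sl] = ex[sl], ey[sl]

    ones = np.ones(n)
    bob = 0.2 * np.sin(2 * np.pi * 0.25 * t_all)
    arrays = {
        "left_paw": np.column_stack([x, y, ones]),
        "right_paw": np.column_stack(
            [np.full(n, rx + 0.6 * d) + bob, np.full(n, py), ones]
        ),
        "mouth": np.column_stack(
            [np.full(n, mouth[0]), np.full(n, mouth[1]) + bob, ones]
        ),
        "platform": np.column_stack(
            [np.full(n, geometry.platform_x), np.full(n, py) + 0.5 * bob, ones]
        ),
        "spout": np.column_stack(
            [np.full(n, geometry.spout_x), np.full(n, geometry.spout_y) + 0.3 * bob, ones]
        ),
    }
    return PoseTracks.from_arrays(arrays, rate)


def _apply_pose_noise(
    tracks: PoseTracks, config: SynthConfig, rng: np.random.Generator,
    occlusion_fraction: float = 0.0,
) -> PoseTracks:
    """Measurement model: smooth jitter plus low-confidence glitch frames.

    ``occlusion_fraction`` > 0 additionally blacks out one contiguous span
    covering that fraction of the trial (the animal's body blocking the
    camera view), which no amount of short-gap interpolation can recover.
    """
    df = tracks.data.copy()
    n = len(df)
    p_drop = config.pose_dropout_probability
    occluded = np.zeros(n, bool)
    if occlusion_fraction > 0:
        span = int(round(occlusion_fraction * n))
        start = int(rng.integers(0, n - span + 1))
        occluded[start : start + span] = True
    for kp in tracks.keypoints:
        conf = rng.uniform(0.95, 1.0, n)
        x = df[(kp, "x")].to_numpy(float)
        y = df[(kp, "y")].to_numpy(float)
        if config.pose_jitter_px > 0:
            kern = np.exp(-0.5 * (np.arange(-9, 10) / 3.0) ** 2)
            kern /= np.sqrt(np.sum(kern**2))
            x = x + config.pose_jitter_px * np.convolve(
                rng.standard_normal(n + 18), kern, mode="valid"
            )
            y = y + config.pose_jitter_px * np.convolve(
                rng.standard_normal(n + 18), kern, mode="valid"
            )
        drop = (rng.random(n) < p_drop) | occluded
        conf[drop] = rng.uniform(0.05, 0.45, int(drop.sum()))
        # glitched detections jump to an arbitrary image location
        x[drop] += rng.normal(0, 40, int(drop.sum()))
        y[drop] += rng.normal(0, 40, int(drop.sum()))
        df[(kp, "x")] = x
        df[(kp, "y")] = y
        df[(kp, "confidence")] = conf
    return PoseTracks(df, tracks.rate)


def transient_kernel(
    t: np.ndarray, rise_s: float = KERNEL_RISE_S, decay_s: float = KERNEL_DECAY_S
) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, unit peak amplitude."""
    t = np.asarray(t, float)
    t_peak = (
        np.log(decay_s / rise_s) / (1.0 / rise_s - 1.0 / decay_s)
    )
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    out = np.where(
        t >= 0, np.exp(-t / decay_s) - np.exp(-np.clip(t, 0, None) / rise_s), 0.0
    )
    return out / peak


def hemo_waveform(t: np.ndarray, phase: float, onset_s: float | None) -> np.ndarray:
    """Unit-gain hemodynamic artifact: slow sinusoid + reach-locked bump."""
    w = HEMO_SINE_AMP * np.sin(2 * np.pi * HEMO_SINE_HZ * t + phase)
    if onset_s is not None:
        w = w + HEMO_BUMP_AMP * transient_kernel(
            t - onset_s, HEMO_BUMP_RISE_S, HEMO_BUMP_DECAY_S
        )
    return w


def _baseline_image(shape: tuple[int, int], base: float) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    profile = 0.85 + 0.3 * np.exp(
        -(((rows - h / 2) ** 2 + (cols - w / 2) ** 2)) / (2 * (0.45 * h) ** 2)
    )
    return base * profile


def simulate_widefield(
    truth: TrialGroundTruth,
    timeline: TrialTimeline,
    roi_map: AtlasROIMap,
    config: SynthConfig,
    rng: np.random.Generator,
) -> StrobedStack:
    """Strobed two-channel movie for one trial.

    Fluorescence frames carry ROI-localized transients (for reach trials)
    plus the hemodynamic waveform at ``hemodynamic_gain_fluo``; reflectance
    frames carry the same waveform at ``hemodynamic_gain_reflect`` and no
    neural signal.  Channels are interleaved fluorescence-first at the
    combined rate and quantized to the 12-bit range.
    """
    unknown = sorted(set(config.roi_peak_amplitudes) - set(roi_map.names))
    if unknown:
        raise ConfigError(f"roi_peak_amplitudes: unknown ROI names {unknown}")

    rate = config.frame_rate_imaging_combined / 2.0
    n = frame_window(0.0, timeline.end_s, rate)[1]
    t = np.arange(n) / rate
    h, w = config.image_shape

    hemo = (
        hemo_waveform(t, truth.hemo_phase or 0.0, truth.reach_onset_s)
        if truth.hemo_phase is not None
        else np.zeros(n)
    )

    neural = np.zeros((n, h, w), np.float32)
    if truth.roi_amplitudes:
        for roi, amp in truth.roi_amplitudes.items():
            onset = truth.reach_onset_s
            if onset is None:
                continue
            k = transient_kernel(t - onset).astype(np.float32)
            neural += amp * k[:, None, None] * roi_map.mask(roi).astype(np.float32)

    def channel(base_img, signal_pct, gain):
        pct = signal_pct + np.float32(gain) * hemo.astype(np.float32)[:, None, None]
        if config.noise_sd > 0:
            pct = pct + config.noise_sd * rng.standard_normal(
                (n, h, w), dtype=np.float32
            )
        frames = base_img[None] * (1.0 + pct / 100.0)
        return np.clip(np.round(frames), 0, MAX_12BIT).astype(np.uint16)

    f0 = _baseline_image((h, w), config.baseline_intensity).astype(np.float32)
    r0 = (0.8 * f0).astype(np.float32)
    fluo = channel(f0, neural, config.hemodynamic_gain_fluo)
    zero = np.zeros((n, h, w), np.float32)
    reflect = channel(r0, zero, config.hemodynamic_gain_reflect)

    combined = np.empty((2 * n, h, w), np.uint16)
    combined[0::2] = fluo
    combined[1::2] = reflect
    return StrobedStack(
        frames=combined,
        combined_rate=config.frame_rate_imaging_combined,
        channel_order=(FLUORESCENCE, REFLECTANCE),
    )


def _sample_target_length(rng, config, minimum: float) -> float:
    for _ in range(1000):
        v = rng.normal(config.trajectory_length_mean, config.trajectory_length_sd)
        if v >= minimum:
            return float(v)
    return minimum


def generate_session(
    config: SynthConfig,
    *,
    include_imaging: bool = True,
    roi_map: AtlasROIMap | None = None,
) -> Session:
    """Generate one complete session (log, pose, movies, ground truth).

    Trial types strictly alternate starting rewarded.  Per-trial latents
    (category, reach onset, target path length, ROI amplitudes, artifact
    phase) are drawn from the trial substream and recorded in the returned
    ground truth.
    """
    config.validate()
    if roi_map is None:
        roi_map = default_atlas(config.image_shape)
    geometry = default_geometry(config)
    rate = config.frame_rate_behavior

    log_rows = []
    pose: list[PoseTracks] = []
    stacks: list[StrobedStack] | None = [] if include_imaging else None
    truths: list[TrialGroundTruth] = []
    timelines: list[TrialTimeline] = []

    for i in range(config.n_trials):
        rng = np.random.default_rng([config.seed, i])
        trial_type = REWARDED if i % 2 == 0 else NONREWARDED
        probs = (
            config.rewarded_category_probs
            if trial_type == REWARDED
            else config.nonrewarded_category_probs
        )
        cats = sorted(probs)
        category = str(rng.choice(cats, p=[probs[c] for c in cats]))

        onset = None
        early = False
        early_time = None
        target = None
        touch = None
        if trial_type == REWARDED:
            if category in ("success", "partial_fail", "complete_fail"):
                onset = TONE_S + rng.uniform(0.08, 0.25)
                minimum = 1.0 if category != "complete_fail" else 0.80
                target = _sample_target_length(rng, config, minimum)
            if category in ("success", "partial_fail"):
                touch = TONE_S + CONTACT_DELAY_S
            if category == "success" and rng.random() < config.early_reach_probability:
                early = True
                early_time = rng.uniform(3.0, 5.2)
            if category == "groom":
                onset = TONE_S + rng.uniform(0.2, 0.6)
        else:
            if category == "unrewarded_reach":
                onset = rng.uniform(1.0, 8.0)
                target = _sample_target_length(rng, config, 0.80)

        timeline = build_timeline(trial_type, touch)
        clean = simulate_trajectory(
            category,
            geometry,
            target,
            rng,
            timeline=timeline,
            rate=rate,
            reach_onset_s=onset,
            early_reach_time_s=early_time,
        )
        noisy = _apply_pose_noise(
            clean,
            config,
            rng,
            occlusion_fraction=0.7 if category == "disregard" else 0.0,
        )
        truth = TrialGroundTruth(
            index=i,
            trial_type=trial_type,
            category=category,
            early_reach=early,
            reach_onset_s=onset if category in REACH_CATEGORIES else None,
            early_reach_time_s=early_time,
            target_path_length=(
                target if category in ("success", "partial_fail", "complete_fail") else None
            ),
            touch_s=touch,
            roi_amplitudes=(
                dict(config.roi_peak_amplitudes)
                if category in REACH_CATEGORIES
                else None
            ),
            hemo_phase=float(rng.uniform(0, 2 * np.pi)),
        )
        if include_imaging:
            stacks.append(simulate_widefield(truth, timeline, roi_map, config, rng))
        pose.append(noisy)
        truths.append(truth)
        timelines.append(timeline)
        log_rows.append(
            {
                "trial_index": i,
                "type": trial_type,
                "cue_time_s": timeline.visual_cue_s,
                "tone_time_s": timeline.tone_s,
                "reward_time_s": timeline.reward_s,
                "touch_time_s": timeline.touch_s,
                "end_time_s": timeline.end_s,
            }
        )

    return Session(
        log=pd.DataFrame(log_rows),
        pose=pose,
        stacks=stacks,
        truth=SessionGroundTruth(seed=config.seed, trials=truths),
        roi_map=roi_map,
        geometry=geometry,
        timelines=timelines,
    )


def write_session(session: Session, out_dir) -> None:
    """Persist a session: event log + pose CSVs, TIFF movies + sidecars,
    ground-truth JSON and the atlas (PNG label image + JSON metadata)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.log.to_csv(out / "event_log.csv", index=False)
    for i, tracks in enumerate(session.pose):
        tracks.to_csv(out / f"pose_trial_{i:03d}.csv")
    if session.stacks is not None:
        for i, stack in enumerate(session.stacks):
            stack.save(
                out / f"widefield_trial_{i:03d}.tif",
                out / f"widefield_trial_{i:03d}.json",
            )
    session.truth.to_json(out / "ground_truth.json")
    session.roi_map.save(out / "atlas_labels.png", out / "atlas_meta.json")
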