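"""Trial state machine and behavioral categorization.

The task alternates rewarded (water drop) and nonrewarded trials.  Every
trial starts camera recording at t = 0, shows a visual cue at 2 s and plays
a tone at 6 s; on rewarded trials the tone coincides with water delivery.
A rewarded trial ends 4 s after a detected spout touch, otherwise (and on
all nonrewarded trials) 10 s after the tone, so rewarded trials span
10-16 s and nonrewarded trials are exactly 16 s.  All analysis windows use
only the first 10 s of each trial.

Rewarded trials are scored into six categories (disregard, no_reach, groom,
success, partial_fail, complete_fail) and nonrewarded trials into three
(disregard, no_reach, unrewarded_reach); the original scoring was manual,
so the classifier here is an explicit, configurable operationalization of
those category definitions on pose tracks.  Touch-sensor times are used for
trial timelines only, never for categorization (the capacitive sensor does
not reliably report reaches).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TrialTimingError, TruncationError
from .kinematics import SpoutGeometry
from .pose import PoseTracks, clean_track, frame_window

REWARDED = "rewarded"
NONREWARDED = "nonrewarded"

CATEGORIES_REWARDED = (
    "disregard",
    "no_reach",
    "groom",
    "success",
    "partial_fail",
    "complete_fail",
)
CATEGORIES_NONREWARDED = ("disregard", "no_reach", "unrewarded_reach")

VISUAL_CUE_S = 2.0
TONE_S = 6.0
ITI_S = 4.0
POST_TOUCH_S = 4.0  # recording stops this long after a spout touch
TIMEOUT_S = 10.0  # ... or this long after the tone if no touch
ANALYSIS_DURATION_S = 10.0


@dataclass(frozen=True)
class TrialTimeline:
    """Event times of a single trial, seconds from camera start (t = 0)."""

    trial_type: str
    end_s: float
    visual_cue_s: float = VISUAL_CUE_S
    tone_s: float = TONE_S
    reward_s: float | None = None  # equals tone_s on rewarded trials
    touch_s: float | None = None
    iti_s: float = ITI_S


def build_timeline(
    trial_type: str,
    touch_s: float | None = None,
    *,
    visual_cue_s: float = VISUAL_CUE_S,
    tone_s: float = TONE_S,
    iti_s: float = ITI_S,
) -> TrialTimeline:
    """Resolve a trial's end time from its type and (optional) spout touch.

    Rewarded trial with a touch -> ends 4 s after the touch; without a
    touch, or any nonrewarded trial -> ends 10 s after the tone.  The end
    time is capped at the no-touch timeout, so rewarded trials always span
    10-16 s.  A touch reported before reward delivery is a sensor artifact
    and is rejected.
    """
    if trial_type not in (REWARDED, NONREWARDED):
        raise TrialTimingError(f"unknown trial type {trial_type!r}")
    if not visual_cue_s < tone_s:
        raise TrialTimingError("visual cue must precede the tone")
    timeout_end = tone_s + TIMEOUT_S
    reward_s = tone_s if trial_type == REWARDED else None
    if trial_type == NONREWARDED:
        touch_s = None
        end_s = timeout_end
    elif touch_s is None:
        end_s = timeout_end
    else:
        if touch_s < tone_s:
            raise TrialTimingError(
                f"touch at {touch_s} s precedes reward delivery at {tone_s} s"
            )
        end_s = min(touch_s + POST_TOUCH_S, timeout_end)
    return TrialTimeline(
        trial_type=trial_type,
        end_s=end_s,
        visual_cue_s=visual_cue_s,
        tone_s=tone_s,
        reward_s=reward_s,
        touch_s=touch_s,
        iti_s=iti_s,
    )


def truncate_trial(
    stream: np.ndarray, rate: float, duration_s: float = ANALYSIS_DURATION_S
) -> np.ndarray:
    """Keep the first ``duration_s`` seconds of a trial-aligned signal.

    ``stream``'s first axis is time at ``rate`` Hz.  Errors if the stream
    does not cover the full window.
    """
    stream = np.asarray(stream)
    n = frame_window(0.0, duration_s, rate)[1]
    if stream.shape[0] < n:
        raise TruncationError(
            f"stream has {stream.shape[0]} samples "
            f"({stream.shape[0] / rate:.3f} s) < required {duration_s} s"
        )
    return stream[:n]


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the categorization cascade, in spout-distance units.

    The original scoring was manual; these defaults operationalize the
    written category definitions and are all configurable.
    """

    lift_threshold: float = 0.10  # paw above platform by this x spout dist.
    forward_threshold: float = 0.15  # net displacement toward the spout
    contact_radius: float = 0.10  # "touching" the spout / mouth
    retrieval_window_s: float = 2.0  # contact -> mouth within this time
    groom_min_cycles: int = 3  # paw-mouth oscillations for groom
    rest_window_s: float = 2.0  # pre-cue span defining the rest posture
    max_gap_frames: int = 5  # interpolate dropout gaps up to this
    disregard_masked_fraction: float = 0.5  # more masked than this -> disregard
    conf_threshold: float = 0.5


@dataclass(frozen=True)
class ReachEvent:
    """One lift episode qualifying as a reach."""

    onset_s: float
    offset_s: float
    peak_lift: float  # spout-distance multiples
    max_forward: float


@dataclass
class Classification:
    """Category plus the evidence the cascade used."""

    category: str
    reach_events: list[ReachEvent] = field(default_factory=list)
    contact_s: float | None = None
    retrieval_s: float | None = None
    groom_cycles: int = 0
    reason: str = ""

    @property
    def reached(self) -> bool:
        return bool(self.reach_events)


def detect_reach_events(
    tracks: PoseTracks,
    geometry: SpoutGeometry,
    params: ClassifierParams = ClassifierParams(),
) -> list[ReachEvent]:
    """Lift episodes of the left (reaching) paw.

    A reach is a contiguous run of frames with the paw above the platform
    by more than ``lift_threshold`` whose net displacement toward the spout
    reaches ``forward_threshold`` (both in spout-distance multiples).
    """
    d = geometry.spout_distance_px
    paw = clean_track(
        tracks, "left_paw", params.conf_threshold, params.max_gap_frames
    )
    lift = (geometry.platform_y - paw.y) / d
    rest_n = frame_window(0.0, params.rest_window_s, tracks.rate)[1]
    rest_x = np.nanmedian(paw.x[:rest_n])
    toward = np.sign(geometry.spout_x - rest_x) or 1.0
    forward = (paw.x - rest_x) * toward / d

    lifted = np.where(np.isnan(lift), False, lift > params.lift_threshold)
    events: list[ReachEvent] = []
    i, n = 0, len(lifted)
    while i < n:
        if not lifted[i]:
            i += 1
            continue
        j = i
        while j < n and lifted[j]:
            j += 1
        fwd = np.nanmax(forward[i:j])
        if fwd >= params.forward_threshold:
            events.append(
                ReachEvent(
                    onset_s=i / tracks.rate,
                    offset_s=j / tracks.rate,
                    peak_lift=float(np.nanmax(lift[i:j])),
                    max_forward=float(fwd),
                )
            )
        i = j
    return events


def _near(paw_x, paw_y, px, py, radius_px):
    with np.errstate(invalid="ignore"):
        d2 = (paw_x - px) ** 2 + (paw_y - py) ** 2
        return np.where(np.isnan(d2), False, d2 <= radius_px**2)


def _count_cycles(near_mask: np.ndarray) -> int:
    """Number of distinct entries into the near-mouth zone."""
    entries = np.flatnonzero(near_mask[1:] & ~near_mask[:-1]).size
    if near_mask.size and near_mask[0]:
        entries += 1
    return entries


def classify_trial(
    tracks: PoseTracks,
    timeline: TrialTimeline,
    geometry: SpoutGeometry,
    params: ClassifierParams = ClassifierParams(),
) -> Classification:
    """Deterministic rule cascade mirroring the manual scoring categories.

    On the 10-s analysis window: (1) reach events are lift episodes with
    net forward displacement; (2) spout contact is the paw coming within
    ``contact_radius`` of the spout; (3) retrieval is the paw reaching the
    mouth within ``retrieval_window_s`` after contact.  Rewarded mapping:
    contact + retrieval -> success, contact alone -> partial_fail, >= 3
    paw-mouth cycles without contact -> groom, reach without contact ->
    complete_fail, otherwise no_reach.  Nonrewarded: any reach or groom ->
    unrewarded_reach, else no_reach.  Trials with more than half of the
    paw frames unusable are disregarded.
    """
    tracks = tracks.truncate(ANALYSIS_DURATION_S)
    paw = clean_track(
        tracks, "left_paw", params.conf_threshold, params.max_gap_frames
    )
    if paw.masked_fraction > params.disregard_masked_fraction:
        return Classification(
            category="disregard",
            reason=f"{paw.masked_fraction:.0%} of paw frames unusable",
        )

    d = geometry.spout_distance_px
    radius_px = params.contact_radius * d
    mouth = clean_track(
        tracks, "mouth", params.conf_threshold, params.max_gap_frames
    )
    events = detect_reach_events(tracks, geometry, params)

    near_spout = _near(paw.x, paw.y, geometry.spout_x, geometry.spout_y, radius_px)
    near_mouth = _near(paw.x, paw.y, mouth.x, mouth.y, radius_px)

    contact_idx = np.flatnonzero(near_spout)
    contact_s = contact_idx[0] / tracks.rate if contact_idx.size else None

    retrieval_s = None
    if contact_s is not None:
        i0 = contact_idx[0]
        i1 = frame_window(
            0.0, contact_s + params.retrieval_window_s, tracks.rate
        )[1]
        ret = np.flatnonzero(near_mouth[i0:i1])
        if ret.size:
            retrieval_s = (i0 + ret[0]) / tracks.rate

    groom_cycles = 0 if contact_s is not None else _count_cycles(near_mouth)

    if timeline.trial_type == REWARDED:
        if contact_s is not None:
            category = "success" if retrieval_s is not None else "partial_fail"
        elif groom_cycles >= params.groom_min_cycles:
            category = "groom"
        elif events:
            category = "complete_fail"
        else:
            category = "no_reach"
    else:
        reached = bool(events) or groom_cycles >= params.groom_min_cycles
        category = "unrewarded_reach" if reached else "no_reach"

    return Classification(
        category=category,
        reach_events=events,
        contact_s=contact_s,
        retrieval_s=retrieval_s,
        groom_cycles=groom_cycles,
    )


def detect_early_reach(
    tracks: PoseTracks,
    timeline: TrialTimeline,
    geometry: SpoutGeometry,
    params: ClassifierParams = ClassifierParams(),
    classification: Classification | None = None,
) -> bool:
    """Reach onset strictly before water delivery in a successful trial.

    Early reaches (together with unrewarded reaches) index an event-sequence
    deficit: reaching that is uncoupled from reward delivery.
    """
    if timeline.reward_s is None:
        return False
    if classification is None:
        classification = classify_trial(tracks, timeline, geometry, params)
    if classification.category != "success":
        return False
    events = classification.reach_events or detect_reach_events(
        tracks.truncate(ANALYSIS_DURATION_S), geometry, params
    )
    return any(e.onset_s < timeline.reward_s for e in events)


@dataclass(frozen=True)
class TrialRecord:
    """One scored trial."""

    index: int
    trial_type: str
    category: str
    early_reach: bool = False
    timeline: TrialTimeline | None = None
    day: int | None = None

    def __post_init__(self):
        legal = (
            CATEGORIES_REWARDED
            if self.trial_type == REWARDED
            else CATEGORIES_NONREWARDED
        )
        if self.category not in legal:
            raise ValueError(
                f"category {self.category!r} illegal for {self.trial_type} trial"
            )
        if self.early_reach and self.category != "success":
            raise ValueError("early_reach is defined only for success trials")

    def with_day(self, day: int) -> "TrialRecord":
        return replace(self, day=day)


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "type": [r.trial_type for r in records],
            "category": [r.category for r in records],
            "early_reach": [r.early_reach for r in records],
            "day": [r.day for r in records],
        }
    )


REWARDED_FRACTION_COLUMNS = [
    "success_frac",
    "partial_fail_frac",
    "complete_fail_frac",
    "no_reach_frac",
    "groom_frac",
]


def summarize_performance(records: list[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-day category fractions, excluding disregarded trials.

    Rewarded-category fractions are relative to non-disregarded rewarded
    trials and sum to 1; ``unrewarded_reach_frac`` is relative to
    non-disregarded nonrewarded trials; ``early_reach_frac`` is relative to
    successful trials.  Days with no scorable trials of a kind get NaN
    fractions and ``empty = True``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows = []
    for day, sub in df.groupby("day", dropna=False):
        scored = sub[sub["category"] != "disregard"]
        rew = scored[scored["type"] == REWARDED]
        non = scored[scored["type"] == NONREWARDED]
        row: dict = {"day": day, "n_rewarded": len(rew), "n_nonrewarded": len(non)}
        for cat in ("success", "partial_fail", "complete_fail", "no_reach", "groom"):
            row[f"{cat}_frac"] = (
                float((rew["category"] == cat).mean()) if len(rew) else np.nan
            )
        row["unrewarded_reach_frac"] = (
            float((non["category"] == "unrewarded_reach").mean())
            if len(non)
            else np.nan
        )
        succ = rew[rew["category"] == "success"]
        row["early_reach_frac"] = (
            float(succ["early_reach"].mean()) if len(succ) else np.nan
        )
        row["empty"] = len(rew) == 0 and len(non) == 0
        rows.append(row)
    return pd.DataFrame(rows)
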