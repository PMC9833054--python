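"""Reach-trajectory kinematics.

All reach metrics are expressed in multiples of the *spout distance*: the
vertical separation between the paw-rest platform and the water spout.
One spout distance is the most efficient route the paw can take, so a path
length of 1.0 is a perfectly direct reach.  Path length is the Euclidean
distance traveled by the left paw from water-reward delivery to 1.1 s
afterward (the time needed to complete a successful reach), binned in
integer multiples of spout distance; per-animal mean and SD are computed
first, then averaged across animals of a genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, WindowError
from .pose import PoseTracks, clean_track, frame_window

MIN_CONFIDENT_FRAMES = 10
REACH_WINDOW_S = 1.1  # reward -> +1.1 s covers the reach-grasp phase


@dataclass(frozen=True)
class SpoutGeometry:
    """Platform/spout geometry resolved from landmark medians (pixels)."""

    spout_distance_px: float
    platform_y: float
    spout_y: float
    platform_x: float = np.nan
    spout_x: float = np.nan


def spout_distance(
    tracks: PoseTracks,
    conf_threshold: float = 0.5,
) -> SpoutGeometry:
    """Spout distance = |median platform height - median spout height|.

    Medians run over confident frames only, making the estimate robust to
    tracking jitter.  Requires at least 10 confident frames per landmark
    and a strictly positive separation.
    """
    med = {}
    for name in ("platform", "spout"):
        x, y, conf = tracks.xy(name)
        ok = conf >= conf_threshold
        if ok.sum() < MIN_CONFIDENT_FRAMES:
            raise GeometryError(
                f"only {int(ok.sum())} confident frames for {name!r} "
                f"(need >= {MIN_CONFIDENT_FRAMES})"
            )
        med[name] = (float(np.median(x[ok])), float(np.median(y[ok])))
    dist = abs(med["platform"][1] - med["spout"][1])
    if dist <= 0:
        raise GeometryError("platform and spout heights coincide (zero distance)")
    return SpoutGeometry(
        spout_distance_px=dist,
        platform_y=med["platform"][1],
        spout_y=med["spout"][1],
        platform_x=med["platform"][0],
        spout_x=med["spout"][0],
    )


@dataclass(frozen=True)
class PathLength:
    """Path length in spout-distance multiples; ``flagged`` marks trials
    with an uninterpolatable tracking gap inside the window."""

    value: float
    flagged: bool = False

    def __float__(self) -> float:
        return self.value


def path_length(
    tracks: PoseTracks,
    timeline,
    geometry: SpoutGeometry,
    *,
    window_s: float = REACH_WINDOW_S,
    conf_threshold: float = 0.5,
    max_gap: int = 5,
) -> PathLength:
    """Euclidean distance traveled by the left paw over reward -> +1.1 s.

    Sum of frame-to-frame segment lengths sqrt(dx^2 + dy^2) over usable
    frames, divided by the spout distance.  Short low-confidence gaps are
    interpolated and contribute; a longer gap inside the window flags the
    result (segments touching masked frames are skipped).
    """
    if timeline.reward_s is None:
        raise WindowError("path length is defined for rewarded trials only")
    t0 = timeline.reward_s
    i0, i1 = frame_window(t0, t0 + window_s, tracks.rate)
    if i1 > tracks.n_frames:
        raise WindowError(
            f"window [{t0}, {t0 + window_s}) s needs {i1} frames, "
            f"tracks have {tracks.n_frames}"
        )
    paw = clean_track(tracks, "left_paw", conf_threshold, max_gap)
    x, y, valid = paw.x[i0:i1], paw.y[i0:i1], paw.valid[i0:i1]
    seg_ok = valid[1:] & valid[:-1]
    dx = np.diff(x)[seg_ok]
    dy = np.diff(y)[seg_ok]
    total = float(np.sum(np.hypot(dx, dy)))
    return PathLength(
        value=total / geometry.spout_distance_px,
        flagged=not valid.all(),
    )


def bin_distances(lengths) -> pd.Series:
    """Relative-frequency histogram (%) of path lengths.

    Bin k covers [k, k+1) spout distances, so a trial whose path is 4.x
    spout distances falls in bin 4.  Empty input yields an empty histogram.
    """
    vals = np.asarray([float(v) for v in lengths], float)
    if vals.size == 0:
        return pd.Series(dtype=float, name="relative_frequency_pct")
    if np.any(vals < 0):
        raise ValueError("path lengths must be nonnegative")
    bins = np.floor(vals).astype(int)
    counts = pd.Series(bins).value_counts().sort_index()
    freq = counts / counts.sum() * 100.0
    freq.name = "relative_frequency_pct"
    freq.index.name = "bin"
    return freq


def per_mouse_stats(lengths_by_mouse: dict[str, list]) -> pd.DataFrame:
    """Per-animal mean and sample SD (n-1) of path lengths."""
    rows = []
    for mouse, lengths in lengths_by_mouse.items():
        vals = np.asarray([float(v) for v in lengths], float)
        rows.append(
            {
                "mouse": mouse,
                "n_trials": vals.size,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def trajectory_stats(lengths_by_mouse: dict[str, list]) -> dict:
    """Two-level aggregation: per-animal mean/SD, then the group average.

    The group statistic is always the unweighted mean of per-animal values
    (never pooled across animals), so unequal trial counts cannot skew it.
    SEM is over animals.
    """
    per_mouse = per_mouse_stats(lengths_by_mouse)
    means = per_mouse["mean"].to_numpy(float)
    sds = per_mouse["sd"].to_numpy(float)
    n = len(per_mouse)

    def _sem(v):
        v = v[~np.isnan(v)]
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan

    return {
        "per_mouse": per_mouse,
        "n_mice": n,
        "mean_of_means": float(np.nanmean(means)) if n else np.nan,
        "sem_of_means": _sem(means),
        "mean_of_sds": float(np.nanmean(sds)) if n else np.nan,
        "sem_of_sds": _sem(sds),
    }


def lift_trace(
    tracks: PoseTracks,
    geometry: SpoutGeometry,
    *,
    conf_threshold: float = 0.5,
    max_gap: int = 5,
) -> np.ndarray:
    """Platform-referenced left-paw height over the 10-s trial (pixels).

    ``platform_y - paw_y``: positive when the paw is lifted above the
    platform (image y grows downward).  Masked frames are NaN.
    """
    paw = clean_track(tracks, "left_paw", conf_threshold, max_gap)
    return geometry.platform_y - paw.y
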