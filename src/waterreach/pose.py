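"""Keypoint time series (markerless-pose export dialect).

Pose tracks hold x/y pixel coordinates and a per-frame confidence for each
tracked body part or equipment landmark, sampled at the behavior-camera rate
(60 Hz).  The CSV dialect mirrors common pose-estimation exports: two header
rows (bodypart, coordinate) over a plain frame-indexed table.  Image
convention applies throughout: y increases downward, so a lifted paw has a
*smaller* y than the platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TruncationError

KEYPOINTS = ("left_paw", "right_paw", "mouth", "platform", "spout")
COORDS = ("x", "y", "confidence")

#: confidence below this marks a frame as unreliable (dropout)
CONFIDENCE_THRESHOLD = 0.5


def frame_window(t0: float, t1: float, rate: float) -> tuple[int, int]:
    """Frame-index bounds of the half-open time window [t0, t1).

    Frame ``i`` (at time ``i / rate``) is inside iff ``t0 <= i/rate < t1``.
    A small guard absorbs float rounding at exact frame boundaries.
    """
    eps = 1e-9
    i0 = int(np.ceil(t0 * rate - eps))
    i1 = int(np.ceil(t1 * rate - eps))
    return max(i0, 0), max(i1, 0)


@dataclass
class PoseTracks:
    """Trial-aligned keypoint trajectories at a fixed sampling rate."""

    data: pd.DataFrame  # columns: MultiIndex (bodypart, {x, y, confidence})
    rate: float = 60.0

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("PoseTracks.data needs (bodypart, coord) columns")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def keypoints(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def xy(self, keypoint: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, y, confidence) arrays for one keypoint."""
        sub = self.data[keypoint]
        return (
            sub["x"].to_numpy(float),
            sub["y"].to_numpy(float),
            sub["confidence"].to_numpy(float),
        )

    def truncate(self, duration_s: float = 10.0) -> "PoseTracks":
        """First ``duration_s`` seconds; error if the tracks are shorter."""
        n = frame_window(0.0, duration_s, self.rate)[1]
        if self.n_frames < n:
            raise TruncationError(
                f"tracks cover {self.duration_s:.3f} s "
                f"< required {duration_s:.3f} s"
            )
        return PoseTracks(self.data.iloc[:n].reset_index(drop=True), self.rate)

    @classmethod
    def from_arrays(
        cls, arrays: dict[str, np.ndarray], rate: float = 60.0
    ) -> "PoseTracks":
        """Build from ``{keypoint: (n, 3) array of x, y, confidence}``."""
        cols = {}
        for name, arr in arrays.items():
            arr = np.asarray(arr, float)
            for j, coord in enumerate(COORDS):
                cols[(name, coord)] = arr[:, j]
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["bodypart", "coord"]
        )
        return cls(df, rate)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate: float = 60.0) -> "PoseTracks":
        df = pd.read_csv(path, header=[0, 1])
        df.columns = pd.MultiIndex.from_tuples(
            [(a, b) for a, b in df.columns], names=["bodypart", "coord"]
        )
        return cls(df, rate)


@dataclass
class CleanTrack:
    """One keypoint after confidence filtering and short-gap interpolation.

    ``valid`` marks frames usable for kinematics: confident frames plus
    interpolated gaps of at most ``max_gap`` frames.  Longer low-confidence
    runs stay masked (``valid`` False; x/y are NaN there).
    """

    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = field(repr=False)

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(np.mean(self.valid))


def clean_track(
    tracks: PoseTracks,
    keypoint: str,
    conf_threshold: float = CONFIDENCE_THRESHOLD,
    max_gap: int = 5,
) -> CleanTrack:
    """Interpolate short low-confidence gaps; mask long ones.

    Gaps of ``<= max_gap`` consecutive low-confidence frames bounded by
    confident frames are linearly interpolated.  Gaps longer than that, or
    touching either end of the trial, are masked.
    """
    x, y, conf = tracks.xy(keypoint)
    good = conf >= conf_threshold
    x = x.copy()
    y = y.copy()
    valid = good.copy()
    n = len(good)
    i = 0
    while i < n:
        if good[i]:
            i += 1
            continue
        j = i
        while j < n and not good[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            # linear interpolation across the gap
            t = np.arange(i, j)
            x[i:j] = np.interp(t, [i - 1, j], [x[i - 1], x[j]])
            y[i:j] = np.interp(t, [i - 1, j], [y[i - 1], y[j]])
            valid[i:j] = True
        else:
            x[i:j] = np.nan
            y[i:j] = np.nan
        i = j
    return CleanTrack(x=x, y=y, valid=valid)
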