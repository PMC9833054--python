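"""Widefield GCaMP image processing.

The cortex is imaged through a single camera under strobed illumination:
blue light excites GCaMP (green epi-fluorescence) and green light measures
reflectance, which carries hemodynamic (blood volume/oxygenation) and
movement artifacts but no indicator signal.  Frames alternate at 120 Hz
combined, so each channel runs at 60 Hz.  Processing: demultiplex the two
channels, express each pixel as percent dF/F against its pre-reward
baseline, and subtract the reflectance dF/F from the fluorescence dF/F to
cancel the shared artifact.  Region metrics come from a 5x5-pixel window
at each atlas ROI centroid: peak amplitude relative to the 1-5 s baseline,
and the cortical area whose response exceeds 4x its baseline SD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .atlas import AtlasROIMap
from .errors import ImagingError, WindowError
from .pose import frame_window

logger = logging.getLogger(__name__)

FLUORESCENCE = "fluorescence"
REFLECTANCE = "reflectance"

PEAK_BASELINE_S = (1.0, 5.0)  # baseline window for peak/area statistics
POST_REWARD_SEARCH_S = 4.0  # peak search: reward -> +4 s (cued reaches)
FULL_TRIAL_S = 10.0  # peak search window for un-cued (unrewarded) reaches
ROI_WINDOW = 5  # 5x5-pixel region at the ROI centroid
MAX_12BIT = 4095


@dataclass
class StrobedStack:
    """Raw interleaved two-channel movie (12-bit counts) with metadata."""

    frames: np.ndarray  # (T, H, W) integer counts in [0, 4095]
    combined_rate: float = 120.0
    channel_order: tuple[str, str] = (FLUORESCENCE, REFLECTANCE)
    pixel_size_um: float = 68.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, tiff_path, sidecar_path) -> None:
        tifffile.imwrite(tiff_path, self.frames.astype(np.uint16))
        meta = {
            "combined_rate_hz": self.combined_rate,
            "channel_order": list(self.channel_order),
            "bit_depth": 12,
            "pixel_size_um": self.pixel_size_um,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, tiff_path, sidecar_path) -> "StrobedStack":
        frames = tifffile.imread(tiff_path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            frames=frames,
            combined_rate=float(meta["combined_rate_hz"]),
            channel_order=tuple(meta["channel_order"]),
            pixel_size_um=float(meta.get("pixel_size_um", 68.0)),
        )


@dataclass
class ChannelMovie:
    """Single-channel movie after demultiplexing (raw counts, 60 Hz)."""

    frames: np.ndarray  # (T, H, W) float32
    rate: float
    channel: str


@dataclass
class DFFMovie:
    """Percent dF/F movie with baseline provenance.

    ``valid_mask`` marks pixels with a usable baseline (F0 above the dark
    floor); invalid pixels are zeroed, never NaN.
    """

    values: np.ndarray  # (T, H, W) float32, percent
    rate: float
    baseline_window_s: tuple[float, float]
    corrected: bool = False
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def demultiplex(stack: StrobedStack) -> tuple[ChannelMovie, ChannelMovie]:
    """Split the interleaved stack into its two 60-Hz channels.

    Even frames belong to ``channel_order[0]``; a trailing unpaired frame
    is dropped with a warning.
    """
    if stack.n_frames < 2:
        raise ImagingError(f"stack has {stack.n_frames} frame(s); need >= 2")
    frames = stack.frames
    if stack.n_frames % 2:
        logger.warning(
            "dropping trailing unpaired frame (%d frames total)", stack.n_frames
        )
        frames = frames[:-1]
    rate = stack.combined_rate / 2.0
    first = ChannelMovie(frames[0::2].astype(np.float32), rate, stack.channel_order[0])
    second = ChannelMovie(frames[1::2].astype(np.float32), rate, stack.channel_order[1])
    if stack.channel_order[0] == FLUORESCENCE:
        return first, second
    return second, first


def compute_dff(
    movie: ChannelMovie,
    baseline_window_s: tuple[float, float],
    eps: float = 1.0,
) -> DFFMovie:
    """Percent dF/F: ``(F - F0) / F0 * 100`` per pixel.

    F0 is the per-pixel mean over the baseline window (by default the span
    from trial start to water-reward delivery).  Pixels whose F0 does not
    exceed ``eps`` counts are masked out (set to 0).
    """
    i0, i1 = frame_window(*baseline_window_s, movie.rate)
    if i1 > movie.frames.shape[0] or i1 <= i0:
        raise WindowError(
            f"baseline window {baseline_window_s} s not covered by "
            f"{movie.frames.shape[0]} frames at {movie.rate} Hz"
        )
    f0 = movie.frames[i0:i1].mean(axis=0)
    valid = f0 > eps
    if not valid.any():
        raise ImagingError("all pixels below the dark floor (F0 <= eps)")
    safe_f0 = np.where(valid, f0, 1.0)
    values = (movie.frames - f0[None]) / safe_f0[None] * 100.0
    values[:, ~valid] = 0.0
    return DFFMovie(
        values=values.astype(np.float32),
        rate=movie.rate,
        baseline_window_s=tuple(baseline_window_s),
        corrected=False,
        valid_mask=valid,
    )


def hemodynamic_correct(fluo_dff: DFFMovie, reflect_dff: DFFMovie) -> DFFMovie:
    """Subtract reflectance dF/F from fluorescence dF/F, pixelwise.

    The reflectance channel sees the hemodynamic/movement artifact but no
    indicator fluorescence, so the subtraction cancels the shared artifact
    and leaves the neural signal.
    """
    if fluo_dff.values.shape != reflect_dff.values.shape:
        raise ImagingError(
            f"shape mismatch {fluo_dff.values.shape} vs {reflect_dff.values.shape}"
        )
    if fluo_dff.rate != reflect_dff.rate:
        raise ImagingError("rate mismatch between channels")
    if fluo_dff.baseline_window_s != reflect_dff.baseline_window_s:
        raise ImagingError("channels use different baseline windows")
    valid = None
    if fluo_dff.valid_mask is not None and reflect_dff.valid_mask is not None:
        valid = fluo_dff.valid_mask & reflect_dff.valid_mask
    values = fluo_dff.values - reflect_dff.values
    if valid is not None:
        values[:, ~valid] = 0.0
    return DFFMovie(
        values=values,
        rate=fluo_dff.rate,
        baseline_window_s=fluo_dff.baseline_window_s,
        corrected=True,
        valid_mask=valid,
    )


@dataclass
class ROITrace:
    """Mean dF/F over a 5x5-pixel window at one ROI centroid."""

    values: np.ndarray  # (T,) percent
    rate: float
    roi: str


def _round_half_down(v: float) -> int:
    """Nearest integer; exact .5 ties go to the smaller index."""
    return int(np.ceil(v - 0.5))


def extract_trace(dff: DFFMovie, roi_map: AtlasROIMap, roi: str) -> ROITrace:
    """Per-frame mean over the 5x5-pixel window at the ROI centroid."""
    if dff.values.shape[1:] != roi_map.shape:
        raise ImagingError(
            f"movie shape {dff.values.shape[1:]} != atlas shape {roi_map.shape}"
        )
    cr, cc = roi_map.centroid(roi)
    r, c = _round_half_down(cr), _round_half_down(cc)
    half = ROI_WINDOW // 2
    h, w = roi_map.shape
    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        raise ImagingError(
            f"5x5 window for ROI {roi!r} at ({r}, {c}) clips the image border"
        )
    window = dff.values[:, r - half : r + half + 1, c - half : c + half + 1]
    return ROITrace(
        values=window.mean(axis=(1, 2)).astype(np.float64), rate=dff.rate, roi=roi
    )


@dataclass(frozen=True)
class PeakResult:
    roi: str
    amplitude: float  # percent dF/F above baseline mean
    peak_time_s: float
    baseline_mean: float
    baseline_sd: float
    search_window_s: tuple[float, float]


def search_window(timeline, category: str) -> tuple[float, float]:
    """Peak-search window by trial category.

    Cued reaches (success / partial_fail) respond after the water drop, so
    the search spans reward -> +4 s; unrewarded reaches can happen anywhere
    in the trial, so the full 10 s are searched.
    """
    if category in ("success", "partial_fail"):
        if timeline.reward_s is None:
            raise WindowError(f"category {category!r} needs a reward time")
        return (timeline.reward_s, timeline.reward_s + POST_REWARD_SEARCH_S)
    if category == "unrewarded_reach":
        return (0.0, FULL_TRIAL_S)
    raise WindowError(f"no peak-search window defined for category {category!r}")


def peak_amplitude(
    trace: ROITrace,
    timeline,
    category: str,
    baseline_s: tuple[float, float] = PEAK_BASELINE_S,
) -> PeakResult:
    """Peak amplitude from the 1-5 s baseline to the in-window maximum.

    Amplitude = max of the trace over the category's search window minus
    the baseline mean; ties go to the earliest peak.
    """
    win = search_window(timeline, category)
    b0, b1 = frame_window(*baseline_s, trace.rate)
    w0, w1 = frame_window(*win, trace.rate)
    n = trace.values.shape[0]
    if w1 > n or b1 > n:
        raise WindowError(
            f"search window {win} s / baseline {baseline_s} s exceed "
            f"trace length {n / trace.rate:.2f} s"
        )
    base = trace.values[b0:b1]
    seg = trace.values[w0:w1]
    k = int(np.argmax(seg))  # argmax returns the first maximum (earliest)
    return PeakResult(
        roi=trace.roi,
        amplitude=float(seg[k] - base.mean()),
        peak_time_s=(w0 + k) / trace.rate,
        baseline_mean=float(base.mean()),
        baseline_sd=float(base.std(ddof=1)),
        search_window_s=win,
    )


@dataclass(frozen=True)
class ActivatedArea:
    pixel_count: int
    area_mm2: float
    n_eligible: int
    n_zero_variance: int


def area_activated(
    dff: DFFMovie,
    timeline,
    category: str,
    brain_mask: np.ndarray,
    baseline_s: tuple[float, float] = PEAK_BASELINE_S,
    pixel_size_um: float = 68.0,
    sd_factor: float = 4.0,
    global_sd: bool = False,
) -> ActivatedArea:
    """Cortical area whose response exceeds ``sd_factor`` x baseline SD.

    A pixel is activated when its maximum over the category's peak-search
    window strictly exceeds ``sd_factor`` times its own baseline (1-5 s)
    SD.  Only brain-mask pixels are eligible; zero-variance pixels are
    excluded and reported.  ``global_sd`` switches to a single SD pooled
    over all eligible pixels (alternative reading of the threshold rule).
    """
    win = search_window(timeline, category)
    b0, b1 = frame_window(*baseline_s, dff.rate)
    w0, w1 = frame_window(*win, dff.rate)
    if w1 > dff.n_frames or b1 > dff.n_frames:
        raise WindowError("baseline or search window exceeds the movie length")
    mask = np.asarray(brain_mask, bool)
    if dff.valid_mask is not None:
        mask = mask & dff.valid_mask
    base = dff.values[b0:b1]
    sd = base.std(axis=0, ddof=1)
    zero_var = mask & (sd <= 0)
    eligible = mask & (sd > 0)
    if global_sd:
        pooled = float(np.sqrt(np.mean(sd[eligible] ** 2))) if eligible.any() else 0.0
        thresh = np.full_like(sd, sd_factor * pooled)
    else:
        thresh = sd_factor * sd
    peak_img = dff.values[w0:w1].max(axis=0)
    activated = eligible & (peak_img > thresh)
    count = int(activated.sum())
    mm = pixel_size_um / 1000.0
    return ActivatedArea(
        pixel_count=count,
        area_mm2=count * mm * mm,
        n_eligible=int(eligible.sum()),
        n_zero_variance=int(zero_var.sum()),
    )
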