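"""Batch orchestration: simulate -> classify -> kinematics -> imaging -> report.

A run covers a cohort (genotype x mouse x day), generates or loads one
session per mouse-day, scores every trial, computes reach kinematics and
ROI peak amplitudes, and emits a tidy summary table with one row per
(mouse, day).  Group statistics never pool trials across animals: each
animal is first reduced to per-animal summaries, and genotype values are
means of those (SEM over animals).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .imaging import (
    compute_dff,
    demultiplex,
    extract_trace,
    hemodynamic_correct,
    peak_amplitude,
)
from .kinematics import path_length, spout_distance, trajectory_stats
from .pose import frame_window
from .synth import Session, SynthConfig, generate_session
from .trials import (
    REWARDED,
    TrialRecord,
    classify_trial,
    detect_early_reach,
    records_to_frame,
    summarize_performance,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Cohort-level configuration for a reproducible batch run."""

    seed: int = 0
    out_dir: str = "waterreach_run"
    n_trials: int = 40
    include_imaging: bool = False
    image_shape: tuple[int, int] = (64, 64)
    cohort: dict[str, list[str]] = field(
        default_factory=lambda: {"WT": ["wt1", "wt2"], "HD": ["hd1", "hd2"]}
    )
    days: list[int] = field(default_factory=lambda: [8, 45])
    #: optional {genotype: {day: {field: value}}} overrides of SynthConfig
    #: fields; ``success`` is shorthand for the rewarded success probability
    #: (the remaining rewarded mass is rescaled).
    day_params: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    rois: list[str] = field(default_factory=lambda: ["M1_contra", "M2_contra"])

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.image_shape, list):
            cfg.image_shape = tuple(cfg.image_shape)
        return cfg

    def canonical_json(self) -> str:
        def default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, sort_keys=True, default=default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _rescale_rewarded(probs: dict[str, float], success: float) -> dict[str, float]:
    """Set the success probability, rescaling the other categories."""
    rest = {k: v for k, v in probs.items() if k != "success"}
    total = sum(rest.values())
    if total <= 0:
        out = dict.fromkeys(probs, 0.0)
        out["no_reach"] = 1.0 - success
    else:
        out = {k: v * (1.0 - success) / total for k, v in rest.items()}
    out["success"] = success
    return out


def resolve_synth_config(
    config: RunConfig, genotype: str, mouse_idx: int, day_idx: int
) -> SynthConfig:
    """SynthConfig for one mouse-day, with a stable derived seed (< 2^31)."""
    genotypes = sorted(config.cohort)
    g_idx = genotypes.index(genotype)
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(g_idx, mouse_idx, day_idx)
    )
    derived = int(ss.generate_state(1, np.uint32)[0] % (2**31))

    kwargs: dict = dict(config.synth)
    day = config.days[day_idx]
    overrides = dict(config.day_params.get(genotype, {}).get(day, {}))
    success = overrides.pop("success", None)
    kwargs.update(overrides)
    kwargs.setdefault("n_trials", config.n_trials)
    kwargs.setdefault("image_shape", tuple(config.image_shape))
    sc = SynthConfig(seed=derived, **kwargs)
    if success is not None:
        sc.rewarded_category_probs = _rescale_rewarded(
            sc.rewarded_category_probs, float(success)
        )
    sc.validate()
    return sc


def analyze_session(
    session: Session, rois: list[str] | None = None, with_imaging: bool = True
) -> dict:
    """Score one session: trial records, kinematics, ROI peaks.

    Classification and geometry come from the pose tracks alone (the
    synthetic ground truth is never consulted).
    """
    geometry = spout_distance(session.pose[0])
    records: list[TrialRecord] = []
    lengths: list[float] = []
    peaks: dict[str, list[float]] = {r: [] for r in (rois or [])}

    for i, tracks in enumerate(session.pose):
        timeline = session.timelines[i]
        cls = classify_trial(tracks, timeline, geometry)
        early = detect_early_reach(
            tracks, timeline, geometry, classification=cls
        )
        records.append(
            TrialRecord(
                index=i,
                trial_type=timeline.trial_type,
                category=cls.category,
                early_reach=early,
                timeline=timeline,
            )
        )
        if cls.category == "success":
            pl = path_length(tracks, timeline, geometry)
            if not pl.flagged:
                lengths.append(pl.value)
        if (
            with_imaging
            and session.stacks is not None
            and rois
            and cls.category in ("success", "partial_fail", "unrewarded_reach")
        ):
            fluo, reflect = demultiplex(session.stacks[i])
            base = (0.0, timeline.reward_s if timeline.reward_s is not None else timeline.tone_s)
            corrected = hemodynamic_correct(
                compute_dff(fluo, base), compute_dff(reflect, base)
            )
            n10 = frame_window(0.0, 10.0, corrected.rate)[1]
            corrected.values = corrected.values[:n10]
            for roi in rois:
                trace = extract_trace(corrected, session.roi_map, roi)
                peaks[roi].append(
                    peak_amplitude(trace, timeline, cls.category).amplitude
                )

    return {
        "records": records,
        "success_lengths": lengths,
        "roi_peaks": peaks,
        "geometry": geometry,
    }


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the full batch; returns the tidy summary table.

    Writes per-stage tables and a manifest (version, seed, config hash)
    under ``config.out_dir``.  Deterministic for a fixed config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    all_records = []
    t0 = time.time()
    for genotype, mice in sorted(config.cohort.items()):
        for m_idx, mouse in enumerate(mice):
            for d_idx, day in enumerate(config.days):
                stage = f"{genotype}/{mouse}/day{day}"
                try:
                    sc = resolve_synth_config(config, genotype, m_idx, d_idx)
                    session = generate_session(
                        sc, include_imaging=config.include_imaging
                    )
                    res = analyze_session(
                        session,
                        rois=config.rois if config.include_imaging else None,
                        with_imaging=config.include_imaging,
                    )
                except ConfigError:
                    raise
                except Exception as exc:  # pragma: no cover - defensive
                    raise StageError(stage, str(exc)) from exc
                rec_df = records_to_frame(res["records"])
                rec_df["day"] = day
                rec_df["mouse"] = mouse
                rec_df["genotype"] = genotype
                all_records.append(rec_df)
                perf = summarize_performance(rec_df).iloc[0]
                lengths = res["success_lengths"]
                row = {
                    "genotype": genotype,
                    "mouse": mouse,
                    "day": day,
                    "n_trials": sc.n_trials,
                    "success_frac": perf["success_frac"],
                    "partial_fail_frac": perf["partial_fail_frac"],
                    "complete_fail_frac": perf["complete_fail_frac"],
                    "no_reach_frac": perf["no_reach_frac"],
                    "groom_frac": perf["groom_frac"],
                    "unrewarded_reach_frac": perf["unrewarded_reach_frac"],
                    "early_reach_frac": perf["early_reach_frac"],
                    "n_success": len(lengths),
                    "path_mean": float(np.mean(lengths)) if lengths else np.nan,
                    "path_sd": (
                        float(np.std(lengths, ddof=1)) if len(lengths) > 1 else np.nan
                    ),
                }
                for roi, vals in res["roi_peaks"].items():
                    row[f"peak_{roi}"] = float(np.mean(vals)) if vals else np.nan
                rows.append(row)
                logger.info("finished %s in %.1f s", stage, time.time() - t0)

    table = pd.DataFrame(rows)
    table.to_csv(out / "summary_table.csv", index=False)
    pd.concat(all_records, ignore_index=True).to_csv(
        out / "trial_records.csv", index=False
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return table


def genotype_compare(
    table: pd.DataFrame, measure: str, by_day: bool = True
) -> pd.DataFrame:
    """Descriptive genotype contrast: mean of per-animal values, SEM, n.

    Each (mouse, day) row contributes one value; the genotype mean is the
    unweighted mean of animal values and the SEM runs over animals.
    Inferential testing is deliberately not part of this layer.
    """
    if measure not in table.columns:
        raise ConfigError(f"unknown measure {measure!r}")
    keys = ["genotype", "day"] if by_day else ["genotype"]
    rows = []
    for key, sub in table.groupby(keys):
        vals = sub[measure].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            {
                "measure": measure,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sem": (
                    float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else np.nan
                ),
                "n_mice": int(vals.size),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_run(table: pd.DataFrame, measures: list[str] | None = None) -> pd.DataFrame:
    """Genotype x day contrast tables for a set of measures."""
    if measures is None:
        measures = ["success_frac", "early_reach_frac", "path_mean", "path_sd"]
    parts = [genotype_compare(table, m) for m in measures if m in table.columns]
    return pd.concat(parts, ignore_index=True)
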