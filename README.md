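# waterreach

Analysis toolkit for a head-fixed water-reaching task with simultaneous
widefield calcium imaging, plus a synthetic-session generator with recorded
ground truth for end-to-end validation.

Mice alternate between rewarded trials (visual cue at 2 s, tone plus water
drop at 6 s) and nonrewarded trials (tone only). On rewarded trials a spout
touch ends the trial 4 s later (bounded to 10-16 s); nonrewarded trials
last 16 s. The cortex is imaged through strobed illumination: fluorescence
and reflectance frames alternate at 120 Hz, giving two 60 Hz channels. The
package covers:

- **Trial engine** (`waterreach.trials`) — trial timelines, 10-s analysis
  truncation, and a rule-based classifier that scores each trial into
  behavioral categories (success, partial fail, complete fail, no reach,
  groom, unrewarded reach, disregard) from pose tracks alone.
- **Kinematics** (`waterreach.kinematics`) — spout-distance normalization,
  reach path length over the 1.1 s after reward, per-distance histograms,
  and hierarchical per-animal/per-group statistics that never pool trials
  across animals.
- **Imaging** (`waterreach.imaging`, `waterreach.atlas`) — channel
  demultiplexing, percent dF/F against the pre-reward baseline,
  reflectance-subtraction hemodynamic correction, landmark-based affine
  atlas registration, ROI peak amplitudes from 5x5-pixel centroid windows,
  and activated cortical area (response above 4x baseline SD).
- **Synthetic sessions** (`waterreach.synth`) — a generator that simulates
  pose tracks, event logs and strobed movies from explicit per-trial
  latents (category, reach onset, target path length, ROI amplitudes,
  artifact phase), all recorded as ground truth.
- **Pipeline + CLI** (`waterreach.pipeline`, `waterreach` command) — cohort
  runs (genotype x mouse x day) producing tidy summary tables, and thin
  subcommands `simulate`, `classify`, `kinematics`, `imaging`, `report`,
  `run-all`.

## Quick start

```python
from waterreach import (
    SynthConfig, generate_session, spout_distance, classify_trial, path_length,
)

session = generate_session(SynthConfig(n_trials=20, seed=1), include_imaging=False)
geom = spout_distance(session.pose[0])
for tracks, timeline in zip(session.pose, session.timelines):
    result = classify_trial(tracks, timeline, geom)
    if result.category == "success":
        print(timeline.trial_type, path_length(tracks, timeline, geom).value)
```

Command line:

```sh
waterreach simulate --out session_dir --seed 1 --n-trials 20
waterreach classify --out scored_dir --seed 1 --n-trials 20
waterreach run-all --config examples/cohort.yaml
```

## Repository layout

- `src/waterreach/` — the library
- `tests/` — unit, property and acceptance tests (`pytest -q tests/`)
- `scripts/acceptance.py` — recomputes headline quantities from scratch:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
- `examples/` — narrative walk-throughs of each stage
- `docs/methods.md` — precise definitions of every metric and rule

## Conventions

- Time windows are half-open `[t0, t1)`; frame indices use
  `ceil(t * rate)` with a 1e-9 guard against float noise.
- All dF/F values are in percent; path lengths are in multiples of the
  platform-to-spout distance.
- Group statistics are means of per-animal values (SEM across animals);
  trials are never pooled across animals.
- Every random quantity flows from explicit integer seeds; rerunning any
  entry point with the same seed is byte-identical.
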