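"""Reach path lengths: per-trial metric, histogram, group statistics.

The path length of a successful reach is the Euclidean length of the
left-paw trajectory over the 1.1 s after the water drop, expressed in
multiples of the platform-to-spout distance.

Run:  python examples/02_reach_kinematics.py
"""

import numpy as np

from waterreach import (
    SynthConfig,
    bin_distances,
    classify_trial,
    generate_session,
    path_length,
    spout_distance,
    trajectory_stats,
)

# Treat each seed as one animal; collect that animal's success-trial
# path lengths.
per_mouse = {}
for mouse, seed in [("m1", 21), ("m2", 22), ("m3", 23)]:
    session = generate_session(
        SynthConfig(n_trials=60, seed=seed), include_imaging=False
    )
    geometry = spout_distance(session.pose[0])
    lengths = []
    for tracks, timeline in zip(session.pose, session.timelines):
        if classify_trial(tracks, timeline, geometry).category != "success":
            continue
        result = path_length(tracks, timeline, geometry)
        if not result.flagged:  # skip trials with uninterpolatable gaps
            lengths.append(result.value)
    per_mouse[mouse] = lengths
    print(f"{mouse}: {len(lengths)} successes, "
          f"mean {np.mean(lengths):.2f} spout distances")

# Relative-frequency histogram over integer bins, pooled for display only.
pooled = [v for vals in per_mouse.values() for v in vals]
print("\npath-length histogram (% of reaches per bin):")
print(bin_distances(pooled).to_string())

# Group statistics reduce each animal to its own mean/SD first.
stats = trajectory_stats(per_mouse)
print(f"\ngroup mean of per-animal means: {stats['mean_of_means']:.3f} "
      f"+/- {stats['sem_of_means']:.3f} (SEM over animals)")
print(f"group mean of per-animal SDs:   {stats['mean_of_sds']:.3f}")
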