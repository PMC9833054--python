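# Methods

Precise definitions of every rule and metric implemented by `waterreach`.
All analysis operates on the first 10 s of each trial unless stated
otherwise; time windows are half-open `[t0, t1)` and are mapped to frame
indices as `[ceil(t0 * rate), ceil(t1 * rate))` (with a 1e-9 tolerance).

## Trial structure

Camera and timers start at t = 0. The visual cue appears at 2 s; the tone
(and, on rewarded trials, the water drop) arrives at 6 s. Trial types
strictly alternate, starting with a rewarded trial, with a 4-s inter-trial
interval.

- **Rewarded trials** end `min(touch + 4 s, 16 s)` after a spout touch, or
  at 16 s when no touch occurs; trial length is therefore bounded to
  [10 s, 16 s]. A touch before the reward time is a timing fault and is
  rejected.
- **Nonrewarded trials** always last 16 s; touch events are ignored.

Touch-sensor times define timelines only; behavioral scoring never uses
them (the capacitive sensor does not reliably report reaches).

## Pose handling

Pose tables follow the two-header-row CSV convention (body part, then
coordinate) at 60 Hz with key points `left_paw`, `right_paw`, `mouth`,
`platform`, `spout`. Frames with confidence below 0.5 are dropout; gaps of
at most 5 frames are linearly interpolated, longer gaps (and gaps touching
the trial edges) stay masked. The *masked fraction* of a track counts
frames still unusable after interpolation.

## Behavioral classification

Let D be the spout distance: `|median(platform_y) - median(spout_y)` over
confident frames (at least 10 required; a degenerate geometry is an
error). The rest posture is the median paw position over the 2 s before
the visual cue. The classifier applies, in order:

1. **Disregard** — more than 50 % of paw frames masked.
2. **Reach detection** — an episode where the paw rises more than 0.10 D
   above the platform with net forward displacement (toward the spout) of
   at least 0.15 D.
3. **Contact** — paw within 0.10 D of the spout.
4. **Retrieval** — paw within 0.10 D of the mouth within 2 s of contact.
5. **Groom** — at least 3 paw-mouth oscillation cycles without spout
   contact (checked before complete fail).

Rewarded categories: contact + retrieval → `success`; contact without
retrieval → `partial_fail`; groom cycles → `groom`; reach without contact
→ `complete_fail`; otherwise `no_reach`. Nonrewarded categories: any
reach or groom → `unrewarded_reach`, else `no_reach`. An **early reach**
is a reach onset strictly before the reward time on a success trial.

## Kinematics

The **path length** of a reach is the Euclidean length of the left-paw
polyline over `[reward, reward + 1.1 s)`, expressed in multiples of D.
Results with uninterpolatable gaps inside the window are flagged.
Histograms use integer bins `[k, k + 1)` and report relative frequency in
percent. Per-animal statistics are the mean and sample SD (ddof = 1) of
that animal's trials; group values are unweighted means of per-animal
values with SEM across animals. Trials are never pooled across animals.

## Widefield imaging

The camera alternates fluorescence and reflectance frames at 120 Hz
(fluorescence first); demultiplexing yields two 60-Hz channels, dropping a
trailing unpaired frame with a warning. Raw counts are 12-bit (0-4095)
with a pixel size of 68 µm after binning.

- **dF/F** — per pixel, `(F - F0) / F0 * 100` with F0 the mean over
  `[0, reward)`; pixels whose F0 is at the dark floor are masked.
- **Hemodynamic correction** — the reflectance channel carries the
  hemodynamic/movement artifact but no indicator signal, so the corrected
  movie is `fluorescence dF/F - reflectance dF/F`, pixelwise.
- **Atlas** — 12 regions per hemisphere (M1, M2, sspm, sspfl, ssphl,
  sspun, sspn, sspbfd, ssptr, visp, rspagl, rspd; `_contra` = right
  hemisphere). The packaged reference atlas is procedural (elliptical
  brain mask, nearest-seed partition) with bregma/lambda plus two lateral
  landmark anchors. Registration fits a least-squares affine on at least
  three non-collinear matched landmarks and warps labels by nearest
  neighbor; the RMS landmark residual is reported.
- **ROI traces** — per-frame mean over the 5x5-pixel window at the ROI
  centroid (rounded half-toward-the-smaller index). The window must be at
  least 5x5 pixels of ROI, which requires a grid of 128x128 or finer for
  the default atlas.
- **Peak amplitude** — maximum of the trace over the category's search
  window minus the mean over the 1-5 s baseline; ties resolve to the
  earliest frame. Search windows: `[reward, reward + 4 s)` for success and
  partial-fail trials, the full `[0, 10 s)` for unrewarded reaches.
- **Activated area** — count of brain-mask pixels whose window maximum
  strictly exceeds 4x their own baseline SD (ddof = 1, 1-5 s window),
  converted to mm² with (68/1000)² per pixel. Zero-variance pixels are
  excluded and reported.

## Synthetic sessions

Each trial draws its latents from an independent substream
(`default_rng([seed, trial_index])`): category (from configurable
probabilities), reach onset, target path length (normal with mean 2.1 and
SD 0.6 spout distances, resampled to at least the category minimum), early
reach injection, ROI peak amplitudes and artifact phase. Trajectories are
frame-aligned polylines whose lateral oscillation amplitude is solved
numerically so the discrete in-window path length equals the target
exactly. Measurement noise is dropout (glitched low-confidence frames,
2 % by default) plus optional smooth jitter; disregard trials get one
contiguous occlusion span covering 70 % of the trial.

Movies combine a smooth baseline intensity image, ROI-masked calcium
transients (difference-of-exponentials kernel, 0.1 s rise / 1.0 s decay,
unit peak), and a shared hemodynamic waveform (0.3-amplitude 0.1 Hz
sinusoid plus a causal reach-locked bump, 0.15 s rise / 1.2 s decay)
scaled by per-channel gains in percent, with per-pixel Gaussian noise,
then quantized to 12 bits and interleaved fluorescence-first.

## Pipeline

A cohort run iterates genotype x mouse x day, derives one independent
sub-seed per cell (`SeedSequence(entropy=seed, spawn_key=(genotype,
mouse, day))`), generates and scores a session, and emits one summary row
per (mouse, day): category fractions (excluding disregarded trials from
denominators), early-reach fraction among successes, path-length mean/SD
over unflagged successes, and mean corrected ROI peaks over reach trials.
Genotype contrasts are descriptive (mean of per-animal values, SEM over
animals); inferential statistics are deliberately out of scope.
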