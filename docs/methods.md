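# Methods

This note documents the models, rules and numerical choices behind
`stalltrack`: what each stage computes, which parameters matter, what the
synthetic scenarios do and do not emulate, and where the design was
genuinely open.

## Coordinate and file conventions

Positions are sub-pixel floats in image coordinates: origin at the top-left
corner, x rightward, y downward, frames indexed from 1.  The default image
is 2704 × 1520 px (2.7K) and the default acquisition rate 2 time-lapse
images per second; both are explicit configuration everywhere — no
conversion ever infers a frame rate.  Track CSVs use the fixed dialect
`frame,marker,x,y,predicted` (ground truth: `...,visibility`; behaviour:
`frame,behaviour`) with `#`-comment metadata headers; other trackers'
exports are expected to be adapted by a small reader shim.

### Training-frame subsampling

`subsample_training_frames` selects every `stride`-th frame among the
first `limit` frames for annotation.  "Every 10th of the first 2500"
naively yields 250; the implemented convention takes multiples of the
stride *strictly below* the limit (10, 20, …, 2490), i.e. 249 frames per
video — the simplest exclusion rule consistent with the published
per-video count for this protocol, and it is fixed as the package-wide
convention.

## Mislabel screening

Two rules operate on predicted tracks:

* **Jumps.**  For successive predicted frames the squared-pixel screening
  statistic `((Δx)·(Δf))² + ((Δy)·(Δf))²` is computed and reported
  verbatim.  Thresholding, however, uses the Euclidean displacement: the
  statistic multiplies displacement by the frame gap, which deliberately
  inflates values across prediction gaps, whereas the 200-px rule is
  defined between *consecutive* frames, where the statistic reduces to the
  squared distance.  The implementation therefore flags gap-1 pairs when
  displacement > 200 px (strict), and pairs with gap g > 1 when
  displacement > g·200 px — genuine motion can accumulate roughly linearly
  across a gap, so the scaled rule degrades gracefully instead of flagging
  every long gap.  The unscaled variant is available
  (`scale_threshold_by_gap=False`) since either reading is defensible.
* **Missing runs.**  Maximal runs of > 30 consecutive unpredicted frames
  (strict) where the marker is *expected* visible.  With ground truth
  supplied, frames annotated `not_visible` neither accrue nor interrupt a
  run; without it, every frame counts as expected-visible (conservative
  screening).

WP (wrongly-predicted count) is the number of distinct predicted frames
participating in at least one jump segment — set semantics, so overlapping
segments never double-count a frame.

## Detection performance

"Hidden" means the annotation class `not_visible` only: partially occluded
markers (25/50/75 %) carry annotated positions, so failing to predict them
is a miss (FN), not a correct rejection.  Because automated scoring needs a
distance criterion where a human inspector used judgement, a **match
radius** decides TP vs FP; the default is 100 px (~3.7 % of the 2.7K image
width) — generous relative to the coarse body-area definitions of the
markers, but far below typical distractor mislabels, which sit hundreds of
pixels away.  Sensitivity, error rate and accuracy are exact formula
applications; any metric with a zero denominator propagates as undefined
(NaN) and is excluded, with its count, from mean ± SD aggregation
(sample SD, n − 1).

The version comparison is a **paired** two-sided Student's t-test, pairing
videos by id, because the two tracker versions score the same recordings;
an unpaired Welch variant is exposed for unpaired designs.  Zero variance
of the paired differences with a non-zero mean is reported as a degenerate
comparison rather than an infinite statistic.  The across-marker comparison
is a one-way ANOVA on per-video metric values.  Both use scipy.stats, and
the test suite cross-checks them against values frozen from an independent
statistics environment plus the two-group identity F = t².  No
multiple-testing correction is applied; significance is judged at
p < 0.05.

## Synthetic stall scenarios

The simulator emulates the *statistical structure* of tracker output on
stall video, not its appearance: no images are rendered and lighting exists
only as a dropout probability.

* **Behaviour chain.**  One of four states per frame (standing
  observation, rest, feeding, moving) from a row-stochastic 4×4 matrix.
  Default self-transition probabilities give stationary bouts of roughly
  2–4 minutes and locomotion bouts of ~15 s, with stationary states
  exchanging through "moving" — a horse walks between its preferred spots.
  The published protocol quantifies no horse kinematics (speeds, dwell
  times), so all kinematic defaults are synthetic choices of realistic
  magnitude, marked as such in config, and fixed once.
* **Kinematics.**  The nose is the anchor: it is pulled toward the active
  state's preferred region centroid at a speed-capped rate (pull rate 0.15
  per frame, caps 30–40 px/frame) plus white jitter per state (standing
  5 px, feeding 2 px, rest 0.25 px, moving 6 px).  During a moving bout the
  horse walks at full speed toward the preferred region of the *next*
  stationary state in the label sequence (labels are simulated first, so
  the lookahead is well defined) and orbits nearby once arrived; this keeps
  transit kinematics inside the moving label, so the chain's stationary
  distribution is preserved exactly and stationary labels describe
  genuinely stationary motion.  Withers and tail trail the nose along an
  exponentially smoothed heading at fixed body lengths (250 and 280 px);
  the heading only updates above 15 px/frame so stationary jitter cannot
  spin the body.  A full skeleton is deliberately not modelled — markers
  are analysed independently downstream, so distance-bounded trailing
  suffices.  Simulation is in the 2D image plane; the oblique camera
  projection is not modelled because every downstream analysis consumes
  pixel coordinates only.
* **Rest oscillation.**  Rest frames add a sinusoid to the nose
  y-coordinate (default amplitude 8 px, period 40 frames = 20 s), the
  weight-shifting signature.  Amplitude 0 is the settled variant.
* **Occlusion and visibility.**  Only the tail is scheduled `not_visible`,
  when the heading points toward the door (cosine > 0.55) — the dominant
  real-world occlusion for an oblique stall camera.  2 % of otherwise
  visible marker-frames receive a random partial-occlusion class (with
  positions, as annotation practice supplies them).
* **Degradation.**  In order: Gaussian localisation jitter (default
  σ = 1 px), dropout runs (start probability 0.01/frame, geometric lengths,
  mean 3), and Poisson teleports (default 1 per 1000 frames) relocated onto
  distractor objects — waterer, manure pile, shoes — or uniform positions,
  always ≥ `jump_min_magnitude_px` (default 250) from the true position.  A
  teleport landing on a hidden frame becomes a false positive.  Every event
  is logged (type, marker, frame, magnitude) for recovery tests.
* **Determinism.**  One numpy Generator per seed, consumed in a fixed
  order (labels → positions → visibility; degradation takes its own seed),
  so identical (config, seed) reproduce bit-identical outputs.

What passing tests on these scenarios shows: the *rules and metrics recover
exactly what was injected* under controlled artifact structure.  What they
do not show: performance on real horses — real mislabels are not
independent Poisson events, real occlusion is not a clean heading rule, and
real behaviour is not Markovian.  The scenario parameters set the
difficulty of the recovery problems; they are not claims about horses.

## Behaviour classifier

A per-frame rule cascade on gap-filled (forward-filled) tracks, all
displacements smoothed by a centred 7-frame rolling mean:

1. withers displacement > 18 px/frame → **moving**;
2. else nose y > 1100 px (the trough sits low in the image) → **feeding**;
3. else nose displacement < 3.5 px/frame → **rest**;
4. else → **standing observation**;

followed by a minimum-duration filter (5 frames) that absorbs short runs
into the neighbouring class earliest in cascade order.  The published
proposal names the goal but no algorithm or thresholds, so these defaults
are calibrated on the default synthetic scenario: 18 px separates the
standing jitter envelope (~6 px mean step) from locomotion (~40 px);
3.5 px separates resting (~0.4 px true step plus noise) from standing; the
feeding line is the top of the trough region.  On the default 28,800-frame
scenario the cascade agrees with generator labels on ≈ 93–95 % of frames;
residual disagreement concentrates at bout boundaries (smoothing lag) and
in locomotion bouts too short to survive the duration filter.  Agreement
degrades monotonically with localisation noise, as the rest/standing
displacement contrast drowns first.  These thresholds transfer to real data
only as starting points; they are plain configuration (`ClassifierParams`).

## Occupancy and the weight-shift signature

Heat maps use half-open square bins `[k·s, (k+1)·s)` with far-edge
positions assigned to the last bin; total mass equals the predicted-frame
count by construction (asserted).  Region containment is
boundary-inclusive; overlapping regions each accrue a frame and the
multiply-counted total is reported, while the implicit `elsewhere` key
makes disjoint partitions exhaustive (percents sum to 100 within 1e-9).
Both boundary conventions are fixed for cross-platform determinism.

`rolling_dispersion` is a centred rolling sample variance over predicted
frames (window default 120 frames = 1 min; frames with under half a window
of support are missing).

`detect_weight_shifting` flags rest bouts whose vertical nose variance
betrays unsettled standing.  Robustness required three guards, each
motivated by a concrete failure mode of the naive rolling variance:

* non-rest frames are masked out *before* windowing, so locomotion
  bordering a bout cannot bleed into its windows;
* positions deviating > 50 px from a rolling median are rejected
  (residual teleports, already reported by QC, would otherwise dominate),
  and a centred 41-frame rolling mean is subtracted, removing the slow
  settling drift at bout onset while passing the faster oscillation
  (period ≈ 40 frames) through;
* the first 60 frames of each bout are excluded outright (settling), and
  each bout is summarised by the *median* of its rolling variance; bouts
  with < 60 supported frames are reported but never flagged.

A bout is flagged when its summary exceeds `variance_ratio_threshold`
(default 3) times a reference variance.  The default reference is an
**absolute quiet-posture baseline** of 5 px² (postural sway plus ~1 px
localisation noise over a 1-min window) rather than the track's own median
rest variance: a relative reference cannot detect a recording in which
*every* rest bout oscillates — the exact between-day contrast the signature
exists for — because the median is then itself elevated and no bout can
exceed a ratio of ~1.  The relative mode remains available
(`baseline_variance_px2="median_rest"`) and is the right tool for spotting
one unusual bout within a single recording; both modes are tested.  For an
oscillation of amplitude A the detrended rolling variance plateaus near
A²/2 (32 px² at the default A = 8), comfortably above 3 × 5 px²; quiet rest
sits near 1–2 px².

## Pipeline and reproducibility

`run_validation` and `run_case_study` orchestrate the stages from one
config (synthetic scenario or input files — exactly one), log per-stage
counts in and out, and write CSV bundles whose headers record the seed and
a hash of the scientific configuration (the output directory is excluded
from the hash), making reruns byte-identical per (config, seed).  The CLI
is a thin click layer over these two functions plus `simulate` and `qc`.

## Problem sizes

Default analysis scales used throughout the tests and the acceptance
script: 28,800 frames (4 h) for classifier agreement; 20 scenarios of
10,000 frames for jump recovery; 8 videos of 4,000 frames for the
validation bundle; 20 seeds × 6,000 frames per arm for the weight-shift
contrast; 1,000 random 200-frame windows for the confusion oracle check.

## Known limitations

* The simulator's horse hovers near region centroids (OU-style pull); real
  horses cover regions more broadly, so synthetic heat maps are more
  concentrated than real ones.
* The behaviour chain has no diurnal structure and no inter-horse
  variability.
* Orientation ("looking toward the sidewall") is only approximated by the
  nose–withers heading; with three markers, position and orientation
  cannot be fully disentangled, so occupancy and heading are reported
  separately and no single "looking at" figure is asserted.
* Classifier thresholds are synthetic-calibrated; on real data they must
  be re-tuned against scored video.
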