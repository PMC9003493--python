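# Methods

## Signal model and preprocessing

The input is a uniformly sampled single-axis accelerometer series — the
axis aligned with the bottle's vertical, so the resting value is the
gravity projection and a drinking tilt produces a smooth bump. All
processing is sample-indexed; `sample_rate_hz` (default 20 Hz) only
converts indices to seconds, and every duration-valued constant (the
120-sample episode = 6 s, the maximum sip length) assumes that rate.
Higher-rate recordings should be decimated before entry.

**Filtering.** A centered moving average of `ma_window` samples
(default 5, odd required) with symmetric shrink at the edges. A centered
window keeps gesture peaks in place; the interior is computed by direct
per-window summation rather than a running sum, which would cancel
catastrophically when values span many orders of magnitude.

**Segmentation.** Local extrema use strict comparison, with plateaus
collapsed to their first sample — this makes behavior on noise-free
(piecewise-constant) streams deterministic. A peak segment spans two
consecutive local minima below `segmentation_threshold` and must contain a
local maximum above that threshold; the extra above-threshold condition
discards sub-threshold noise ripple between two quiet minima, which would
otherwise flood the classifier with degenerate episodes. A gesture that
has not returned below threshold when the stream ends is dropped rather
than emitted half-formed.

The default threshold is estimated per stream as
`median + max(0.25·(max − median), 8·MAD)`: the median estimates the
resting baseline, the 25% rule places the cut well below the smallest sip
bump but above gentle non-sip motion, and the MAD floor (≈ 5.4 σ for
Gaussian noise) keeps an activity-free stream from being segmented at all.
A fixed raw-units threshold can be supplied instead.

Note that two distinct thresholds exist and must not be conflated: the
raw-domain `segmentation_threshold` above, and the normalized-domain
`th_norm` = 10 used by the feature extractor (10 is the floor of the
normalized range, so "above 10" means "above the gesture's own minimum").

**Normalization and windowing.** Each segment is affinely mapped to
[10, 20]; a constant segment maps to all-10 (the range floor), the only
degenerate case. Windows are right-padded with 10; segments longer than
120 samples are truncated to their first 120 samples rather than
discarded — discarding would silently drop unusually slow sips, and the
truncated prefix still carries the gesture's rise and plateau (the
`last_height` feature then correctly reports an unfinished gesture).

## Episode features

Five per-episode features: peak count above `th_norm`, raw-domain maximum
height, above-threshold duration, stable-band occupancy, and last-sample
height. The maximum height is deliberately taken from the raw segment
rather than the normalized window: normalization maps every non-constant
segment's maximum to exactly 20, so the normalized value carries no
information, while the raw maximum is the tilt-magnitude proxy the
first-sip detector also relies on. The stable band is multiplicative by
default (`≥ 0.8 · window max`), which is scale-free; an additive variant
(`≥ max − 0.2·(norm span)`) is a config switch. A window whose maximum
does not exceed `th_norm` (an all-pad window) has no peak and is assigned
zero stable samples. Features are standardized (mean/sd of the training
split) before entering the network, because their units are heterogeneous
— counts, raw acceleration, normalized heights; the constants are stored
with the model.

## Classifiers

Both classifiers are dense feed-forward networks small enough to count
parameters by hand (`Σ (fan_in + 1)·fan_out`), with sigmoid output and
binary cross-entropy loss. Training is implemented directly (explicit
forward/backward passes over numpy arrays) so a seed fully determines the
result: Glorot-uniform initialization, seeded stratified 80:20
shuffle-split, seeded epoch shuffles, mini-batch SGD (lr 0.01) or Adam
(lr 0.001). Defaults follow the two training recipes used in this setting:
sip classifier — SGD, 300 epochs, batch 100; first-sip detector — Adam,
150 epochs, batch 10. Hidden activation is ReLU (configurable); learning
rates are configurable since the choice is otherwise unconstrained.
Training loss is recorded per epoch for inspection; it is monitored, not
asserted, since mini-batch descent is not strictly monotone.

The first-sip detector's training data have one positive per drinking
cycle, so samples are weighted by inverse class frequency. Early sip
indices (i ≤ 3) clamp missing lag references to the first height, giving
neutral near-zero features; since those cannot identify the session's
opening sip, the pipeline labels the first detected sip of a session a
first-sip by convention (it opens the first cycle; the volume estimator
treats it identically either way).

## Volume estimator

State: cumulative intake `Vintake`, per-sip estimate `VSip`, sips since
the last first-sip `Scount`, the cycle's starting intake, and the cycle's
*uncapped* accumulation. Non-first sips add
`min(VSip, Vbottle − cycle consumption)` — the cap that freezes the
display at one full bottle when a refill was missed. The snap at a first
sip chooses `k* = argmin_{k≥1} |uncapped − k·Vbottle|` from the uncapped
accumulation: the capped value saturates at one bottle and could never
indicate that two bottles were drunk, whereas the uncapped sum grows
through the missed refill and correctly yields k* = 2. Ties (residual
exactly half a bottle) break toward the smaller k; k = 0 is excluded
because a completed cycle implies at least one bottle — a first-sip
arriving with `Scount = 0` (session start, or two first-sips in a row) is
treated as the cycle-opening sip with no correction. The default ordering
closes the old cycle before adding the new first sip's volume, so the snap
covers exactly the sips that emptied the bottle; an add-then-correct
variant is available behind `literal_order=True`. `VSip` re-estimation
uses the closed cycle's count (`k*·Vbottle / Scount`), the only
dimensionally sensible choice.

Consequences, verified by the test suite: `Vintake` is non-decreasing
(the correction is always ≥ 0); per-cycle displayed consumption never
exceeds `Vbottle`; under perfect detection the boundary error is exactly
zero; with a fraction q < 0.5 of sips dropped at random the boundary is
still snapped to the correct multiple and intra-cycle error is bounded by
roughly `q·Vbottle + VSip`; partial refills are out of scope (the snap
always targets integer multiples of the stated bottle volume).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not bottle biomechanics. Sips are raised-cosine bumps (smooth, one local
maximum, so a clean sip has exactly one counted peak) of 1.5–4 s, with
amplitude `base + rank·increment` within a cycle (defaults: baseline 1.0,
base amplitude 1.0, increment 0.15 in arbitrary raw units — only relative
amplitudes survive normalization) and a reset to the base amplitude at
each refill, which realizes the refill drop of
`(sips_per_cycle − 1)·increment`, several times any within-cycle step, so
the gradient features are separable by construction. Non-sip kernels are
plausibility-driven, not fitted: rectified ~2 Hz sinusoids for walking
(slower/larger on stairs, damped in a bag), low-amplitude noise for
stationary and in-car, and sub-second spikes for fidgeting — encoding the
qualitative contrasts the features rely on (few peaks and long durations
for sips, the opposite for oscillatory activities). Quiet stretches carry
a small centered "settle" dip (the bottle being put down), which
guarantees a delimiting minimum between gestures even in noise-free
streams, where a perfectly flat gap would be a single undetectable
plateau. Per-sip true volumes within a cycle are equal
(`Vbottle / sips_in_cycle`), matching the estimator's constant-VSip model;
heterogeneous volumes are available for stress tests. Everything is
driven by one seed; identical configs and seeds give identical streams.

What passing tests show — and do not. The generator guarantees the
qualitative structure (single-bump sips, monotone within-cycle heights,
sharp refill drops) that the feature design presumes; real recordings add
inter-subject gesture variation, drifting baselines, and non-sip gestures
that mimic sips more closely than these kernels do. Accuracy figures
measured on synthetic data therefore validate the machinery, not
real-world performance.

## Sizes and tolerances

Default test and acceptance problem sizes: 200 training + 120 held-out
episodes for the sip classifier, 12 × 6 noise-free cycles for the
first-sip detector, 100 random instances per numeric-kernel oracle
comparison, and 4–6-cycle sessions for the estimator properties — sizes at
which every stochastic check is comfortably stable under its fixed seed.
Forward passes are compared to the independent matrix oracle at relative
tolerance 1e−10; metric percentages are floored to integers when reported
(26.82% → 26%).
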