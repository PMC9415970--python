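# Methods

## Model and procedure

`breathalert` treats outlier detection on breathing features as a
per-person problem: no population model is fitted, and every threshold
is learned from one individual's own resting data. The procedure is

1. **Windowing.** Sliding windows of W samples, stride 1 by default.
   Two enumeration conventions are exposed because the extremum and
   frequency analyses traditionally index their series differently:
   `all_full_windows` produces ⌊(N−W)/stride⌋ + 1 values (used for
   moving max/min and amplitude; 2880 training samples with W = 12 give
   2869 values), while `drop_last` discards the final window and
   produces ⌊(N−W)/stride⌋ values (used for the FFT feature; 2880
   samples with W = 48 give 2832 values). The off-by-one is a
   convention, not a property of the data; both are configurable.
2. **Features.** Per-window max, min, max−min, and the DFT-magnitude
   argmax bin. The dominant-frequency feature is reported in bin
   indices, not Hz, and ties break toward the smallest bin.
3. **Baselines.** Per person × feature × variant, from the resting
   segment only (leading sit+walk phases in field mode; first half of
   the recording in literature mode).
4. **Alerts.** Strict threshold violations on test windows, with a side
   (above/below the band). Summaries: per-subject alert fraction,
   cohort mean ± sd (population sd, so one subject gives sd 0), RA/LA
   counts.

Assumptions: the belt signal is stationary enough *within* the training
segment that a single (μ, σ) or quantile pair describes it; activity
labels are trustworthy; windows from filtered variants (talking-only or
non-talking-only samples concatenated) may span removed gaps, which
slightly blurs features at the seams but keeps every variant's pipeline
identical.

## FFT handling

The literal dominant-frequency definition takes the argmax over all W
DFT bins, DC included. A belt signal has a large positive offset, so
bin 0 then dominates every window and the feature degenerates. The
default mode therefore demeans each window and restricts the argmax to
bins 1…⌊W/2⌋; a `paper_literal` mode (no demeaning, all bins) is kept
for strict replication. In the literal mode the argmax is computed on
the real-FFT half-spectrum: mirrored bins j and W−j of a real signal
have exactly equal magnitude in exact arithmetic, so under the
smallest-index tie-break the winner always lies in 0…⌊W/2⌋, and
computing it there keeps the tie-break exact instead of leaving it to
floating-point noise between mirrored bins. No tapering, zero-padding
or window function is applied.

## Threshold rules and their parameters

* **α (dimensionless, default 1.5)** — half-width of the Gaussian band
  in standard deviations. 1.5 is the reference operating point for the
  extremum and amplitude features. σ uses the population convention
  (ddof = 0, configurable); at n ≈ 2900 the sample correction is
  negligible, but determinism requires one fixed choice.
* **outlier_fraction (default 0.05)** — training mass left outside a
  quantile band; two-sided splits it equally between tails. Univariate
  quantile thresholds are the *nearest order statistics* to the
  requested levels rather than interpolated values: with strict
  outside-comparisons, an interpolated threshold lies strictly inside
  the sample range for every fraction > 0 and would always flag the
  sample extremes, whereas order-statistic thresholds make the band
  span the full range as the fraction → 0 while still matching the
  requested outside-count to within ~1/n at moderate fractions.
* **jitter (uniform on ±0.5 by default, seeded)** — added before
  quantile estimation for integer-binned features, where ties at one
  bin would make quantiles degenerate. 0.5 is half the spacing of the
  frequency-bin grid, so jitter never moves a value across bins. Same
  seed → bit-identical thresholds.
* **Bivariate frame** — both coordinates are jittered, then a common
  per-axis two-tailed quantile level is found by bisection (60
  iterations on [0, 2·fraction], keeping the best level visited) so the
  fraction of jittered training points strictly outside the rectangle
  matches the joint target to within 1/n; the achieved fraction is a
  step function of the level, so the bisection tracks the closest
  plateau rather than assuming an exact root. The frame's
  "extreme 5 %" is interpreted as total outside-rectangle training
  mass, allocated symmetrically per axis. No jitter at test time.
* **Degenerate inputs** — a constant training signal gives σ = 0: the
  band collapses to a point and any deviation alerts; this is legal and
  logged as a warning, not an error. Values exactly at a threshold do
  not alert; values exactly at the training mean count toward neither
  RA nor LA.

Per-feature default side rules: moving max alerts above only (deep
breathing), moving min below only (exhausted exhalation), amplitude
above only, dominant frequency two-sided (too fast or too slow) with
the quantile rule. The RA/LA window-size sweep uses *two-sided*
amplitude alerts, since one-sided alerts would make LA identically zero
and the left/right comparison vacuous.

## Simulator

The generator emulates a field protocol (sit, walk, run, sit — 2 min
each at 12 Hz, talking during each phase's second minute; 5760 samples)
and a literature-style two-channel recording (63 s at 128 Hz; 8064
samples). The signal model is

    s(i) = level + drift(i) + a(i)·sin(φ(i)) + ε(i)

with per-activity frequency and amplitude, phase continuity across
activity boundaries, per-breath multiplicative amplitude jitter
(coefficient of variation per activity), a talking multiplier on the
amplitude (default 0.8, with the per-breath CV doubled while talking),
a random-walk drift (sd 0.02 belt units per √s) and white noise. All
randomness flows from one seed through independent substreams (phase,
drift, breath jitter, noise), so any component can be zeroed without
perturbing the others.

Default activity parameters — sit 0.25 Hz × 1.0, walk 0.30 Hz × 1.2,
run 0.60 Hz × 2.0 (belt units are arbitrary) — are fixture values
chosen so resting and running feature distributions overlap partially
rather than separating trivially. They are not physiological claims:
real belt traces have non-sinusoidal breath morphology, motion
artefacts, posture shifts and sensor slippage that this model omits.
Passing tests therefore demonstrate that the pipeline's bookkeeping,
calibration and ordering properties are correct, not that the alert
fractions it produces on synthetic subjects will match any particular
field cohort.

## Problem sizes

Tests and the acceptance script run at the protocol's native sizes
(5760-sample field traces, 8064-sample two-channel recordings, cohorts
of 10 subjects), which complete in seconds; the brute-force oracles use
1000 random extremum instances at N ≤ 40 and 200 random DFT windows at
W ≤ 64.

## Known limitations

* Only the 2-D rectangular frame is implemented for multivariate
  baselines; no robust estimators or parametric fits beyond mean/sd —
  deliberately minimal, matching the method's design.
* Quantile calibration guarantees are per training set; nothing is
  claimed about false-alarm rates on non-stationary test data.
* Alert fractions count windows; overlapping windows mean a single
  breathing event inflates several windows' worth of alerts.
* The simulator's ocular channel is an independent
  oscillation-plus-noise process; real respiration–ocular coupling is
  not modelled, so bivariate results only exercise the calibration
  machinery.
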