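# Methods

This note records what `sotyper` computes, the defaults it ships with,
and the choices made where the design was genuinely open.  Units are μV,
seconds and Hz throughout; sample index *i* at rate *f* maps to time
*i/f* from recording start (0-based).

## Detection

The detector works on the 0.1–4 Hz trace of each channel, produced by a
4th-order Butterworth filter applied forward–backward (zero phase, so
trough latencies are not shifted; this matters because base features are
time offsets).  Zero crossings are located by sign change between
consecutive samples and refined by linear interpolation, giving
sub-sample timing.  An event is a down–up–down crossing triple with

| criterion | default | comparison |
|---|---|---|
| negative half-wave duration | 0.3–1.0 s | inclusive |
| whole event span | ≤ 10 s | inclusive |
| trough voltage | ≤ −80 μV | inclusive (−80 passes) |
| peak-to-trough range | ≥ 80 μV | inclusive |
| stage containment | event ⊂ one N2 or N3 epoch | — |
| artifact containment | event ⊂ unmasked samples | — |

Candidates sharing a zero crossing are both kept if each passes on its
own (no merging rule is imposed).  Outlier pruning is applied once per
channel: events with |trough| above mean + 4·SD of the surviving
candidates' |trough| are dropped; channels with fewer than three
candidates skip pruning because the SD estimate is meaningless there.
The 4·SD rule is read as a from-the-mean rule on trough amplitude (not
peak-to-trough range); both readings are defensible and the choice is
recorded here deliberately.

Samples beyond the hypnogram's last epoch are treated as unstaged and
can host no event — stage membership is mandatory, which is the only
consistent reading of the same-stage containment rule.

## Artifact masks

Two band-power bin rules run per channel before detection; both use the
mean of squared band-filtered samples per bin as the bin statistic
(the rules' sources speak only of bins "greater than the median"; a
power statistic is the standard reading, and this choice is flagged as
such):

* **local rule** — 26.25–32 Hz, 4-s bins, reject when power > 4× the
  median of the 45 bins centered on the bin (window truncated at
  recording edges so the ends are not discarded wholesale);
* **global rule** — 4–50 Hz, 5-s bins, reject when power > 6× the median
  over all bins.

The combined mask is the AND of both rules and of any hypnogram
"artifact" epochs.  An all-zero signal masks nothing (0 > 4·0 is false).

## Co-detection typing

Every detection is one row of the binary co-detection matrix — a
traveling SO seen on six channels contributes six rows.  Entry (i, c) is
1 iff channel c holds a trough within ±400 ms of event i's trough; the
interval is closed at both ends (an epsilon of 1 ns guards float
representation of the boundary).  K-means (k = 3, Euclidean, 50
restarts, tolerance 1e-6, seeded) partitions the rows; naming is a
heuristic: the cluster with the largest mean row sum is Global; of the
remaining two, the one with the higher mean frontal fraction (share of
F3/F4 entries per row) is Frontal; the last is Local.  Ties closer than
a relative 1e-3 raise an error demanding manual assignment rather than
guessing.  When a cohort is labeled, rows from all subjects are pooled
and clustered once so labels mean the same thing across subjects; the
seed and the channel set used are recorded in the stage metadata.

## Feature bank

Each labeled event yields, per montage channel, 35 features computed on
a 2-s epoch centered on the trough and resampled to 200 Hz (polyphase,
anti-aliased).  The continuous recording is filtered *before* cutting so
the 2-s windows carry no filter edge artifacts.  Two versions of each
epoch are kept: the 0.1–4 Hz trace (for the six base waveform
coordinates, consistent with the detector) and the broadband trace (for
everything else).

* **Base (6)** — amplitude and time offset of the trough (global
  minimum), the nearest local maximum before t = 0 and the nearest local
  maximum after t = 0; when no interior local maximum exists the
  half-window maximum is used.  Offsets are measured from the detection
  channel's trough, so they are generally nonzero on other channels.
  Trough amplitudes are stored negative.
* **Band powers (7)** — mean Welch PSD (1-s Hann segments, 50% overlap,
  1 Hz resolution) over closed bands δ 1–4, SWA 0.1–4, θ 5–8, α 9–12,
  σ 13–15, β 16–30, low-γ 31–48 Hz.  At 1 Hz resolution the SWA and δ
  bands select the same bins; both columns are kept for schema
  stability, and tree models are indifferent to duplicated columns.
* **Band amplitudes (7)** — mean |x| of the trace band-filtered
  (4th-order zero-phase Butterworth) to the same bands.
* **Complexity (13)** — definitions fixed as: LZ76 phrase count of the
  median-binarized trace normalized by n/log₂n; sign changes of the
  mean-centered trace; Hjorth activity (variance), mobility and
  complexity; permutation and SVD entropies (order 3, delay 1,
  normalized); sample entropy (m = 2, r = 0.2·SD, Chebyshev,
  self-matches excluded, 0 when a count vanishes); Petrosian and Katz
  fractal dimensions; Higuchi fractal dimension (k_max = 10); DFA
  exponent (log-spaced windows of 4–100 samples, linear detrend);
  lag-1 autocorrelation.  Constant input falls back to entropies 0,
  fractal dimensions 1, DFA 0, mobility/complexity 0.  Each entropy and
  the LZ76 parser are verified in the test suite against naive
  brute-force implementations.
* **Descriptive (2)** — the integer code of the detection electrode in
  fixed montage order, replicated across channels so every channel
  carries 35 values (a constant column is harmless to tree models), and
  a spindle flag.  The spindle detector is pluggable; the default marks
  a channel when its sigma-band (11–16 Hz) moving RMS (250 ms boxcar)
  exceeds 3× the median of that moving-RMS trace *and* an absolute floor
  of 5 μV for ≥ 0.5 s contiguously.  The median (not the plain epoch
  RMS) defines the background because a genuine 0.7-s burst inside a 2-s
  epoch inflates the plain RMS enough to hide itself; the absolute floor
  stops large slow waves with negligible sigma content from triggering
  on filter residue.

Feature columns are named `<channel>__<feature>`; a full table at the
8-channel FCPO montage has 280 predictors, and the "base" mode keeps the
6 waveform coordinates per channel (12 predictors at the 2-channel F
montage).  No normalization is applied anywhere.

## Classifier

`SOTypeClassifier(table).fit(seed)` trains five XGBoost multiclass
models (`multi:softprob`), one per random subject-level 70–30 split, and
returns a results object with per-split held-out metrics, the pooled
confusion matrix (rows = true, class order Global/Frontal/Local
everywhere), the analytic chance baseline Σ pc² computed from label
proportions, and `summary()`.  Ensemble prediction is the unweighted
arithmetic mean of the five probability vectors.  Hyperparameter
defaults — 500 trees, depth 6, learning rate 0.1, hist tree method, no
early stopping — are deliberately untuned and recorded in the model
metadata.  Both per-split held-out metrics and pooled 5-model-average
evaluation on an external table are available and labeled distinctly.
Log-loss clips probabilities to [1e-15, 1−1e-15].  The montage battery
retrains on column subsets of an FCPO-featurized table for the five
montages × {full, base}; detection-node codes keep their FCPO values, as
the event set itself still comes from 8-channel detection.  A stage
filter (`stage="N2"` / `"N3"`) restricts training to one sleep stage so
stage-specific models can be trained and cross-evaluated.

## SHAP

Attributions are tree-path-dependent SHAP values on the margin
(log-odds) output, computed natively by XGBoost and averaged over the
five models; per model, attributions plus base value equal the margin
exactly.  Aggregations: signed mean per (feature, class); mean |SHAP|
per feature across classes (the ranking rule for "top features", ties
broken by schema order); family means across the montage's channels; and
per-channel values for scalp topographies, where trough amplitude's sign
is flipped so that large troughs read positive.  Summaries average over
all records, not only correctly classified ones.

## Synthetic cohorts

The generator is the study's test substrate and its defaults are the
reference conditions: 12 subjects × 600 s at 200 Hz, alternating 300-s
N3/N2 blocks, one event per minute of staged sleep per archetype, 1/f
background (exponent 1.0, 15 μV RMS, spectrum floored below 0.5 Hz).
Waveforms are a positive pre-peak (0.15–0.3 of the depth), a negative
half-sine of 0.45–0.85 s, and a positive rebound (0.3–0.5 of the depth);
the half-sine's amplitude is divided by the 0.1–4 Hz filter's measured
trough attenuation so the drawn depth is what the detector sees, which
is what "supra-threshold by construction" has to mean.  Archetypes:

* **Global** — all eight channels, anterior→posterior lag 30 ms per
  montage step (≤ 210 ms total, inside the ±400 ms window), regional
  depth profile with central maximum (F 0.85, C 1.0, P 0.90, O 0.78)
  times a per-channel jitter U(0.85, 1), drawn depth −200…−140 μV;
* **Frontal** — F3/F4, extending to C3/C4 at 0.9 scale with
  probability 0.15, depth −155…−110 μV;
* **Local** — one uniformly random channel, depth −130…−90 μV.

The depth ranges overlap deliberately: real SO amplitude distributions
overlap across types, and without overlap the posterior channels carry
no information the frontal/central ones lack, which would make the
montage-reduction experiment vacuous.  The extension probability sits
below an empirical phase transition (near 0.2) above which k-means
starts splitting the Frontal cluster by footprint size instead of
separating Frontal from Local.  Spindles are 13 Hz Hann-windowed bursts
(0.7 s, 25 μV) planted 0.25 s after the trough with per-type coupling
probabilities (0.3/0.2/0.1); artifact bursts (28 Hz, 4–6 s, 10× noise
RMS) are off by default.  Troughs are kept ≥ 3.5 s apart and ≥ 2.5 s
from stage-block edges; placement redraws on collision and errors out
after a bounded number of tries.  All randomness flows from one seed
with per-subject substreams, so cohorts are bit-identical under a seed
and subjects can be generated independently.

Ground-truth matching is greedy one-to-one by trough-time proximity
within 0.4 s (the co-detection delay; events are seconds apart, so the
window is unambiguous, while background noise can shift a detected
trough's argmin by ~0.1 s).  With no detections, recall is 0 and
precision is reported as 1 with an explicit flag.

What the generator does *not* emulate: realistic traveling-wave
streamlines, REM/N1 phenomenology, ocular and cardiac artifacts,
inter-subject amplitude scaling, electrode impedance drift, and
co-detection noise from overlapping physiological events.  Passing
tests therefore demonstrate that the pipeline's logic is correct and
self-consistent under known ground truth — not that the classifier's
synthetic accuracy (~0.95 at 8 channels) transfers to real recordings,
where reported accuracies are substantially lower.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run desk-scale problems
chosen to keep every stage deterministic and quick: detector checks use
one 10-min subject; labeling checks use 300 archetype rows with 2% bit
flips; end-to-end runs use 12 subjects × 240 s per seed (≈ 500–650
events) with 120 trees, depth 4, learning rate 0.15 — a scaled-down
setting of the shipped defaults appropriate for cohorts three orders of
magnitude smaller than a multi-night study.  The end-to-end test
averages 10 seeds; the acceptance script 3.  K-means recovery is judged
against an independent restart-swept Lloyd's implementation (adjusted
Rand index), not against the fitted path itself.

Known limitations: the EDF writer is minimal (one data record, 16-bit,
physical range per channel from the data); the SWA/δ band duplication at
1 Hz Welch resolution noted above; Frontal–Local confusion is the
dominant error mode on synthetic cohorts, as it is in the problem this
pipeline addresses; and cluster naming assumes the three archetypes are
actually present — on data where they are not, the tie error is the
intended outcome.
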