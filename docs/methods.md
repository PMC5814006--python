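# Methods

## Problem and model

`emglift` asks how early, during a symmetrical lift, low-back surface EMG
carries enough information to identify which of three loads (no-weight,
10 lbs, 24 lbs) is being lifted.  The reference time point is **load-onset**:
the instant the load is fully supported by the lifter, detected from a force
plate (weighted lifts) or a contact circuit (no-weight lifts).  Muscle
activity recorded at 1.2 kHz from four bipolar electrodes at L4/L5 is reduced
to two normalized linear envelopes (left, right), aligned at onset, and
classified window by window over the ±2 s region.

The classifier is a multinomial logistic regression (MLR): for feature vector
x and classes k ∈ {no-weight, 10-lbs, 24-lbs},

  P(y = k | x) = exp(β_k·x̃) / Σ_j exp(β_j·x̃),   x̃ = (1, x),

with the 24-lbs class as the implicit reference (β fixed at 0).  The output
label is the argmax probability; exact ties resolve to the earlier class in
the fixed class order.

## Processing chain

1. **Linear envelope** (raw mode): 20–300 Hz bandpass → 59–61 Hz bandstop →
   subtract the whole-recording mean → full-wave rectify → 4 Hz lowpass.
   All filters are Butterworth designs of order 5 applied forward–backward
   (`scipy.signal.sosfiltfilt`), i.e. zero phase with an effective
   10th-order magnitude response.  We read the stated order as the *design*
   order; this choice is centralized in `FilterSpec` so the alternative
   reading (order 5 effective) is a one-line change.  De-meaning uses the
   whole recording — the simplest defensible window.
2. **Amplitude normalization**: envelopes are divided by the peak envelope of
   the subject's maximal-effort recording (×100 → %MVC).  In synthetic raw
   mode the generator supplies the matched constant 2/π (the rectified-mean
   gain of a unit-MVC Gaussian carrier passed through the chain).
3. **Side averaging**: left = mean(left-lateral, left-medial), right
   likewise.  If one channel of a side is marked faulty the surviving
   channel is used verbatim.  A correlation report flags channel pairs with
   Pearson r < 0.96.
4. **Per-subject renormalization**: every sample of every lift of a subject
   is divided by the maximum (over both channels) of that subject's
   chronologically first 24-lbs lift.  The maximum is taken jointly over
   both channels since neither channel is singled out by the protocol.
   This step makes amplitudes comparable across subjects and is what makes
   inter-subject (leave-one-subject-out) classification viable.
5. **Onset detection**: force-plate lifts — first sample with force ≤ table
   weight + 5% of load weight ("fully lifted" tolerance); circuit lifts —
   first crossing of the closed/open midpoint that persists for 10 ms
   (debounce).  Both thresholds are engineering defaults exposed in
   configuration, not protocol constants.  Trials that do not cover the
   full ±2 s region raise an error; nothing is padded.
6. **Features**: 100 ms windows, 50 ms overlap → 79 windows over ±2 s; per
   window and channel: mean, SD, diff (= last − first sample), max, min,
   amp (= max − min), RMS — 14 features.  SD uses the sample (n−1)
   denominator (`sd_ddof` switches to population).  Windows are half-open
   sample intervals; at 1.2 kHz a window holds 120 samples.
7. **z-scoring**: per feature, (y − mean)/SD with mean and SD pooled over
   the training+validation observations of the current outer fold and
   window; the same parameters transform the test set (the only reading
   that keeps the test subject out of every fitted statistic).

## Evaluation protocol

Nested leave-one-subject-out.  Outer folds hold out each subject once as
the test set; within an outer fold, each remaining subject serves once as
the validation set (inner folds), the others as training.

Per (window, outer fold):

- **Redundancy removal**: features scanned in a fixed priority order
  (mean, SD, diff, max, min, amp, RMS; left before right); a feature is
  dropped when its |Pearson r| with an already-retained feature is ≥ 0.80.
  Computed on the pooled training+validation observations of the fold —
  the same pool the z-score uses — so the test subject never contributes.
  A `redundancy_scope="global"` flag computes one removal outcome on all
  data instead, for comparison.
- **Greedy feedforward selection**: starts empty; each round trains one
  classifier per remaining candidate (appended to the current set) on every
  inner fold and scores it by mean validation accuracy across inner folds;
  the best candidate is added; the search stops when all candidates are
  used or no candidate strictly improves the score.  Ties go to the
  earliest candidate in priority order — deterministic and seed-free.
  One optimal feature set is recorded per (window, outer fold):
  79 × 9 = 711 for the default protocol.
- **Final model**: refit on the pooled training+validation lifts with the
  selected features, then applied to the test subject's lifts.

Reported surfaces: per-window test and validation accuracy (mean ± SD over
outer folds), per-class recall curves, row-normalized confusion matrices at
the best fully-pre-onset and fully-post-onset windows (ties break toward
onset), the selected-feature frequency table and set-size histogram, and
per-subject × class recall at the optimal windows.  A leakage audit tags
every fitted object (redundancy report, z-score parameters, final model,
optimal set) with the subject set it saw and asserts the test subject is
absent — 4 checks per (window, fold) cell.

## Numerical choices

- MLR fitting: damped Newton from a zero start, gradient tolerance 1e-8
  (scaled by n), max 500 iterations, ridge 1e-6 on non-intercept
  coefficients.  If the coefficient ∞-norm passes 50 (perfect separation:
  the unpenalized optimum diverges), the fit restarts with ridge 1e-3 and
  the model is flagged.  The evaluation loop batches the (candidate × inner
  fold) fits of one greedy round through a vectorized Newton path; it is
  verified against the single-problem path to 1e-6.
- Undefined quantities fail loudly: zero pooled SD names the feature,
  constant features are removed with a flag before z-scoring, a constant
  accuracy curve makes the test/validation agreement NaN (reported missing)
  rather than an arbitrary number.

## Synthetic data

The generator emulates the structure visible in averaged lift envelopes:
activity rises as the subject bends toward the load, spikes near load-onset
with an amplitude that grows with the lifted load, and relaxes afterwards.
Per trial, the envelope is

  base(t)·g_subject + A_class·g_subject·g_trial·exp(−(t − t₀ − j)²/2σ²) + ε(t),

clipped at zero, with defaults: spike peaks A = 0.15 / 0.45 / 0.70 of MVC
for no-weight / 10-lbs / 24-lbs (ordering constrained strictly increasing;
the values are tunable stand-ins, not measured quantities), spike width
σ = 250 ms, bend-ramp plateau 0.10 MVC, additive noise SD 0.03 MVC,
subject gain g_subject log-normal (σ = 0.15), left/right asymmetry ±10%.

Two noise sources beyond the obvious ones matter:

- **Trial-to-trial amplitude variability** (g_trial log-normal, σ = 0.20):
  real lifts vary in vigor from repetition to repetition.  Without it, the
  per-subject renormalization cancels the subject gain almost exactly and
  classification saturates near 100%, which no surface-EMG protocol
  achieves.  σ = 0.20 puts peak accuracy in the low-to-mid 80s percent —
  the regime the method is designed for.
- **Spike-centre jitter** (σ = 30 ms) decouples the EMG spike slightly from
  the mechanical onset, as electromechanical delay variability does.

Event channels: weighted lifts get a force trace at table+load weight
stepping to table-only weight at the true onset sample (with a brief
unloading undershoot and 0.1 lb sensor noise) — the step construction makes
noise-free threshold detection land exactly on the true onset, which the
tests rely on; no-weight lifts get a 5 V → 0 V circuit drop.  Raw mode
replaces the two envelope channels with four channels of band-limited
(20–300 Hz) Gaussian noise amplitude-modulated by the same envelopes plus a
60 Hz interference tone, to exercise the full filter chain.

What the generator does **not** emulate: motor-unit statistics, fatigue
drift, electrode lift-off artifacts, inter-muscle crosstalk, or any
postural kinematics.  Passing tests on synthetic data therefore demonstrate
that the pipeline recovers the structure it assumes (onset-locked,
load-ordered spikes under multiplicative inter-subject and inter-trial
variability) — not that it would reach the same numbers on any particular
human dataset.

Randomness: one stream per trial keyed (seed, subject, lift), so any trial
can be regenerated independently of generation order; identical
configuration and seed give bit-identical datasets.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the full default protocol (9 subjects × 30
lifts, 79 windows; ≈ 50 s single-threaded).  The test suite runs one full
protocol and performs the multi-seed and separation-sweep checks on a
window grid restricted to ±600 ms around onset: windows are computed
independently, so the peak over that subgrid equals the full-grid peak
whenever the peak is onset-adjacent — which the full-grid run itself
verifies.

## Known limitations

- The greedy search evaluates candidates by mean inner-fold validation
  accuracy; how multiple validation subjects combine is a design choice
  (any monotone aggregate would also be defensible).
- Redundancy removal per outer fold can retain slightly different sets in
  different folds; the report keeps the per-fold ledger so this is visible.
- The supplementary-envelope reader (`read_s1_envelopes`) expects a
  long-format delimited table and offers both "as-is" and "normalize"
  modes because the deposited archive's normalization state is not
  documented; the adapter contract is defined by its fixture-based tests.
- Accuracy at a window is estimated from 30 lifts per test subject;
  per-fold SDs are correspondingly coarse.
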