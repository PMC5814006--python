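# emglift

Pre-onset lifted-load classification from low-back surface EMG.

When a person lifts a weight from a table, the lumbar paraspinal muscles
ramp up *before* the load is fully supported — and the size of that
preparatory burst grows with the load.  `emglift` implements the complete
analysis that turns this observation into an intent classifier for
assistive devices: it converts multi-channel surface EMG into normalized
linear envelopes, aligns every lift at **load-onset** (the instant the load
leaves the table, detected from a force plate or contact circuit), slides
100 ms windows across the ±2 s region, and classifies each window into
three load classes — *no-weight*, *10-lbs*, *24-lbs* — with a multinomial
logistic regression

&nbsp;&nbsp;&nbsp;&nbsp;P(y = k | x) = exp(β_k·x̃) / Σ_j exp(β_j·x̃)

trained per window under a **nested leave-one-subject-out** protocol:
each subject is the test set once; the remaining subjects rotate through
validation/training inner folds that drive correlation-based redundancy
removal (|r| ≥ 0.80), pooled train+validation z-scoring, and greedy
feedforward feature selection over 7 window statistics × 2 channels
(mean, SD, diff, max, min, amp, RMS).  The package reports accuracy and
per-class recall over the lift cycle, confusion matrices at the best
pre-/post-onset windows, and the selected-feature ledger across all
(window × test-subject) folds.

It ships a synthetic multi-subject lift generator (envelope or raw
four-channel mode, with force-plate and circuit event channels) so the
entire pipeline is testable without any data download, plus a reader for
deposited per-lift envelope tables.

Audience: biomedical-signal-processing and neuromechanics researchers
prototyping myoelectric intent recognition, and anyone who needs a clean
reference implementation of windowed nested-LOSO wrapper selection.

## Worked example

```python
import numpy as np
import emglift as eg

trials = eg.generate_dataset(eg.SimConfig(seed=1))        # 9 subjects × 30 lifts
report = eg.run_pipeline(trials)                          # ~1 min single-threaded

curves = report.accuracy_curves()
peak = int(np.argmax(curves["test_mean"]))
print(f"windows: {report.grid.n_windows}, optimal sets: {len(report.optimal_sets)}")
print(f"peak test accuracy {curves['test_mean'][peak]:.1f}% "
      f"at window centred {curves['centers_ms'][peak]:+.0f} ms")
print(f"test/validation curve agreement r = {report.curve_agreement():.3f}")
pre_w, post_w = report.optimal_windows()
conf, _ = report.confusion_at(pre_w)
print("pre-onset confusion (% of true class, rows no-weight/10-lbs/24-lbs):")
print(np.round(conf, 1))
```

prints

```
windows: 79, optimal sets: 711
peak test accuracy 83.7% at window centred -50 ms
test/validation curve agreement r = 0.993
pre-onset confusion (% of true class, rows no-weight/10-lbs/24-lbs):
[[98.9  1.1  0. ]
 [ 5.6 75.6 18.9]
 [ 0.  23.3 76.7]]
```

Reading: with the default simulated cohort the classifier identifies the
load with ~84% accuracy from a window that *ends before* the load leaves
the table; errors are almost entirely confusions between the two weighted
classes, whose preparatory bursts differ only in amplitude.  The
test-vs-validation agreement near 1 indicates the inner cross-validation
generalizes to the held-out subject.  Accuracy at ±2 s sits at the 33%
chance line, as it must — there is no load information that far from onset.

The same pipeline runs from the shell:

```bash
emglift simulate --out data/ --seed 1
emglift evaluate --data data/ --out run/
emglift report --run run/
```

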