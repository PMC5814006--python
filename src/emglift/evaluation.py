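"""Nested leave-one-subject-out evaluation over the lift cycle.

For every 100 ms time window and every outer fold (one held-out test
subject), the pipeline

1. removes redundant features on the pooled training+validation
   observations (the non-test subjects),
2. z-scores all sets with parameters fitted on that same pool,
3. runs greedy feedforward selection, scoring each candidate set by its
   mean validation accuracy over the inner leave-one-subject-out folds,
4. refits the classifier on the pooled training+validation lifts with the
   selected (optimal) feature set, and
5. classifies the held-out test subject's lifts.

One optimal feature set is recorded per (window, outer fold) — 79 × 9 = 711
for the default nine-subject protocol.  The report aggregates test and
validation accuracy curves, per-class recall, confusion matrices, the
selected-feature ledger and a leakage audit asserting that no fitted object
ever saw the test subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import features as feat
from . import mlr
from .onset import align, detect_onset
from .preprocessing import FilterSpec, average_sides, linear_envelope, normalize_to_mvc, renormalize_subject
from .selection import OptimalFeatureSet, greedy_select, remove_redundant
from .synthetic import DEFAULT_CLASSES, LiftTrial

__all__ = [
    "PipelineConfig",
    "FoldPlan",
    "EvaluationReport",
    "preprocess_dataset",
    "prepare_feature_tensor",
    "run_pipeline",
    "feature_frequency",
    "curve_agreement",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    table_weight: float = 36.0
    load_weight_by_class: dict[str, float] = field(
        default_factory=lambda: {"no-weight": 0.0, "10-lbs": 10.0, "24-lbs": 24.0}
    )
    onset_fraction: float = 0.05
    debounce: float = 0.010
    redundancy_threshold: float = 0.80
    redundancy_scope: str = "per_fold"        # or "global"
    sd_ddof: int = 1
    mlr_options: mlr.MLROptions = field(default_factory=mlr.MLROptions)
    renormalize: bool = True
    heavy_class: str = "24-lbs"
    audit: bool = True


@dataclass
class FoldPlan:
    """Nested leave-one-subject-out split layout."""

    subject_ids: tuple[str, ...]
    # outer fold = (test subject, inner folds); inner fold = (val subject, train subjects)
    outer: tuple[tuple[str, tuple[tuple[str, tuple[str, ...]], ...]], ...] = ()

    @classmethod
    def build(cls, subject_ids) -> "FoldPlan":
        sids = tuple(subject_ids)
        if len(sids) < 3:
            raise ValueError("nested LOSO needs at least 3 subjects")
        outer = []
        for test in sids:
            rest = tuple(s for s in sids if s != test)
            inner = tuple((val, tuple(s for s in rest if s != val)) for val in rest)
            outer.append((test, inner))
        return cls(subject_ids=sids, outer=tuple(outer))

    @property
    def n_outer(self) -> int:
        return len(self.outer)

    @property
    def n_inner(self) -> int:
        return len(self.outer[0][1])


def preprocess_dataset(trials, config: PipelineConfig | None = None) -> list[LiftTrial]:
    """Raw four-channel trials → normalized two-channel envelope trials."""
    import copy

    config = config or PipelineConfig()
    out = []
    for tr in trials:
        envs = {
            name: normalize_to_mvc(
                linear_envelope(tr.emg[k], tr.fs, config.filter_spec), tr.mvc_peak
            )
            for k, name in enumerate(tr.channel_names)
        }
        left, right, _ = average_sides(envs)
        new = copy.copy(tr)
        new.emg = np.vstack([left, right])
        new.channel_names = ("left-avg", "right-avg")
        out.append(new)
    return out


def prepare_feature_tensor(
    trials, grid: feat.WindowGrid, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Envelope trials → (features (n,W,14), labels, subject index, subject ids).

    Applies per-subject renormalization, onset detection and ±region
    alignment.  Envelope-mode trials (two channels) are consumed directly;
    raw trials must go through :func:`preprocess_dataset` first.
    """
    if trials[0].emg.shape[0] != 2:
        raise ValueError("expected two-channel envelope trials; run preprocess_dataset first")
    subject_ids = tuple(dict.fromkeys(tr.subject_id for tr in trials))
    by_subject = {s: [tr for tr in trials if tr.subject_id == s] for s in subject_ids}
    if config.renormalize:
        for s in subject_ids:
            by_subject[s], _ = renormalize_subject(by_subject[s], config.heavy_class)

    lo, hi = grid.region_ms
    half = max(abs(lo), abs(hi)) / 1000.0
    aligned, labels, subj_idx = [], [], []
    for si, s in enumerate(subject_ids):
        for tr in by_subject[s]:
            onset = detect_onset(
                tr,
                table_weight=config.table_weight,
                load_weight=config.load_weight_by_class.get(tr.label, 0.0),
                fraction=config.onset_fraction,
                debounce=config.debounce,
            )
            aligned.append(align(tr, onset, half_window=half))
            labels.append(tr.label)
            subj_idx.append(si)
    F = feat.extract_all(aligned, grid, ddof=config.sd_ddof)
    y = np.array([config.classes.index(lb) for lb in labels], dtype=int)
    return F, y, np.array(subj_idx, dtype=int), subject_ids


@dataclass
class EvaluationReport:
    grid: feat.WindowGrid
    classes: tuple[str, ...]
    subject_ids: tuple[str, ...]
    test_acc_pct: np.ndarray                 # (n_windows, n_outer)
    val_acc_pct: np.ndarray                  # (n_windows, n_outer)
    confusion_counts: np.ndarray             # (n_windows, n_outer, K, K) true × predicted
    optimal_sets: list[OptimalFeatureSet]
    retained: list[list[tuple[str, ...]]]    # [window][outer] retained feature names
    fold_plan: FoldPlan | None = None
    audit_passed: bool = True
    audit_checks: int = 0
    config: PipelineConfig | None = None

    @property
    def window_centers_ms(self) -> np.ndarray:
        return self.grid.centers_ms

    # ------------------------------------------------------------------ curves
    def accuracy_curves(self) -> dict[str, np.ndarray]:
        """Per-window mean ± SD accuracy (percent) over outer folds."""
        return {
            "centers_ms": self.window_centers_ms,
            "test_mean": self.test_acc_pct.mean(axis=1),
            "test_sd": self.test_acc_pct.std(axis=1, ddof=1) if self.test_acc_pct.shape[1] > 1 else np.zeros(self.test_acc_pct.shape[0]),
            "val_mean": self.val_acc_pct.mean(axis=1),
            "val_sd": self.val_acc_pct.std(axis=1, ddof=1) if self.val_acc_pct.shape[1] > 1 else np.zeros(self.val_acc_pct.shape[0]),
        }

    def recall_curves(self) -> dict[str, np.ndarray]:
        """Per-window per-class recall (percent), mean ± SD over outer folds."""
        counts = self.confusion_counts
        totals = counts.sum(axis=3, keepdims=True)  # true-class lift counts
        with np.errstate(invalid="ignore", divide="ignore"):
            recall = 100.0 * np.diagonal(counts, axis1=2, axis2=3) / totals[:, :, :, 0]
        return {
            "centers_ms": self.window_centers_ms,
            "mean": np.nanmean(recall, axis=1),
            "sd": np.nanstd(recall, axis=1, ddof=1) if recall.shape[1] > 1 else np.zeros_like(recall[:, 0, :]),
        }

    def confusion_at(self, window: int) -> tuple[np.ndarray, np.ndarray]:
        """Row-normalized confusion (percent) at one window: (mean, SD) over folds.

        Rows are true classes, columns predicted; each fold's rows sum to
        100% before averaging, so the averaged rows do too.
        """
        if not 0 <= window < self.grid.n_windows:
            raise ValueError(f"window {window} outside grid (0..{self.grid.n_windows - 1})")
        counts = self.confusion_counts[window].astype(float)  # (S, K, K)
        totals = counts.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * counts / totals
        mean = np.nanmean(pct, axis=0)
        sd = np.nanstd(pct, axis=0, ddof=1) if pct.shape[0] > 1 else np.zeros_like(mean)
        return mean, sd

    def optimal_windows(self) -> tuple[int, int]:
        """(pre-onset, post-onset) window indices of maximal mean test accuracy.

        Pre-onset windows end at or before t = 0; post-onset windows start at
        or after t = 0.  Ties break toward the window nearest onset.
        """
        m = self.test_acc_pct.mean(axis=1)
        starts = self.grid.starts_ms
        ends = starts + self.grid.window_ms
        pre = np.flatnonzero(ends <= 0)
        post = np.flatnonzero(starts >= 0)
        if pre.size == 0 or post.size == 0:
            raise ValueError("grid has no fully pre-onset or post-onset windows")

        def _pick(idx: np.ndarray, nearest_last: bool) -> int:
            best = m[idx].max()
            cand = idx[m[idx] >= best - 1e-12]
            return int(cand[-1] if nearest_last else cand[0])

        return _pick(pre, True), _pick(post, False)

    def per_subject_recall(self, windows: tuple[int, int] | None = None):
        """Per-subject × class recall (%) at the optimal windows → DataFrame."""
        import pandas as pd

        if windows is None:
            windows = self.optimal_windows()
        rows = []
        for phase, w in zip(("pre", "post"), windows):
            for si, s in enumerate(self.subject_ids):
                counts = self.confusion_counts[w, si]
                totals = counts.sum(axis=1)
                for k, cls in enumerate(self.classes):
                    rec = 100.0 * counts[k, k] / totals[k] if totals[k] else np.nan
                    rows.append(
                        {"phase": phase, "window": w, "subject": s, "class": cls, "recall_pct": rec}
                    )
        return pd.DataFrame(rows)

    def curve_agreement(self) -> float:
        curves = self.accuracy_curves()
        return curve_agreement(curves["test_mean"], curves["val_mean"])


def curve_agreement(test_curve: np.ndarray, val_curve: np.ndarray) -> float:
    """Pearson correlation of the test and validation accuracy curves.

    Returns NaN (flagged via log) when either curve is constant, where the
    correlation is undefined.
    """
    a = np.asarray(test_curve, dtype=float)
    b = np.asarray(val_curve, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    if a.std() == 0 or b.std() == 0:
        log.warning("curve agreement undefined: a curve is constant; reporting NaN")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def feature_frequency(sets: list[OptimalFeatureSet], names=feat.FEATURE_NAMES) -> dict:
    """Selection percentage per feature and the optimal-set size histogram."""
    if not sets:
        raise ValueError("no optimal feature sets")
    n = len(sets)
    sel = {name: 100.0 * sum(name in s.features for s in sets) / n for name in names}
    sizes: dict[int, float] = {}
    for s in sets:
        sizes[len(s.features)] = sizes.get(len(s.features), 0.0) + 1
    sizes = {k: 100.0 * v / n for k, v in sorted(sizes.items())}
    return {"selection_pct": sel, "set_size_pct": sizes}


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth))


def run_pipeline(
    trials,
    grid: feat.WindowGrid | None = None,
    config: PipelineConfig | None = None,
    progress: bool = False,
) -> EvaluationReport:
    """Run the full windowed nested-LOSO classification protocol."""
    grid = grid or feat.WindowGrid()
    config = config or PipelineConfig()
    if trials and trials[0].emg.shape[0] > 2:
        trials = preprocess_dataset(trials, config)
    F, y, subj_idx, subject_ids = prepare_feature_tensor(trials, grid, config)
    plan = FoldPlan.build(subject_ids)
    K = len(config.classes)
    for si, s in enumerate(subject_ids):
        present = set(y[subj_idx == si])
        if len(present) < K:
            missing = [config.classes[k] for k in range(K) if k not in present]
            raise ValueError(f"subject {s} is missing class(es) {missing}")

    W = grid.n_windows
    S = len(subject_ids)
    test_acc = np.zeros((W, S))
    val_acc = np.zeros((W, S))
    confusion = np.zeros((W, S, K, K), dtype=int)
    optimal_sets: list[OptimalFeatureSet] = []
    retained_ledger: list[list[tuple[str, ...]]] = [[() for _ in range(S)] for _ in range(W)]
    audit_checks = 0
    names = feat.FEATURE_NAMES
    opts = config.mlr_options

    global_report = None
    if config.redundancy_scope == "global":
        # one removal outcome on all observations of all windows
        allX = F.reshape(-1, F.shape[-1])
        global_report = remove_redundant(
            allX, names, config.redundancy_threshold, subjects=subject_ids
        )

    for so, (test_subject, inner) in enumerate(plan.outer):
        ti = subject_ids.index(test_subject)
        pool_mask = subj_idx != ti
        test_mask = ~pool_mask
        pool_rows = np.flatnonzero(pool_mask)
        pool_subjects = frozenset(subject_ids[i] for i in np.unique(subj_idx[pool_mask]))
        # inner-fold row indices, fixed across windows
        inner_rows = []
        for val_subject, _train in inner:
            vi = subject_ids.index(val_subject)
            inner_rows.append(
                (
                    np.flatnonzero(pool_mask & (subj_idx != vi)),  # train
                    np.flatnonzero(subj_idx == vi),                # validation
                )
            )
        tr_sizes = {r[0].size for r in inner_rows}
        va_sizes = {r[1].size for r in inner_rows}
        balanced = len(tr_sizes) == 1 and len(va_sizes) == 1
        if balanced:
            tr_idx = np.stack([r[0] for r in inner_rows])
            va_idx = np.stack([r[1] for r in inner_rows])
        if progress:
            log.info("outer fold %d/%d (test %s)", so + 1, S, test_subject)

        for w in range(W):
            Xp = F[pool_rows, w, :]
            if global_report is None:
                report = remove_redundant(
                    Xp, names, config.redundancy_threshold, subjects=pool_subjects
                )
            else:
                report = global_report
            retained = report.retained
            if not retained:
                raise ValueError(f"all features removed as redundant at window {w}")
            cols = report.retained_indices
            zp = feat.fit_zscore(Xp[:, cols], retained, subjects=pool_subjects)
            Z = feat.apply_zscore(zp, F[:, w, :][:, cols])  # all rows, retained cols

            if config.audit:
                for art in (report, zp):
                    assert test_subject not in art.subjects, (
                        f"leakage: test subject {test_subject} inside {type(art).__name__}"
                    )
                    audit_checks += 1

            lut = {n: i for i, n in enumerate(retained)}
            if balanced:
                # same train/val sizes in every inner fold: batch one greedy
                # round's (candidate × inner fold) fits through one Newton run
                Ztr, Zva = Z[tr_idx], Z[va_idx]          # (B, n_tr/n_va, r)
                ytr, yva = y[tr_idx], y[va_idx]
                nB = tr_idx.shape[0]

                def round_score(sets: list[tuple[str, ...]]) -> np.ndarray:
                    C = len(sets)
                    sel = np.array([[lut[f] for f in s] for s in sets])
                    k = sel.shape[1]
                    Xtr = np.moveaxis(Ztr[:, :, sel], 2, 0).reshape(C * nB, -1, k)
                    Xva = np.moveaxis(Zva[:, :, sel], 2, 0).reshape(C * nB, -1, k)
                    yb = np.broadcast_to(ytr, (C, *ytr.shape)).reshape(C * nB, -1)
                    coefs, _ = mlr.fit_batch(Xtr, yb, config.classes, opts)
                    pred = mlr.predict_proba_batch(coefs, Xva).argmax(axis=2)
                    yv = np.broadcast_to(yva, (C, *yva.shape)).reshape(C * nB, -1)
                    return (pred == yv).mean(axis=1).reshape(C, nB).mean(axis=1)

                best = greedy_select(retained, round_score_fn=round_score)
            else:

                def score(feats: tuple[str, ...]) -> float:
                    sel = [lut[f] for f in feats]
                    accs = 0.0
                    for tr_rows, va_rows in inner_rows:
                        model = mlr.fit(Z[tr_rows][:, sel], y[tr_rows], config.classes, opts)
                        P = mlr.predict_proba(model, Z[va_rows][:, sel])
                        accs += _accuracy(P.argmax(axis=1), y[va_rows])
                    return accs / len(inner_rows)

                best = greedy_select(retained, score)
            best = replace(
                best,
                window_index=w,
                test_subject=test_subject,
                subjects=pool_subjects,
            )
            optimal_sets.append(best)
            retained_ledger[w][so] = retained
            val_acc[w, so] = 100.0 * best.validation_accuracy

            sel = [lut[f] for f in best.features]
            final = mlr.fit(
                Z[pool_rows][:, sel], y[pool_rows], config.classes, opts,
                subjects=pool_subjects,
            )
            if config.audit:
                assert test_subject not in final.subjects and test_subject not in best.subjects
                audit_checks += 2
            P = mlr.predict_proba(final, Z[test_mask][:, sel])
            pred = P.argmax(axis=1)
            truth = y[test_mask]
            test_acc[w, so] = 100.0 * _accuracy(pred, truth)
            for t_k, p_k in zip(truth, pred):
                confusion[w, so, t_k, p_k] += 1

    return EvaluationReport(
        grid=grid,
        classes=tuple(config.classes),
        subject_ids=subject_ids,
        test_acc_pct=test_acc,
        val_acc_pct=val_acc,
        confusion_counts=confusion,
        optimal_sets=optimal_sets,
        retained=retained_ledger,
        fold_plan=plan,
        audit_passed=True,
        audit_checks=audit_checks,
        config=config,
    )
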