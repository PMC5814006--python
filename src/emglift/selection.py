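"""Dimensionality reduction: correlation-based redundancy removal and
greedy feedforward feature selection.

Redundancy removal scans the 14 features in a fixed priority order (the
seven statistics in declaration order, left channel before right) and drops
any feature whose absolute Pearson correlation with an already-retained
feature is 0.80 or higher; constant features are dropped with a warning
flag.  Greedy selection then grows a feature set one feature at a time,
adding whichever candidate maximizes validation accuracy, and stops when all
candidates are used or no candidate strictly improves on the current best.
Ties go to the candidate earliest in the priority order, keeping the whole
procedure deterministic and seed-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RedundancyReport",
    "OptimalFeatureSet",
    "remove_redundant",
    "greedy_select",
    "greedy_forward_select",
]

log = logging.getLogger(__name__)


@dataclass
class RedundancyReport:
    matrix: np.ndarray                     # full pairwise correlation matrix
    names: tuple[str, ...]
    removed: tuple[str, ...]
    retained: tuple[str, ...]
    threshold: float
    constant_features: tuple[str, ...] = ()
    subjects: frozenset = field(default_factory=frozenset)  # provenance tag

    @property
    def retained_indices(self) -> np.ndarray:
        lut = {n: i for i, n in enumerate(self.names)}
        return np.array([lut[n] for n in self.retained], dtype=int)


def remove_redundant(
    X: np.ndarray,
    names: Sequence[str],
    threshold: float = 0.80,
    priority: Sequence[str] | None = None,
    subjects: Sequence | None = None,
) -> RedundancyReport:
    """Drop features correlated at ``threshold`` or higher with a retained one.

    ``priority`` (default: ``names`` order) fixes the scan order: earlier
    features are considered first and survive conflicts with later ones.
    Constant features (undefined correlation) are removed and flagged.
    """
    X = np.asarray(X, dtype=float)
    names = tuple(names)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 observations per feature")
    if X.shape[1] != len(names):
        raise ValueError("names must match feature columns")
    order = list(priority) if priority is not None else list(names)
    if set(order) != set(names):
        raise ValueError("priority must be a permutation of the feature names")

    sd = X.std(axis=0)
    constant = tuple(n for n, s in zip(names, sd) if not s > 0)
    if constant:
        log.warning("constant feature(s) removed: %s", ", ".join(constant))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)

    lut = {n: i for i, n in enumerate(names)}
    retained: list[str] = []
    removed: list[str] = []
    for name in order:
        i = lut[name]
        if name in constant:
            removed.append(name)
            continue
        if any(abs(corr[i, lut[r]]) >= threshold for r in retained):
            removed.append(name)
        else:
            retained.append(name)
    return RedundancyReport(
        matrix=corr,
        names=names,
        removed=tuple(removed),
        retained=tuple(retained),
        threshold=threshold,
        constant_features=constant,
        subjects=frozenset(subjects or ()),
    )


@dataclass
class OptimalFeatureSet:
    """One greedy-selection outcome (one time window × one outer fold)."""

    features: tuple[str, ...]              # in selection order
    accuracy_trace: tuple[float, ...]      # validation accuracy after each addition
    window_index: int = -1
    test_subject: str | None = None
    subjects: frozenset = field(default_factory=frozenset)  # provenance tag

    @property
    def validation_accuracy(self) -> float:
        return self.accuracy_trace[-1]


def greedy_select(
    candidates: Sequence[str],
    score_fn: Callable[[tuple[str, ...]], float] | None = None,
    round_score_fn: Callable[[list[tuple[str, ...]]], Sequence[float]] | None = None,
) -> OptimalFeatureSet:
    """Greedy feedforward selection over ``candidates`` (priority order).

    Each round scores every remaining candidate appended to the current set
    and keeps the best (ties → earliest candidate).  Stops when candidates
    are exhausted or no candidate strictly improves the best score.  A
    candidate whose scoring raises is skipped with a logged warning.

    ``round_score_fn``, when given, scores all of a round's candidate sets
    in one call (same semantics; lets callers batch classifier training).
    """
    if not candidates:
        raise ValueError("no candidate features")
    if (score_fn is None) == (round_score_fn is None):
        raise ValueError("give exactly one of score_fn / round_score_fn")
    selected: list[str] = []
    trace: list[float] = []
    best = -np.inf
    remaining = list(candidates)
    while remaining:
        sets = [tuple(selected) + (c,) for c in remaining]
        if round_score_fn is not None:
            scores = list(round_score_fn(sets))
        else:
            scores = []
            for cand_set in sets:
                try:
                    scores.append(score_fn(cand_set))
                except Exception as exc:  # pragma: no cover - defensive path
                    log.warning("candidate %s skipped: %s", cand_set[-1], exc)
                    scores.append(-np.inf)
        k = int(np.argmax(scores))      # first max wins ties
        if scores[k] > best or not selected:
            best = scores[k]
            selected.append(remaining.pop(k))
            trace.append(best)
        else:
            break
    return OptimalFeatureSet(features=tuple(selected), accuracy_trace=tuple(trace))


def greedy_forward_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    names: Sequence[str],
    trainer: Callable,
    predictor: Callable,
) -> OptimalFeatureSet:
    """Convenience wrapper: greedy selection against a single train/val split.

    ``trainer(X, y)`` fits a classifier; ``predictor(model, X)`` returns
    labels.  Validation accuracy is the fraction of correctly classified
    validation observations.
    """
    names = tuple(names)
    lut = {n: i for i, n in enumerate(names)}
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)

    def score(feats: tuple[str, ...]) -> float:
        idx = [lut[f] for f in feats]
        model = trainer(X_train[:, idx], y_train)
        return float(np.mean(predictor(model, X_val[:, idx]) == np.asarray(y_val)))

    return greedy_select(names, score)
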