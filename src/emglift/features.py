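"""Sliding-window time-domain features and pooled z-score normalization.

The aligned ±2 s envelope of each lift is segmented into 100 ms windows
overlapping by 50 ms (79 windows over the 4 s region), and seven descriptive
statistics are computed per window and channel: mean, standard deviation
(SD), difference (diff = last sample − first sample), maximum, minimum,
amplitude (amp = max − min) and root-mean-square (RMS) — 14 features per
window.  Features are z-scored against the pooled training+validation values
of each feature (the same parameters are then applied unchanged to the test
set, which keeps the test subject out of every fitted statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "FEATURE_NAMES",
    "STAT_NAMES",
    "WindowGrid",
    "ZScoreParams",
    "segment",
    "extract",
    "extract_all",
    "fit_zscore",
    "apply_zscore",
]

#: Statistic order doubles as the redundancy-removal priority order.
STAT_NAMES = ("mean", "sd", "diff", "max", "min", "amp", "rms")
SIDES = ("left", "right")
FEATURE_NAMES = tuple(f"{stat}-{side}" for stat in STAT_NAMES for side in SIDES)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over the onset-aligned region (times in ms)."""

    region_ms: tuple[float, float] = (-2000.0, 2000.0)
    window_ms: float = 100.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.region_ms
        if hi <= lo:
            raise ValueError(f"empty region {self.region_ms}")
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.window_ms > hi - lo:
            raise ValueError("window longer than region")

    @property
    def n_windows(self) -> int:
        lo, hi = self.region_ms
        return int((hi - lo - self.window_ms) // self.step_ms) + 1

    @property
    def starts_ms(self) -> np.ndarray:
        lo, _ = self.region_ms
        return lo + self.step_ms * np.arange(self.n_windows)

    @property
    def centers_ms(self) -> np.ndarray:
        return self.starts_ms + self.window_ms / 2.0

    def window_samples(self, fs: float) -> tuple[int, int]:
        """(window length, step) in samples; both must be integral at fs."""
        win = self.window_ms * fs / 1000.0
        step = self.step_ms * fs / 1000.0
        if abs(win - round(win)) > 1e-9 or abs(step - round(step)) > 1e-9:
            raise ValueError(
                f"window/step ({self.window_ms}/{self.step_ms} ms) not integral "
                f"at fs={fs}"
            )
        return int(round(win)), int(round(step))


def segment(aligned, grid: WindowGrid | None = None) -> np.ndarray:
    """Window sample-blocks of an aligned envelope.

    Returns an array of shape ``(n_windows, 2, window_samples)``; window i
    covers the half-open interval ``[start_i, start_i + window)`` with
    ``start_i = region_start + i * step`` relative to onset (t = 0 at the
    aligned onset sample).
    """
    grid = grid or WindowGrid()
    fs = aligned.fs
    win, step = grid.window_samples(fs)
    sig = np.vstack([aligned.left, aligned.right])
    lo_ms, hi_ms = grid.region_ms
    start0 = aligned.onset_sample + int(round(lo_ms * fs / 1000.0))
    end = start0 + int(round((hi_ms - lo_ms) * fs / 1000.0))
    if start0 < 0 or end > sig.shape[1]:
        raise ValueError(
            f"aligned envelope (length {sig.shape[1]}) does not cover the "
            f"grid region {grid.region_ms} ms"
        )
    views = sliding_window_view(sig[:, start0:end], win, axis=1)[:, ::step, :]
    n = grid.n_windows
    return np.swapaxes(views[:, :n, :], 0, 1)


def _window_stats(w: np.ndarray, ddof: int = 1) -> dict[str, np.ndarray]:
    """Seven statistics along the last axis."""
    if w.shape[-1] == 0:
        raise ValueError("empty window")
    return {
        "mean": w.mean(axis=-1),
        "sd": w.std(axis=-1, ddof=ddof) if w.shape[-1] > ddof else np.zeros(w.shape[:-1]),
        "diff": w[..., -1] - w[..., 0],
        "max": w.max(axis=-1),
        "min": w.min(axis=-1),
        "amp": w.max(axis=-1) - w.min(axis=-1),
        "rms": np.sqrt(np.mean(w * w, axis=-1)),
    }


def extract(window: np.ndarray, ddof: int = 1) -> dict[str, float]:
    """The 14 named features for one ``(2, n)`` window block."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[-1] == 0:
        raise ValueError("empty window")
    stats = _window_stats(window, ddof=ddof)
    out: dict[str, float] = {}
    for stat in STAT_NAMES:
        for k, side in enumerate(SIDES[: window.shape[0]]):
            out[f"{stat}-{side}"] = float(stats[stat][k])
    return out


def extract_all(
    aligned_list: Sequence, grid: WindowGrid | None = None, ddof: int = 1
) -> np.ndarray:
    """Feature tensor ``(n_lifts, n_windows, 14)`` in ``FEATURE_NAMES`` order."""
    grid = grid or WindowGrid()
    blocks = np.stack([segment(a, grid) for a in aligned_list])  # (n, W, 2, win)
    stats = _window_stats(blocks, ddof=ddof)                     # each (n, W, 2)
    cols = [stats[stat][:, :, k] for stat in STAT_NAMES for k in range(2)]
    return np.stack(cols, axis=-1)


@dataclass
class ZScoreParams:
    """Pooled mean/SD per feature, fitted on train+validation observations."""

    mean: np.ndarray
    sd: np.ndarray
    names: tuple[str, ...]
    subjects: frozenset = field(default_factory=frozenset)  # provenance tag


def fit_zscore(
    values: np.ndarray,
    names: Sequence[str],
    subjects: Sequence | None = None,
) -> ZScoreParams:
    """Fit pooled z-score parameters (sample SD, n−1 denominator)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ValueError(
            "zero pooled SD for feature(s): " + ", ".join(names[i] for i in bad)
        )
    return ZScoreParams(
        mean=mu,
        sd=sd,
        names=tuple(names),
        subjects=frozenset(subjects or ()),
    )


def apply_zscore(params: ZScoreParams, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != params.mean.shape[0]:
        raise ValueError(
            f"feature arity {values.shape[-1]} != fitted arity {params.mean.shape[0]}"
        )
    return (values - params.mean) / params.sd
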