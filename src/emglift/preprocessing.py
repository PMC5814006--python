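"""Raw EMG → normalized two-channel linear envelopes.

The chain, applied in order to each raw channel: 20–300 Hz bandpass,
59–61 Hz bandstop (mains rejection), de-mean, full-wave rectification, 4 Hz
lowpass.  All filters are 5th-order Butterworth designs applied forward and
backward (zero phase; the effective magnitude response is 10th order — the
order field names the design order).  Envelopes are scaled to percent of the
subject's maximum voluntary contraction (%MVC), the four electrode channels
are averaged into a left and a right signal, and each subject's lifts are
finally rescaled by the maximum %MVC observed in that subject's first
(chronologically) 24-lbs lift, which suppresses between-subject strength
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "FilterSpec",
    "CorrelationReport",
    "linear_envelope",
    "normalize_to_mvc",
    "average_sides",
    "renormalize_subject",
]

LEFT_CHANNELS = ("left-lateral", "left-medial")
RIGHT_CHANNELS = ("right-medial", "right-lateral")


@dataclass(frozen=True)
class FilterSpec:
    bandpass: tuple[float, float] = (20.0, 300.0)
    bandstop: tuple[float, float] = (59.0, 61.0)
    lowpass: float = 4.0
    order: int = 5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError(f"invalid bandpass corners {self.bandpass}")
        lo, hi = self.bandstop
        if not 0 < lo < hi:
            raise ValueError(f"invalid bandstop corners {self.bandstop}")
        if self.lowpass <= 0:
            raise ValueError("lowpass corner must be positive")

    def validate_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        corners = (*self.bandpass, *self.bandstop, self.lowpass)
        for c in corners:
            if c >= nyq:
                raise ValueError(
                    f"filter corner {c} Hz is at or above Nyquist ({nyq} Hz) for fs={fs}"
                )


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        try:
            return sosfiltfilt(sos, x)
        except ValueError as exc:  # too short for edge padding
            raise ValueError(
                f"signal of length {x.shape[-1]} is too short for zero-phase "
                f"filtering edge padding: {exc}"
            ) from exc
    from scipy.signal import sosfilt

    return sosfilt(sos, x)


def linear_envelope(
    raw: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Linear envelope of one raw EMG channel.

    Applies, in order: bandpass, bandstop, mean subtraction (whole-recording
    mean), full-wave rectification, lowpass.  Output has the input's length.
    The final lowpass can ring slightly below zero; no clipping is applied.
    """
    spec = spec or FilterSpec()
    spec.validate_fs(fs)
    x = np.asarray(raw, dtype=float)
    sos_bp = butter(spec.order, spec.bandpass, btype="bandpass", fs=fs, output="sos")
    sos_bs = butter(spec.order, spec.bandstop, btype="bandstop", fs=fs, output="sos")
    sos_lp = butter(spec.order, spec.lowpass, btype="lowpass", fs=fs, output="sos")
    x = _apply(sos_bp, x, spec.zero_phase)
    x = _apply(sos_bs, x, spec.zero_phase)
    x = x - x.mean()
    x = np.abs(x)
    return _apply(sos_lp, x, spec.zero_phase)


def normalize_to_mvc(envelope: np.ndarray, mvc_peak: float) -> np.ndarray:
    """Scale an envelope to percent of maximum voluntary contraction."""
    if not mvc_peak > 0:
        raise ValueError(f"mvc_peak must be positive, got {mvc_peak}")
    return 100.0 * np.asarray(envelope, dtype=float) / mvc_peak


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of the four %MVC channels."""

    pairs: dict[tuple[str, str], float]
    threshold: float = 0.96
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flagged = [p for p, r in self.pairs.items() if not r >= self.threshold]


def average_sides(
    channels: dict[str, np.ndarray],
    faulty: str | None = None,
    corr_threshold: float = 0.96,
) -> tuple[np.ndarray, np.ndarray, CorrelationReport]:
    """Average the two channels of each side into (left, right) signals.

    A channel named in ``faulty`` is excluded and the surviving channel of
    that side is used verbatim.  The report carries Pearson correlations for
    every available channel pair and flags pairs below ``corr_threshold``.
    """
    names = [n for n in (*LEFT_CHANNELS, *RIGHT_CHANNELS) if n in channels]
    missing = [n for n in (*LEFT_CHANNELS, *RIGHT_CHANNELS) if n not in channels and n != faulty]
    if missing:
        raise ValueError(f"missing channels {missing} (not marked faulty)")
    lengths = {len(channels[n]) for n in names}
    if len(lengths) > 1:
        raise ValueError(f"channel length mismatch: {lengths}")

    usable = [n for n in names if n != faulty]
    pairs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(channels[a], channels[b])[0, 1])
            pairs[(a, b)] = r

    def _side(side_names: tuple[str, str], side: str) -> np.ndarray:
        avail = [n for n in side_names if n in channels and n != faulty]
        if not avail:
            raise ValueError(f"both {side} channels unavailable or faulty")
        if len(avail) == 1:
            return np.asarray(channels[avail[0]], dtype=float)
        return np.mean([channels[n] for n in avail], axis=0)

    left = _side(LEFT_CHANNELS, "left")
    right = _side(RIGHT_CHANNELS, "right")
    return left, right, CorrelationReport(pairs=pairs, threshold=corr_threshold)


def renormalize_subject(
    lifts: Sequence, heavy_class: str = "24-lbs"
) -> tuple[list, float]:
    """Rescale all of one subject's lifts by the first heavy lift's peak.

    ``lifts`` are envelope-mode trials of a single subject carrying
    ``lift_index`` (chronological order), ``label`` and a 2-row ``emg``
    array.  The scaling factor is the maximum over both channels of the
    chronologically first ``heavy_class`` lift; every sample of every lift is
    divided by it, making that lift's peak exactly 1.0.  Returns the rescaled
    trials (new objects) and the factor.
    """
    import copy

    subjects = {getattr(tr, "subject_id", None) for tr in lifts}
    if len(subjects) > 1:
        raise ValueError(f"renormalize_subject got trials from several subjects: {subjects}")
    ordered = sorted(lifts, key=lambda tr: tr.lift_index)
    heavy = [tr for tr in ordered if tr.label == heavy_class]
    if not heavy:
        raise ValueError(
            f"subject {next(iter(subjects))!r} has no {heavy_class!r} lift to renormalize by"
        )
    factor = float(np.max(heavy[0].emg))
    if not factor > 0:
        raise ValueError(f"non-positive renormalization factor {factor}")
    out = []
    for tr in lifts:
        new = copy.copy(tr)
        new.emg = tr.emg / factor
        out.append(new)
    return out, factor
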