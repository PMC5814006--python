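"""Load-onset detection and ±2 s alignment.

Load-onset is the instant the lifted load is fully supported by the subject
(the load leaves the table).  For weighted lifts it is detected from the
vertical force-plate channel: the force sits at table+load weight before the
lift and drops to table-only weight at onset; onset is the first sample at
which the remaining load on the table is within a small fraction (default
5%) of the load weight.  For no-weight lifts the sticks close a contact
circuit whose voltage drops when they are raised; onset is the first
persistent crossing of the level midpoint (10 ms debounce by default).

Every lift is then cropped to the ±2 s region of interest with onset defined
as time zero.  Trials that do not cover the full region raise — no padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignedEnvelope",
    "detect_onset_force",
    "detect_onset_circuit",
    "detect_onset",
    "align",
]


@dataclass
class AlignedEnvelope:
    """Two-channel envelope over t ∈ [−half_window, +half_window] around onset.

    Length is ``2 * round(half_window * fs) + 1``; the onset sample sits at
    the centre index and maps to t = 0.
    """

    left: np.ndarray
    right: np.ndarray
    fs: float
    subject_id: str
    label: str
    lift_index: int = 0
    onset_sample: int = 0          # index of t = 0 within the cropped arrays
    half_window: float = 2.0

    @property
    def t(self) -> np.ndarray:
        n = len(self.left)
        return (np.arange(n) - self.onset_sample) / self.fs


def detect_onset_force(
    force: np.ndarray,
    table_weight: float,
    load_weight: float,
    fraction: float = 0.05,
) -> int:
    """First sample at which the load is (within tolerance) fully off the table.

    Threshold = ``table_weight + fraction * load_weight``; returns the first
    index where the force is at or below it.
    """
    if load_weight <= 0:
        raise ValueError("load_weight must be positive for force-plate detection")
    force = np.asarray(force, dtype=float)
    threshold = table_weight + fraction * load_weight
    below = np.flatnonzero(force <= threshold)
    if below.size == 0:
        raise ValueError(
            f"force never crossed the onset threshold {threshold:g} "
            f"(min observed {force.min():g})"
        )
    return int(below[0])


def detect_onset_circuit(
    voltage: np.ndarray,
    fs: float,
    closed_level: float | None = None,
    open_level: float | None = None,
    debounce: float = 0.010,
) -> int:
    """First persistent crossing of the closed/open midpoint.

    Levels default to the medians of the first and last 5% of the recording.
    Polarity is inferred from the levels, so an inverted circuit (voltage
    rising at onset) behaves symmetrically.  A crossing must hold for the
    debounce window (default 10 ms) to count; set ``debounce=0`` to disable.
    """
    v = np.asarray(voltage, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("voltage trace too short for onset detection")
    edge = max(1, n // 20)
    if closed_level is None:
        closed_level = float(np.median(v[:edge]))
    if open_level is None:
        open_level = float(np.median(v[-edge:]))
    if np.isclose(closed_level, open_level):
        raise ValueError(
            f"no transition: closed level {closed_level:g} equals open level {open_level:g}"
        )
    threshold = 0.5 * (closed_level + open_level)
    beyond = v < threshold if open_level < closed_level else v > threshold
    hold = max(1, int(round(debounce * fs)))
    idx = np.flatnonzero(beyond)
    for i in idx:
        if beyond[i : i + hold].all():
            return int(i)
    raise ValueError(
        f"no persistent crossing of threshold {threshold:g} (debounce {hold} samples)"
    )


def detect_onset(
    trial,
    table_weight: float,
    load_weight: float,
    fraction: float = 0.05,
    debounce: float = 0.010,
) -> int:
    """Dispatch on the trial's event-channel kind."""
    if trial.event_kind == "force":
        return detect_onset_force(trial.event_signal, table_weight, load_weight, fraction)
    return detect_onset_circuit(trial.event_signal, trial.fs, debounce=debounce)


def align(trial, onset_sample: int, half_window: float = 2.0) -> AlignedEnvelope:
    """Crop a two-channel envelope trial to ±``half_window`` s around onset.

    The cropped series holds ``2h + 1`` samples (``h = round(half_window *
    fs)``) with the onset at the centre.  Raises, naming the deficit, if the
    trial does not cover the region; no padding is fabricated.
    """
    h = int(round(half_window * trial.fs))
    n = trial.n_samples
    if onset_sample - h < 0:
        raise ValueError(
            f"trial {trial.subject_id}/{trial.lift_index}: onset at sample "
            f"{onset_sample} leaves only {onset_sample / trial.fs:.3f} s before "
            f"onset; {half_window} s required"
        )
    if onset_sample + h >= n:
        raise ValueError(
            f"trial {trial.subject_id}/{trial.lift_index}: only "
            f"{(n - 1 - onset_sample) / trial.fs:.3f} s after onset; "
            f"{half_window} s required"
        )
    if trial.emg.shape[0] != 2:
        raise ValueError("align expects a two-channel (left, right) envelope trial")
    sl = slice(onset_sample - h, onset_sample + h + 1)
    return AlignedEnvelope(
        left=trial.emg[0, sl].copy(),
        right=trial.emg[1, sl].copy(),
        fs=trial.fs,
        subject_id=trial.subject_id,
        label=trial.label,
        lift_index=trial.lift_index,
        onset_sample=h,
        half_window=half_window,
    )
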