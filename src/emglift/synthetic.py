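"""Synthetic multi-subject lift-trial generator.

Emulates the signal structure of repeated symmetrical floor-to-waist lifts
instrumented with low-back surface EMG: muscle activity rises as the subject
bends toward the load, spikes near the instant the load leaves the table
("load-onset"), and the spike amplitude grows with the lifted load.  Weighted
lifts carry a vertical force-plate channel (table + load weight stepping down
to table-only weight at onset); no-weight lifts carry a contact-circuit
voltage that drops when the sticks leave the charged rails.

Two emission modes:

``envelope``
    Channels are already linear envelopes in fraction-of-MVC units
    (``left-avg``, ``right-avg``) — the form the classification pipeline
    consumes directly.
``raw``
    Four channels (``left-lateral``, ``left-medial``, ``right-medial``,
    ``right-lateral``) of band-limited (20–300 Hz) zero-mean noise amplitude-
    modulated by the same envelope, plus 60 Hz mains interference, so the
    preprocessing filter chain is exercised end to end.

Randomness is drawn from per-trial streams keyed ``(seed, subject, lift)``,
so regenerating any single trial is independent of generation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CLASSES",
    "SimConfig",
    "LiftTrial",
    "generate_dataset",
    "class_mean_envelopes",
]

DEFAULT_CLASSES = ("no-weight", "10-lbs", "24-lbs")

#: Envelope carrier scale: E|x| of a unit-variance Gaussian carrier.
_RECTIFIED_GAUSSIAN_MEAN = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Amplitudes are fractions of the subject's maximum voluntary contraction
    (MVC); times are seconds; the event-channel force unit is pounds.
    """

    n_subjects: int = 9
    lifts_per_class: int = 10
    classes: tuple[str, ...] = DEFAULT_CLASSES
    fs: float = 1200.0
    lift_duration: float = 8.0
    onset_time: float = 4.0
    spike_amplitude_by_class: dict[str, float] = field(
        default_factory=lambda: {"no-weight": 0.15, "10-lbs": 0.45, "24-lbs": 0.70}
    )
    spike_width: float = 0.25          # Gaussian sigma of the onset spike
    baseline_ramp_peak: float = 0.10   # bend-forward activity level at onset
    rest_level: float = 0.02
    subject_gain_sd: float = 0.15      # multiplicative, between subjects
    trial_gain_sd: float = 0.20        # multiplicative, between lifts (log-normal)
    onset_jitter_sd: float = 0.030     # spike centre jitter around true onset (s)
    noise_sd: float = 0.03             # additive envelope noise, fraction of MVC
    left_right_asymmetry: float = 0.10
    # event channels
    table_weight: float = 36.0
    load_weight_by_class: dict[str, float] = field(
        default_factory=lambda: {"no-weight": 0.0, "10-lbs": 10.0, "24-lbs": 24.0}
    )
    force_noise_sd: float = 0.1
    unload_transient: float = 0.08     # post-onset undershoot, fraction of load
    transient_tau: float = 0.05        # undershoot decay constant (s)
    circuit_closed_level: float = 5.0
    circuit_open_level: float = 0.0
    circuit_noise_sd: float = 0.05
    # raw mode
    raw_interference_amp: float = 0.2  # 60 Hz amplitude, fraction of MVC scale
    raw_noise_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.lifts_per_class < 1:
            raise ValueError("lifts_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.lift_duration <= 0:
            raise ValueError("lift_duration must be positive")
        if not 0.0 < self.onset_time < self.lift_duration:
            raise ValueError("onset_time must lie strictly inside the lift")
        amps = [self.spike_amplitude_by_class[c] for c in self.classes]
        if not all(a < b for a, b in zip(amps, amps[1:])):
            raise ValueError(
                "spike amplitudes must strictly increase with load class; got "
                f"{dict(zip(self.classes, amps))}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.lift_duration * self.fs))

    @property
    def true_onset_sample(self) -> int:
        return int(round(self.onset_time * self.fs))


@dataclass
class LiftTrial:
    """One lift by one subject."""

    subject_id: str
    lift_index: int                 # chronological order within the subject
    label: str
    emg: np.ndarray                 # (n_channels, n_samples)
    channel_names: tuple[str, ...]
    event_signal: np.ndarray
    event_kind: Literal["force", "circuit"]
    fs: float
    true_onset_sample: int          # kept for testing only
    mvc_peak: float = 1.0           # raw-mode normalization constant

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.event_signal = np.asarray(self.event_signal, dtype=float)
        if self.emg.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match the EMG channel count")
        if self.emg.shape[1] != self.event_signal.shape[0]:
            raise ValueError("EMG channels and event_signal must share length")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.emg[self.channel_names.index(name)]


def _envelope_base(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Deterministic bend-and-hold activity profile (no spike, no noise)."""
    onset = cfg.onset_time
    ramp = np.clip((t - (onset - 2.5)) / 2.0, 0.0, 1.0)          # rise over bend
    decay = np.clip(((onset + 3.0) - t) / 2.0, 0.0, 1.0)         # relax after lift
    shape = np.minimum(ramp, decay)
    # smoothstep for continuous derivative
    shape = shape * shape * (3.0 - 2.0 * shape)
    return cfg.rest_level + (cfg.baseline_ramp_peak - cfg.rest_level) * shape


def deterministic_envelope(cfg: SimConfig, label: str) -> np.ndarray:
    """Noise-free class template: base profile plus the class-scaled spike."""
    t = np.arange(cfg.n_samples) / cfg.fs
    amp = cfg.spike_amplitude_by_class[label]
    spike = amp * np.exp(-0.5 * ((t - cfg.onset_time) / cfg.spike_width) ** 2)
    return _envelope_base(t, cfg) + spike


def _trial_rng(cfg: SimConfig, subject: int, lift: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, subject, lift])


def _subject_rng(cfg: SimConfig, subject: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, subject])


def _event_signal(
    cfg: SimConfig, label: str, t: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    onset = cfg.onset_time
    if cfg.load_weight_by_class[label] > 0:
        load = cfg.load_weight_by_class[label]
        force = np.full_like(t, cfg.table_weight + load)
        post = t >= onset
        force[post] = cfg.table_weight - (
            cfg.unload_transient * load
            * np.exp(-(t[post] - onset) / cfg.transient_tau)
        )
        if cfg.force_noise_sd > 0:
            force = force + rng.normal(0.0, cfg.force_noise_sd, t.shape)
        return force, "force"
    volt = np.where(t < onset, cfg.circuit_closed_level, cfg.circuit_open_level)
    if cfg.circuit_noise_sd > 0:
        volt = volt + rng.normal(0.0, cfg.circuit_noise_sd, t.shape)
    return volt, "circuit"


def _bandlimited_carrier(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float] = (20.0, 300.0)
) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    white = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, white)
    return x / x.std()


def _make_trial(
    cfg: SimConfig,
    subject: int,
    lift: int,
    label: str,
    subject_gain: float,
    asym: float,
    mode: str,
) -> LiftTrial:
    rng = _trial_rng(cfg, subject, lift)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    trial_gain = float(np.exp(rng.normal(0.0, cfg.trial_gain_sd))) if cfg.trial_gain_sd > 0 else 1.0
    jitter = float(rng.normal(0.0, cfg.onset_jitter_sd)) if cfg.onset_jitter_sd > 0 else 0.0
    amp = cfg.spike_amplitude_by_class[label] * subject_gain * trial_gain
    spike = amp * np.exp(-0.5 * ((t - (cfg.onset_time + jitter)) / cfg.spike_width) ** 2)
    core = _envelope_base(t, cfg) * subject_gain + spike
    left_env = core * (1.0 + asym)
    right_env = core * (1.0 - asym)

    event, kind = _event_signal(cfg, label, t, rng)

    if mode == "envelope":
        emg = np.vstack([left_env, right_env])
        if cfg.noise_sd > 0:
            emg = emg + rng.normal(0.0, cfg.noise_sd, emg.shape)
        emg = np.clip(emg, 0.0, None)
        names = ("left-avg", "right-avg")
        mvc_peak = 1.0
    elif mode == "raw":
        sides = {"left": left_env, "right": right_env}
        chans, names_list = [], []
        for side_name, pos in (("left", ("lateral", "medial")), ("right", ("medial", "lateral"))):
            for p in pos:
                carrier = _bandlimited_carrier(rng, n, cfg.fs)
                x = carrier * sides[side_name] * _RECTIFIED_GAUSSIAN_MEAN
                x = x + cfg.raw_interference_amp * np.sin(2 * np.pi * 60.0 * t)
                if cfg.raw_noise_floor > 0:
                    x = x + rng.normal(0.0, cfg.raw_noise_floor, n)
                chans.append(x)
                names_list.append(f"{side_name}-{p}")
        emg = np.vstack(chans)
        names = tuple(names_list)
        # Linear-envelope extraction of a unit (MVC-level) modulated carrier
        # recovers E|x| * (2/pi)^-1 ... the chain's own gain; the matched
        # normalization constant is the rectified-Gaussian mean squared away:
        mvc_peak = _RECTIFIED_GAUSSIAN_MEAN**2
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'envelope' or 'raw'")

    return LiftTrial(
        subject_id=f"S{subject + 1:02d}",
        lift_index=lift,
        label=label,
        emg=emg,
        channel_names=names,
        event_signal=event,
        event_kind=kind,
        fs=cfg.fs,
        true_onset_sample=cfg.true_onset_sample,
        mvc_peak=mvc_peak,
    )


def generate_dataset(
    config: SimConfig, mode: Literal["envelope", "raw"] = "envelope"
) -> list[LiftTrial]:
    """Generate ``n_subjects × len(classes) × lifts_per_class`` lift trials.

    Lift order within each subject is a random permutation of the class
    labels (each repeated ``lifts_per_class`` times), mirroring a randomized
    lifting protocol; ``lift_index`` records the chronological order, which
    the per-subject renormalization step depends on.
    """
    if mode not in ("envelope", "raw"):
        raise ValueError(f"unknown mode {mode!r}; expected 'envelope' or 'raw'")
    trials: list[LiftTrial] = []
    for s in range(config.n_subjects):
        srng = _subject_rng(config, s)
        gain = float(np.exp(srng.normal(0.0, config.subject_gain_sd))) if config.subject_gain_sd > 0 else 1.0
        asym = float(srng.normal(0.0, config.left_right_asymmetry)) if config.left_right_asymmetry > 0 else 0.0
        labels = np.repeat(config.classes, config.lifts_per_class)
        labels = labels[srng.permutation(labels.size)]
        for j, label in enumerate(labels):
            trials.append(_make_trial(config, s, j, str(label), gain, asym, mode))
    return trials


def class_mean_envelopes(
    trials: Sequence[LiftTrial],
    half_window: float = 2.0,
    classes: Sequence[str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-class pointwise mean ± SD envelope, aligned on the true onset.

    Uses the first EMG channel (the left envelope in envelope mode).  Returns
    ``{label: {"t": ..., "mean": ..., "sd": ...}}`` over ±``half_window`` s
    around onset.  Raises if any requested class has no trials.
    """
    if classes is None:
        classes = list(dict.fromkeys(tr.label for tr in trials))
    out: dict[str, dict[str, np.ndarray]] = {}
    for label in classes:
        members = [tr for tr in trials if tr.label == label]
        if not members:
            raise ValueError(f"no trials for class {label!r}")
        stacks = []
        for tr in members:
            h = int(round(half_window * tr.fs))
            lo, hi = tr.true_onset_sample - h, tr.true_onset_sample + h + 1
            if lo < 0 or hi > tr.n_samples:
                raise ValueError(
                    f"trial {tr.subject_id}/{tr.lift_index} too short for ±{half_window} s window"
                )
            stacks.append(tr.emg[0, lo:hi])
        arr = np.vstack(stacks)
        fs = members[0].fs
        h = int(round(half_window * fs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        out[label] = {
            "t": np.arange(-h, h + 1) / fs,
            "mean": arr.mean(axis=0),
            "sd": sd,
        }
    return out


def noiseless(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with every stochastic source switched off."""
    return replace(
        config,
        subject_gain_sd=0.0,
        trial_gain_sd=0.0,
        onset_jitter_sd=0.0,
        noise_sd=0.0,
        force_noise_sd=0.0,
        circuit_noise_sd=0.0,
        left_right_asymmetry=0.0,
        raw_noise_floor=0.0,
    )
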