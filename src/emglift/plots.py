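"""Optional figure helpers mirroring the standard result surfaces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_class_means(envelopes: dict, path) -> Path:
    """Per-class mean ± SD envelope around onset (left channel)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, d in envelopes.items():
        ax.plot(d["t"], d["mean"], label=label)
        ax.fill_between(d["t"], d["mean"] - d["sd"], d["mean"] + d["sd"], alpha=0.2)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("time from load-onset (s)")
    ax.set_ylabel("envelope (norm. %MVC)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_accuracy_curve(report, path) -> Path:
    """Mean ± SD test and validation accuracy over the lift cycle."""
    c = report.accuracy_curves()
    fig, ax = plt.subplots(figsize=(6, 4))
    for key, label in (("test", "testing"), ("val", "validation")):
        m, s = c[f"{key}_mean"], c[f"{key}_sd"]
        ax.plot(c["centers_ms"], m, label=label)
        ax.fill_between(c["centers_ms"], m - s, m + s, alpha=0.2)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.axhline(100.0 / len(report.classes), color="grey", lw=0.8, ls=":", label="chance")
    ax.set_xlabel("window centre, time from load-onset (ms)")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_feature_frequency(freq: dict, path) -> Path:
    """Selection percentage per feature across all optimal sets."""
    sel = freq["selection_pct"]
    fig, ax = plt.subplots(figsize=(7, 4))
    names = list(sel)
    ax.bar(range(len(names)), [sel[n] for n in names])
    ax.set_xticks(range(len(names)), names, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("% of optimal sets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
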