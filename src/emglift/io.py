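"""Plain-text dataset persistence, report bundles and the supplementary
envelope-table reader.

Trials are stored one delimited table per lift (columns: time, EMG
channels, event) next to a tab-separated manifest and a small JSON metadata
file, at full float precision so write→read round-trips are exact.  The
deposited supplementary envelope archive (average left/right linear
envelopes per lift for every subject and loading condition) is read through
one adapter expecting a long-format delimited table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_CLASSES, LiftTrial

__all__ = [
    "write_trials",
    "read_trials",
    "read_s1_envelopes",
    "write_report",
    "read_report_summary",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def write_trials(trials, outdir) -> Path:
    """Write a dataset as per-trial TSV tables plus manifest and metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        fname = f"{tr.subject_id}_lift{tr.lift_index:03d}.tsv"
        t = np.arange(tr.n_samples) / tr.fs
        data = np.column_stack([t, tr.emg.T, tr.event_signal])
        header = "\t".join(["time", *tr.channel_names, "event"])
        np.savetxt(outdir / fname, data, fmt=_FLOAT_FMT, delimiter="\t",
                   header=header, comments="")
        rows.append(
            {
                "subject": tr.subject_id,
                "lift_index": tr.lift_index,
                "label": tr.label,
                "event_kind": tr.event_kind,
                "fs": tr.fs,
                "true_onset_sample": tr.true_onset_sample,
                "mvc_peak": tr.mvc_peak,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    classes = sorted({tr.label for tr in trials}, key=lambda c: (c not in DEFAULT_CLASSES, c))
    (outdir / "meta.json").write_text(
        json.dumps({"n_trials": len(trials), "classes": classes}, indent=1)
    )
    return outdir


def read_trials(path) -> list[LiftTrial]:
    """Read a dataset written by :func:`write_trials`; validates as it goes."""
    path = Path(path)
    manifest_path = path / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.tsv under {path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    meta = json.loads((path / "meta.json").read_text()) if (path / "meta.json").exists() else {}
    known = set(meta.get("classes", DEFAULT_CLASSES))
    trials = []
    for row in manifest.itertuples(index=False):
        f = path / row.file
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file {f}")
        if row.label not in known:
            raise ValueError(f"unknown class label {row.label!r} in manifest (known: {sorted(known)})")
        table = pd.read_csv(f, sep="\t", float_precision="round_trip")
        if table.isna().any().any():
            bad = np.argwhere(table.isna().to_numpy())
            r, c = bad[0]
            raise ValueError(
                f"{f.name}: {len(bad)} NaN sample(s); first at row {r}, "
                f"column {table.columns[c]!r}"
            )
        cols = list(table.columns)
        if cols[0] != "time" or cols[-1] != "event" or len(cols) < 3:
            raise ValueError(f"{f.name}: unexpected columns {cols}")
        chan_names = tuple(cols[1:-1])
        trials.append(
            LiftTrial(
                subject_id=row.subject,
                lift_index=int(row.lift_index),
                label=row.label,
                emg=table[list(chan_names)].to_numpy().T,
                channel_names=chan_names,
                event_signal=table["event"].to_numpy(),
                event_kind=row.event_kind,
                fs=float(row.fs),
                true_onset_sample=int(row.true_onset_sample),
                mvc_peak=float(row.mvc_peak),
            )
        )
    return trials


_S1_COLUMN_ALIASES = {
    "subject": {"subject", "subject_id", "subj", "participant"},
    "lift": {"lift", "lift_index", "trial", "rep"},
    "label": {"label", "class", "weight", "condition", "load"},
    "time": {"time", "t", "time_s"},
    "left": {"left", "left_avg", "left-avg", "l"},
    "right": {"right", "right_avg", "right-avg", "r"},
}


def read_s1_envelopes(path, mode: str = "as-is", fs: float = 1200.0) -> list[LiftTrial]:
    """Read a deposited average-envelope table into envelope-mode trials.

    Expects a long-format delimited table with (at least) subject, lift,
    class-label, time, left and right columns (several common spellings are
    accepted).  A lift missing one side is flagged with a warning and the
    surviving side's envelope is used for both channels, mirroring the
    faulty-channel handling of the acquisition protocol.  ``mode``:

    - ``"as-is"``: envelopes are taken as already normalized;
    - ``"normalize"``: per-subject renormalization by the first 24-lbs
      lift's maximum is applied.
    """
    from .preprocessing import renormalize_subject

    if mode not in ("as-is", "normalize"):
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if table.empty:
        raise ValueError(f"{path}: empty envelope archive")
    colmap = {}
    lower = {c.lower().strip(): c for c in table.columns}
    for want, aliases in _S1_COLUMN_ALIASES.items():
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is not None:
            colmap[want] = hit
    required = {"subject", "lift", "label", "left"}
    if not required <= set(colmap):
        raise ValueError(
            "unrecognized envelope-archive layout; need columns for "
            f"{sorted(required)} (plus optional time/right). Found columns: "
            f"{list(table.columns)}"
        )
    trials = []
    for (subj, lift, label), g in table.groupby(
        [colmap["subject"], colmap["lift"], colmap["label"]], sort=True
    ):
        if "time" in colmap:
            g = g.sort_values(colmap["time"])
        left = g[colmap["left"]].to_numpy(dtype=float)
        if "right" in colmap and not g[colmap["right"]].isna().all():
            right = g[colmap["right"]].to_numpy(dtype=float)
        else:
            log.warning(
                "lift %s/%s (%s): right channel missing; using left verbatim",
                subj, lift, label,
            )
            right = left.copy()
        n = left.size
        trials.append(
            LiftTrial(
                subject_id=str(subj),
                lift_index=int(lift),
                label=str(label),
                emg=np.vstack([left, right]),
                channel_names=("left-avg", "right-avg"),
                event_signal=np.zeros(n),
                event_kind="circuit",
                fs=fs,
                true_onset_sample=n // 2,  # archive envelopes are onset-centred
            )
        )
    if mode == "normalize":
        out = []
        for s in dict.fromkeys(tr.subject_id for tr in trials):
            subject_trials = [tr for tr in trials if tr.subject_id == s]
            renorm, _ = renormalize_subject(subject_trials)
            out.extend(renorm)
        trials = out
    return trials


def _config_hash(config) -> str:
    import dataclasses

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(map(str, o)) if isinstance(o, (frozenset, set)) else list(o)
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(report, outdir, seed=None) -> Path:
    """Write an evaluation report as a bundle of delimited tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves = report.accuracy_curves()
    pd.DataFrame(
        {
            "center_ms": curves["centers_ms"],
            "test_mean_pct": curves["test_mean"],
            "test_sd_pct": curves["test_sd"],
            "val_mean_pct": curves["val_mean"],
            "val_sd_pct": curves["val_sd"],
        }
    ).to_csv(outdir / "accuracy_curve.tsv", sep="\t", index=False)

    rc = report.recall_curves()
    rec = pd.DataFrame(rc["mean"], columns=[f"recall_{c}_pct" for c in report.classes])
    rec.insert(0, "center_ms", rc["centers_ms"])
    rec.to_csv(outdir / "recall_curves.tsv", sep="\t", index=False)

    pre_w, post_w = report.optimal_windows()
    for tag, w in (("pre", pre_w), ("post", post_w)):
        mean, sd = report.confusion_at(w)
        df = pd.DataFrame(mean, index=report.classes, columns=report.classes)
        df.to_csv(outdir / f"confusion_{tag}_mean.tsv", sep="\t")
        pd.DataFrame(sd, index=report.classes, columns=report.classes).to_csv(
            outdir / f"confusion_{tag}_sd.tsv", sep="\t"
        )

    from .evaluation import feature_frequency

    freq = feature_frequency(report.optimal_sets)
    pd.DataFrame(
        sorted(freq["selection_pct"].items()), columns=["feature", "selected_pct"]
    ).to_csv(outdir / "feature_frequency.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(freq["set_size_pct"].items()), columns=["set_size", "share_pct"]
    ).to_csv(outdir / "set_sizes.tsv", sep="\t", index=False)

    report.per_subject_recall().to_csv(outdir / "per_subject_recall.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "window": s.window_index,
                "test_subject": s.test_subject,
                "features": "|".join(s.features),
                "val_accuracy_pct": 100.0 * s.validation_accuracy,
            }
            for s in report.optimal_sets
        ]
    ).to_csv(outdir / "optimal_sets.tsv", sep="\t", index=False)

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(report.config),
        "n_windows": report.grid.n_windows,
        "n_subjects": len(report.subject_ids),
        "n_optimal_sets": len(report.optimal_sets),
        "optimal_windows": {"pre": pre_w, "post": post_w},
        "curve_agreement": report.curve_agreement(),
        "audit": {"passed": report.audit_passed, "checks": report.audit_checks},
        "fold_plan": {
            "subjects": list(report.subject_ids),
            "outer_folds": len(report.fold_plan.outer) if report.fold_plan else None,
            "inner_folds": report.fold_plan.n_inner if report.fold_plan else None,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_report_summary(rundir) -> dict:
    rundir = Path(rundir)
    manifest = json.loads((rundir / "manifest.json").read_text())
    curve = pd.read_csv(rundir / "accuracy_curve.tsv", sep="\t")
    peak = curve.loc[curve["test_mean_pct"].idxmax()]
    manifest["peak_test_accuracy_pct"] = float(peak["test_mean_pct"])
    manifest["peak_window_center_ms"] = float(peak["center_ms"])
    return manifest
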