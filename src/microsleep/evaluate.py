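"""Whole-recording inference and chance-corrected agreement evaluation.

Inference slides the trained network across a conditioned recording and
assigns the predicted class to the center sample of each window; samples
between strided centers, and the half-window edges, inherit the nearest
computed center so the output track always has the recording's length.

Agreement with the expert scoring is measured with Cohen's kappa, computed
one-vs-rest per class on the per-sample label tracks.  Recordings are
concatenated before computing kappa (some recordings lack entire classes,
so per-recording kappas are undefined); the degenerate case where both
tracks are constant and identical — chance agreement probability 1 —
returns kappa 0 with a flag, the convention that makes an all-wake
recording scored perfectly count as "no evidence" rather than failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, SizeError
from .io import EventList, Recording
from .labels import TRACK_CLASSES, Label
from .preprocess import LabelTrack, extract_runs, scale_cnn, scale_lstm
from .windowing import valid_centers

__all__ = [
    "PredictionTrack",
    "EvalReport",
    "KappaResult",
    "predict_sliding",
    "majority_coarsen",
    "apply_duration_criteria",
    "cohen_kappa",
    "per_class_kappa",
    "pooled_evaluation",
    "write_label_track",
    "read_label_track",
]


def write_label_track(labels: np.ndarray, fs: int, path) -> None:
    """One label name per line, preceded by a ``# fs=<rate>`` header."""
    names = [Label(int(x)).name for x in np.asarray(labels).ravel()]
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        fh.write("\n".join(names) + "\n")


def read_label_track(path) -> LabelTrack:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise DataError(f"{path}: missing '# fs=' header")
        fs = int(header.split("=", 1)[1])
        labels = [int(Label[line.strip()]) for line in fh if line.strip()]
    return LabelTrack(labels=np.asarray(labels, dtype=np.int64), fs=fs)


@dataclass
class PredictionTrack:
    """Per-sample class probabilities and argmax labels for one recording."""

    probs: np.ndarray        # (n_samples, n_classes), rows sum to 1
    labels: np.ndarray       # (n_samples,) argmax, lowest class index on ties
    stride_used: int
    fs: int

    def __len__(self) -> int:
        return len(self.labels)

    def to_events(self, min_s: float = 1.0, max_s: float = 15.0) -> EventList:
        """Detected episodes: run extraction plus the MSE duration criteria."""
        runs = extract_runs(LabelTrack(labels=self.labels, fs=self.fs))
        return apply_duration_criteria(runs, min_s=min_s, max_s=max_s)


@dataclass(frozen=True)
class KappaResult:
    value: float
    degenerate: bool


@dataclass
class EvalReport:
    """Per-class agreement over (concatenated) recordings."""

    per_class_kappa: dict[str, float]
    degenerate_flags: dict[str, bool]
    confusion: np.ndarray                  # (K, K), rows = reference
    n_samples: int
    note: str = (
        "kappa computed on recordings concatenated across subjects; "
        "per-recording error bars are unavailable by construction"
    )

    def to_dict(self) -> dict:
        return {
            "per_class_kappa": self.per_class_kappa,
            "degenerate_flags": self.degenerate_flags,
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
            "note": self.note,
        }


def _nearest_fill(values: np.ndarray, centers: np.ndarray, n: int) -> np.ndarray:
    """Assign every sample 0..n−1 the value of its nearest center."""
    pos = np.arange(n)
    right = np.searchsorted(centers, pos)
    right = np.clip(right, 0, len(centers) - 1)
    left = np.clip(right - 1, 0, len(centers) - 1)
    pick_left = np.abs(pos - centers[left]) <= np.abs(centers[right] - pos)
    idx = np.where(pick_left, left, right)
    return values[idx]


def predict_sliding(
    model,
    recording: Recording,
    stride: int = 1,
    channels: Sequence[str] | None = None,
    batch_size: int = 512,
) -> PredictionTrack:
    """Per-sample prediction over a whole conditioned recording.

    The recording must already be bandpass-filtered; amplitude scaling
    (÷100 → [−1,1] for CNNs, (x+100)/200 → [0,1] for the CNN-LSTM) is
    applied here according to the model kind.  ``channels`` selects and
    orders the input channels (default: the first ``in_channels`` of the
    recording; evaluation conventionally uses O1M2, E1M1, E2M1).

    For a CNN, a prediction is computed at every ``stride``-th valid window
    center and spread to neighbouring samples by nearest-center assignment;
    the CNN-LSTM's native 0.25 s grid is expanded the same way, so the
    output always has one row per recording sample.
    """
    if stride < 1:
        raise DataError("stride must be ≥ 1")
    if channels is None:
        data = recording.data[: model.spec.in_channels]
    else:
        data = np.vstack([recording.channel(c) for c in channels])
    if data.shape[0] != model.spec.in_channels:
        raise DataError(
            f"model expects {model.spec.in_channels} channels, got {data.shape[0]}"
        )
    n = data.shape[1]
    L = model.window_samples
    if n < L:
        raise SizeError(f"recording of {n} samples shorter than the {L}-sample window")

    if model.kind == "cnn":
        data = scale_cnn(data)
        centers = valid_centers(n, L, stride)
        probs = np.empty((len(centers), model.n_classes))
        start0 = centers - L // 2
        for lo in range(0, len(centers), batch_size):
            sel = start0[lo : lo + batch_size]
            batch = np.stack([data[:, s : s + L] for s in sel])
            probs[lo : lo + len(sel)] = model.predict(batch)
        stride_used = stride
    else:
        data = scale_lstm(data)
        centers, probs = model.predict_windows(data)
        stride_used = model.spec.cnn_stride

    full_probs = _nearest_fill(probs, centers, n)
    labels = np.argmax(full_probs, axis=1).astype(np.int64)  # ties → lowest index
    return PredictionTrack(
        probs=full_probs, labels=labels, stride_used=stride_used, fs=recording.fs
    )


def majority_coarsen(labels: np.ndarray, interval: int) -> np.ndarray:
    """Replace each consecutive interval by its most frequent label.

    Ties take the previous interval's (coarsened) label when one exists,
    otherwise wake.  Constant input is returned unchanged; the operation is
    idempotent at a fixed interval.
    """
    if interval < 1:
        raise DataError("interval must be ≥ 1")
    labels = np.asarray(labels, dtype=np.int64)
    out = np.empty_like(labels)
    prev: int | None = None
    for lo in range(0, len(labels), interval):
        chunk = labels[lo : lo + interval]
        counts = np.bincount(chunk)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        lab = int(tied[0]) if len(tied) == 1 else (prev if prev is not None else int(Label.W))
        out[lo : lo + interval] = lab
        prev = lab
    return out


def apply_duration_criteria(
    events: EventList, min_s: float = 1.0, max_s: float = 15.0
) -> EventList:
    """Enforce the 1–15 s microsleep definition post hoc.

    MSE episodes shorter than ``min_s`` are dropped (treated as wake);
    longer than ``max_s`` are relabeled SLEEP.  Other labels pass through.
    """
    from .io import Event

    out = []
    for ev in events:
        if ev.label is Label.MSE:
            if ev.duration_s < min_s:
                continue
            if ev.duration_s > max_s:
                ev = Event(start_s=ev.start_s, end_s=ev.end_s, label=Label.SLEEP)
        out.append(ev)
    return EventList(events=out, total_duration_s=events.total_duration_s)


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> KappaResult:
    """Cohen's kappa from the contingency table of two label sequences.

    κ = (p_o − p_e) / (1 − p_e).  When p_e = 1 — both sequences constant
    and identical, so chance "explains" everything — returns 0 with the
    degenerate flag set instead of 0/0.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DataError("empty sequences")
    k = int(max(a.max(), b.max())) + 1
    table = np.zeros((k, k))
    np.add.at(table, (a, b), 1.0)
    n = a.size
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-12:
        return KappaResult(value=0.0, degenerate=True)
    return KappaResult(value=float((p_o - p_e) / (1.0 - p_e)), degenerate=False)


def per_class_kappa(
    a: np.ndarray,
    b: np.ndarray,
    classes: Sequence[Label] = TRACK_CLASSES,
) -> dict[Label, KappaResult]:
    """One-vs-rest kappa per class: binarize (class k → 1, rest → 0), then κ."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    return {
        cls: cohen_kappa((a == int(cls)).astype(np.int64),
                         (b == int(cls)).astype(np.int64))
        for cls in classes
    }


def pooled_evaluation(
    pred_tracks: Mapping[str, np.ndarray],
    ref_tracks: Mapping[str, np.ndarray],
    classes: Sequence[Label] = TRACK_CLASSES,
) -> EvalReport:
    """Concatenate recordings (sorted by id) and evaluate per-class kappa."""
    if set(pred_tracks) != set(ref_tracks):
        raise DataError(
            f"recording ids differ: {sorted(pred_tracks)} vs {sorted(ref_tracks)}"
        )
    order = sorted(pred_tracks)
    for rid in order:
        if len(pred_tracks[rid]) != len(ref_tracks[rid]):
            raise DataError(f"length mismatch for recording {rid!r}")
    pred = np.concatenate([np.asarray(pred_tracks[r]).ravel() for r in order])
    ref = np.concatenate([np.asarray(ref_tracks[r]).ravel() for r in order])
    kappas = per_class_kappa(ref, pred, classes)
    K = len(classes)
    confusion = np.zeros((K, K), dtype=np.int64)
    np.add.at(confusion, (ref, pred), 1)
    return EvalReport(
        per_class_kappa={cls.name: res.value for cls, res in kappas.items()},
        degenerate_flags={cls.name: res.degenerate for cls, res in kappas.items()},
        confusion=confusion,
        n_samples=int(ref.size),
    )
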