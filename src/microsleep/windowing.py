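"""Center-labeled sliding-window frames and training batches.

Each training example ("frame") is one window of the multichannel signal
labeled with the class of its *central* sample — not the window majority —
so the classifier learns the state at a single point with symmetric
context.  An even-length window has no exact center; the convention here
is that a window of length L starting at sample s has its center at
s + floor(L/2).

Training-set augmentation follows the clinical montage: each frame draws
its EEG channel at random from the two occipital derivations (O1M2/O2M1),
which roughly doubles the effective training set; the two EOG channels are
always included as-is (unless the single-EEG-channel configuration is
chosen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import DataError, SizeError
from .io import Recording
from .labels import TRACK_CLASSES
from .preprocess import LabelTrack, scale_cnn, scale_lstm

__all__ = [
    "SamplerConfig",
    "Frame",
    "Batch",
    "valid_centers",
    "make_frame",
    "sample_batches",
    "class_weights",
    "SUPPORTED_WINDOWS_S",
]

#: Sliding-window lengths the architecture family supports, in seconds.
SUPPORTED_WINDOWS_S: tuple[int, ...] = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class SamplerConfig:
    """How frames are cut and batched from recordings."""

    window_s: int = 16
    stride: int = 1              # frame subsampling for desk-scale training
    batch_size: int = 200        # 200 for CNNs, 128 for the CNN-LSTM
    seed: int = 0
    eeg_channels: tuple[str, ...] = ("O1M2", "O2M1")  # drawn at random per frame
    eog_channels: tuple[str, ...] = ("E1M1", "E2M1")  # () for single-channel mode
    scaling: str = "cnn"         # "cnn" → [-1,1]; "lstm" → [0,1]

    def __post_init__(self) -> None:
        if self.window_s not in SUPPORTED_WINDOWS_S:
            raise DataError(
                f"window_s must be one of {SUPPORTED_WINDOWS_S}, got {self.window_s}"
            )
        if self.batch_size <= 0 or self.stride <= 0:
            raise DataError("batch_size and stride must be positive")
        if not self.eeg_channels:
            raise DataError("need at least one EEG channel")
        if self.scaling not in ("cnn", "lstm"):
            raise DataError(f"scaling must be 'cnn' or 'lstm', got {self.scaling!r}")

    @property
    def n_channels(self) -> int:
        return 1 + len(self.eog_channels)

    def window_samples(self, fs: int) -> int:
        return self.window_s * fs

    def scale(self, x: np.ndarray) -> np.ndarray:
        return scale_cnn(x) if self.scaling == "cnn" else scale_lstm(x)


@dataclass
class Frame:
    """One training example: scaled window + label of its central sample."""

    x: np.ndarray          # (channels, window_samples)
    y: int
    center_idx: int
    source_id: str


@dataclass
class Batch:
    x: np.ndarray          # (batch, channels, window_samples)
    y: np.ndarray          # (batch,)
    centers: np.ndarray    # (batch,) sample index of each frame center
    sources: np.ndarray    # (batch,) index into the frame-source list


def valid_centers(n_samples: int, window_samples: int, stride: int = 1) -> np.ndarray:
    """Sample indices that can be the center of a full window.

    A center c is valid when c − floor(L/2) ≥ 0 and c + ceil(L/2) ≤ n;
    centers are stepped by ``stride`` from the first valid one.
    """
    L = window_samples
    if L > n_samples:
        raise SizeError(f"window of {L} samples exceeds recording of {n_samples}")
    first = L // 2
    last = n_samples - (L - L // 2)  # n - ceil(L/2)
    return np.arange(first, last + 1, stride)


def _window_rows(
    recording: Recording, center: int, window_samples: int, cfg: SamplerConfig,
    eeg_name: str,
) -> np.ndarray:
    start = center - window_samples // 2
    stop = start + window_samples
    if start < 0 or stop > recording.n_samples:
        raise SizeError(f"center {center} does not admit a full window")
    rows = [recording.channel(eeg_name)[start:stop]]
    rows += [recording.channel(name)[start:stop] for name in cfg.eog_channels]
    return cfg.scale(np.vstack(rows))


def make_frame(
    recording: Recording,
    track: LabelTrack,
    center: int,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> Frame:
    """Cut one frame; the EEG derivation is drawn at random from the pair."""
    if len(track) != recording.n_samples:
        raise DataError("label track length does not match the recording")
    eeg = cfg.eeg_channels[rng.integers(len(cfg.eeg_channels))]
    x = _window_rows(recording, center, cfg.window_samples(recording.fs), cfg, eeg)
    return Frame(x=x, y=int(track.labels[center]), center_idx=center,
                 source_id=recording.id)


def sample_batches(
    frames_source: Sequence[tuple[Recording, LabelTrack]],
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> Iterator[Batch]:
    """One training iteration: every (strided) center exactly once, shuffled.

    Frames are pooled over all recordings, visited in a seeded random
    permutation, and emitted in batches of ``cfg.batch_size`` (the final
    batch may be smaller).  No center is emitted twice within the
    iteration.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pairs = []
    for si, (rec, track) in enumerate(frames_source):
        if len(track) != rec.n_samples:
            raise DataError(f"track/recording length mismatch for {rec.id!r}")
        L = cfg.window_samples(rec.fs)
        for c in valid_centers(rec.n_samples, L, cfg.stride):
            pairs.append((si, c))
    if len(pairs) < cfg.batch_size:
        raise DataError(
            f"only {len(pairs)} frames available for batch size {cfg.batch_size}"
        )
    order = rng.permutation(len(pairs))
    for lo in range(0, len(order), cfg.batch_size):
        chunk = [pairs[i] for i in order[lo : lo + cfg.batch_size]]
        xs, ys, centers, sources = [], [], [], []
        for si, c in chunk:
            rec, track = frames_source[si]
            frame = make_frame(rec, track, int(c), cfg, rng)
            xs.append(frame.x)
            ys.append(frame.y)
            centers.append(frame.center_idx)
            sources.append(si)
        yield Batch(
            x=np.stack(xs),
            y=np.asarray(ys, dtype=np.int64),
            centers=np.asarray(centers, dtype=np.int64),
            sources=np.asarray(sources, dtype=np.int64),
        )


def class_weights(
    labels: np.ndarray, n_classes: int = len(TRACK_CLASSES), uniform: bool = False
) -> np.ndarray:
    """Per-class loss weights, inversely proportional to class frequency.

    Weights are normalized to mean 1 over the classes actually present;
    absent classes get weight 0 (with a warning).  ``uniform=True`` gives
    every present class weight 1 — the ablation that tests whether the
    class imbalance (wake vastly outnumbers microsleep) matters.
    """
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise DataError("empty label pool")
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    if not present.all():
        absent = [c for c, p in zip(range(n_classes), present) if not p]
        warnings.warn(f"classes {absent} absent from the training pool; weight 0")
    w = np.zeros(n_classes)
    if uniform:
        w[present] = 1.0
        return w
    freqs = counts[present] / counts.sum()
    raw = 1.0 / freqs
    w[present] = raw / raw.mean()
    return w
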