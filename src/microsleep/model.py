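"""CNN and CNN-LSTM architectures for per-sample wake/microsleep scoring.

The CNN family is a stack of convolutional blocks — convolution (N filters
of length 3, stride 1) → batch normalization → ReLU → max-pooling (size 2)
— applied to a window of raw (conditioned, scaled) signal, ending in
flatten → dropout → dense → softmax over the four classes.  Convolutions
are unpadded ("valid"), so each block maps a temporal length L to
floor((L−2)/2).

Depth follows the window: the final block is repeated once more for every
doubling of the window length (3 repetitions at 2 s up to 7 at 32 s), on
top of four fixed leading blocks whose filter counts follow the ladder
8 → 16 → 32 → 64.  With this stack every supported window (2–32 s at
200 Hz) collapses to a temporal extent of exactly 1 after the last
pooling — the receptive field of the last layer covers the whole window —
e.g. 400 → 199 → 98 → 48 → 23 → 10 → 4 → 1 for the 2 s window.

The CNN-LSTM variant runs a 1 s CNN over overlapping windows strided by
50 samples (0.25 s) and feeds the resulting 64-d feature sequence to an
LSTM that labels every window (2 classes by default: MSE vs everything
else); the label belongs to the center of the corresponding CNN window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, SizeError, TrainingError
from .nn import (
    LSTM,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GaussianNoise,
    MaxPool1d,
    Nadam,
    ReLU,
    Sequential,
    Softmax,
    clip_by_global_norm,
    weighted_cross_entropy,
)
from .windowing import SUPPORTED_WINDOWS_S

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "N_FIXED_BLOCKS",
    "n_repeated_blocks",
    "block_filters",
    "build_cnn",
    "build_cnn_lstm",
    "build_model",
    "MicrosleepCNN",
    "MicrosleepCnnLstm",
    "train",
    "save_model",
    "load_model",
]

#: Leading convolutional blocks present for every window length; the
#: window-dependent repetitions come on top of these.
N_FIXED_BLOCKS = 4


def n_repeated_blocks(window_s: int) -> int:
    """Repetitions of the final convolutional block for a window length.

    One extra repetition per doubling of the window, anchored at 3 for the
    shortest supported window (2 s): 2 s → 3, 4 s → 4, 8 s → 5, 16 s → 6,
    32 s → 7.
    """
    if window_s not in SUPPORTED_WINDOWS_S:
        raise ConfigurationError(
            f"unsupported window {window_s} s; supported: {SUPPORTED_WINDOWS_S}"
        )
    return 3 + int(round(np.log2(window_s / 2)))


def block_filters(n_blocks: int, ladder: Sequence[int]) -> list[int]:
    """Filter count per block: climb the ladder, then stay at its cap."""
    return [ladder[min(i, len(ladder) - 1)] for i in range(n_blocks)]


@dataclass
class ModelSpec:
    """Declarative description of a network, serializable to JSON/YAML."""

    kind: str = "cnn"                      # "cnn" | "cnn_lstm"
    window_s: int = 16                     # CNN sliding-window length
    fs: int = 200
    in_channels: int = 3                   # 1 EEG (+ 2 EOG unless single-channel)
    n_classes: int = 4                     # CNN default; CNN-LSTM default is 2
    filter_ladder: tuple[int, ...] = (8, 16, 32, 64)
    dense_units: int = 64
    dropout: float = 0.5
    noise_sd: float = 0.0005
    feature_layer: bool = False            # extra 64-filter conv for visualization
    # CNN-LSTM specifics
    lstm_units: int = 128
    cnn_window_s: int = 1                  # window of the per-step CNN
    cnn_stride: int = 50                   # 0.25 s at 200 Hz
    seq_len: int = 32                      # windows per training sequence

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "cnn_lstm"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.in_channels < 1:
            raise ConfigurationError("need at least one input channel")
        if self.kind == "cnn":
            n_repeated_blocks(self.window_s)  # raises on unsupported windows

    @property
    def window_samples(self) -> int:
        w = self.window_s if self.kind == "cnn" else self.cnn_window_s
        return int(w * self.fs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["filter_ladder"] = tuple(d.get("filter_ladder", (8, 16, 32, 64)))
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings (Nadam with Nesterov momentum throughout)."""

    learning_rate: float = 0.002
    iterations: int = 3                    # 3 for CNNs, 8 for the CNN-LSTM
    grad_clip_norm: float | None = None    # 1.0 for the CNN-LSTM
    class_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.iterations < 1:
            raise ConfigurationError("learning_rate ≥ 0 and iterations ≥ 1 required")


def _conv_blocks(
    in_channels: int,
    n_blocks: int,
    ladder: Sequence[int],
    rng: np.random.Generator,
    length: int,
) -> tuple[list, list[int], int]:
    """Build the block stack, tracking the temporal extent symbolically."""
    layers: list = []
    lengths: list[int] = []
    ch = in_channels
    for filt in block_filters(n_blocks, ladder):
        conv = Conv1d(ch, filt, rng)
        pool = MaxPool1d(2)
        length = pool.out_length(conv.out_length(length))
        if length < 1:
            raise ConfigurationError(
                f"window too short: temporal extent vanished after "
                f"{len(lengths) + 1} blocks"
            )
        layers += [conv, BatchNorm1d(filt), ReLU(), pool]
        lengths.append(length)
        ch = filt
    return layers, lengths, ch


class MicrosleepCNN:
    """Sliding-window CNN predicting the class of the window's center sample."""

    kind = "cnn"

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        if spec.kind != "cnn":
            raise ConfigurationError("spec.kind must be 'cnn'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.window_samples
        layers: list = [GaussianNoise(spec.noise_sd, rng)]
        blocks, lengths, ch = _conv_blocks(
            spec.in_channels, N_FIXED_BLOCKS + n_repeated_blocks(spec.window_s),
            spec.filter_ladder, rng, L,
        )
        layers += blocks
        self.block_output_lengths = lengths
        self.feature_index: int | None = None
        if spec.feature_layer:
            # Appended 64-filter conv (kernel 3, same-padded) whose output is
            # the 64-d internal feature vector used for visualization.
            layers += [Conv1d(ch, 64, rng, padding="same"), BatchNorm1d(64), ReLU()]
            ch = 64
            self.feature_index = len(layers)  # features = output of this ReLU
        flat = lengths[-1] * ch
        layers += [
            Flatten(),
            Dropout(spec.dropout, rng),
            Dense(flat, spec.dense_units, rng),
            ReLU(),
            Dense(spec.dense_units, spec.n_classes, rng),
            Softmax(),
        ]
        self.net = Sequential(layers)

    # training/inference surface -------------------------------------------
    @property
    def window_samples(self) -> int:
        return self.spec.window_samples

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def final_temporal_extent(self) -> int:
        """Temporal size after the last pooling block (symbolic propagation)."""
        return self.block_output_lengths[-1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a (batch, channels, window) array."""
        return self.net.forward(np.asarray(x, dtype=float), train=False)

    def forward_train(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x, train=True)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        self.net.backward_from_logits(dlogits)

    def parameters(self):
        return self.net.parameters()

    def gradients(self):
        return self.net.gradients()

    def features(self, x: np.ndarray) -> np.ndarray:
        """64-d feature vectors from the appended convolutional layer."""
        if self.feature_index is None:
            raise ConfigurationError(
                "model was built without the extra 64-filter feature layer "
                "(set ModelSpec.feature_layer=True)"
            )
        h = np.asarray(x, dtype=float)
        for layer in self.net.layers[: self.feature_index]:
            h = layer.forward(h, train=False)
        return h.reshape(h.shape[0], -1)

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)


class MicrosleepCnnLstm:
    """1 s CNN feature extractor + LSTM sequence labeler, trained end-to-end.

    The CNN trunk is shared across the windows of a sequence; the LSTM
    emits one probability vector per window.  Default output is two
    classes (MSE vs everything-else).
    """

    kind = "cnn_lstm"

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        if spec.kind != "cnn_lstm":
            raise ConfigurationError("spec.kind must be 'cnn_lstm'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.window_samples  # 200 at 1 s / 200 Hz
        layers: list = [GaussianNoise(spec.noise_sd, rng)]
        # 200 → 99 → 48 → 23 → 10 → 4 → 1 with 6 blocks
        blocks, lengths, ch = _conv_blocks(spec.in_channels, 6, spec.filter_ladder,
                                           rng, L)
        if lengths[-1] != 1:
            raise ConfigurationError(
                f"per-step CNN does not collapse to extent 1 (got {lengths[-1]})"
            )
        layers += blocks + [Flatten()]
        self.block_output_lengths = lengths
        self.trunk = Sequential(layers)
        self.feat_dim = ch
        self.lstm = LSTM(ch, spec.lstm_units, rng)
        self.head = Sequential(
            [Dense(spec.lstm_units, spec.n_classes, rng), Softmax()]
        )

    @property
    def window_samples(self) -> int:
        return self.spec.window_samples

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def _forward(self, xseq: np.ndarray, train: bool) -> np.ndarray:
        B, T, C, L = xseq.shape
        feats = self.trunk.forward(xseq.reshape(B * T, C, L), train=train)
        hs = self.lstm.forward(feats.reshape(B, T, self.feat_dim), train=train)
        return self.head.forward(hs, train=train)

    def predict(self, xseq: np.ndarray) -> np.ndarray:
        """Probabilities (batch, T, n_classes) for (batch, T, channels, window)."""
        return self._forward(np.asarray(xseq, dtype=float), train=False)

    def forward_train(self, xseq: np.ndarray) -> np.ndarray:
        self._seq_shape = xseq.shape
        return self._forward(xseq, train=True)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        gH = self.head.backward_from_logits(dlogits)
        gF = self.lstm.backward(gH)
        B, T, C, L = self._seq_shape
        g = gF.reshape(B * T, self.feat_dim)
        for layer in reversed(self.trunk.layers):
            g = layer.backward(g)

    def parameters(self):
        return (
            self.trunk.parameters()
            + [self.lstm.params[k] for k in ("W", "U", "b")]
            + self.head.parameters()
        )

    def gradients(self):
        return (
            self.trunk.gradients()
            + [self.lstm.grads[k] for k in ("W", "U", "b")]
            + self.head.gradients()
        )

    def window_centers(self, n_samples: int) -> np.ndarray:
        """Centers of the overlapping 1 s windows strided by cnn_stride."""
        L = self.window_samples
        if n_samples < L:
            raise SizeError(f"recording of {n_samples} samples shorter than one window")
        starts = np.arange(0, n_samples - L + 1, self.spec.cnn_stride)
        return starts + L // 2

    def predict_windows(self, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-window probabilities over a whole (channels, samples) array.

        The window sequence is processed in chunks of ``seq_len`` (the LSTM
        state resets between chunks).  Returns (centers, probs).
        """
        data = np.asarray(data, dtype=float)
        centers = self.window_centers(data.shape[1])
        L = self.window_samples
        wins = np.stack([data[:, c - L // 2 : c - L // 2 + L] for c in centers])
        T = self.spec.seq_len
        probs = []
        for lo in range(0, len(wins), T):
            chunk = wins[lo : lo + T][None]  # (1, t, C, L)
            probs.append(self.predict(chunk)[0])
        return centers, np.concatenate(probs, axis=0)

    def state_dict(self):
        out = {f"trunk.{k}": v for k, v in self.trunk.state_dict().items()}
        out |= {f"lstm.{k}": v for k, v in self.lstm.params.items()}
        out |= {f"head.{k}": v for k, v in self.head.state_dict().items()}
        return out

    def load_state_dict(self, state):
        self.trunk.load_state_dict(
            {k[6:]: v for k, v in state.items() if k.startswith("trunk.")}
        )
        for k, v in state.items():
            if k.startswith("lstm."):
                self.lstm.params[k[5:]] = np.asarray(v, dtype=float)
        self.head.load_state_dict(
            {k[5:]: v for k, v in state.items() if k.startswith("head.")}
        )


def build_cnn(spec: ModelSpec, seed: int = 0) -> MicrosleepCNN:
    """Construct the sliding-window CNN described by ``spec``."""
    return MicrosleepCNN(spec, seed=seed)


def build_cnn_lstm(spec: ModelSpec, seed: int = 0) -> MicrosleepCnnLstm:
    """Construct the CNN-LSTM sequence labeler described by ``spec``."""
    return MicrosleepCnnLstm(spec, seed=seed)


def build_model(spec: ModelSpec, seed: int = 0):
    return build_cnn(spec, seed) if spec.kind == "cnn" else build_cnn_lstm(spec, seed)


def map_two_class(labels: np.ndarray) -> np.ndarray:
    """Collapse {W, MSEc, ED, SLEEP} → 0 and MSE → 1 (CNN-LSTM targets)."""
    from .labels import Label

    return (np.asarray(labels) == int(Label.MSE)).astype(np.int64)


def train(
    model,
    batches: Iterable | Callable[[int], Iterable],
    cfg: TrainConfig,
) -> list[float]:
    """Train a model in place; returns the per-batch loss history.

    ``batches`` is either an iterable of :class:`~microsleep.windowing.Batch`
    (consumed once; only usable with ``iterations=1``) or a callable
    ``iteration_index -> iterable`` producing a fresh pass per training
    iteration.  Loss is class-weighted cross-entropy; gradients are
    clipped to ``cfg.grad_clip_norm`` (global norm) when set.
    """
    if not callable(batches) and cfg.iterations > 1:
        raise TrainingError(
            "a one-shot batch iterable cannot drive multiple iterations; "
            "pass a callable producing a fresh stream per iteration"
        )
    opt = Nadam(lr=cfg.learning_rate)
    weights = cfg.class_weights
    if weights is None:
        weights = np.ones(model.n_classes)
    weights = np.asarray(weights, dtype=float)
    history: list[float] = []
    for it in range(cfg.iterations):
        stream = batches(it) if callable(batches) else batches
        got_any = False
        for batch in stream:
            got_any = True
            x, y = batch.x, batch.y
            probs = model.forward_train(x)
            loss, dlogits = weighted_cross_entropy(probs, y, weights)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at iteration {it}, batch {len(history)}"
                )
            model.backward_from_logits(dlogits)
            grads = model.gradients()
            if cfg.grad_clip_norm is not None:
                grads = clip_by_global_norm(grads, cfg.grad_clip_norm)
            opt.step(model.parameters(), grads)
            history.append(loss)
        if not got_any:
            raise TrainingError("empty batch stream")
    return history


def save_model(model, path: str | Path) -> None:
    """Checkpoint: .npz of weights plus a JSON sidecar with the spec."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.spec.to_dict(), indent=1))


def load_model(path: str | Path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    spec = ModelSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = build_model(spec)
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
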