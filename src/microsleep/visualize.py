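"""Internal-feature extraction, 2-D embedding, and scoring plots.

The best classifier's internal representation is inspected by appending a
64-filter convolutional layer to the trained CNN, taking its output as a
64-d feature vector per window, and projecting the (subsampled) vectors
to 2-D with t-SNE colored by the expert label.  Well-trained networks
show wake and microsleep as two clusters with borderline classes smeared
across the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .errors import DataError
from .evaluate import majority_coarsen
from .io import Recording
from .labels import TRACK_CLASSES
from .preprocess import LabelTrack, scale_cnn
from .windowing import valid_centers

__all__ = [
    "FeatureTrack",
    "extract_features",
    "tsne_embed",
    "plot_scoring_comparison",
    "plot_embedding",
]

_CLASS_COLORS = {"W": "tab:blue", "MSE": "tab:red", "MSEC": "tab:green", "ED": "m"}


@dataclass
class FeatureTrack:
    """64-d feature vectors at (subsampled) window centers with expert labels."""

    vectors: np.ndarray   # (n_windows, 64)
    centers: np.ndarray   # (n_windows,)
    labels: np.ndarray    # (n_windows,) expert label at each center


def extract_features(
    model,
    recording: Recording,
    track: LabelTrack,
    subsample: int = 100,
    channels: list[str] | None = None,
    batch_size: int = 256,
) -> FeatureTrack:
    """Run the feature-extractor CNN over every ``subsample``-th window center.

    The model must have been built with the extra 64-filter convolutional
    layer (``ModelSpec.feature_layer=True``); the recording must be
    conditioned (bandpass-filtered), scaling is applied here.
    """
    if subsample < 1:
        raise DataError("subsample must be ≥ 1")
    if channels is None:
        data = recording.data[: model.spec.in_channels]
    else:
        data = np.vstack([recording.channel(c) for c in channels])
    data = scale_cnn(data)
    L = model.window_samples
    centers = valid_centers(recording.n_samples, L)[::subsample]
    vecs = []
    for lo in range(0, len(centers), batch_size):
        sel = centers[lo : lo + batch_size]
        batch = np.stack([data[:, c - L // 2 : c - L // 2 + L] for c in sel])
        vecs.append(model.features(batch))
    return FeatureTrack(
        vectors=np.concatenate(vecs, axis=0),
        centers=centers,
        labels=track.labels[centers],
    )


def tsne_embed(
    features: FeatureTrack | np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Project feature vectors to 2-D with t-SNE (seeded, PCA init)."""
    X = features.vectors if isinstance(features, FeatureTrack) else np.asarray(features)
    if X.shape[0] < 10:
        raise DataError(f"need at least 10 vectors for an embedding, got {X.shape[0]}")
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca", random_state=seed)
    return tsne.fit_transform(X)


def plot_embedding(
    coords: np.ndarray, labels: np.ndarray, out: str, title: str = "t-SNE of features"
) -> None:
    """Scatter the 2-D embedding colored by expert class."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in TRACK_CLASSES:
        mask = labels == int(cls)
        if mask.any():
            ax.scatter(coords[mask, 0], coords[mask, 1], s=8,
                       c=_CLASS_COLORS[cls.name], label=cls.name, alpha=0.7)
    ax.set_title(title)
    ax.set_xlabel("t-SNE 1 (a.u.)")
    ax.set_ylabel("t-SNE 2 (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_scoring_comparison(
    expert: LabelTrack,
    auto: LabelTrack,
    out: str,
    coarsen_samples: int = 100,
) -> None:
    """Two-panel step plot of expert vs automatic scoring (0.5 s resolution)."""
    if len(expert) != len(auto):
        raise DataError(
            f"track length mismatch: expert {len(expert)} vs automatic {len(auto)}"
        )
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    names = [c.name for c in TRACK_CLASSES]
    for ax, track, title in ((axes[0], expert, "Expert"),
                             (axes[1], auto, "Automatic")):
        coarse = majority_coarsen(track.labels, coarsen_samples)
        t_min = np.arange(len(coarse)) / track.fs / 60.0
        ax.step(t_min, coarse, where="post", lw=0.8)
        ax.set_yticks(range(len(names)), names)
        ax.set_ylim(-0.5, len(names) - 0.5)
        ax.set_title(title, loc="left", fontsize=10)
    axes[1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
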