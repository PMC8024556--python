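"""Sequential container and the weighted cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Softmax

__all__ = ["Sequential", "weighted_cross_entropy"]


def weighted_cross_entropy(
    probs: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy and its gradient w.r.t. the logits.

    ``probs`` are softmax outputs of shape (..., K); integer ``targets``
    have the matching leading shape.  Per-example weights are the class
    weights of the true labels, normalized so the loss is a weighted mean.
    Returns (loss, dL/dlogits) — the gradient is taken at the *logits*
    (softmax fused with the loss), so backpropagation starts below the
    Softmax layer.
    """
    p = probs.reshape(-1, probs.shape[-1])
    y = targets.reshape(-1)
    w = class_weights[y]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all examples in the batch have zero class weight")
    py = np.clip(p[np.arange(len(y)), y], 1e-12, None)
    loss = float(-(w * np.log(py)).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.reshape(probs.shape)


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient taken at the logits (skips the Softmax head)."""
        layers = self.layers
        if isinstance(layers[-1], Softmax):
            layers = layers[:-1]
        g = dlogits
        for layer in reversed(layers):
            g = layer.backward(g)
        return g

    def out_length(self, length: int) -> int:
        for layer in self.layers:
            length = layer.out_length(length)
        return length

    # -- parameter access ---------------------------------------------------
    def param_items(self) -> list[tuple[Layer, str]]:
        return [(lyr, name) for lyr in self.layers for name in lyr.params]

    def parameters(self) -> list[np.ndarray]:
        return [lyr.params[name] for lyr, name in self.param_items()]

    def gradients(self) -> list[np.ndarray]:
        return [lyr.grads[name] for lyr, name in self.param_items()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, lyr in enumerate(self.layers):
            for name, val in lyr.params.items():
                out[f"{i}.{name}"] = val
            for name in ("running_mean", "running_var"):
                if hasattr(lyr, name):
                    out[f"{i}.{name}"] = getattr(lyr, name)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, val in state.items():
            idx, name = key.split(".", 1)
            lyr = self.layers[int(idx)]
            if name in lyr.params:
                lyr.params[name] = np.asarray(val, dtype=float)
            else:
                setattr(lyr, name, np.asarray(val, dtype=float))
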