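"""Long short-term memory layer with full backpropagation through time."""

from __future__ import annotations

import numpy as np

from .layers import Layer, glorot_normal

__all__ = ["LSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Unidirectional LSTM returning the hidden state at every timestep.

    Input (B, T, D) → output (B, T, H).  Gate order in the fused weight
    matrices is [input, forget, cell, output]; the forget-gate bias starts
    at 1 (the usual trick to let memory persist early in training).  Input
    weights are Glorot-normal, recurrent weights orthogonal.
    """

    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        H = units
        # orthogonal recurrent init, block per gate
        blocks = []
        for _ in range(4):
            a = rng.normal(size=(H, H))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget gate
        self.params = {
            "W": glorot_normal(rng, (in_features, 4 * H), in_features, H),
            "U": np.concatenate(blocks, axis=1),
            "b": b,
        }

    def forward(self, x, train=False):
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = [] if train else None
        for t in range(T):
            z = x[:, t] @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            if train:
                cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        if train:
            self._cache = cache
        return hs

    def backward(self, gH):
        W, U = self.params["W"], self.params["U"]
        B, T, H = gH.shape
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros_like(self.params["b"])
        gx = np.empty((B, T, W.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = gH[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            gW += x_t.T @ dz
            gU += h_prev.T @ dz
            gb += dz.sum(axis=0)
            gx[:, t] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads = {"W": gW, "U": gU, "b": gb}
        return gx
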