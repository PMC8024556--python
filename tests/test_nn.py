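"""Numerical gradient checks and optimizer behavior of the numpy NN core.

Every backward pass is verified against central finite differences of the
scalar training loss, parameter-by-parameter and with respect to the
inputs.  Stochastic layers (noise, dropout) are excluded from the checked
stacks; ReLU/max-pool kinks have measure zero under continuous random
inputs.
"""

import numpy as np
import pytest

from microsleep.nn import (
    LSTM,
    BatchNorm1d,
    Conv1d,
    Dense,
    Flatten,
    MaxPool1d,
    Nadam,
    ReLU,
    Sequential,
    Softmax,
    clip_by_global_norm,
    global_norm,
    weighted_cross_entropy,
)


def _loss(net, x, y, w):
    return weighted_cross_entropy(net.forward(x, train=True), y, w)[0]


def _check_param_grads(net, x, y, w, eps=1e-6, tol=1e-6):
    loss, dlog = weighted_cross_entropy(net.forward(x, train=True), y, w)
    net.backward_from_logits(dlog)
    for lyr, name in net.param_items():
        p = lyr.params[name]
        analytic = lyr.grads[name]
        flat = p.ravel()
        idx = np.linspace(0, flat.size - 1, min(6, flat.size)).astype(int)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp = _loss(net, x, y, w)
            flat[i] = orig - eps
            lm = _loss(net, x, y, w)
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            assert analytic.ravel()[i] == pytest.approx(numeric, abs=tol), (
                f"{type(lyr).__name__}.{name}[{i}]"
            )


@pytest.fixture()
def data(rng):
    x = rng.normal(size=(6, 2, 20))
    y = rng.integers(0, 3, size=6)
    w = np.array([1.0, 2.0, 0.5])
    return x, y, w


class TestGradients:
    def test_conv_bn_pool_dense_stack(self, rng, data):
        x, y, w = data
        net = Sequential([
            Conv1d(2, 4, rng), BatchNorm1d(4), ReLU(), MaxPool1d(2),
            Conv1d(4, 5, rng), ReLU(), MaxPool1d(2),
            Flatten(), Dense(5 * 3, 3, rng), Softmax(),
        ])
        _check_param_grads(net, x, y, w)

    def test_same_padded_conv(self, rng, data):
        x, y, w = data
        net = Sequential([
            Conv1d(2, 3, rng, padding="same"), ReLU(),
            Flatten(), Dense(3 * 20, 3, rng), Softmax(),
        ])
        _check_param_grads(net, x, y, w)

    def test_input_gradient_of_conv(self, rng):
        """dL/dx of a valid conv layer matches finite differences."""
        conv = Conv1d(2, 3, rng)
        x = rng.normal(size=(2, 2, 9))
        gy = rng.normal(size=(2, 3, 7))

        def scalar(xv):
            return float((conv.forward(xv, train=True) * gy).sum())

        _ = conv.forward(x, train=True)
        gx = conv.backward(gy)
        eps = 1e-6
        for i in [(0, 0, 0), (1, 1, 4), (0, 1, 8)]:
            xp = x.copy(); xp[i] += eps
            xm = x.copy(); xm[i] -= eps
            numeric = (scalar(xp) - scalar(xm)) / (2 * eps)
            assert gx[i] == pytest.approx(numeric, abs=1e-6)

    def test_lstm_bptt(self, rng):
        B, T, D, H, K = 3, 5, 4, 6, 2
        lstm = LSTM(D, H, rng)
        head = Sequential([Dense(H, K, rng), Softmax()])
        x = rng.normal(size=(B, T, D))
        y = rng.integers(0, K, size=(B, T))
        w = np.ones(K)

        def loss_now():
            hs = lstm.forward(x, train=True)
            return weighted_cross_entropy(head.forward(hs, train=True), y, w)[0]

        hs = lstm.forward(x, train=True)
        _, dlog = weighted_cross_entropy(head.forward(hs, train=True), y, w)
        gH = head.backward_from_logits(dlog)
        lstm.backward(gH)
        eps = 1e-6
        for name in ("W", "U", "b"):
            p = lstm.params[name]
            flat = p.ravel()
            for i in np.linspace(0, flat.size - 1, 5).astype(int):
                orig = flat[i]
                flat[i] = orig + eps; lp = loss_now()
                flat[i] = orig - eps; lm = loss_now()
                flat[i] = orig
                assert lstm.grads[name].ravel()[i] == pytest.approx(
                    (lp - lm) / (2 * eps), abs=1e-6), f"LSTM.{name}[{i}]"


class TestLoss:
    def test_weighted_cross_entropy_manual(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        y = np.array([0, 1])
        w = np.array([1.0, 3.0, 1.0])
        loss, dlog = weighted_cross_entropy(probs, y, w)
        expect = -(1 * np.log(0.7) + 3 * np.log(0.8)) / 4
        assert loss == pytest.approx(expect)
        # gradient rows sum to zero (softmax simplex constraint)
        assert np.allclose(dlog.sum(axis=1), 0.0)

    def test_zero_weight_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.array([[0.5, 0.5]]), np.array([0]),
                                   np.array([0.0, 1.0]))


class TestOptim:
    def test_nadam_minimizes_quadratic(self):
        p = np.array([5.0, -3.0])
        opt = Nadam(lr=0.05)
        for _ in range(300):
            opt.step([p], [2 * p])
        assert np.abs(p).max() < 1e-2

    def test_global_norm_clipping(self):
        grads = [np.array([3.0]), np.array([4.0])]
        assert global_norm(grads) == pytest.approx(5.0)
        clipped = clip_by_global_norm(grads, 1.0)
        assert global_norm(clipped) == pytest.approx(1.0)
        small = [np.array([0.3]), np.array([0.4])]
        assert clip_by_global_norm(small, 1.0) is small


class TestBatchNormRunningStats:
    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm1d(2, momentum=0.0)  # running stats = last batch
        x = rng.normal(loc=3.0, scale=2.0, size=(16, 2, 50))
        bn.forward(x, train=True)
        y = bn.forward(x, train=False)
        # normalized with the batch's own stats → ~zero mean, unit var
        assert np.abs(y.mean(axis=(0, 2))).max() < 0.05
        assert np.abs(y.var(axis=(0, 2)) - 1).max() < 0.05
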