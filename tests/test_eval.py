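"""Kappa protocol, coarsening, duration criteria, sliding inference."""

import numpy as np
import pytest

from microsleep import (
    DataError,
    Event,
    EventList,
    Label,
    ModelSpec,
    Recording,
    apply_duration_criteria,
    cohen_kappa,
    majority_coarsen,
    per_class_kappa,
    pooled_evaluation,
    predict_sliding,
)
from microsleep.evaluate import read_label_track, write_label_track


def brute_force_kappa(a, b):
    """Independent oracle: kappa from an explicitly accumulated table."""
    a, b = np.asarray(a), np.asarray(b)
    classes = sorted(set(a.tolist()) | set(b.tolist()))
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = len(a)
    p_o = np.trace(table) / n
    p_e = sum(table[i].sum() * table[:, i].sum() for i in range(len(classes))) / n**2
    if p_e >= 1 - 1e-12:
        return 0.0
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_perfect_agreement(self):
        a = np.array([0, 0, 1, 1, 2])
        res = cohen_kappa(a, a)
        assert res.value == pytest.approx(1.0)
        assert not res.degenerate

    def test_hand_contingency_example(self):
        # table: p_o = 0.5, p_e = 0.5 → kappa 0
        res = cohen_kappa(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert res.value == pytest.approx(0.0)

    def test_all_wake_convention(self):
        z = np.zeros(100, dtype=int)
        res = cohen_kappa(z, z)
        assert res.value == 0.0 and res.degenerate

    def test_constant_but_different_not_degenerate(self):
        res = cohen_kappa(np.zeros(10, dtype=int), np.ones(10, dtype=int))
        assert res.value == pytest.approx(0.0)
        assert not res.degenerate

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, 50)
            b = rng.integers(0, 4, 50)
            assert cohen_kappa(a, b).value == pytest.approx(cohen_kappa(b, a).value)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(25):
            a = rng.integers(0, 4, 120)
            b = np.where(rng.random(120) < 0.7, a, rng.integers(0, 4, 120))
            assert cohen_kappa(a, b).value == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            cohen_kappa(np.zeros(3), np.zeros(4))


class TestPerClassKappa:
    def test_binary_sequences_symmetric_in_class(self, rng):
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        res = per_class_kappa(a, b, classes=[Label.W, Label.MSE])
        assert res[Label.W].value == pytest.approx(res[Label.MSE].value)

    def test_absent_class_degenerate_zero(self, rng):
        a = rng.integers(0, 2, 100)  # MSEc, ED never occur
        res = per_class_kappa(a, a)
        assert res[Label.MSEC].value == 0.0 and res[Label.MSEC].degenerate
        assert res[Label.ED].value == 0.0 and res[Label.ED].degenerate

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(30):
            a = rng.integers(0, 4, 200)
            b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 4, 200))
            ours = per_class_kappa(a, b)
            for cls in Label.W, Label.MSE, Label.MSEC, Label.ED:
                expect = brute_force_kappa((a == cls).astype(int),
                                           (b == cls).astype(int))
                assert ours[cls].value == pytest.approx(expect, abs=1e-12)

    def test_exhaustive_short_sequences(self, rng):
        """All length-4 pairs over 2 classes against the brute-force oracle."""
        for code_a in range(16):
            for code_b in range(16):
                a = np.array([(code_a >> i) & 1 for i in range(4)])
                b = np.array([(code_b >> i) & 1 for i in range(4)])
                assert cohen_kappa(a, b).value == pytest.approx(
                    brute_force_kappa(a, b), abs=1e-12)


class TestMajorityCoarsen:
    def test_mode_within_interval(self):
        out = majority_coarsen(np.array([0, 0, 0, 1]), 4)
        assert out.tolist() == [0, 0, 0, 0]

    def test_constant_unchanged(self):
        x = np.full(50, 2)
        assert (majority_coarsen(x, 7) == x).all()

    def test_tie_takes_previous_interval_label(self):
        # first interval decides 1; second ties (0,0,1,1) → previous = 1
        out = majority_coarsen(np.array([1, 1, 1, 0, 0, 0, 1, 1]), 4)
        assert out.tolist() == [1] * 8

    def test_tie_without_previous_defaults_to_wake(self):
        out = majority_coarsen(np.array([0, 0, 1, 1]), 4)
        assert out.tolist() == [0, 0, 0, 0]

    def test_idempotent(self, rng):
        x = rng.integers(0, 4, 1000)
        once = majority_coarsen(x, 100)
        assert (majority_coarsen(once, 100) == once).all()


class TestDurationCriteria:
    def test_rules(self):
        events = EventList([
            Event(0.0, 0.5, Label.MSE),     # too short → dropped
            Event(10.0, 20.0, Label.MSE),   # kept
            Event(30.0, 50.0, Label.MSE),   # too long → SLEEP
            Event(60.0, 60.4, Label.ED),    # non-MSE untouched
        ], total_duration_s=100.0)
        out = apply_duration_criteria(events)
        got = [(e.label, e.duration_s) for e in out]
        assert got == [(Label.MSE, 10.0), (Label.SLEEP, 20.0), (Label.ED, pytest.approx(0.4))]


class _StubModel:
    """Minimal CNN-like model: class = sign pattern of the center sample."""

    kind = "cnn"

    def __init__(self, window_samples=400, n_classes=4, rule=None):
        self.window_samples = window_samples
        self.n_classes = n_classes
        self.spec = ModelSpec(kind="cnn", window_s=window_samples // 200,
                              in_channels=1, n_classes=n_classes)
        self.rule = rule or (lambda center_vals: np.zeros(len(center_vals), dtype=int))
        self.windows_seen = 0

    def predict(self, x):
        self.windows_seen += x.shape[0]
        centers = x[:, 0, self.window_samples // 2]
        labels = self.rule(centers)
        probs = np.zeros((len(labels), self.n_classes))
        probs[np.arange(len(labels)), labels] = 1.0
        return probs


def _recording(n=2000, fs=200, data=None):
    if data is None:
        data = np.zeros((1, n))
    return Recording(id="stub", fs=fs, channels=["O1M2"], data=data)


class TestPredictSliding:
    def test_constant_stub_gives_full_length_wake(self):
        track = predict_sliding(_StubModel(), _recording(), stride=7)
        assert len(track) == 2000
        assert (track.labels == int(Label.W)).all()

    def test_strided_center_count_and_expansion(self):
        stub = _StubModel()
        track = predict_sliding(stub, _recording(), stride=100)
        assert stub.windows_seen == 17    # centers 200,300,...,1800
        assert len(track) == 2000

    def test_stride_equivalence_after_coarsening(self):
        """On block-constant input, stride 1 ≈ stride 100 after 0.5 s coarsening."""
        rng = np.random.default_rng(0)
        blocks = rng.integers(0, 4, 20)
        data = np.repeat(blocks, 100)[None, :] * 100.0  # blocks of 100 samples
        rule = lambda v: np.clip(np.round(v), 0, 3).astype(int)
        rec = _recording(data=data.astype(float))
        fine = predict_sliding(_StubModel(rule=rule), rec, stride=1)
        coarse = predict_sliding(_StubModel(rule=rule), rec, stride=100)
        a = majority_coarsen(fine.labels, 100)
        b = majority_coarsen(coarse.labels, 100)
        assert (a == b).all()

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(Exception):
            predict_sliding(_StubModel(), _recording(n=300))

    def test_trained_model_signature(self, prepared_pair):
        """Real model: output is full length with distribution rows."""
        from microsleep import build_cnn
        model = build_cnn(ModelSpec(kind="cnn", window_s=2), seed=0)
        rec, _ = prepared_pair
        track = predict_sliding(model, rec, stride=500,
                                channels=["O1M2", "E1M1", "E2M1"])
        assert len(track) == rec.n_samples
        assert np.abs(track.probs.sum(axis=1) - 1).max() < 1e-6


class TestPooledEvaluation:
    def test_single_recording_equals_per_class(self, rng):
        a = rng.integers(0, 4, 300)
        b = rng.integers(0, 4, 300)
        rep = pooled_evaluation({"x": b}, {"x": a})
        direct = per_class_kappa(a, b)
        for cls in direct:
            assert rep.per_class_kappa[cls.name] == pytest.approx(direct[cls].value)

    def test_equals_kappa_of_concatenation(self, rng):
        a1, a2 = rng.integers(0, 4, 200), rng.integers(0, 4, 150)
        b1, b2 = rng.integers(0, 4, 200), rng.integers(0, 4, 150)
        rep = pooled_evaluation({"r1": b1, "r2": b2}, {"r1": a1, "r2": a2})
        direct = per_class_kappa(np.concatenate([a1, a2]), np.concatenate([b1, b2]))
        for cls in direct:
            assert rep.per_class_kappa[cls.name] == pytest.approx(direct[cls].value)
        assert rep.confusion.sum() == 350

    def test_order_invariance(self, rng):
        tracks = {f"r{i}": rng.integers(0, 4, 100) for i in range(3)}
        other = {k: rng.integers(0, 4, 100) for k in tracks}
        rep1 = pooled_evaluation(tracks, other)
        rep2 = pooled_evaluation(dict(reversed(tracks.items())),
                                 dict(reversed(other.items())))
        assert rep1.per_class_kappa == rep2.per_class_kappa

    def test_id_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            pooled_evaluation({"a": np.zeros(5)}, {"b": np.zeros(5)})

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            pooled_evaluation({"a": np.zeros(5)}, {"a": np.zeros(6)})


class TestLabelTrackFile:
    def test_round_trip(self, tmp_path, rng):
        labels = rng.integers(0, 4, 50)
        path = tmp_path / "t.labels.txt"
        write_label_track(labels, 200, path)
        back = read_label_track(path)
        assert back.fs == 200
        assert (back.labels == labels).all()
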