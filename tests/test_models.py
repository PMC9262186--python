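"""CNN topologies, training/early stopping, metrics and rank-sum comparison."""

import numpy as np
import pytest

from oracle_utils import ranksum_permutation_p
from termscan import _nn
from termscan.models import (
    ModelConfig,
    TermModel,
    build_model,
    compare_models,
    evaluate,
    pretrain_finetune,
    train,
)
from termscan.structure import generate_pretraining_set


def _random_seqs(rng, n, length, alphabet="ACGU"):
    return ["".join(rng.choice(list(alphabet), length)) for _ in range(n)]


def _toy_separable(rng, n=30, length=24):
    """Positives GC-rich, negatives AU-only: linearly separable."""
    pos = _random_seqs(rng, n, length, "GC")
    neg = _random_seqs(rng, n, length, "AU")
    return pos + neg, np.r_[np.ones(n), np.zeros(n)].astype(np.float32)


class TestBuildModel:
    def test_conv_parameter_counts(self):
        onehot = build_model(ModelConfig(topology="onehot_cnn"), seed=0)
        matrix = build_model(ModelConfig(topology="matrix_cnn"), seed=0)
        conv1 = onehot.net.layers[0]
        conv2 = matrix.net.layers[0]
        assert conv1.W.size + conv1.b.size == 30 * (10 * 4 + 1)  # 1230
        assert conv2.W.size + conv2.b.size == 30 * (10 * 10 + 1)  # 3030

    def test_dense_head_parameter_counts(self):
        model = build_model(ModelConfig(topology="onehot_cnn"), seed=0)
        # conv output 66 -> pooled 13 -> flattened 13*30
        dense1 = model.net.layers[4]
        assert dense1.W.shape == (13 * 30, 360)
        total = (
            1230
            + (390 * 360 + 360)
            + (360 * 30 + 30)
            + (30 * 1 + 1)
        )
        assert model.count_params() == total

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for topology in ("onehot_cnn", "matrix_cnn"):
            model = build_model(
                ModelConfig(topology=topology, input_length=20), seed=1
            )
            scores = model.predict_scores(_random_seqs(rng, 8, 20))
            assert np.all((scores >= 0) & (scores <= 1))

    def test_config_errors(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(input_length=5, kernel_size=10))
        with pytest.raises(ValueError):
            build_model(ModelConfig(topology="lstm"))


class TestConvKernels:
    def test_conv2d_matches_im2col_reference(self):
        """Jitted direct conv (fwd + all gradients) equals the standard
        im2col formulation in float64."""
        rng = np.random.default_rng(3)
        B, H, K, F = 4, 16, 5, 6
        x = rng.standard_normal((B, H, H)).astype(np.float32)
        conv = _nn.Conv2D(1, F, K, np.random.default_rng(0))
        act = conv.forward(x)
        OH = H - K + 1
        patches = np.empty((B, OH, OH, K, K))
        for di in range(K):
            for dj in range(K):
                patches[:, :, :, di, dj] = x[:, di : di + OH, dj : dj + OH]
        zref = np.einsum(
            "bijkl,klf->bfij", patches, conv.W.astype(np.float64)
        ) + conv.b[None, :, None, None]
        ref = np.maximum(zref, 0.0)
        assert np.allclose(act, ref, atol=1e-4)
        dout = rng.standard_normal(act.shape).astype(np.float32)
        dx = conv.backward(dout)
        dz = np.where(zref > 0, dout, 0.0)
        dWref = np.einsum("bijkl,bfij->klf", patches, dz)
        assert np.allclose(conv.grads[0], dWref, atol=1e-3)
        assert np.allclose(conv.grads[1], dz.sum(axis=(0, 2, 3)), atol=1e-3)
        dxref = np.zeros((B, H, H))
        dpatches = np.einsum("bfij,klf->bijkl", dz, conv.W.astype(np.float64))
        for di in range(K):
            for dj in range(K):
                dxref[:, di : di + OH, dj : dj + OH] += dpatches[:, :, :, di, dj]
        assert np.allclose(dx, dxref, atol=1e-3)


class TestTrain:
    cfg = ModelConfig(
        topology="onehot_cnn", input_length=24, batch_size=16, patience=3
    )

    def test_determinism(self):
        rng = np.random.default_rng(1)
        seqs, y = _toy_separable(rng)
        histories = []
        for _ in range(2):
            model = build_model(self.cfg, seed=2)
            histories.append(
                train(model, (seqs, y), (seqs, y), seed=3, epochs=4)
            )
        assert histories[0].train_acc == histories[1].train_acc
        assert histories[0].test_acc == histories[1].test_acc

    def test_separable_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        seqs, y = _toy_separable(rng, n=40)
        model = build_model(self.cfg, seed=0)
        history = train(model, (seqs, y), (seqs, y), seed=1, epochs=20)
        assert max(history.test_acc) == 1.0

    def test_early_stopping_restores_best(self):
        rng = np.random.default_rng(3)
        seqs, y = _toy_separable(rng, n=30)
        model = build_model(self.cfg, seed=0)
        history = train(
            model, (seqs, y), (seqs, y), seed=1, epochs=30, patience=2
        )
        assert history.stop_epoch >= history.best_epoch
        assert history.stop_epoch <= 30

    def test_shuffled_labels_auprc_near_prevalence(self):
        rng = np.random.default_rng(4)
        seqs, y = _toy_separable(rng, n=40)
        y_shuffled = np.random.default_rng(0).permutation(y)
        model = build_model(self.cfg, seed=0)
        train(model, (seqs, y_shuffled), (seqs, y_shuffled), seed=1, epochs=3)
        rng2 = np.random.default_rng(5)
        val_seqs = _random_seqs(rng2, 80, 24)
        val_y = np.r_[np.ones(40), np.zeros(40)].astype(np.float32)
        metrics = evaluate(model, (val_seqs, val_y))
        assert abs(metrics.auprc - 0.5) < 0.25

    def test_empty_data_errors(self):
        model = build_model(self.cfg, seed=0)
        with pytest.raises(ValueError):
            train(model, ([], np.empty(0)), ([], np.empty(0)), seed=0)


class TestPretrainFinetune:
    def test_identity_without_pretraining(self):
        rng = np.random.default_rng(5)
        seqs, y = _toy_separable(rng, n=20)
        cfg = ModelConfig(topology="onehot_cnn", input_length=24, batch_size=16)
        model, pre_hist, hist = pretrain_finetune(
            cfg, None, (seqs, y), (seqs, y), seed=0, epochs=3
        )
        assert pre_hist is None
        assert len(hist.train_acc) >= 1

    def test_pretrained_separates_structure_data(self):
        """After pre-training alone the model scores held-out structure
        positives vs random negatives at accuracy > 0.9."""
        structures = [
            "." * 4 + "(" * 6 + "..." + ")" * 6 + "." * 5,
            "." * 3 + "(" * 7 + "...." + ")" * 7 + "." * 3,
        ]
        length = len(structures[0])
        pset = generate_pretraining_set(structures, 100, seed=6)
        cfg = ModelConfig(
            topology="matrix_cnn", input_length=length, batch_size=16
        )
        model = build_model(cfg, seed=0)
        train(model, pset.pretrain(), pset.earlystop(), seed=1, epochs=15,
              patience=4)
        seqs, y = pset.earlystop()
        scores = model.predict_scores(seqs)
        acc = np.mean((scores > 0.5) == (y > 0.5))
        assert acc > 0.9

    def test_length_mismatch(self):
        pset = generate_pretraining_set(["((((...))))"], 4, seed=0)
        cfg = ModelConfig(topology="onehot_cnn", input_length=75)
        with pytest.raises(ValueError):
            pretrain_finetune(cfg, pset, (["A" * 75], np.ones(1)),
                              (["A" * 75], np.ones(1)), seed=0)


class TestEvaluate:
    def test_perfect_scorer(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        metrics = evaluate(lambda s: np.array([0.9, 0.8, 0.1, 0.2]),
                           (["A"] * 4, y))
        assert metrics.precision == metrics.recall == metrics.f1 == 1.0
        assert metrics.auprc == 1.0

    def test_constant_scorer_auprc_is_prevalence(self):
        y = np.array([1, 0, 0, 0], dtype=float)
        metrics = evaluate(lambda s: np.full(4, 0.7), (["A"] * 4, y))
        assert metrics.auprc == pytest.approx(0.25)

    def test_all_negative_predictions(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        metrics = evaluate(lambda s: np.zeros(4), (["A"] * 4, y))
        assert metrics.recall == 0.0
        assert metrics.specificity == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate(lambda s: np.zeros(3), (["A"] * 3, np.ones(3)))


class TestCompareModels:
    def test_known_exact_value(self):
        assert compare_models([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert compare_models([5, 5, 5], [5, 5, 5]) == 1.0

    def test_monotone_invariance(self):
        a, b = [0.1, 0.5, 0.9, 0.3], [0.2, 0.8, 0.7]
        p1 = compare_models(a, b)
        p2 = compare_models(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compare_models([], [1.0])

    def test_matches_permutation_oracle(self):
        """Exact branch equals brute-force permutation enumeration for all
        random sample pairs with combined n <= 10 (including ties)."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            na = int(rng.integers(1, 6))
            nb = int(rng.integers(1, 11 - na))
            a = rng.integers(0, 6, size=na) / 2.0  # ties likely
            b = rng.integers(0, 6, size=nb) / 2.0
            assert compare_models(a, b) == pytest.approx(
                ranksum_permutation_p(a, b), abs=1e-12
            )

    def test_large_sample_normal_branch(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1.2, 1, 40)
        p = compare_models(a, b)
        assert 0 < p < 0.01


class TestSaveLoad:
    def test_roundtrip_scores(self, tmp_path):
        rng = np.random.default_rng(0)
        cfg = ModelConfig(topology="onehot_cnn", input_length=20)
        model = build_model(cfg, seed=4)
        seqs = _random_seqs(rng, 6, 20)
        before = model.predict_scores(seqs)
        model.save(tmp_path / "ckpt")
        loaded = TermModel.load(tmp_path / "ckpt")
        assert np.allclose(loaded.predict_scores(seqs), before)
        assert loaded.config == cfg
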