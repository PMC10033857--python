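"""Loss values, splitting, metrics arithmetic, optimisation behaviour, sweep."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from melcrnn.labeling import Segment
from melcrnn.model import ModelConfig, build_model, xavier_init
from melcrnn.synthetic import easy_preset
from melcrnn.training import (Metrics, TrainConfig, _metrics_from_confusion,
                              cross_entropy, evaluate, format_sweep_table,
                              parameter_sweep, predict, train, train_test_split)


def make_segments(rng, n=20, c=2, length=64, labels=None):
    labels = labels if labels is not None else rng.integers(0, 2, n)
    return [Segment(patches=rng.standard_normal((4, c, length)), label=int(l),
                    span=(i * length, (i + 1) * length)) for i, l in enumerate(labels)]


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy([1, 0], [1, 0]) == 0.0

    def test_uniform_prediction_is_ln2(self):
        assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_correct(self):
        assert cross_entropy([1, 0], [0.9, 0.1]) == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            loss = cross_entropy([1.0, 0.0], [0.0, 1.0])
        assert np.isfinite(loss) and loss > 20

    def test_unnormalised_prediction_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([1, 0], [0.7, 0.7])

    def test_nonnegative_with_equality_iff_onehot(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            loss = cross_entropy([0, 1, 0], p)
            assert loss >= 0
            assert (loss == 0) == (p[1] == 1.0)


class TestSplit:
    def test_80_20_counts(self, rng):
        tr, te = train_test_split(make_segments(rng, 100), 0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20

    def test_same_seed_same_partition(self, rng):
        segs = make_segments(rng, 30)
        a = train_test_split(segs, 0.8, seed=9)
        b = train_test_split(segs, 0.8, seed=9)
        assert [id(s) for s in a[0]] == [id(s) for s in b[0]]

    def test_groups_do_not_straddle(self, rng):
        segs = make_segments(rng, 30)
        groups = np.repeat(np.arange(6), 5)
        tr, te = train_test_split(segs, 0.8, seed=1, groups=groups)
        tr_ids = {id(s) for s in tr}
        for g in range(6):
            members = [id(segs[i]) for i in np.flatnonzero(groups == g)]
            sides = {m in tr_ids for m in members}
            assert len(sides) == 1

    def test_degenerate_ratio_rejected(self, rng):
        with pytest.raises(ValueError):
            train_test_split(make_segments(rng, 4), 0.01, seed=0)


class TestMetrics:
    def test_worked_confusion_example(self):
        conf = np.array([[50, 10], [5, 35]])
        m = _metrics_from_confusion(conf, "binary_positive")
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx(35 / 45)
        assert m.recall == pytest.approx(35 / 40)
        assert m.f1 == pytest.approx(2 * (35 / 45) * (35 / 40) / (35 / 45 + 35 / 40))

    def test_perfect_predictions(self):
        m = _metrics_from_confusion(np.diag([7, 9]), "binary_positive")
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_majority_predictor_on_balanced_set(self):
        m = _metrics_from_confusion(np.array([[50, 0], [50, 0]]), "binary_positive")
        assert m.accuracy == 0.5

    @pytest.mark.parametrize("averaging,z", [("binary_positive", 2), ("macro", 3)])
    def test_agrees_with_sklearn(self, averaging, z, rng):
        """Cross-check the confusion-matrix arithmetic against sklearn."""
        y_true = rng.integers(0, z, 200)
        y_pred = rng.integers(0, z, 200)
        conf = np.zeros((z, z), dtype=int)
        for t, p in zip(y_true, y_pred):
            conf[t, p] += 1
        m = _metrics_from_confusion(conf, averaging)
        avg = "binary" if averaging == "binary_positive" else "macro"
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average=avg, pos_label=1, zero_division=0)
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f1 == pytest.approx(f)
        assert m.accuracy == pytest.approx((y_true == y_pred).mean())


@pytest.fixture
def tiny_setup(rng, tiny_spectral, tiny_model_cfg):
    model = xavier_init(build_model(tiny_model_cfg, tiny_spectral), seed=2)
    segs = make_segments(rng, 12)
    return model, segs


class TestTrainLoop:
    def test_history_length_matches_epochs(self, tiny_setup):
        model, segs = tiny_setup
        _, hist = train(model, segs, TrainConfig(epochs=2, batch_size=4, seed=0))
        assert len(hist) == 2
        assert {"epoch", "loss", "train_accuracy"} <= set(hist.columns)

    def test_zero_learning_rate_freezes_parameters(self, rng, tiny_spectral):
        # full-batch, no dropout: the degenerate optimiser leaves params and
        # loss exactly unchanged epoch over epoch
        cfg = ModelConfig(in_channels=2, conv_widths=(4, 6, 8), rnn_hidden=8,
                          fc_size=8, n_classes=2, dropout_p=0.0)
        model = xavier_init(build_model(cfg, tiny_spectral), seed=2)
        segs = make_segments(rng, 8)
        before = [p.data.copy() for p in model.parameters()]
        _, hist = train(model, segs,
                        TrainConfig(learning_rate=0.0, epochs=2, batch_size=8, seed=0))
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)
        # batch order permutes the float summation; the loss is constant up to that
        assert hist.loss.iloc[0] == pytest.approx(hist.loss.iloc[1], rel=1e-6)

    def test_single_step_decreases_batch_loss(self, tiny_setup, rng):
        """Gradient flow: one small-lr step reduces the loss on that batch."""
        from melcrnn.nn.optim import Adam, softmax_cross_entropy
        model, segs = tiny_setup
        x = np.stack([s.patches for s in segs[:6]]).astype(np.float32)
        y = np.array([s.label for s in segs[:6]])
        model.eval()  # freeze batch-norm stats and dropout for a clean comparison
        opt = Adam(model.parameters(), lr=1e-3)
        loss0 = softmax_cross_entropy(model.forward(x), y)
        loss0.backward()
        opt.step()
        loss1 = softmax_cross_entropy(model.forward(x), y)
        assert float(loss1.data) < float(loss0.data)

    def test_overfits_separable_toy_classes(self, tiny_spectral, tiny_model_cfg, rng):
        """Two spectrally separated classes are learned to >=95 % train accuracy."""
        t = np.arange(64) / 400.0
        segs = []
        for i in range(24):
            label = i % 2
            freq = 30.0 if label else 90.0
            base = np.sin(2 * np.pi * freq * np.arange(4 * 64) / 400.0 + rng.uniform(0, 6))
            sig = 5 * base.reshape(4, 64)[None].repeat(2, 0).transpose(1, 0, 2)
            segs.append(Segment(patches=sig + 0.2 * rng.standard_normal((4, 2, 64)),
                                label=label, span=(0, 256)))
        model = xavier_init(build_model(tiny_model_cfg, tiny_spectral), seed=4)
        model, hist = train(model, segs,
                            TrainConfig(epochs=15, batch_size=8, learning_rate=3e-3, seed=0))
        assert hist.train_accuracy.iloc[-1] >= 0.95

    def test_reproducible_history(self, tiny_spectral, tiny_model_cfg, rng):
        segs = make_segments(rng, 10)
        runs = []
        for _ in range(2):
            model = xavier_init(build_model(tiny_model_cfg, tiny_spectral), seed=7)
            _, hist = train(model, segs, TrainConfig(epochs=2, batch_size=4, seed=7))
            runs.append(hist)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_empty_training_set_rejected(self, tiny_setup):
        model, _ = tiny_setup
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=1))


class TestEvaluate:
    def test_argmax_predictions_fill_confusion(self, tiny_setup, two_class):
        model, segs = tiny_setup
        m = evaluate(model, segs, two_class)
        assert m.confusion.sum() == len(segs)
        assert 0.0 <= m.accuracy <= 1.0
        y_pred = predict(model, segs)
        acc = (y_pred == np.array([s.label for s in segs])).mean()
        assert m.accuracy == pytest.approx(acc)

    def test_empty_dataset_rejected(self, tiny_setup, two_class):
        model, _ = tiny_setup
        with pytest.raises(ValueError):
            evaluate(model, [], two_class)


@pytest.fixture(scope="module")
def sweep_inputs():
    preset = easy_preset(seed=3, windows_per_class=4, n_channels=3)
    mcfg = ModelConfig(in_channels=3, conv_widths=(2, 3, 4), rnn_hidden=4,
                       fc_size=4)
    tcfg = TrainConfig(epochs=1, batch_size=4, seed=3)
    return preset, mcfg, tcfg


class TestParameterSweep:
    def test_table_layout_and_best_mark(self, sweep_inputs):
        preset, mcfg, tcfg = sweep_inputs
        df = parameter_sweep({"n_mels": [6, 12]}, preset.recording, preset.trace,
                             preset.scheme, spectral=preset.spectral_config,
                             model_cfg=mcfg, train_cfg=tcfg)
        assert list(df.value) == [6, 12]
        assert {"accuracy", "precision", "recall", "f1"} <= set(df.columns)
        assert df.best.sum() == 1
        text = format_sweep_table(df, "n_mels")
        assert "Accuracy %" in text and "F1 score %" in text

    def test_invalid_grid_point_marked_failed(self, sweep_inputs):
        preset, mcfg, tcfg = sweep_inputs
        df = parameter_sweep({"patch_len": [200, 300]}, preset.recording, preset.trace,
                             preset.scheme, spectral=preset.spectral_config,
                             model_cfg=mcfg, train_cfg=tcfg)
        assert not df.iloc[0].failed
        assert df.iloc[1].failed and "divisible" in df.iloc[1].reason

    def test_singleton_grid_matches_direct_run(self, sweep_inputs):
        """A one-point sweep equals train+evaluate called directly."""
        from melcrnn.labeling import build_dataset
        preset, mcfg, tcfg = sweep_inputs
        df = parameter_sweep({"hop": [1]}, preset.recording, preset.trace,
                             preset.scheme, spectral=preset.spectral_config,
                             model_cfg=mcfg, train_cfg=tcfg)
        segs = build_dataset(preset.recording, preset.trace, preset.scheme)
        tr, te = train_test_split(segs, tcfg.split_ratio, tcfg.seed)
        model = xavier_init(build_model(mcfg, preset.spectral_config), tcfg.seed)
        model, _ = train(model, tr, tcfg)
        m = evaluate(model, te, preset.scheme)
        assert df.iloc[0].accuracy == pytest.approx(100 * m.accuracy)
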