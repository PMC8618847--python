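import numpy as np
import pytest

from bsound import detectors, nn
from bsound.detectors import (
    BaselineConfig,
    CDNN,
    CRNN,
    ModelSpec,
    TrainConfig,
    augment,
    baseline_classify,
    build_model,
    predict,
    train,
)
from bsound.spectro import FrameTensor


@pytest.fixture()
def tiny_dataset(rng):
    """Four 200-frame fragments with block-mean separable classes."""
    x = rng.normal(0, 1, (4, 200, 15, 4))
    y = rng.integers(0, 2, (4, 200)).astype(np.int8)
    x += 3.0 * y[..., None, None]  # positives are brighter
    return x, y


class TestBaseline:
    def test_threshold_decisions(self):
        ft = FrameTensor(blocks=np.zeros((1, 15, 4)), frame_ms=10, standardized=True)
        assert baseline_classify(ft, BaselineConfig(0.07)).decisions[0] == 0
        ft2 = FrameTensor(blocks=np.full((1, 15, 4), 0.08), frame_ms=10,
                          standardized=True)
        assert baseline_classify(ft2, BaselineConfig(0.07)).decisions[0] == 1

    def test_requires_standardized_input(self):
        ft = FrameTensor(blocks=np.zeros((1, 15, 4)), frame_ms=10, standardized=False)
        with pytest.raises(detectors.ContractError):
            baseline_classify(ft, BaselineConfig())

    def test_monotone_in_cutoff(self, rng):
        """Lowering the cutoff can only enlarge the predicted-positive set."""
        ft = FrameTensor(blocks=rng.normal(0, 1, (300, 15, 4)), frame_ms=10,
                         standardized=True)
        prev = None
        for cutoff in (0.20, 0.10, 0.08, 0.07, 0.06, 0.05):
            dec = baseline_classify(ft, BaselineConfig(cutoff)).decisions
            if prev is not None:
                assert np.all(dec >= prev)  # positives never flip back
            prev = dec


class TestArchitectures:
    def test_crnn_parameter_count(self):
        assert build_model(ModelSpec(kind="crnn")).parameter_count() == 342_281

    def test_cdnn_parameter_count(self):
        assert build_model(ModelSpec(kind="cdnn")).parameter_count() == 115_521

    def test_counts_truncate_to_printed_thousands(self):
        assert build_model(ModelSpec(kind="crnn")).parameter_count() // 1000 == 342
        assert build_model(ModelSpec(kind="cdnn")).parameter_count() // 1000 == 115

    @pytest.mark.parametrize("kind", ["crnn", "cdnn"])
    def test_interchangeable_shapes(self, kind, rng):
        """Both models map (B, T, 15, 4) to per-frame probabilities in [0,1]."""
        model = build_model(ModelSpec(kind=kind), seed=0)
        x = rng.normal(size=(2, 200, 15, 4))
        probs = model.predict_proba(x)
        assert probs.shape == (2, 200)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_zeroed_output_layer_gives_half(self, rng):
        model = build_model(ModelSpec(kind="cdnn"), seed=0)
        model.params["out_w"].data[:] = 0.0
        model.params["out_b"].data[:] = 0.0
        probs = model.predict_proba(rng.normal(size=(1, 200, 15, 4)))
        assert np.allclose(probs, 0.5)

    def test_predict_shape_contract(self, rng):
        model = build_model(ModelSpec(kind="cdnn"), seed=0)
        ft = FrameTensor(blocks=rng.normal(size=(200, 15, 4)), frame_ms=10,
                         standardized=True)
        pred = predict(model, ft)
        assert pred.probabilities.shape == (200,)
        bad = FrameTensor(blocks=rng.normal(size=(200, 10, 4)), frame_ms=10,
                          standardized=True)
        with pytest.raises(detectors.ContractError):
            predict(model, bad)
        with pytest.raises(detectors.ContractError):
            predict(model, FrameTensor(blocks=np.zeros((200, 15, 4)),
                                       frame_ms=10, standardized=False))

    def test_gradients_match_finite_differences(self, rng):
        """Spot-check analytic gradients of both architectures."""
        for kind in ("cdnn", "crnn"):
            spec = ModelSpec(kind=kind, seq_len=5)
            m = build_model(spec, seed=1)
            x = rng.normal(size=(2, 5, 15, 4))
            y = rng.integers(0, 2, size=(2, 5)).astype(float)

            def loss_of():
                lg = m.forward(x, train=False)
                return float(nn.bce_with_logits(lg.reshape(10), y.ravel()).data)

            lg = m.forward(x, train=False)
            loss = nn.bce_with_logits(lg.reshape(10), y.ravel())
            for p in m.params.values():
                p.grad = None
            loss.backward()
            for name, p in m.params.items():
                flat, g = p.data.ravel(), p.grad.ravel()
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    h, old = 1e-6, flat[i]
                    flat[i] = old + h
                    lp = loss_of()
                    flat[i] = old - h
                    lm = loss_of()
                    flat[i] = old
                    num = (lp - lm) / (2 * h)
                    assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7), (kind, name)


class TestAugment:
    def test_sigma_zero_identity(self, rng):
        x = rng.normal(size=(3, 10, 15, 4))
        y = rng.integers(0, 2, (3, 10))
        xa, ya = augment(x, y, sigma=0.0, copies=2, seed=0)
        assert xa.shape[0] == 9 and ya.shape[0] == 9
        assert np.array_equal(xa[3:6], x)

    def test_noise_std_matches_sigma(self, rng):
        x = rng.normal(size=(17, 200, 15, 4))
        y = np.zeros((17, 200), dtype=np.int8)
        xa, _ = augment(x, y, sigma=0.05, copies=5, seed=1)
        diffs = (xa[17:] - np.tile(x, (5, 1, 1, 1))).ravel()
        assert diffs.std() == pytest.approx(0.05, abs=0.001)

    def test_labels_copied_unchanged(self, rng):
        y = rng.integers(0, 2, (4, 10))
        _, ya = augment(rng.normal(size=(4, 10, 15, 4)), y, 0.1, copies=5, seed=2)
        assert np.array_equal(ya, np.tile(y, (6, 1)))


class TestTraining:
    @pytest.mark.parametrize("kind", ["crnn", "cdnn"])
    def test_one_epoch_smoke(self, kind, tiny_dataset):
        x, y = tiny_dataset
        model = build_model(ModelSpec(kind=kind), seed=0)
        hist = train(model, (x[:2], y[:2]), (x[2:], y[2:]),
                     TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1
        assert np.isfinite(hist[0]["loss"])

    def test_history_deterministic(self, tiny_dataset):
        x, y = tiny_dataset
        hists = []
        for _ in range(2):
            model = build_model(ModelSpec(kind="cdnn"), seed=5)
            hists.append(train(model, (x[:2], y[:2]), (x[2:], y[2:]),
                               TrainConfig(epochs=2, seed=5)))
        assert hists[0] == hists[1]

    def test_single_class_warns_but_trains(self, tiny_dataset):
        x, y = tiny_dataset
        y0 = np.zeros_like(y)
        model = build_model(ModelSpec(kind="cdnn"), seed=0)
        with pytest.warns(UserWarning):
            train(model, (x[:2], y0[:2]), (x[2:], y[2:]), TrainConfig(epochs=1))

    def test_learns_separable_classes(self, tiny_dataset):
        """Block-mean separable frames are learned nearly perfectly."""
        x, y = tiny_dataset
        model = build_model(ModelSpec(kind="cdnn"), seed=0)
        hist = train(model, (x[:3], y[:3]), (x[3:], y[3:]),
                     TrainConfig(epochs=10, seed=0))
        assert max(h["val_accuracy"] for h in hist) >= 95.0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(ModelSpec(kind="cdnn"), seed=3)
        detectors.save_model(model, tmp_path / "m", norm_mean=-40.0, norm_std=7.0)
        loaded, meta = detectors.load_model(tmp_path / "m")
        assert meta["norm_mean"] == -40.0 and meta["norm_std"] == 7.0
        x = rng.normal(size=(1, 200, 15, 4))
        assert np.array_equal(model.predict_proba(x), loaded.predict_proba(x))
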