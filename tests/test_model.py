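import numpy as np
import pytest

import emgeca as eg
from emgeca.errors import ValidationError
from emgeca.model import arrange_input, variant_spec
from emgeca import nn


def oracle_param_count(spec, eca_cfg=None):
    """Independent layer-by-layer arithmetic: conv kh*kw*Cin*Cout + Cout,
    BN 4*C, FC in*out + out, ECA K per module."""
    eca_cfg = eca_cfg or eg.EcaConfig()
    h, w, c = spec.input_shape
    total = 0
    for i, (kern, nf, stride) in enumerate(
            zip(spec.conv_kernels, spec.conv_filters, spec.conv_strides)):
        total += kern[0] * kern[1] * c * nf + nf      # conv weights + bias
        total += 4 * nf                               # BN gamma/beta/mean/var
        if spec.padding == "same":
            h = -(-h // stride[0]); w = -(-w // stride[1])
        else:
            h = (h - kern[0]) // stride[0] + 1; w = (w - kern[1]) // stride[1] + 1
        c = nf
        if i == 0 and spec.eca_after_first_conv:
            total += eg.eca_kernel_size(w, eca_cfg)   # attention over electrodes
    width = h * w * c
    for u in spec.fc_units:
        total += width * u + u
        width = u
    if spec.eca_after_final_fc:
        total += eg.eca_kernel_size(width, eca_cfg)
    total += width * spec.n_classes + spec.n_classes  # softmax projection
    return total


class TestBuild:
    def test_parameter_count_matches_arithmetic_oracle(self):
        for spec in [
            eg.compact_spec(300, 8, 8),
            eg.ModelSpec(),  # full-size architecture, input (300, 8, 1)
            variant_spec("conv1d", 300, 8, 8),
            eg.ModelSpec(input_shape=(60, 8, 1), conv_filters=(4, 8, 8),
                         padding="valid", fc_units=(16,), n_classes=3),
        ]:
            net = eg.build_model(spec)
            assert eg.n_parameters(net) == oracle_param_count(spec)
            del net

    def test_softmax_rows_are_probabilities(self, tiny_trained, tiny_ws):
        x, _ = tiny_ws.subset("test")
        probs = eg.predict_proba(tiny_trained, x)
        assert probs.shape == (len(x), 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_output_width_equals_n_classes(self):
        spec = eg.compact_spec(60, 4, n_classes=5)
        net = eg.build_model(spec)
        out = net.forward(np.zeros((3, 60, 4, 1)), training=False)
        assert out.shape == (3, 5)

    def test_collapsing_input_rejected(self):
        spec = eg.ModelSpec(input_shape=(4, 2, 1), padding="valid")
        with pytest.raises(ValidationError):
            eg.build_model(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            eg.ModelSpec(dropout_rate=1.0).validate()
        with pytest.raises(ValidationError):
            eg.ModelSpec(n_classes=1).validate()
        with pytest.raises(ValidationError):
            variant_spec("lstm", 300, 8)


class TestArrangeInput:
    def test_layouts(self):
        w = np.zeros((5, 60, 4))
        spec2d = eg.compact_spec(60, 4)
        assert arrange_input(w, spec2d).shape == (5, 60, 4, 1)
        spec1d = variant_spec("conv1d", 60, 4)
        assert arrange_input(w, spec1d).shape == (5, 60, 1, 4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            arrange_input(np.zeros((5, 61, 4)), eg.compact_spec(60, 4))


class TestTrain:
    def test_single_epoch_history(self, tiny_ws):
        spec = eg.compact_spec(tiny_ws.window_len, tiny_ws.n_channels, 2)
        tm = eg.train_model(spec, tiny_ws, eg.TrainConfig(1e-3, epochs=1,
                                                          batch_size=64, seed=0))
        assert len(tm.history) == 1
        assert tm.best_epoch == 1

    def test_training_is_deterministic(self, tiny_ws):
        spec = eg.compact_spec(tiny_ws.window_len, tiny_ws.n_channels, 2)
        cfg = eg.TrainConfig(1e-3, epochs=2, batch_size=64, seed=9)
        a = eg.train_model(spec, tiny_ws, cfg)
        b = eg.train_model(spec, tiny_ws, cfg)
        assert a.history.equals(b.history)

    def test_checkpoint_attains_max_validation_accuracy(self, tiny_trained, tiny_ws):
        hist = tiny_trained.history
        best = hist["val_acc"].max()
        assert hist.loc[tiny_trained.best_epoch - 1, "val_acc"] == best
        # the restored parameters reproduce the recorded best accuracy
        from emgeca.model import _evaluate_split
        x, y = tiny_ws.subset("val")
        _, acc = _evaluate_split(tiny_trained.net, arrange_input(x, tiny_trained.spec), y)
        assert acc == pytest.approx(best, abs=1e-12)

    def test_learns_separable_synthetic_data(self, tiny_trained):
        assert tiny_trained.history["train_acc"].iloc[-1] > 0.8
        assert tiny_trained.history["val_acc"].max() > 0.9

    def test_empty_split_rejected(self, tiny_ws):
        ws = eg.WindowSet(tiny_ws.windows, tiny_ws.labels,
                          np.zeros_like(tiny_ws.split), tiny_ws.fs,
                          tiny_ws.rec_ids, tiny_ws.starts)  # all train, no val
        spec = eg.compact_spec(tiny_ws.window_len, tiny_ws.n_channels, 2)
        with pytest.raises(ValidationError):
            eg.train(eg.build_model(spec), ws, eg.TrainConfig(1e-3, 1, 64, 0))


class TestPredict:
    def test_batch_equals_per_window_predictions(self, tiny_trained, tiny_ws):
        x, _ = tiny_ws.subset("test")
        x = x[:6]
        batch = eg.predict_proba(tiny_trained, x)
        singles = np.vstack([eg.predict_proba(tiny_trained, x[i:i + 1])
                             for i in range(len(x))])
        assert np.allclose(batch, singles, atol=1e-5)

    def test_duplicated_windows_get_identical_rows(self, tiny_trained, tiny_ws):
        x, _ = tiny_ws.subset("test")
        dup = np.stack([x[0], x[0], x[1]])
        probs = eg.predict_proba(tiny_trained, dup)
        assert np.array_equal(probs[0], probs[1])
        assert not np.array_equal(probs[0], probs[2])


def test_model_round_trip(tmp_path, tiny_trained, tiny_ws):
    eg.save_model(tiny_trained, tmp_path / "m")
    back = eg.load_model(tmp_path / "m")
    x, _ = tiny_ws.subset("test")
    assert np.allclose(eg.predict_proba(back, x),
                       eg.predict_proba(tiny_trained, x), atol=1e-12)
    assert back.best_epoch == tiny_trained.best_epoch


def test_dense_and_conv_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    conv = nn.Conv2D(3, 2, 2, 3, stride=(2, 1), padding="same", rng=rng)
    x = rng.normal(size=(2, 5, 3, 2))
    out = conv.forward(x, training=True)
    dout = rng.normal(size=out.shape)
    dx = conv.backward(dout)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (1, 4, 2, 1), (0, 2, 1, 0)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (np.sum(conv.forward(xp, True) * dout)
               - np.sum(conv.forward(xm, True) * dout)) / (2 * eps)
        assert num == pytest.approx(dx[idx], rel=1e-4, abs=1e-7)
    widx = (1, 0, 1, 2)
    conv.forward(x, True); conv.backward(dout)
    w0 = conv.variables["W"].copy()
    conv.variables["W"][widx] += eps; up = np.sum(conv.forward(x, True) * dout)
    conv.variables["W"][widx] -= 2 * eps; dn = np.sum(conv.forward(x, True) * dout)
    conv.variables["W"] = w0
    conv.forward(x, True)
    grads = conv.backward(dout)
    assert (up - dn) / (2 * eps) == pytest.approx(conv.grads["W"][widx],
                                                  rel=1e-4, abs=1e-7)


def test_batchnorm_gradient_matches_finite_differences():
    rng = np.random.default_rng(4)
    bn = nn.BatchNorm(3)
    x = rng.normal(size=(4, 2, 2, 3))
    dout = rng.normal(size=x.shape)
    bn.forward(x, training=True)
    dx = bn.backward(dout)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (3, 1, 1, 2)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        bnp = nn.BatchNorm(3); bnm = nn.BatchNorm(3)
        num = (np.sum(bnp.forward(xp, True) * dout)
               - np.sum(bnm.forward(xm, True) * dout)) / (2 * eps)
        assert num == pytest.approx(dx[idx], rel=1e-3, abs=1e-6)
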