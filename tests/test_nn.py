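"""Network: convolution correctness, training contracts, checkpoints."""

import numpy as np
import pytest
from scipy import signal

from singlepulse import (
    ArchConfig,
    CorrelationMapper,
    UNet,
    evaluate_mse,
    load_checkpoint,
    save_checkpoint,
)
from singlepulse.nn import layers as L
from singlepulse.synth import examples_to_arrays, sample_example
from conftest import MICRO_ARCH, micro_config


def conv_oracle(x, w, b):
    """Direct scipy correlate reference for 'same' stride-1 convolution."""
    co, ci, kh, kw = w.shape
    c, bs, h, wd = x.shape
    out = np.zeros((co, bs, h, wd))
    for o in range(co):
        for bb in range(bs):
            acc = np.zeros((h, wd))
            for i in range(ci):
                acc += signal.correlate(x[i, bb], w[o, i], mode="same")
            out[o, bb] = acc + b[o]
    return out


class TestConvLayer:
    @pytest.mark.parametrize("path,ci,co,k", [
        ("direct", 3, 4, 3),
        ("fft", 3, 4, 5),
        ("fft", 5, 2, 7),
    ])
    def test_forward_matches_scipy(self, path, ci, co, k):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(ci, 2, 11, 9)).astype(np.float32)
        w = rng.normal(size=(co, ci, k, k)).astype(np.float32)
        b = rng.normal(size=(co,)).astype(np.float32)
        y, cache = L.conv2d_forward(x, w, b)
        assert cache[0] == path
        assert np.allclose(y, conv_oracle(x, w, b), atol=1e-4)

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_backward_matches_numeric(self, k):
        rng = np.random.default_rng(1)
        ci, co = 3, 2
        x = rng.normal(size=(ci, 2, 8, 7)).astype(np.float32)
        w = rng.normal(size=(co, ci, k, k)).astype(np.float32)
        b = np.zeros(co, dtype=np.float32)
        dy = rng.normal(size=(co, 2, 8, 7)).astype(np.float32)
        _, cache = L.conv2d_forward(x, w, b)
        dx, dw, db = L.conv2d_backward(dy, cache)
        eps = 1e-2
        for idx in [(0, 0, 0, 0), (1, 2, k // 2, k - 1), (0, 1, 1, 0)]:
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            num = np.sum(dy * (
                (conv_oracle(x, wp, b) - conv_oracle(x, wm, b)) / (2 * eps)
            ))
            assert dw[idx] == pytest.approx(num, rel=2e-3, abs=1e-4)
        for idx in [(0, 0, 0, 0), (2, 1, 4, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = np.sum(dy * (
                (conv_oracle(xp, w, b) - conv_oracle(xm, w, b)) / (2 * eps)
            ))
            assert dx[idx] == pytest.approx(num, rel=2e-3, abs=1e-4)

    def test_fft_and_direct_paths_agree(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2, 12, 10)).astype(np.float32)
        w = rng.normal(size=(3, 4, 5, 5)).astype(np.float32)
        b = rng.normal(size=(3,)).astype(np.float32)
        dy = rng.normal(size=(3, 2, 12, 10)).astype(np.float32)
        yf, cf = L._conv2d_forward_fft(x, w, b)
        yd, cd = L._conv2d_forward_direct(x, w, b)
        assert np.allclose(yf, yd, atol=1e-4)
        for rf, rd in zip(L._conv2d_backward_fft(dy, cf),
                          L._conv2d_backward_direct(dy, cd)):
            assert np.allclose(rf, rd, atol=1e-3)


class TestModel:
    def test_full_model_gradient_vs_float64_oracle(self):
        """Backprop through the whole net (skips, pools, upsamples) matches
        finite differences of an independent float64 scipy implementation."""
        arch = ArchConfig(widths=(3, 4, 5), kernels=(3,) * 7 + (1,),
                          dropout_rate=0.0)
        net = UNet(arch, rng=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        yt = rng.normal(size=(2, 8, 8)).astype(np.float32)
        P = {k: v.astype(np.float64) for k, v in net.params.items()}

        def pool(a):
            c, b, h, w = a.shape
            return a.reshape(c, b, h // 2, 2, w // 2, 2).mean((3, 5))

        def up(a):
            return a.repeat(2, axis=2).repeat(2, axis=3)

        def fwd(P):
            xa = x.astype(np.float64)
            e1 = np.maximum(conv_oracle(xa, P["enc1.w"], P["enc1.b"]), 0)
            e2 = np.maximum(conv_oracle(pool(e1), P["enc2.w"], P["enc2.b"]), 0)
            m1 = np.maximum(conv_oracle(pool(e2), P["mid1.w"], P["mid1.b"]), 0)
            m2 = np.maximum(conv_oracle(m1, P["mid2.w"], P["mid2.b"]), 0)
            d1 = np.maximum(conv_oracle(up(m2) + e2, P["dec1.w"], P["dec1.b"]), 0)
            d2 = np.maximum(conv_oracle(up(d1) + e1, P["dec2.w"], P["dec2.b"]), 0)
            d3 = np.maximum(conv_oracle(d2, P["dec3.w"], P["dec3.b"]), 0)
            return conv_oracle(d3, P["out.w"], P["out.b"])[0]

        assert np.allclose(fwd(P), net.forward(x, train=False), atol=1e-5)

        def loss(P):
            return float(np.mean((fwd(P) - yt) ** 2))

        pred, cache = net.forward(x, train=True)
        grads = net.backward((2.0 / pred.size) * (pred - yt), cache)
        eps = 1e-5
        for name in ("enc1", "enc2", "mid1", "mid2", "dec1", "dec2", "dec3",
                     "out"):
            k = name + ".w"
            for _ in range(2):
                idx = tuple(int(rng.integers(0, s)) for s in P[k].shape)
                Pp = {kk: vv.copy() for kk, vv in P.items()}
                Pp[k][idx] += eps
                lp = loss(Pp)
                Pp[k][idx] -= 2 * eps
                lm = loss(Pp)
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-2, abs=1e-5)

    def test_weight_counts(self):
        assert 1.5e5 <= ArchConfig.preset("reduced").n_weights() <= 2.5e5
        assert 4.0e6 <= ArchConfig.preset("full").n_weights() <= 5.0e6

    def test_zero_input_finite_output(self):
        net = UNet(MICRO_ARCH, rng=0)
        x = np.zeros((2, 1, 16, 8), dtype=np.float32)
        y = net.forward(x)
        assert y.shape == (1, 16, 8)
        assert np.isfinite(y).all()

    def test_deterministic_without_dropout(self):
        net = UNet(MICRO_ARCH, rng=0)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 1, 16, 8)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_dropout_layers_present_except_last_hidden(self):
        net = UNet(MICRO_ARCH, rng=0)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 1, 16, 8)).astype(np.float32)
        _, cache = net.forward(x, train=True,
                               dropout_rng=np.random.default_rng(0))
        dropped = {n for n in cache
                   if isinstance(cache[n], tuple) and len(cache[n]) == 3
                   and cache[n][2] is not None}
        assert dropped == {"enc1", "enc2", "mid1", "mid2", "dec1", "dec2"}

    def test_receptive_field_warning(self):
        net = UNet(ArchConfig(widths=(3, 4, 5), kernels=(3,) * 7 + (1,)),
                   rng=0)
        with pytest.warns(UserWarning, match="receptive field"):
            net.check_receptive_field(400)


class TestEstimator:
    def test_same_seed_same_history(self, micro_gen_config):
        rng = np.random.default_rng(10)
        exs = [sample_example(micro_config(n_peaks_max=2), rng)
               for _ in range(8)]
        X, y = examples_to_arrays(exs)
        h = []
        for _ in range(2):
            est = CorrelationMapper(arch=MICRO_ARCH, batch_size=4,
                                    random_state=5)
            est.fit(X, y)
            h.append(list(est.loss_history_))
        assert h[0] == h[1]

    def test_nan_loss_aborts_with_diagnostics(self, micro_gen_config):
        est = CorrelationMapper(arch=MICRO_ARCH, random_state=0)
        X = np.full((2, 16, 8, 2), np.nan, dtype=np.float32)
        y = np.zeros((2, 16, 8), dtype=np.float32)
        with pytest.raises(FloatingPointError, match="non-finite loss"):
            est.fit(X, y)

    def test_evaluate_mse_closed_forms(self, mini_model, micro_gen_config):
        rng = np.random.default_rng(11)
        exs = [sample_example(micro_gen_config, rng) for _ in range(4)]
        X, y = examples_to_arrays(exs)
        pred = mini_model.predict(X)
        # a model evaluated against its own output has zero error
        assert evaluate_mse(mini_model, X, pred)["mse"] == pytest.approx(0.0)
        # against all-zero targets the MSE is the mean squared prediction
        zeros = np.zeros_like(y)
        expected = float(np.mean(pred.astype(np.float64) ** 2))
        assert evaluate_mse(mini_model, X, zeros)["mse"] == pytest.approx(
            expected, rel=1e-6
        )

    def test_checkpoint_round_trip(self, mini_model, micro_gen_config, tmp_path):
        rng = np.random.default_rng(12)
        exs = [sample_example(micro_gen_config, rng) for _ in range(3)]
        X, y = examples_to_arrays(exs)
        before = evaluate_mse(mini_model, X, y)["mse"]
        path = tmp_path / "model.npz"
        save_checkpoint(mini_model, path)
        loaded = load_checkpoint(path)
        after = evaluate_mse(loaded, X, y)["mse"]
        assert after == pytest.approx(before, rel=1e-6)
        assert loaded.n_weights_ == mini_model.n_weights_
        assert np.array_equal(loaded.predict(X), mini_model.predict(X))

    def test_mini_training_localizes_single_peaks(self, mini_model):
        """Peak-localization benchmark: the reconstruction's global maximum
        lands on the true peak pixel for the vast majority of held-out
        single-peak examples."""
        cfg = micro_config(n_peaks_max=1, noise_max_range=(0.0, 0.005))
        hits = 0
        n = 60
        for i in range(n):
            ex = sample_example(cfg, 50_000 + i)
            X, y = examples_to_arrays([ex])
            pred = mini_model.predict(X)[0]
            pm = np.unravel_index(np.argmax(pred), pred.shape)
            tm = np.unravel_index(np.argmax(y[0]), y[0].shape)
            if abs(pm[0] - tm[0]) <= 1 and abs(pm[1] - tm[1]) <= 1:
                hits += 1
        assert hits >= 0.9 * n

    def test_mini_training_reduces_mse(self, mini_model, micro_gen_config):
        rng = np.random.default_rng(13)
        exs = [sample_example(micro_config(n_peaks_max=2), rng)
               for _ in range(30)]
        X, y = examples_to_arrays(exs)
        trained = evaluate_mse(mini_model, X, y)["mse"]
        untrained = CorrelationMapper(arch=MICRO_ARCH, random_state=0)
        untrained._ensure_model()
        base = evaluate_mse(untrained, X, y)["mse"]
        assert trained < base / 5

    def test_translation_equivariance(self, mini_model):
        """Shifting a single-peak input along 1H shifts the reconstructed
        maximum by the same amount (within a pixel, away from edges)."""
        cfg = micro_config(n_peaks_max=1, noise_max_range=(0.0, 0.0),
                           fid_phase_range=(0.0, 0.0))
        ex = sample_example(cfg, 123)
        X, _ = examples_to_arrays([ex])
        shift = 8
        Xs = np.roll(X, shift, axis=1)
        p0 = mini_model.predict(X)[0]
        p1 = mini_model.predict(Xs)[0]
        m0 = np.unravel_index(np.argmax(p0), p0.shape)
        m1 = np.unravel_index(np.argmax(p1), p1.shape)
        assert abs((m1[0] - m0[0]) - shift) <= 1
        assert abs(m1[1] - m0[1]) <= 1

    def test_intensity_monotonicity(self, mini_model):
        cfg = micro_config(n_peaks_max=1, noise_max_range=(0.0, 0.0))
        ex = sample_example(cfg, 321)
        X, _ = examples_to_arrays([ex])
        full = mini_model.predict(X)[0].max()
        half = mini_model.predict(0.5 * X)[0].max()
        assert 0 < half < full
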