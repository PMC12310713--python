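import numpy as np
import pytest

from flaseg.network import (
    FLAUNet,
    ConvBlock,
    NetworkConfig,
    load_checkpoint,
    save_checkpoint,
)


def small_config(base=4, use_flab=True, **kw):
    return NetworkConfig(base_width=base, use_flab=use_flab, **kw)


class TestConvBlock:
    def test_output_nonnegative_and_shape(self, rng):
        blk = ConvBlock(3, 5, rng)
        x = rng.normal(size=(2, 8, 8, 3)).astype(np.float32)
        y = blk.forward(x, train=True)
        assert y.shape == (2, 8, 8, 5)
        assert np.all(y >= 0)

    def test_eval_mode_matches_hand_composition(self, rng):
        blk = ConvBlock(1, 2, rng)
        # freeze known running statistics
        blk.bn.running_mean[...] = [0.3, -0.1]
        blk.bn.running_var[...] = [1.5, 0.7]
        x = rng.normal(size=(1, 3, 3, 1)).astype(np.float32)
        y = blk.forward(x, train=False)
        w, b = blk.conv.weight.data, blk.conv.bias.data
        gamma, beta = blk.bn.gamma.data, blk.bn.beta.data
        for o in range(2):
            for yy in range(3):
                for xx in range(3):
                    s = float(b[o])
                    for u in range(3):
                        for v in range(3):
                            y2, x2 = yy + u - 1, xx + v - 1
                            if 0 <= y2 < 3 and 0 <= x2 < 3:
                                s += float(w[o, 0, u, v]) * float(x[0, y2, x2, 0])
                    s = gamma[o] * (s - blk.bn.running_mean[o]) / np.sqrt(
                        blk.bn.running_var[o] + blk.bn.eps) + beta[o]
                    s = max(s, 0.0)
                    assert abs(y[0, yy, xx, o] - s) < 1e-4


class TestEncoder:
    def test_channel_spatial_ladder(self):
        net = FLAUNet(small_config(base=8), seed=0)
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        feats = net.encoder_forward(x, train=False)
        assert [(f.shape[1], f.shape[2]) for f in feats] == [
            (8, 64), (16, 32), (32, 16), (64, 8), (128, 4)]

    def test_indivisible_input_rejected(self):
        net = FLAUNet(small_config(), seed=0)
        with pytest.raises(ValueError, match="divisible by 16"):
            net.encoder_forward(np.zeros((1, 1, 60, 60), dtype=np.float32))

    def test_channel_mismatch_rejected(self):
        net = FLAUNet(small_config(), seed=0)
        with pytest.raises(ValueError, match="channels"):
            net.forward(np.zeros((1, 3, 64, 64), dtype=np.float32))


class TestDecoderSchedule:
    @pytest.mark.parametrize("base", [4, 8])
    def test_flab_halves_triple_width_concat(self, base):
        net = FLAUNet(small_config(base=base), seed=0)
        widths = [base * 2 ** s for s in range(5)]
        for lvl, dec in zip(range(3, -1, -1), net.decoders):
            concat = widths[lvl + 1] + widths[lvl]
            assert concat == 3 * widths[lvl]
            assert dec.flab.channels == concat
            assert dec.flab.proj.cout == concat // 2
            assert dec.block1.conv.cin == concat // 2
            assert dec.block2.conv.cout == widths[lvl]

    def test_baseline_has_no_flab(self):
        net = FLAUNet(small_config(use_flab=False), seed=0)
        for dec in net.decoders:
            assert dec.flab is None
            assert dec.block1.conv.cin == 3 * dec.block2.conv.cout

    def test_baseline_matches_reference_census(self):
        """use_flab=False reproduces a bilinear-upsampling U-Net layer for layer."""
        base = 4
        net = FLAUNet(small_config(base=base, use_flab=False), seed=0)
        widths = [base * 2 ** s for s in range(5)]
        expected = []
        cin = 1
        for w in widths:  # encoder: two 3x3 conv blocks per stage
            expected += [(cin, w, 3), (w, w, 3)]
            cin = w
        for lvl in range(3, -1, -1):  # decoder: concat -> two conv blocks
            cat = widths[lvl + 1] + widths[lvl]
            expected += [(cat, widths[lvl], 3), (widths[lvl], widths[lvl], 3)]
        expected.append((base, 2, 1))  # classification head
        convs = [net.encoders[s].mods[i].conv for s in range(5) for i in range(2)]
        convs += [c for d in net.decoders for c in (d.block1.conv, d.block2.conv)]
        convs.append(net.head)
        assert [(c.cin, c.cout, c.k) for c in convs] == expected


class TestFullForward:
    def test_softmax_simplex(self, rng):
        net = FLAUNet(small_config(), seed=1)
        out = net.forward(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
        assert out.probabilities.shape == (1, 2, 64, 64)
        np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-5)
        assert out.probabilities.min() >= 0
        assert set(np.unique(out.predicted_mask)) <= {0, 1}

    def test_equal_logits_give_half(self):
        net = FLAUNet(small_config(), seed=0)
        net.head.weight.data[...] = 0.0
        net.head.bias.data[...] = 0.7
        out = net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))
        np.testing.assert_allclose(out.probabilities, 0.5, atol=1e-6)

    def test_deterministic(self, rng):
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        a = FLAUNet(small_config(), seed=3).forward(x)
        b = FLAUNet(small_config(), seed=3).forward(x)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        np.testing.assert_array_equal(a.predicted_mask, b.predicted_mask)

    @pytest.mark.parametrize("hw", [64, 96])
    def test_spatial_dims_preserved(self, hw):
        net = FLAUNet(small_config(), seed=0)
        out = net.forward(np.zeros((1, 1, hw, hw), dtype=np.float32))
        assert out.predicted_mask.shape == (1, hw, hw)

    def test_reflection_padding_flag(self):
        net = FLAUNet(small_config(pad_to_multiple=True), seed=0)
        out = net.forward(np.zeros((1, 1, 52, 60), dtype=np.float32))
        assert out.predicted_mask.shape == (1, 52, 60)
        np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-5)

    def test_skip_mismatch_error_reports_both_shapes(self, rng):
        from flaseg.network import DecoderStage
        from flaseg.attention import FlabConfig
        ds = DecoderStage(4, 2, 2, rng, True, FlabConfig())
        bottom = np.zeros((1, 4, 4, 4), dtype=np.float32)
        skip = np.zeros((1, 10, 10, 2), dtype=np.float32)
        with pytest.raises(ValueError, match="mismatch.*8, 8.*10, 10"):
            ds.forward(bottom, skip)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(base_width=3).validate()
        with pytest.raises(ValueError):
            NetworkConfig(depth=4).validate()
        with pytest.raises(ValueError):
            NetworkConfig(num_classes=1).validate()


class TestCheckpoint:
    def test_roundtrip(self, rng, tmp_path):
        net = FLAUNet(small_config(), seed=2)
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        net.forward(x, train=True)  # perturb BN running stats
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, seed=2, note="unit")
        loaded, meta = load_checkpoint(path)
        assert meta["seed"] == 2 and meta["note"] == "unit"
        np.testing.assert_array_equal(net.forward(x).probabilities,
                                      loaded.forward(x).probabilities)

    def test_config_echo(self, tmp_path):
        net = FLAUNet(small_config(base=8, use_flab=False), seed=0)
        save_checkpoint(tmp_path / "m.npz", net)
        loaded, _ = load_checkpoint(tmp_path / "m.npz")
        assert loaded.config.base_width == 8
        assert loaded.config.use_flab is False


class TestMemorisation:
    def test_tiny_overfit(self):
        """Capacity check: loss sinks on one tiny image within 200 steps."""
        from flaseg.pipeline import TrainConfig, fit_model, prepare_arrays
        from flaseg.synthetic import SynthConfig, generate_dataset

        pairs = generate_dataset(SynthConfig(n_images=1, size=48, seed=3,
                                             faz_radius_range=(0.18, 0.22)))
        x, y = prepare_arrays(pairs, 48)
        cfg = TrainConfig(epochs=200, batch_size=1, crop_size=48, n_restarts=1,
                          seed=3, model=small_config(base=4))
        model = FLAUNet(cfg.model, seed=3)
        losses = fit_model(model, x, y, cfg, np.random.default_rng(3),
                           max_steps=200, stop_below=0.05)
        assert min(losses) < 0.05
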