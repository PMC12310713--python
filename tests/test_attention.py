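import numpy as np
import pytest

from flaseg.attention import (
    FLAB,
    FlabConfig,
    FlabParams,
    feature_weight,
    flab_forward,
    location_weight,
    pooled_pair,
)

from conftest import (
    oracle_feature_weight,
    oracle_location_weight,
    oracle_pooled_pair,
    random_flab_params,
)


class TestPooledPair:
    def test_constant_slice(self):
        for k in (1, 3, 5):
            avg, mx = pooled_pair(np.full((6, 6), 3.25), k)
            assert np.allclose(avg, 3.25)
            assert np.allclose(mx, 3.25)

    def test_kernel_one_is_identity(self, rng):
        x = rng.normal(size=(5, 7))
        avg, mx = pooled_pair(x, 1)
        assert np.allclose(avg, x)
        assert np.allclose(mx, x)

    def test_4x4_distinct_vs_bruteforce(self):
        x = np.arange(16, dtype=float).reshape(4, 4)
        avg, mx = pooled_pair(x, 3)
        avg_ref, mx_ref = oracle_pooled_pair(x, 3)
        np.testing.assert_allclose(avg, avg_ref, rtol=1e-12)
        np.testing.assert_allclose(mx, mx_ref, rtol=1e-12)

    def test_avg_le_max_and_window_bounds(self, rng):
        x = rng.normal(size=(8, 8))
        avg, mx = pooled_pair(x, 3)
        assert np.all(avg <= mx + 1e-12)
        assert mx.max() <= x.max() and avg.min() >= x.min()

    @pytest.mark.parametrize("k", [0, 2, -1, 4])
    def test_bad_kernel_rejected(self, k):
        with pytest.raises(ValueError, match="odd"):
            pooled_pair(np.zeros((4, 4)), k)

    def test_nonfinite_rejected(self):
        x = np.zeros((4, 4))
        x[1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pooled_pair(x, 3)


class TestFeatureWeight:
    def test_zero_params(self, rng):
        params = FlabParams(3, np.zeros((2, 2)), np.zeros(2), np.zeros((1, 2)),
                            np.zeros(1), np.zeros((7, 7, 2)), 0.0)
        out = feature_weight(rng.normal(size=(5, 5)), params)
        assert np.allclose(out, 0.0)

    def test_identity_like_passes_avg(self, rng):
        # first conv forwards the avg channel, second conv forwards it again
        params = FlabParams(3, np.array([[1.0, 0.0], [0.0, 0.0]]), np.zeros(2),
                            np.array([[1.0, 0.0]]), np.zeros(1),
                            np.zeros((7, 7, 2)), 0.0)
        x = np.abs(rng.normal(size=(6, 6)))  # nonnegative -> ReLU transparent
        out = feature_weight(x, params)
        avg, _ = pooled_pair(x, 3)
        np.testing.assert_allclose(out, avg, rtol=1e-10)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(5):
            params = random_flab_params(rng)
            x = rng.normal(size=(5, 5))
            np.testing.assert_allclose(feature_weight(x, params),
                                       oracle_feature_weight(x, params), rtol=1e-9)


class TestLocationWeight:
    def test_zero_params(self, rng):
        params = random_flab_params(rng)
        params.location_w = np.zeros((7, 7, 2))
        params.location_b = 0.0
        assert np.allclose(location_weight(rng.normal(size=(8, 8)), params), 0.0)

    def test_delta_kernel_passes_avg(self, rng):
        params = random_flab_params(rng)
        w = np.zeros((7, 7, 2))
        w[3, 3, 0] = 1.0  # centred tap on the avg channel
        params.location_w = w
        params.location_b = 0.0
        x = rng.normal(size=(9, 9))
        avg, _ = pooled_pair(x, 3)
        np.testing.assert_allclose(location_weight(x, params), avg, rtol=1e-10)

    def test_matches_dense_correlation_oracle(self, rng):
        for _ in range(5):
            params = random_flab_params(rng)
            x = rng.normal(size=(8, 8))
            np.testing.assert_allclose(location_weight(x, params),
                                       oracle_location_weight(x, params), rtol=1e-9)

    def test_non_7x7_kernel_rejected(self, rng):
        params = random_flab_params(rng)
        params.location_w = np.zeros((5, 5, 2))
        with pytest.raises(ValueError, match="7x7"):
            location_weight(np.zeros((8, 8)), params)


def _full_params(rng, channels, **kw):
    p = random_flab_params(rng, **kw)
    p.proj_w = rng.normal(size=(channels // 2, channels, 3, 3)) * 0.1
    p.proj_b = rng.normal(size=(channels // 2,)) * 0.1
    return p


class TestFlabForward:
    def test_zero_input_zero_bias_gives_proj_bias(self, rng):
        c = 4
        params = _full_params(rng, c)
        params.feature_b1 = np.zeros(2)
        params.feature_b2 = np.zeros(1)
        params.location_b = 0.0
        params.proj_w = np.zeros((c // 2, c, 3, 3))
        x = np.zeros((1, c, 6, 6))
        out = flab_forward(x, params)
        # gates are sigmoid(0) = 0.5, gated maps all zero, conv leaves bias
        np.testing.assert_allclose(out, np.broadcast_to(
            params.proj_b[None, :, None, None], out.shape), atol=1e-6)

    def test_saturated_gate_passes_input(self, rng):
        c = 2
        params = _full_params(rng, c)
        params.feature_w1 = np.zeros((2, 2))
        params.feature_w2 = np.zeros((1, 2))
        params.feature_b2 = np.array([50.0])  # huge additive bias -> gate ~ 1
        params.location_w = np.zeros((7, 7, 2))
        params.location_b = 0.0
        # identity projection of channel 0
        params.proj_w = np.zeros((1, 2, 3, 3))
        params.proj_w[0, 0, 1, 1] = 1.0
        params.proj_b = np.zeros(1)
        x = rng.normal(size=(1, c, 8, 8))
        out = flab_forward(x, params)
        np.testing.assert_allclose(out[0, 0], x[0, 0], atol=1e-4)

    def test_staged_composition_oracle(self, rng):
        c = 4
        params = _full_params(rng, c)
        x = rng.normal(size=(1, c, 6, 6))
        out = flab_forward(x, params)
        # stage-by-stage in float64 with the functional per-channel ops
        gated = np.zeros_like(x)
        for i in range(c):
            z = (oracle_feature_weight(x[0, i], params)
                 + oracle_location_weight(x[0, i], params))
            gate = 1.0 / (1.0 + np.exp(-z))
            assert np.all(gate > 0) and np.all(gate < 1)
            gated[0, i] = gate * x[0, i]
        expect = np.zeros((1, c // 2, 6, 6))
        for o in range(c // 2):
            s = np.full((6, 6), params.proj_b[o])
            for i in range(c):
                for u in range(3):
                    for v in range(3):
                        shifted = np.zeros((6, 6))
                        ys, xs = u - 1, v - 1
                        src = gated[0, i]
                        for yy in range(6):
                            for xx in range(6):
                                y2, x2 = yy + ys, xx + xs
                                if 0 <= y2 < 6 and 0 <= x2 < 6:
                                    shifted[yy, xx] = src[y2, x2]
                        s += params.proj_w[o, i, u, v] * shifted
            expect[0, o] = s
        np.testing.assert_allclose(out, expect, rtol=1e-3, atol=1e-4)

    def test_odd_channel_count_rejected(self, rng):
        params = random_flab_params(rng)
        with pytest.raises(ValueError, match="FLAB"):
            flab_forward(np.zeros((1, 3, 8, 8)), params)

    def test_shape_contract(self, rng):
        for n, c, h, w in [(1, 2, 7, 7), (2, 6, 8, 10), (1, 8, 12, 12)]:
            params = _full_params(rng, c)
            out = flab_forward(rng.normal(size=(n, c, h, w)), params)
            assert out.shape == (n, c // 2, h, w)

    def test_determinism(self, rng):
        params = _full_params(rng, 4)
        x = rng.normal(size=(2, 4, 8, 8))
        a = flab_forward(x, params)
        b = flab_forward(x, params)
        np.testing.assert_array_equal(a, b)


class TestFlabLayer:
    def test_gate_bounded_and_attenuating(self, rng):
        blk = FLAB(6, rng)
        x = rng.normal(size=(2, 9, 9, 6)).astype(np.float32)
        blk.forward(x, train=True)
        _, gate, *_ = blk._cache
        assert np.all(gate > 0) and np.all(gate < 1)
        gated = gate * np.ascontiguousarray(x)
        assert np.all(np.abs(gated) <= np.abs(x) + 1e-7)

    def test_branch_independence_by_parameter_surgery(self, rng):
        # zeroing the location branch must reduce the block to feature gating
        blk = FLAB(2, rng)
        blk.lw.data[...] = 0.0
        blk.lb.data[...] = 0.0
        x = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        out = blk.forward(x, train=False)
        params = blk.export_params()
        for i in range(2):
            wf = feature_weight(x[0, :, :, i], params)
            wl = location_weight(x[0, :, :, i], params)
            assert np.allclose(wl, 0.0, atol=1e-7)
            assert not np.allclose(wf, 0.0)
        # and vice versa: zero feature branch leaves pure location gating
        blk2 = FLAB(2, np.random.default_rng(5))
        blk2.fw2.data[...] = 0.0
        blk2.fb2.data[...] = 0.0
        p2 = blk2.export_params()
        for i in range(2):
            assert np.allclose(feature_weight(x[0, :, :, i], p2), 0.0, atol=1e-7)

    def test_gradient_flow_to_both_branches(self, rng):
        blk = FLAB(4, rng)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        gy = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        blk.zero_grad()
        blk.forward(x, train=True)
        blk.backward(gy)
        feature_gnorm = sum(np.abs(p.grad).sum() for p in
                            (blk.fw1, blk.fb1, blk.fw2, blk.fb2))
        location_gnorm = np.abs(blk.lw.grad).sum() + np.abs(blk.lb.grad).sum()
        assert np.isfinite(feature_gnorm) and feature_gnorm > 0
        assert np.isfinite(location_gnorm) and location_gnorm > 0
        # directional finite-difference agreement over all parameters
        ps = blk.parameters()
        dirs = [np.random.default_rng(7).normal(size=p.data.shape).astype(np.float32)
                for p in ps]
        analytic = sum(float((p.grad * d).sum()) for p, d in zip(ps, dirs))
        t = 1e-4

        def loss():
            return float((blk.forward(x, train=True).astype(np.float64) * gy).sum())

        for p, d in zip(ps, dirs):
            p.data += t * d
        lp = loss()
        for p, d in zip(ps, dirs):
            p.data -= 2 * t * d
        lm = loss()
        fd = (lp - lm) / (2 * t)
        assert abs(fd - analytic) <= 2e-3 * max(1.0, abs(fd))

    def test_per_channel_mode_shapes_and_grads(self, rng):
        blk = FLAB(4, rng, FlabConfig(share_across_channels=False))
        assert blk.lw.data.shape == (4, 7, 7, 2)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        out = blk.forward(x, train=True)
        assert out.shape == (1, 8, 8, 2)
        blk.zero_grad()
        blk.backward(np.ones_like(out))
        assert np.isfinite(blk.lw.grad).all() and np.abs(blk.lw.grad).sum() > 0

    def test_bitwise_determinism(self, rng):
        blk = FLAB(4, rng)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        np.testing.assert_array_equal(blk.forward(x, train=False),
                                      blk.forward(x, train=False))
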