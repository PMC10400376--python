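"""Numerical verification of the hand-written layers and optimizers.

Every backward pass is checked against central finite differences on small
tensors; float32 storage limits the attainable agreement, so tolerances are
relative ~1e-2 with tiny probe steps.
"""

import numpy as np
import pytest

from legnet.nn.layers import (
    BatchNorm1d,
    Conv1d,
    CPBilinear,
    GlobalAvgPool,
    Linear,
    SiLU,
    log_softmax,
    softmax,
)
from legnet.nn.optim import AdamW, Lion, ReduceLROnPlateau, one_cycle_lr
from legnet.arch import SqueezeExcite


def _num_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def _check(analytic, numeric, rtol=2e-2, atol=2e-3):
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


def _loss_through(layer, x, training=True):
    """Scalar probe loss: weighted sum of outputs (fixed weights)."""
    y = layer.forward(x, training)
    w = np.sin(np.arange(y.size, dtype=np.float64)).reshape(y.shape)
    return float((y.astype(np.float64) * w).sum()), w


class TestGradients:
    @pytest.mark.parametrize(
        "cin,cout,k,groups",
        [(4, 6, 1, 1), (4, 6, 7, 1), (8, 8, 7, 4), (6, 6, 3, 6)],  # incl. depthwise
    )
    def test_conv1d(self, cin, cout, k, groups, rng):
        conv = Conv1d(cin, cout, k, groups=groups, bias=True, rng=rng)
        x = rng.normal(size=(cin, 2, 9)).astype(np.float32)

        def loss():
            y = conv.forward(x, training=False)
            return float((y.astype(np.float64) * w).sum())

        y0 = conv.forward(x, training=True)
        w = np.sin(np.arange(y0.size)).reshape(y0.shape)
        conv.weight.grad[...] = 0
        conv.bias.grad[...] = 0
        dx = conv.backward(w.astype(np.float32))
        _check(dx, _num_grad(loss, x))
        _check(conv.weight.grad, _num_grad(loss, conv.weight.value))
        _check(conv.bias.grad, _num_grad(loss, conv.bias.value))

    def test_batchnorm(self, rng):
        bn = BatchNorm1d(5)
        bn.gamma.value[...] = rng.uniform(0.5, 1.5, 5).astype(np.float32)
        bn.beta.value[...] = rng.normal(size=5).astype(np.float32)
        x = rng.normal(size=(5, 3, 7)).astype(np.float32)

        def loss():
            y = bn.forward(x, training=True)
            return float((y.astype(np.float64) * w).sum())

        y0 = bn.forward(x, training=True)
        w = np.cos(np.arange(y0.size)).reshape(y0.shape)
        bn.gamma.grad[...] = 0
        bn.beta.grad[...] = 0
        dx = bn.backward(w.astype(np.float32))
        _check(dx, _num_grad(loss, x), rtol=5e-2, atol=5e-3)
        _check(bn.gamma.grad, _num_grad(loss, bn.gamma.value))
        _check(bn.beta.grad, _num_grad(loss, bn.beta.value))

    def test_silu(self, rng):
        act = SiLU()
        x = rng.normal(size=(4, 2, 5)).astype(np.float32)

        def loss():
            y = act.forward(x, training=False)
            return float((y.astype(np.float64) * w).sum())

        y0 = act.forward(x, training=True)
        w = np.sin(np.arange(y0.size)).reshape(y0.shape)
        _check(act.backward(w.astype(np.float32)), _num_grad(loss, x))

    def test_cp_bilinear(self, rng):
        layer = CPBilinear(6, 3, rank=4, bias=True, rng=rng)
        s = rng.normal(size=(2, 6)).astype(np.float32)

        def loss():
            y = layer.forward(s, training=False)
            return float((y.astype(np.float64) * w).sum())

        y0 = layer.forward(s, training=True)
        w = np.sin(np.arange(y0.size)).reshape(y0.shape)
        for p in layer.params():
            p.grad[...] = 0
        ds = layer.backward(w.astype(np.float32))
        _check(ds, _num_grad(loss, s))
        for p in layer.params():
            _check(p.grad, _num_grad(loss, p.value))

    @pytest.mark.parametrize("variant", ["custom_lowrank", "efficientnetv2"])
    def test_squeeze_excite(self, variant, rng):
        se = SqueezeExcite(6, 3, variant, cp_rank=2, rng=rng, name="se")
        x = rng.normal(size=(6, 2, 5)).astype(np.float32)

        def loss():
            y = se.forward(x, training=False)
            return float((y.astype(np.float64) * w).sum())

        y0 = se.forward(x, training=True)
        w = np.sin(np.arange(y0.size)).reshape(y0.shape)
        for p in se.params():
            p.grad[...] = 0
        dx = se.backward(w.astype(np.float32))
        _check(dx, _num_grad(loss, x))
        for p in se.params():
            _check(p.grad, _num_grad(loss, p.value))

    def test_linear_and_pool(self, rng):
        lin = Linear(4, 3, rng=rng)
        s = rng.normal(size=(2, 4)).astype(np.float32)
        y0 = lin.forward(s, training=True)
        w = np.sin(np.arange(y0.size)).reshape(y0.shape)
        lin.weight.grad[...] = 0

        def loss():
            return float((lin.forward(s, training=False).astype(np.float64) * w).sum())

        _check(lin.backward(w.astype(np.float32)), _num_grad(loss, s))
        _check(lin.weight.grad, _num_grad(loss, lin.weight.value))

        pool = GlobalAvgPool()
        x = rng.normal(size=(3, 2, 5)).astype(np.float32)
        y = pool.forward(x, training=True)
        assert y.shape == (2, 3)
        g = np.ones((2, 3), dtype=np.float32)
        dx = pool.backward(g)
        assert dx.shape == x.shape
        np.testing.assert_allclose(dx, 1.0 / 5)

    def test_se_gate_of_one_is_identity(self, rng):
        se = SqueezeExcite(4, 2, "efficientnetv2", cp_rank=1, rng=rng, name="se")
        # force the gate open: huge positive bias on the expand stage
        se.stage2.bias.value[...] = 50.0
        se.stage2.weight.value[...] = 0.0
        x = rng.normal(size=(4, 2, 5)).astype(np.float32)
        np.testing.assert_allclose(se.forward(x), x, rtol=1e-5)

    def test_cp_parameter_saving(self, rng):
        layer = CPBilinear(64, 8, rank=10, rng=rng)
        n_factor = sum(p.size for p in layer.params())
        assert n_factor < layer.dense_parameter_count()


class TestSoftmaxHelpers:
    def test_softmax_rows_normalise(self, rng):
        z = rng.normal(size=(5, 18)).astype(np.float32)
        p = softmax(z)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, rtol=1e-6)
        np.testing.assert_allclose(np.log(p), log_softmax(z), rtol=1e-4, atol=1e-5)


class TestOptimizers:
    def _quadratic(self, opt_cls, **kw):
        from legnet.nn.layers import Param

        p = Param(np.array([5.0], dtype=np.float32))
        opt = opt_cls([p], **kw)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            losses.append(float(p.value[0] ** 2))
            p.grad[...] = 2 * p.value
            opt.step()
        return losses

    def test_adamw_descends(self):
        losses = self._quadratic(AdamW, lr=0.1, weight_decay=0.0)
        assert losses[-1] < losses[0] * 0.1

    def test_lion_descends(self):
        # sign updates move at a fixed lr per step: give it room to reach 0
        losses = self._quadratic(Lion, lr=0.2, weight_decay=0.0)
        assert losses[-1] < losses[0] * 0.1

    def test_adamw_decay_flag_respected(self):
        from legnet.nn.layers import Param

        decayed = Param(np.array([1.0], dtype=np.float32), decay=True)
        frozen = Param(np.array([1.0], dtype=np.float32), decay=False)
        opt = AdamW([decayed, frozen], lr=0.1, weight_decay=0.5)
        opt.zero_grad()
        opt.step()  # zero gradients: only decay acts
        assert decayed.value[0] < 1.0
        assert frozen.value[0] == pytest.approx(1.0)


class TestSchedules:
    def test_one_cycle_shape(self):
        total = 1000
        lrs = np.array([one_cycle_lr(s, total, 0.005) for s in range(total)])
        peak_at = int(np.argmax(lrs))
        assert lrs.max() == pytest.approx(0.005)
        assert peak_at == pytest.approx(0.3 * total, abs=2)
        assert lrs[0] == pytest.approx(0.005 / 25)
        assert lrs[-1] <= 0.005 / 1e4 * 1.5
        # unimodal: non-decreasing then non-increasing
        assert np.all(np.diff(lrs[: peak_at + 1]) >= -1e-12)
        assert np.all(np.diff(lrs[peak_at:]) <= 1e-12)

    def test_one_cycle_domain(self):
        with pytest.raises(ValueError):
            one_cycle_lr(10, 10, 0.005)

    def test_plateau_only_decreases_after_patience(self):
        from legnet.nn.layers import Param

        p = Param(np.zeros(1, dtype=np.float32))
        opt = AdamW([p], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=2)
        lrs = [sched.step(m) for m in [1.0, 0.9, 0.9, 0.9, 0.9, 0.5, 0.5]]
        assert lrs[:4] == [1.0, 1.0, 1.0, 1.0]
        assert lrs[4] == pytest.approx(0.1)  # patience of 2 exhausted
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))
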