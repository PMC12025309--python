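"""Finite-difference validation of the reverse-mode autodiff core.

Every spatial/attention primitive used by the segmentation networks is checked
against central differences on small random inputs; these are the bedrock for
trusting gradients of the full models.
"""

import numpy as np
import pytest

from swindaf3d._autodiff import Tensor, nn
from swindaf3d._autodiff import tensor as T

RNG = np.random.default_rng(7)


def numeric_grad(f, x, eps=1e-3):
    """Central-difference gradient of scalar f at float64 resolution."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_op(make_out, x, rtol=2e-2, atol=2e-3):
    xt = Tensor(x.astype(np.float32), requires_grad=True)
    out = make_out(xt)
    loss = T.tsum(out * out)
    loss.backward()

    def f(arr):
        o = make_out(Tensor(arr.astype(np.float32)))
        return float((o.data.astype(np.float64) ** 2).sum())

    ng = numeric_grad(f, x.copy())
    np.testing.assert_allclose(xt.grad, ng, rtol=rtol, atol=atol)


@pytest.mark.parametrize("op", [
    lambda x: T.exp(x),
    lambda x: T.log(x + 3.0),
    lambda x: T.sigmoid(x),
    lambda x: T.tanh(x),
    lambda x: T.gelu(x),
    lambda x: T.relu(x + 0.1),
    lambda x: T.sqrt(x + 3.0),
    lambda x: T.softmax(x, axis=-1),
    lambda x: T.power(x + 3.0, 1.7),
    lambda x: T.clip(x, -0.5, 0.5),
    lambda x: T.roll(x, (1, 2), (0, 1)),
    lambda x: T.pad(x, ((1, 2), (0, 1), (2, 0))),
    lambda x: x[1:3, :2, ::2],
    lambda x: T.tmean(x, axis=(0, 2), keepdims=True) * 3.0,
])
def test_elementwise_and_shape_ops(op):
    check_op(op, RNG.normal(size=(4, 3, 6)))


def test_matmul_broadcast_grad():
    a = RNG.normal(size=(2, 3, 4, 5))
    b = RNG.normal(size=(5, 6)).astype(np.float32)
    check_op(lambda x: T.matmul(x, Tensor(b)), a)
    # gradient w.r.t. the broadcast right operand
    at = Tensor(a.astype(np.float32))
    bt = Tensor(b, requires_grad=True)
    out = T.matmul(at, bt)
    T.tsum(out * out).backward()

    def f(arr):
        o = at.data.astype(np.float64) @ arr.astype(np.float64)
        return float((o ** 2).sum())

    ng = numeric_grad(f, b.astype(np.float64))
    np.testing.assert_allclose(bt.grad, ng, rtol=2e-2, atol=2e-3)


def test_concat_grad():
    a = RNG.normal(size=(3, 4))
    b = RNG.normal(size=(3, 2)).astype(np.float32)
    check_op(lambda x: T.concat([x, Tensor(b)], axis=1), a)


@pytest.mark.parametrize("dilation", [1, 2])
def test_conv3d_grad(dilation):
    rng = np.random.default_rng(100 + dilation)
    x = rng.normal(size=(5, 4, 4, 3)) * 0.5
    w = rng.normal(size=(3, 3, 3, 3, 2)).astype(np.float32) * 0.3
    bias = rng.normal(size=2).astype(np.float32)
    check_op(lambda t: T.conv3d(t, Tensor(w), Tensor(bias), dilation=dilation), x,
             rtol=2e-2, atol=2e-2)
    # weight gradient
    xt = Tensor(x.astype(np.float32))
    wt = Tensor(w, requires_grad=True)
    out = T.conv3d(xt, wt, Tensor(bias), dilation=dilation)
    T.tsum(out * out).backward()

    def f(arr):
        o = T.conv3d(xt, Tensor(arr.astype(np.float32)), Tensor(bias), dilation=dilation)
        return float((o.data.astype(np.float64) ** 2).sum())

    ng = numeric_grad(f, w.astype(np.float64))
    # float32 forward + central differences: slack absolute floor
    np.testing.assert_allclose(wt.grad, ng, rtol=2e-2, atol=2e-2)


def test_conv3d_matches_scipy():
    from scipy.ndimage import correlate
    x = RNG.normal(size=(6, 5, 4, 1)).astype(np.float32)
    w = RNG.normal(size=(3, 3, 3, 1, 1)).astype(np.float32)
    out = T.conv3d(Tensor(x), Tensor(w)).data[..., 0]
    ref = correlate(x[..., 0].astype(np.float64), w[..., 0, 0].astype(np.float64),
                    mode="constant")
    np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)


def test_upsample2_grad_and_values():
    x = RNG.normal(size=(4, 3, 2))
    check_op(lambda t: T.upsample2(T.upsample2(t, 0), 1), x)
    # interior values follow the half-voxel linear rule
    v = Tensor(np.arange(4, dtype=np.float32).reshape(4, 1, 1))
    up = T.upsample2(v, 0).data[:, 0, 0]
    np.testing.assert_allclose(up, [0.0, 0.25, 0.75, 1.25, 1.75, 2.25, 2.75, 3.0])


def test_maxpool2_grad():
    x = RNG.normal(size=(4, 4, 2, 3))
    check_op(lambda t: T.maxpool2(t), x, rtol=5e-2)


def test_gather0_grad_accumulates_repeats():
    table = Tensor(RNG.normal(size=(5, 2)).astype(np.float32), requires_grad=True)
    idx = np.array([[0, 1], [1, 4]])
    out = T.gather0(table, idx)
    T.tsum(out).backward()
    expected = np.zeros((5, 2), dtype=np.float32)
    np.add.at(expected, idx.reshape(-1), 1.0)
    np.testing.assert_array_equal(table.grad, expected)


def test_softmax_with_minus_inf_mask_is_exactly_zero():
    x = np.array([[1.0, 2.0, -np.inf], [0.0, -np.inf, -np.inf]], dtype=np.float32)
    s = T.softmax(Tensor(x), axis=-1).data
    assert s[0, 2] == 0.0 and s[1, 1] == 0.0 and s[1, 2] == 0.0
    np.testing.assert_allclose(s.sum(axis=-1), 1.0, rtol=1e-6)


@pytest.mark.parametrize("norm", ["layer", "group", "batch"])
def test_norm_layers_grad(norm):
    rng = np.random.default_rng(0)
    if norm == "layer":
        mod = nn.LayerNorm(6)
    elif norm == "group":
        mod = nn.GroupNorm(2, 6)
    else:
        mod = nn.BatchNorm(6)
    # normalisation leaves the squared-sum loss almost input-invariant, so
    # analytic gradients are tiny; the absolute floor must sit above the
    # float32 finite-difference noise (~5e-3 here)
    x = RNG.normal(size=(3, 2, 2, 6))
    check_op(lambda t: mod(t), x, rtol=5e-2, atol=1e-2)
    out = mod(Tensor(x.astype(np.float32)))
    # normalised pre-affine output has ~zero mean over the pooled axes
    assert abs(out.data.mean()) < 1e-4


def test_prelu_module_grad():
    mod = nn.PReLU(3, init=0.2)
    x = RNG.normal(size=(4, 3))
    check_op(lambda t: mod(t), x)
    xt = Tensor(x.astype(np.float32))
    T.tsum(mod(xt) * mod(xt)).backward()
    assert mod.alpha.grad is not None and np.all(np.isfinite(mod.alpha.grad))


def test_adam_descends_quadratic():
    from swindaf3d._autodiff.optim import Adam
    p = nn.Parameter(np.array([3.0, -2.0], dtype=np.float32))
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        loss = T.tsum(p * p)
        loss.backward()
        opt.step()
    assert np.all(np.abs(p.data) < 0.05)


def test_state_dict_roundtrip():
    rng = np.random.default_rng(1)
    m = nn.Sequential(nn.Linear(4, 8, rng), nn.LayerNorm(8), nn.Linear(8, 2, rng))
    state = m.state_dict()
    m2 = nn.Sequential(nn.Linear(4, 8, rng), nn.LayerNorm(8), nn.Linear(8, 2, rng))
    m2.load_state_dict(state)
    x = Tensor(RNG.normal(size=(5, 4)).astype(np.float32))
    np.testing.assert_array_equal(m(x).data, m2(x).data)
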