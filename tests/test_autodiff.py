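"""Gradient correctness of the autodiff core against finite differences."""

import numpy as np
import pytest

from csagp.nn import (Adam, BatchNorm1d, Conv2d, LayerNorm, Linear, Tensor,
                      concat, cross_entropy, stack)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def check_grad(build, x_data: np.ndarray, atol: float = 1e-6):
    """`build(tensor) -> scalar Tensor`; compares backward to central diff."""
    x = Tensor(x_data.copy(), requires_grad=True)
    out = build(x)
    out.backward()
    num = numerical_grad(lambda: float(build(Tensor(x.data)).data), x.data)
    np.testing.assert_allclose(x.grad, num, atol=atol, rtol=1e-4)


@pytest.mark.parametrize("expr", [
    lambda x: (x * 3.0 + 1.0).sum(),
    lambda x: ((x @ x.T) ** 2).sum(),
    lambda x: (x.exp() / (1.0 + x.exp())).sum(),
    lambda x: x.sigmoid().mean(),
    lambda x: x.gelu().sum(),
    lambda x: x.tanh().mean(axis=0).sum(),
    lambda x: x.softmax(axis=-1).log().sum(),
    lambda x: x.log_softmax(axis=-1)[0].sum(),
    lambda x: (x[1:] * x[:-1]).sum(),
    lambda x: x.reshape(-1).sum(),
    lambda x: x.transpose().mean(),
    lambda x: concat([x, x * 2.0], axis=0).sum(),
    lambda x: stack([x, x ** 2], axis=0).mean(),
    lambda x: (x / (x.sum(axis=1, keepdims=True) + 5.0)).sum(),
], ids=["affine", "matmul_sq", "logistic", "sigmoid", "gelu", "tanh_mean",
        "softmax_log", "log_softmax_row", "shift_prod", "reshape",
        "transpose", "concat", "stack", "normalized"])
def test_composite_gradients_match_finite_differences(rng, expr):
    x = rng.normal(size=(4, 3))
    check_grad(lambda t: expr(t), x, atol=1e-5)


def test_relu_and_leaky_relu_gradients(rng):
    # offset away from the kink where the derivative is undefined
    x = rng.normal(size=(5, 4))
    x[np.abs(x) < 0.1] += 0.2
    check_grad(lambda t: t.relu().sum(), x.copy())
    check_grad(lambda t: t.leaky_relu(0.2).sum(), x.copy())


def test_fancy_indexing_gradient_accumulates_duplicates():
    x = Tensor(np.arange(4.0), requires_grad=True)
    idx = np.array([0, 0, 2])
    out = x[idx].sum()
    out.backward()
    np.testing.assert_array_equal(x.grad, [2.0, 0.0, 1.0, 0.0])


def test_broadcast_add_unbroadcasts_gradient(rng):
    a = Tensor(rng.normal(size=(3, 1)), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 4)), requires_grad=True)
    ((a + b) ** 2).sum().backward()
    assert a.grad.shape == (3, 1)
    assert b.grad.shape == (1, 4)


def test_conv2d_gradients_match_finite_differences(rng):
    conv = Conv2d(2, 3, 3, rng, stride=2, padding=1)
    x_data = rng.normal(size=(2, 6, 6))

    def run(xd):
        return float(conv(Tensor(xd)).sum().data)

    x = Tensor(x_data.copy(), requires_grad=True)
    conv.zero_grad()
    conv(x).sum().backward()
    np.testing.assert_allclose(x.grad, numerical_grad(lambda: run(x.data), x.data),
                               atol=1e-6)
    num_w = numerical_grad(lambda: run(x.data), conv.weight.data)
    np.testing.assert_allclose(conv.weight.grad, num_w, atol=1e-6)
    num_b = numerical_grad(lambda: run(x.data), conv.bias.data)
    np.testing.assert_allclose(conv.bias.grad, num_b, atol=1e-6)


def test_conv2d_output_shape_matches_formula(rng):
    conv = Conv2d(3, 5, 7, rng, stride=4, padding=3)
    out = conv(Tensor(rng.normal(size=(3, 32, 32))))
    assert out.shape == (5, (32 + 6 - 7) // 4 + 1, (32 + 6 - 7) // 4 + 1)


def test_layernorm_and_batchnorm_gradients(rng):
    ln = LayerNorm(4)
    x = rng.normal(size=(3, 4))
    check_grad(lambda t: (ln(t) ** 2).sum(), x.copy(), atol=1e-5)

    bn = BatchNorm1d(4)
    bn.train()

    def build(t):
        bn._set_buffer("running_mean", np.zeros(4))
        bn._set_buffer("running_var", np.ones(4))
        return (bn(t) ** 2).sum()

    check_grad(build, rng.normal(size=(6, 4)), atol=1e-4)


def test_batchnorm_eval_uses_running_statistics(rng):
    bn = BatchNorm1d(3)
    bn.train()
    x = Tensor(rng.normal(size=(8, 3)) * 2 + 1)
    bn(x)
    bn.eval()
    y = bn(Tensor(np.zeros((2, 3))))
    expected = -bn.running_mean / np.sqrt(bn.running_var + bn.eps)
    np.testing.assert_allclose(y.data, np.broadcast_to(expected, (2, 3)))


def test_cross_entropy_matches_closed_form(rng):
    logits = Tensor(rng.normal(size=(3,)), requires_grad=True)
    loss = cross_entropy(logits, 1)
    p = np.exp(logits.data) / np.exp(logits.data).sum()
    np.testing.assert_allclose(float(loss.data), -np.log(p[1]))
    loss.backward()
    expected = p.copy()
    expected[1] -= 1.0
    np.testing.assert_allclose(logits.grad, expected, atol=1e-12)


def test_adam_decreases_simple_quadratic(rng):
    w = Tensor(rng.normal(size=(5,)), requires_grad=True)
    opt = Adam([w], lr=0.1)
    losses = []
    for _ in range(50):
        opt.zero_grad()
        loss = (w ** 2).sum()
        losses.append(float(loss.data))
        loss.backward()
        opt.step()
    assert losses[-1] < 1e-2 * losses[0]


def test_linear_layer_is_affine(rng):
    lin = Linear(3, 2, rng)
    x = rng.normal(size=(4, 3))
    np.testing.assert_allclose(lin(Tensor(x)).data,
                               x @ lin.weight.data + lin.bias.data)


def test_backward_is_deterministic(rng):
    x_data = rng.normal(size=(4, 4))

    def run():
        x = Tensor(x_data, requires_grad=True)
        ((x @ x).softmax(axis=-1) * x).sum().backward()
        return x.grad.copy()

    np.testing.assert_array_equal(run(), run())
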