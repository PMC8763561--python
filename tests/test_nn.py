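"""Numerical correctness of the autodiff engine (gradient checks)."""

import numpy as np
import pytest

from vesselseg import nn
from vesselseg.nn import functional as F
from vesselseg.nn.tensor import Tensor

RNG = np.random.default_rng(7)


def numerical_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn()
        x[i] = orig - eps
        fm = fn()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(make_out, tensors, tol=1e-6):
    """Check backward() of ``make_out()`` against central differences.

    ``make_out`` must be re-evaluable (it is called once per probed
    scalar); the output tensor is projected to a scalar through a fixed
    random weighting so every output entry influences the check.
    """
    proj = RNG.normal(size=make_out().shape)

    def scalar():
        return F.mean(F.mul(make_out(), proj))

    out = scalar()
    out.backward()
    analytic = [t.grad.copy() for t in tensors]
    for t in tensors:
        t.zero_grad()
    for t, ag in zip(tensors, analytic):
        ng = numerical_grad(lambda: scalar().item(), t.data)
        np.testing.assert_allclose(ag, ng, atol=tol, rtol=1e-4)


@pytest.mark.parametrize("dilation,groups", [(1, 1), (2, 1), (1, 4), (3, 4)])
def test_conv2d_gradients(dilation, groups):
    x = Tensor(RNG.normal(size=(2, 4, 5, 6)), requires_grad=True)
    w = Tensor(RNG.normal(size=(8, 4 // groups, 3, 3)), requires_grad=True)
    b = Tensor(RNG.normal(size=8), requires_grad=True)
    assert_grads_match(
        lambda: F.conv2d(x, w, b, dilation=dilation, groups=groups), [x, w, b])


@pytest.mark.parametrize("kshape", [(1, 3), (3, 1)])
def test_asymmetric_kernel_gradients(kshape):
    x = Tensor(RNG.normal(size=(1, 3, 4, 5)), requires_grad=True)
    w = Tensor(RNG.normal(size=(2, 3, *kshape)), requires_grad=True)
    assert_grads_match(lambda: F.conv2d(x, w), [x, w])


def test_up_conv_gradients():
    x = Tensor(RNG.normal(size=(2, 3, 4, 4)), requires_grad=True)
    w = Tensor(RNG.normal(size=(3, 5, 2, 2)), requires_grad=True)
    b = Tensor(RNG.normal(size=5), requires_grad=True)
    assert_grads_match(lambda: F.up_conv2x2(x, w, b), [x, w, b])


def test_pool_and_resize_gradients():
    x = Tensor(3 * RNG.normal(size=(2, 3, 6, 6)), requires_grad=True)
    assert_grads_match(lambda: F.max_pool2x2(x), [x], tol=1e-5)
    y = Tensor(RNG.normal(size=(2, 3, 5, 7)), requires_grad=True)
    assert_grads_match(lambda: F.avg_pool(y, 2), [y])
    z = Tensor(RNG.normal(size=(1, 2, 5, 4)), requires_grad=True)
    assert_grads_match(lambda: F.resize_bilinear(z, (9, 7)), [z])


def test_batchnorm_gradients_train_and_eval():
    x = Tensor(RNG.normal(size=(3, 4, 5, 5)), requires_grad=True)
    gamma = Tensor(RNG.normal(size=4), requires_grad=True)
    beta = Tensor(RNG.normal(size=4), requires_grad=True)

    def train_mode():
        rm, rv = np.zeros(4), np.ones(4)
        return F.batch_norm(x, gamma, beta, rm, rv, True)

    def eval_mode():
        rm, rv = np.full(4, 0.3), np.full(4, 1.7)
        return F.batch_norm(x, gamma, beta, rm, rv, False)

    assert_grads_match(train_mode, [x, gamma, beta], tol=1e-5)
    assert_grads_match(eval_mode, [x, gamma, beta])


def test_softmax_matmul_gradients():
    a = Tensor(RNG.normal(size=(4, 5)), requires_grad=True)
    b = Tensor(RNG.normal(size=(5, 4)), requires_grad=True)
    assert_grads_match(lambda: F.softmax(F.matmul(a, b), axis=-1), [a, b],
                       tol=1e-5)


def test_bce_gradients():
    logits = Tensor(RNG.normal(size=(3, 4)), requires_grad=True)
    target = (RNG.random((3, 4)) > 0.5).astype(float)

    def loss():
        return F.binary_cross_entropy(F.sigmoid(logits), target)

    out = loss()
    out.backward()
    analytic = logits.grad.copy()
    logits.zero_grad()
    ng = numerical_grad(lambda: loss().item(), logits.data)
    np.testing.assert_allclose(analytic, ng, atol=1e-5, rtol=1e-4)


def test_no_grad_builds_no_graph():
    x = Tensor(RNG.normal(size=(2, 2)), requires_grad=True)
    with nn.no_grad():
        y = F.relu(x)
    assert not y.requires_grad and y._backward is None
    y2 = F.relu(x)
    assert y2.requires_grad


def test_adam_descends_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = F.mean(F.mul(p, p))
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2
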