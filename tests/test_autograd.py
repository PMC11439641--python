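"""The autodiff tape: hand-computed values and finite-difference gradients."""

import numpy as np
import pytest

from fragdta.autograd import (
    Tensor,
    concat,
    conv2d,
    gather_rows,
    global_max_pool,
    matmul,
    maxpool2d,
    relu,
    scatter_sum,
    softplus,
)


def numeric_grad(f, tensors, eps=1e-2):
    """Central finite differences of a scalar-valued builder ``f``."""
    grads = []
    for t in tensors:
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = t.data[i]
            t.data[i] = old + eps
            a = float(f().data)
            t.data[i] = old - eps
            b = float(f().data)
            t.data[i] = old
            num[i] = (a - b) / (2 * eps)
        grads.append(num)
    return grads


def analytic_grad(f, tensors):
    for t in tensors:
        t.grad = None
    f().backward()
    return [t.grad.copy() for t in tensors]


class TestGradients:
    def test_conv_pool_chain_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 2, 6, 5)).astype(np.float32), requires_grad=True)
        w = Tensor(0.3 * rng.normal(size=(3, 2, 3, 3)).astype(np.float32), requires_grad=True)
        b = Tensor(0.1 * rng.normal(size=3).astype(np.float32), requires_grad=True)

        def f():
            return global_max_pool(relu(conv2d(x, w, b))).sum()

        ana = analytic_grad(f, [x, w, b])
        num = numeric_grad(f, [x, w, b])
        for a, n in zip(ana, num):
            assert np.abs(a - n).max() < 5e-2  # float32 finite-difference noise

    def test_maxpool_routes_gradient_to_argmax(self):
        x = Tensor(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4),
                   requires_grad=True)
        out = maxpool2d(x, 2)
        assert np.array_equal(out.data[0, 0], [[5, 7], [13, 15]])
        out.sum().backward()
        expected = np.zeros((4, 4), dtype=np.float32)
        expected[[1, 1, 3, 3], [1, 3, 1, 3]] = 1
        assert np.array_equal(x.grad[0, 0], expected)

    def test_scatter_gather_roundtrip_gradients(self):
        rng = np.random.default_rng(1)
        h = Tensor(rng.normal(size=(5, 3)).astype(np.float32), requires_grad=True)
        src = np.array([0, 1, 2, 3, 4, 0])
        dst = np.array([1, 0, 3, 2, 0, 4])

        def f():
            return (scatter_sum(gather_rows(h, src), dst, 5) * Tensor(np.ones((5, 3)))).sum()

        ana = analytic_grad(f, [h])
        num = numeric_grad(f, [h])
        assert np.abs(ana[0] - num[0]).max() < 5e-2


class TestHandComputedValues:
    def test_conv2d_single_pixel_reproduces_kernel(self):
        # one lit pixel at the center: 'same' cross-correlation response equals
        # the kernel flipped around the center
        x = np.zeros((1, 1, 5, 5), dtype=np.float32)
        x[0, 0, 2, 2] = 1.0
        w = np.arange(9, dtype=np.float32).reshape(1, 1, 3, 3)
        out = conv2d(Tensor(x), Tensor(w), Tensor(np.zeros(1, dtype=np.float32)))
        # brute-force oracle: out[i,j] = sum_{u,v} w[u,v] * x[i+u-1, j+v-1]
        expected = np.zeros((5, 5), dtype=np.float32)
        for i in range(5):
            for j in range(5):
                for u in range(3):
                    for v in range(3):
                        ii, jj = i + u - 1, j + v - 1
                        if 0 <= ii < 5 and 0 <= jj < 5:
                            expected[i, j] += w[0, 0, u, v] * x[0, 0, ii, jj]
        assert np.allclose(out.data[0, 0], expected)

    def test_softplus_values_and_stability(self):
        x = Tensor(np.array([0.0, 50.0, -50.0, 700.0, -700.0], dtype=np.float32))
        out = softplus(x).data
        assert np.isclose(out[0], np.log(2), atol=1e-7)
        assert np.isclose(out[1], 50.0, atol=1e-4)
        assert out[2] < 1e-6
        assert np.isfinite(out).all()

    def test_matmul_and_broadcast_add(self):
        a = Tensor(np.array([[1.0, 2.0]], dtype=np.float32), requires_grad=True)
        w = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32))
        b = Tensor(np.array([10.0, 20.0], dtype=np.float32), requires_grad=True)
        out = matmul(a, w) + b
        assert np.allclose(out.data, [[11.0, 22.0]])
        out.sum().backward()
        assert np.allclose(a.grad, [[1.0, 1.0]])
        assert np.allclose(b.grad, [1.0, 1.0])

    def test_concat_splits_gradient(self):
        a = Tensor(np.ones((2, 2), dtype=np.float32), requires_grad=True)
        b = Tensor(np.ones((2, 3), dtype=np.float32), requires_grad=True)
        out = concat([a, b], axis=1)
        assert out.shape == (2, 5)
        (out * Tensor(np.arange(10, dtype=np.float32).reshape(2, 5))).sum().backward()
        assert np.allclose(a.grad, [[0, 1], [5, 6]])
        assert np.allclose(b.grad, [[2, 3, 4], [7, 8, 9]])


def test_backward_requires_scalar():
    t = Tensor(np.ones((2, 2)), requires_grad=True)
    with pytest.raises(ValueError):
        (t * 2).backward()


def test_even_kernel_rejected():
    x = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
    w = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
    with pytest.raises(ValueError):
        conv2d(x, w, Tensor(np.zeros(1, dtype=np.float32)))
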