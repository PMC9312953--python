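"""Layer operators against independent brute-force oracles, plus the
straight-through behaviour of the binary encoding layer."""

import numpy as np
import pytest

from becg import nn

# ---------------------------------------------------------------------------
# brute-force oracles, written directly from the operator definitions


def oracle_conv1d(x, w, pad_left):
    """Sliding dot product; x (L, Cin), w (K, Cin, Cout)."""
    L, cin = x.shape
    k, _, cout = w.shape
    xp = np.zeros((L + k - 1, cin))
    xp[pad_left : pad_left + L] = x
    out = np.zeros((L, cout))
    for n in range(L):
        for j in range(cout):
            s = 0.0
            for tap in range(k):
                for i in range(cin):
                    s += xp[n + tap, i] * w[tap, i, j]
            out[n, j] = s
    return out


def oracle_maxpool(x, size):
    L, c = x.shape
    return np.array([[x[n * size : (n + 1) * size, j].max() for j in range(c)]
                     for n in range(L // size)])


def oracle_upsample(x, size):
    L, c = x.shape
    out = np.zeros((L * size, c))
    for n in range(L):
        out[n * size] = x[n]
    return out


class TestStepFunction:
    def test_piecewise_values_including_boundary(self):
        x = np.array([-1.0, -0.3, 0.0, 0.4, 2.0])
        np.testing.assert_array_equal(nn.step_activation(x), [0, 0, 1, 1, 1])

    def test_output_is_binary_for_any_input(self, rng):
        y = nn.step_activation(rng.normal(scale=10.0, size=1000))
        assert set(np.unique(y)) <= {0.0, 1.0}

    def test_surrogate_gradient_window(self):
        x = np.array([-0.6, -0.5, -0.1, 0.0, 0.49, 0.5, 0.6])
        np.testing.assert_array_equal(
            nn.step_surrogate_gradient(x), [0, 1, 1, 1, 1, 0, 0]
        )


class TestConvOracles:
    N_TRIALS = 40  # x3 operators exercised per trial -> >=100 oracle checks

    def test_conv_identity_kernel(self, rng):
        x = rng.normal(size=12)
        w = np.zeros(3)
        w[1] = 1.0
        np.testing.assert_allclose(nn.conv1d(x, w), x)

    def test_conv_zero_weights_tanh(self, rng):
        x = rng.normal(size=(9, 2))
        w = np.zeros((3, 2, 4))
        out = nn.conv1d(x, w, bias=np.zeros(4), activation="tanh")
        np.testing.assert_array_equal(out, np.zeros((9, 4)))

    def test_conv_matches_bruteforce(self, rng):
        for _ in range(self.N_TRIALS):
            L = int(rng.integers(4, 12))
            k = int(rng.integers(1, 7))
            cin = int(rng.integers(1, 4))
            cout = int(rng.integers(1, 4))
            x = rng.normal(size=(L, cin))
            w = rng.normal(size=(k, cin, cout))
            got = nn.conv1d(x, w)
            want = oracle_conv1d(x, w, (k - 1) // 2)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_tconv_matches_flipped_bruteforce(self, rng):
        for _ in range(self.N_TRIALS):
            L = int(rng.integers(4, 12))
            k = int(rng.integers(1, 7))
            cin = int(rng.integers(1, 4))
            cout = int(rng.integers(1, 4))
            x = rng.normal(size=(L, cin))
            w = rng.normal(size=(k, cin, cout))
            got = nn.tconv1d(x, w)
            want = oracle_conv1d(x, w[::-1], k - 1 - (k - 1) // 2)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_tconv_equals_conv_for_symmetric_kernel(self, rng):
        w = np.zeros((5, 1, 1))
        w[:, 0, 0] = [1.0, 2.0, 7.0, 2.0, 1.0]
        x = rng.normal(size=20)
        np.testing.assert_allclose(nn.tconv1d(x, w[:, 0, 0]), nn.conv1d(x, w[:, 0, 0]))

    def test_tconv_zero_input_bias_through_activation(self):
        w = np.ones((3, 1, 2))
        out = nn.tconv1d(np.zeros(8), w, bias=np.array([0.5, -0.5]), activation="tanh")
        np.testing.assert_allclose(out, np.tanh([[0.5, -0.5]] * 8))


class TestPoolingOracles:
    def test_maxpool_example(self):
        np.testing.assert_array_equal(nn.maxpool(np.array([1.0, 3.0, 2.0, 5.0])), [3, 5])

    def test_maxpool_constant_and_monotone(self):
        np.testing.assert_array_equal(nn.maxpool(np.full(8, 2.5)), np.full(4, 2.5))
        x = np.arange(10.0)
        np.testing.assert_array_equal(nn.maxpool(x), x[1::2])

    def test_maxpool_indivisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            nn.maxpool(np.arange(5.0), 2)

    def test_maxpool_matches_bruteforce(self, rng):
        for _ in range(40):
            c = int(rng.integers(1, 4))
            size = int(rng.integers(1, 4))
            L = size * int(rng.integers(2, 6))
            x = rng.normal(size=(L, c))
            np.testing.assert_allclose(nn.maxpool(x, size), oracle_maxpool(x, size))

    def test_upsample_example_and_inverse_on_support(self, rng):
        np.testing.assert_array_equal(
            nn.upsample_zero(np.array([3.0, 7.0])), [3, 0, 7, 0]
        )
        x = np.abs(rng.normal(size=(6, 2)))
        np.testing.assert_array_equal(nn.maxpool(nn.upsample_zero(x, 2), 2), x)
        np.testing.assert_array_equal(nn.upsample_zero(np.zeros(4)), np.zeros(8))

    def test_upsample_matches_bruteforce(self, rng):
        for _ in range(40):
            c = int(rng.integers(1, 4))
            size = int(rng.integers(1, 4))
            L = int(rng.integers(2, 8))
            x = rng.normal(size=(L, c))
            np.testing.assert_allclose(nn.upsample_zero(x, size), oracle_upsample(x, size))


class TestLinear:
    def test_identity_and_constant(self, rng):
        x = rng.normal(size=(3, 5))
        np.testing.assert_allclose(nn.linear_out(x, np.eye(5)), x)
        np.testing.assert_allclose(
            nn.linear_out(x, np.zeros((5, 2)), bias=np.array([1.5, -2.0])),
            np.tile([1.5, -2.0], (3, 1)),
        )

    def test_matches_matrix_product(self, rng):
        for _ in range(20):
            x = rng.normal(size=(4, 6))
            w = rng.normal(size=(6, 3))
            b = rng.normal(size=3)
            np.testing.assert_allclose(nn.linear_out(x, w, b), x @ w + b, rtol=1e-12)


class TestBackwardPasses:
    """Analytic backward vs central finite differences on small tensors."""

    @pytest.mark.parametrize(
        "factory,shape",
        [
            (lambda: nn.Conv1D(2, 3, 5, activation="tanh", batchnorm=True), (4, 8, 2)),
            (lambda: nn.TConv1D(2, 3, 4, activation="tanh", batchnorm=True), (4, 8, 2)),
            (lambda: nn.Dense(6, 4, activation="relu"), (5, 6)),
            (lambda: nn.MaxPool(2), (3, 8, 2)),
            (lambda: nn.UpsampleZero(2), (3, 4, 2)),
        ],
    )
    def test_input_gradient_matches_finite_differences(self, factory, shape, rng):
        layer = factory()
        layer.init(rng)
        x = rng.normal(size=shape)
        y = layer.forward(x, training=True)
        g_out = rng.normal(size=y.shape)
        gx = layer.backward(g_out)
        eps = 1e-6
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            yp = layer.forward(x, training=True)
            x[i] -= 2 * eps
            ym = layer.forward(x, training=True)
            x[i] += eps
            num[i] = ((yp - ym) * g_out).sum() / (2 * eps)
        np.testing.assert_allclose(gx, num, atol=1e-4 * max(1.0, np.abs(num).max()))

    def test_straight_through_masks_downstream_gradient(self, rng):
        bel = nn.BinaryEncoding()
        x = np.array([-0.7, -0.5, -0.2, 0.0, 0.3, 0.5, 0.8]).reshape(1, 7, 1)
        y = bel.forward(x, training=True)
        np.testing.assert_array_equal(y[0, :, 0], [0, 0, 0, 1, 1, 1, 1])
        g = bel.backward(np.ones_like(y))
        np.testing.assert_array_equal(g[0, :, 0], [0, 1, 1, 1, 1, 0, 0])

    def test_dropout_inverted_scaling_and_inference_identity(self, rng):
        drop = nn.Dropout(0.5)
        drop.reseed(rng)
        x = np.ones((200, 50))
        y = drop.forward(x, training=True)
        assert set(np.unique(y)) <= {0.0, 2.0}
        assert abs(y.mean() - 1.0) < 0.05
        np.testing.assert_array_equal(drop.forward(x, training=False), x)
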