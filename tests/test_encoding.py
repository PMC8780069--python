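"""Residual encoding (soft assignment + aggregation) and global suppression."""

import numpy as np
import pytest

from dsefbe.autograd import Tensor
from dsefbe.encoding import (ResidualEncoding, assign_weights, global_suppress,
                             global_suppression_mask, residual_encode)

from conftest import finite_difference, rel_err


def naive_encode(X, D, S):
    """Independent triple-loop evaluation of the assignment and aggregation."""
    m, c = X.shape
    n = D.shape[0]
    W = np.zeros((m, n))
    for i in range(m):
        logits = [-S[j] * np.sum((X[i] - D[j]) ** 2) for j in range(n)]
        e = np.exp(np.array(logits) - max(logits))
        W[i] = e / e.sum()
    E = np.zeros((n, c))
    for j in range(n):
        for i in range(m):
            E[j] += W[i, j] * (X[i] - D[j])
    return W, E


class TestAssignWeights:
    def test_single_codeword_gives_weight_one(self, rng):
        X = rng.normal(size=(5, 3))
        W = assign_weights(X, rng.normal(size=(1, 3)), np.array([0.7]))
        np.testing.assert_allclose(W.data, 1.0)

    def test_zero_scales_give_uniform_weights(self, rng):
        X = rng.normal(size=(4, 3))
        W = assign_weights(X, rng.normal(size=(5, 3)), np.zeros(5))
        np.testing.assert_allclose(W.data, 0.2, atol=1e-12)

    def test_two_codeword_hand_value(self):
        # x=0, d1=0, d2=1, unit scales: softmax(0, -1) = (0.7311, 0.2689)
        W = assign_weights(np.zeros((1, 1)), np.array([[0.0], [1.0]]),
                           np.ones(2))
        expect = np.array([1.0, np.exp(-1.0)])
        expect /= expect.sum()
        np.testing.assert_allclose(W.data[0], expect, atol=1e-4)
        np.testing.assert_allclose(W.data[0], [0.7311, 0.2689], atol=1e-4)

    def test_channel_mismatch_and_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            assign_weights(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)),
                           np.ones(2))
        bad = np.array([[np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            assign_weights(bad, np.zeros((1, 2)), np.ones(1))

    def test_rows_sum_to_one_on_random_inputs(self, rng):
        for _ in range(100):
            m, n, c = rng.integers(1, 10, size=3)
            W = assign_weights(rng.normal(size=(m, c), scale=3),
                               rng.normal(size=(n, c)),
                               rng.uniform(0, 2, size=n))
            np.testing.assert_allclose(W.data.sum(axis=1), 1.0, atol=1e-6)
            assert (W.data > 0).all()


class TestResidualEncode:
    def test_descriptors_equal_codeword_give_zero_row(self, rng):
        D = rng.normal(size=(3, 4))
        X = np.tile(D[1], (6, 1))
        W = assign_weights(X, D, np.ones(3))
        E = residual_encode(X, D, W)
        np.testing.assert_allclose(E.data[1], 0.0, atol=1e-12)

    def test_single_codeword_sums_residuals(self, rng):
        X = rng.normal(size=(5, 3))
        D = rng.normal(size=(1, 3))
        W = np.ones((5, 1))
        E = residual_encode(X, D, W)
        np.testing.assert_allclose(E.data[0], (X - D[0]).sum(axis=0), atol=1e-12)

    def test_two_codeword_hand_value(self):
        X = np.zeros((1, 1))
        D = np.array([[0.0], [1.0]])
        W = assign_weights(X, D, np.ones(2))
        E = residual_encode(X, D, W)
        w2 = np.exp(-1) / (1 + np.exp(-1))
        np.testing.assert_allclose(E.data, [[0.0], [-w2]], atol=1e-4)
        np.testing.assert_allclose(E.data[1, 0], -0.2689, atol=1e-4)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 17))
            n = int(rng.integers(1, 5))
            c = int(rng.integers(1, 6))
            X = rng.normal(size=(m, c))
            D = rng.normal(size=(n, c))
            S = rng.uniform(0, 2, size=n)
            W = assign_weights(X, D, S)
            E = residual_encode(X, D, W)
            W0, E0 = naive_encode(X, D, S)
            assert rel_err(W.data, W0) < 1e-9
            assert rel_err(E.data, E0) < 1e-9


class TestGlobalSuppress:
    def test_alpha_one_is_bitwise_identity(self, rng):
        E = rng.normal(size=(4, 6))
        out = global_suppress(E, 1.0)
        assert np.array_equal(out.data, E)

    def test_column_example_alpha_zero(self):
        E = np.array([[3.0], [1.0], [2.0]])
        out = global_suppress(E, 0.0)
        np.testing.assert_array_equal(out.data, [[0.0], [1.0], [2.0]])

    def test_ties_all_suppressed(self):
        E = np.array([[2.0], [2.0]])
        out = global_suppress(E, 0.5)
        np.testing.assert_array_equal(out.data, [[1.0], [1.0]])

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            global_suppress(np.ones((2, 2)), 1.5)

    def test_only_per_channel_maxima_change(self, rng):
        E = rng.normal(size=(6, 10))
        out = global_suppress(E, 0.3).data
        changed = out != E
        assert (changed.sum(axis=0) == 1).all()  # no ties in random floats
        assert np.array_equal(out[~changed], E[~changed])  # bitwise elsewhere
        assert (changed.argmax(axis=0) == E.argmax(axis=0)).all()

    def test_suppressed_peak_monotone_in_alpha(self, rng):
        # the suppressed entry moves monotonically from 0 back to the
        # original per-channel maximum as alpha goes 0 → 1
        E = rng.normal(size=(5, 3))
        alphas = np.linspace(0, 1, 11)
        for col in range(3):
            j = E[:, col].argmax()
            vals = np.array([global_suppress(E, a).data[j, col]
                             for a in alphas])
            mags = np.abs(vals)
            assert all(b >= a - 1e-12 for a, b in zip(mags, mags[1:]))
            assert np.all(np.sign(vals[1:]) == np.sign(E[j, col]))
            assert vals[-1] == E[j, col]

    def test_mask_structure(self, rng):
        E = rng.normal(size=(4, 5))
        P = global_suppression_mask(E, 0.25)
        assert set(np.unique(P)) <= {0.25, 1.0}
        assert (P.argmin(axis=0) == E.argmax(axis=0)).all()


class TestEncodingLayer:
    def test_forward_shape_contract(self, rng):
        layer = ResidualEncoding(16, n_codewords=8, alpha=0.5,
                                 rng=rng, dtype=np.float64)
        feat = Tensor(rng.normal(size=(2, 16, 3, 3)))
        out = layer(feat)
        assert out.shape == (2, 8, 16)

    def test_gradients_match_finite_differences(self, rng):
        m_h, m_w, c, n = 2, 2, 3, 2
        layer = ResidualEncoding(c, n_codewords=n, alpha=0.5,
                                 rng=rng, dtype=np.float64)
        x0 = rng.normal(size=(1, c, m_h, m_w))
        w0 = rng.normal(size=(1, n, c))  # random cotangent

        def loss_given(featmap=None, codewords=None, scales=None):
            if codewords is not None:
                layer.codewords.data = codewords
            if scales is not None:
                layer.scales.data = scales
            xin = featmap if featmap is not None else x0
            return float((layer(Tensor(xin)) * Tensor(w0)).sum().data)

        # analytic gradients
        layer.zero_grad()
        xt = Tensor(x0.copy(), requires_grad=True)
        (layer(xt) * Tensor(w0)).sum().backward()
        for analytic, fd in [
            (xt.grad, finite_difference(lambda v: loss_given(featmap=v), x0)),
            (layer.codewords.grad,
             finite_difference(lambda v: loss_given(codewords=v),
                               layer.codewords.data.copy())),
            (layer.scales.grad,
             finite_difference(lambda v: loss_given(scales=v),
                               layer.scales.data.copy())),
        ]:
            assert rel_err(analytic, fd) < 1e-4
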