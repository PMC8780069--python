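"""Factorized bilinear interaction, soft-thresholding, and position fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsefbe.autograd import Tensor
from dsefbe.fusion import (FBEFusion, factorized_bilinear, fbe_fuse,
                           fbe_param_count, full_bilinear_param_count,
                           soft_threshold)

from conftest import finite_difference, rel_err


def full_bilinear_oracle(x, e, U, V, Q, B):
    """Explicit per-component evaluation f_i = xᵀ W_i e + b_i with
    W_i = U_i V_iᵀ, where U_i = U diag(Q_row i scaling) — i.e. the unfactored
    form the low-rank layer is algebraically equal to."""
    o = Q.shape[1]
    out = np.zeros(o)
    for i in range(o):
        Wi = (U * Q[:, i]) @ V.T          # Σ_k q_ki u_k v_kᵀ
        out[i] = x @ Wi @ e + B[i]
    return out


class TestFactorizedBilinear:
    def test_zero_input_returns_bias(self, rng):
        U, V = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        Q, B = rng.normal(size=(2, 5)), rng.normal(size=5)
        out = factorized_bilinear(np.zeros(3), rng.normal(size=4), U, V, Q, B)
        np.testing.assert_allclose(out.data, B, atol=1e-12)

    def test_rank_one_hand_value(self):
        U = V = np.ones((2, 1))
        out = factorized_bilinear(np.ones(2), np.ones(2), U, V,
                                  np.ones((1, 1)), np.zeros(1))
        np.testing.assert_allclose(out.data, [4.0])  # (Uᵀx)(Vᵀe) = 2·2

    def test_matches_full_matrix_oracle(self, rng):
        for _ in range(100):
            a, b, k, o = (int(v) for v in rng.integers(1, 6, size=4))
            k = min(k, a, b)
            x, e = rng.normal(size=a), rng.normal(size=b)
            U, V = rng.normal(size=(a, k)), rng.normal(size=(b, k))
            Q, B = rng.normal(size=(k, o)), rng.normal(size=o)
            got = factorized_bilinear(x, e, U, V, Q, B).data
            want = full_bilinear_oracle(x, e, U, V, Q, B)
            assert rel_err(got, want) < 1e-9

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            factorized_bilinear(np.ones(3), np.ones(4),
                                rng.normal(size=(3, 2)), rng.normal(size=(4, 3)),
                                rng.normal(size=(2, 5)), np.zeros(5))

    def test_parameter_economy(self):
        a = b = o = 2048
        assert fbe_param_count(a, b, 2, o) < full_bilinear_param_count(a, b, o)
        assert fbe_param_count(a, b, 2, o) == a * 2 + b * 2 + 2 * o + o


class TestSoftThreshold:
    def test_lambda_zero_is_identity(self, rng):
        F = rng.normal(size=7)
        np.testing.assert_array_equal(soft_threshold(F, 0.0).data, F)

    def test_branch_values(self):
        out = soft_threshold(np.array([0.5, -0.5, 0.1]), 0.2)
        np.testing.assert_allclose(out.data, [0.3, -0.3, 0.0], atol=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(2), -0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(f=st.floats(-3, 3), lam=st.floats(0, 2))
    def test_minimizes_proximal_objective_on_grid(self, f, lam):
        grid = np.arange(-4, 4, 1e-4)
        obj = 0.5 * (grid - f) ** 2 + lam * np.abs(grid)
        z = float(soft_threshold(np.array([f]), lam).data[0])
        z_obj = 0.5 * (z - f) ** 2 + lam * abs(z)
        assert z_obj <= obj.min() + 1e-9
        assert abs(z - grid[obj.argmin()]) < 1e-4 + 1e-9

    def test_sparsity_monotone_in_lambda(self, rng):
        F = rng.normal(size=50)
        nnz = [np.count_nonzero(soft_threshold(F, lam).data)
               for lam in np.linspace(0, 4, 20)]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))
        assert np.count_nonzero(soft_threshold(F, 1e6).data) == 0


class TestFuse:
    def test_identical_positions_average_to_single_code(self, rng):
        a = b = 3
        U, V = rng.normal(size=(a, 2)), rng.normal(size=(b, 2))
        Q, B = rng.normal(size=(2, 4)), rng.normal(size=4)
        x, e = rng.normal(size=a), rng.normal(size=b)
        Xt = np.tile(x, (5, 1))
        Et = np.tile(e, (5, 1))
        fused = fbe_fuse(Xt, Et, U, V, Q, B, lam=0.1).data
        single = soft_threshold(factorized_bilinear(x, e, U, V, Q, B), 0.1).data
        np.testing.assert_allclose(fused, single / np.linalg.norm(single),
                                   atol=1e-9)
        assert abs(np.linalg.norm(fused) - 1.0) < 1e-9

    def test_two_position_hand_value(self):
        # pre-norm mean of (1,0) and (0,1) is (0.5, 0.5) → (0.7071, 0.7071)
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        mean = Z.mean(axis=0)
        normed = mean / np.linalg.norm(mean)
        np.testing.assert_allclose(normed, [0.70710678, 0.70710678])
        # same arithmetic through the layer: identity-like params, lam=0
        out = fbe_fuse(Z, np.ones((2, 2)),
                       np.eye(2), np.ones((2, 2)) * 0.5, np.eye(2),
                       np.zeros(2), lam=0.0).data
        np.testing.assert_allclose(out, [0.70710678, 0.70710678], atol=1e-9)

    def test_default_module_output_width(self, rng):
        layer = FBEFusion(a=64, b=64, k=2, o=64, rng=rng)
        out = layer(Tensor(rng.normal(size=(2, 9, 64)).astype(np.float32)),
                    Tensor(rng.normal(size=(2, 9, 64)).astype(np.float32)))
        assert out.shape == (2, 64)
        np.testing.assert_allclose(np.linalg.norm(out.data, axis=1), 1.0,
                                   atol=1e-5)

    def test_empty_positions_rejected(self, rng):
        layer = FBEFusion(a=4, b=4, k=2, o=3, rng=rng)
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((1, 0, 4))), Tensor(np.zeros((1, 0, 4))))

    def test_rank_exceeding_dims_rejected(self):
        with pytest.raises(ValueError):
            FBEFusion(a=2, b=3, k=4)

    def test_gradients_match_finite_differences(self, rng):
        a, b, k, o, L = 3, 3, 2, 2, 4
        params = {
            "U": rng.normal(size=(a, k)), "V": rng.normal(size=(b, k)),
            "Q": rng.normal(size=(k, o)), "B": rng.normal(size=o),
        }
        Xt = rng.normal(size=(L, a))
        Et = rng.normal(size=(L, b))
        lam = 0.05
        w0 = rng.normal(size=o)

        def run(**over):
            p = {**params, **{k2: v for k2, v in over.items() if k2 in params}}
            X_ = over.get("Xt", Xt)
            E_ = over.get("Et", Et)
            out = fbe_fuse(X_, E_, p["U"], p["V"], p["Q"], p["B"], lam)
            return float((out * Tensor(w0)).sum().data)

        # keep clear of the |F| = lam kinks so finite differences are valid
        F = ((Xt @ params["U"]) * (Et @ params["V"])) @ params["Q"] + params["B"]
        assert np.abs(np.abs(F) - lam).min() > 1e-3

        tensors = {name: Tensor(v.copy(), requires_grad=True)
                   for name, v in {**params, "Xt": Xt, "Et": Et}.items()}
        out = fbe_fuse(tensors["Xt"], tensors["Et"], tensors["U"], tensors["V"],
                       tensors["Q"], tensors["B"], lam)
        (out * Tensor(w0)).sum().backward()
        for name in ("U", "V", "Q", "B", "Xt", "Et"):
            base = params.get(name, {"Xt": Xt, "Et": Et}.get(name))
            fd = finite_difference(lambda v, n=name: run(**{n: v}), base.copy())
            assert rel_err(tensors[name].grad, fd) < 1e-4, name
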