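"""Factorized bilinear encoding (FBE) fusion of the two feature paths.

Full bilinear fusion of an ``a``-dimensional local feature x and a
``b``-dimensional global feature e computes, per output component i,

    f_i = xᵀ W_i e + b_i,          W_i ∈ R^{a×b},

which costs o·(a·b + 1) parameters.  FBE factorizes each interaction matrix
as W_i = U_i V_iᵀ with rank k ≤ min(a, b) and merges the per-component
factors into three shared matrices, giving

    F = Qᵀ (Uᵀx ∘ Vᵀe) + B,        U ∈ R^{a×k}, V ∈ R^{b×k}, Q ∈ R^{k×o},

at a·k + b·k + k·o + o parameters.  Each position's output is then sparsified
by the closed-form minimizer of the l1-penalized proximal objective
½‖z − F‖² + λ‖z‖₁ — one soft-thresholding (ISTA) step,

    Z = sign(F) ∘ max(|F| − λ, 0),

and the per-position codes are averaged and L2-normalized into the fused
vector fed to the classifier.  The shrinkage counters burstiness: a few
strong bilinear interactions would otherwise dominate the pooled code.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import Module, Parameter, l2_normalize

__all__ = ["factorized_bilinear", "soft_threshold", "fbe_fuse", "FBEFusion",
           "fbe_param_count", "full_bilinear_param_count"]


def fbe_param_count(a: int, b: int, k: int, o: int) -> int:
    return a * k + b * k + k * o + o


def full_bilinear_param_count(a: int, b: int, o: int) -> int:
    return o * (a * b + 1)


def factorized_bilinear(x, e, U, V, Q, B) -> Tensor:
    """Low-rank bilinear interaction F = Qᵀ(Uᵀx ∘ Vᵀe) + B.

    ``x`` and ``e`` may carry arbitrary leading (batch/position) axes; the
    contraction acts on the trailing feature axis.
    """
    x, e = as_tensor(x), as_tensor(e)
    U, V, Q, B = as_tensor(U), as_tensor(V), as_tensor(Q), as_tensor(B)
    a, k = U.shape
    b, k2 = V.shape
    k3, o = Q.shape
    if k != k2 or k != k3:
        raise ValueError(f"rank mismatch: U k={k}, V k={k2}, Q k={k3}")
    if x.shape[-1] != a or e.shape[-1] != b:
        raise ValueError(f"feature dims ({x.shape[-1]}, {e.shape[-1]}) do not "
                         f"match factors ({a}, {b})")
    if B.shape != (o,):
        raise ValueError(f"bias must have shape ({o},), got {B.shape}")
    return ((x @ U) * (e @ V)) @ Q + B


def soft_threshold(F, lam: float) -> Tensor:
    """Closed-form l1-proximal shrinkage sign(F) ∘ max(|F| − λ, 0)."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    F = as_tensor(F)
    if not np.all(np.isfinite(F.data)):
        raise ValueError("soft_threshold input contains non-finite entries")
    return F.soft_threshold(lam)


def fbe_fuse(Xt, Et, U, V, Q, B, lam: float) -> Tensor:
    """Fuse aligned position features into one L2-normalized vector.

    Parameters
    ----------
    Xt : (..., L, a) local-path features, one row per position.
    Et : (..., L, b) global-path features after stretching to L positions.

    Returns
    -------
    Tensor of shape (..., o) with unit Euclidean norm (when nonzero).
    """
    Xt, Et = as_tensor(Xt), as_tensor(Et)
    if Xt.shape[:-1] != Et.shape[:-1]:
        raise ValueError(f"position axes differ: {Xt.shape[:-1]} vs {Et.shape[:-1]}")
    if Xt.shape[-2] == 0:
        raise ValueError("need at least one aligned position")
    F = factorized_bilinear(Xt, Et, U, V, Q, B)
    Z = soft_threshold(F, lam)
    return l2_normalize(Z.mean(axis=-2), axis=-1)


class FBEFusion(Module):
    """Trainable FBE layer.

    Defaults follow the best reported setting of the method: rank ``k=2``,
    output dimension ``o`` equal to the channel width (2048 for a 50-layer
    backbone), shrinkage ``lam=0.01``.  U, V, Q use variance-scaled uniform
    initialization; the bias starts at zero.
    """

    def __init__(self, a: int, b: int, k: int = 2, o: int | None = None,
                 lam: float = 0.01, rng=None, dtype=np.float32):
        super().__init__()
        if k > min(a, b):
            raise ValueError(f"rank k={k} exceeds min(a, b)={min(a, b)}")
        if lam < 0:
            raise ValueError(f"lambda must be non-negative, got {lam}")
        o = a if o is None else o
        rng = rng or np.random.default_rng()

        def init(rows, cols):
            bound = 1.0 / np.sqrt(rows)
            return rng.uniform(-bound, bound, size=(rows, cols)).astype(dtype)

        self.U = Parameter(init(a, k))
        self.V = Parameter(init(b, k))
        self.Q = Parameter(init(k, o))
        self.B = Parameter(np.zeros(o, dtype=dtype))
        self.lam = float(lam)
        self.k, self.o = k, o

    def forward(self, Xt: Tensor, Et: Tensor) -> Tensor:
        return fbe_fuse(Xt, Et, self.U, self.V, self.Q, self.B, self.lam)
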