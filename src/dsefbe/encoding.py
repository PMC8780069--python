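"""Dictionary-based residual encoding with global orderless feature suppression.

A convolutional feature map of shape ``c × h × w`` is flattened into ``m = h·w``
visual descriptors ``x_i ∈ R^c``.  A learnable codebook ``D = {d_1 … d_n}`` with
per-codeword scaling factors ``s_j`` soft-assigns every descriptor to every
codeword,

    ω_ij = softmax_j( −s_j · ‖x_i − d_j‖² ),

and aggregates the weighted residuals into one encoding vector per codeword,

    e_j = Σ_i ω_ij (x_i − d_j),

giving an orderless (spatially unordered) ``n × c`` representation ``E``.
Because background and texture dominate the strongest responses in brain MRI,
the global suppression step attenuates, independently per channel, the
entries of ``E`` attaining the per-channel maximum by a factor ``alpha`` in
``[0, 1]`` (``alpha = 1`` disables suppression).  Ties at the maximum are all
suppressed, which keeps the operation deterministic and order-independent.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import Module, Parameter, softmax

__all__ = [
    "assign_weights", "residual_encode", "global_suppress",
    "global_suppression_mask", "ResidualEncoding",
]


def _check_finite(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")


def _residual_sq_norms(X: Tensor, D: Tensor) -> Tensor:
    """Pairwise squared Euclidean norms ‖x_i − d_j‖², shape (..., m, n)."""
    diff = X.reshape(*X.shape[:-1], 1, X.shape[-1]) - D  # (..., m, n, c)
    return (diff ** 2).sum(axis=-1)


def assign_weights(X, D, S) -> Tensor:
    """Soft-assignment weights ω_ij of descriptors to codewords.

    Parameters
    ----------
    X : (m, c) or (B, m, c) array or Tensor of visual descriptors.
    D : (n, c) codebook.
    S : (n,) non-negative scaling factors, one per codeword.

    Returns
    -------
    Tensor of shape (..., m, n); each row is a probability distribution
    over the n codewords.
    """
    X, D, S = as_tensor(X), as_tensor(D), as_tensor(S)
    if X.shape[-1] != D.shape[-1]:
        raise ValueError(f"channel mismatch: descriptors c={X.shape[-1]}, "
                         f"codebook c={D.shape[-1]}")
    for name, t in (("descriptors", X), ("codebook", D), ("scales", S)):
        _check_finite(name, t.data)
    sq = _residual_sq_norms(X, D)            # (..., m, n)
    return softmax(sq * (-S), axis=-1)


def residual_encode(X, D, W) -> Tensor:
    """Aggregated residual encoding E with rows e_j = Σ_i ω_ij (x_i − d_j)."""
    X, D, W = as_tensor(X), as_tensor(D), as_tensor(W)
    m, c = X.shape[-2], X.shape[-1]
    n = D.shape[0]
    if W.shape[-2:] != (m, n) or D.shape[-1] != c:
        raise ValueError(f"inconsistent shapes: X {X.shape}, D {D.shape}, W {W.shape}")
    # e_j = Σ_i ω_ij x_i − (Σ_i ω_ij) d_j ; the softmax rows sum to 1 but the
    # explicit column sum keeps the expression exact for arbitrary weights.
    wx = W.transpose(*range(W.ndim - 2), W.ndim - 1, W.ndim - 2) @ X   # (..., n, c)
    wsum = W.sum(axis=-2)                                              # (..., n)
    return wx - wsum.reshape(*wsum.shape, 1) * D


def global_suppression_mask(E: np.ndarray, alpha: float) -> np.ndarray:
    """{alpha, 1} mask marking, per channel (column), all entries attaining
    the column maximum of E over the codeword axis."""
    is_max = E == E.max(axis=-2, keepdims=True)
    return np.where(is_max, alpha, 1.0).astype(E.dtype)


def global_suppress(E, alpha: float) -> Tensor:
    """Scale the per-channel maxima of the encoding by ``alpha``.

    The mask is treated as a constant of the backward pass (the max location
    is piecewise constant in E), so gradients at suppressed entries are
    scaled by ``alpha`` and pass through unchanged elsewhere.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    E = as_tensor(E)
    _check_finite("encoding", E.data)
    if alpha == 1.0:
        return E  # identity: matches the no-suppression baseline bitwise
    return E * Tensor(global_suppression_mask(E.data, alpha))


class ResidualEncoding(Module):
    """Trainable encoding layer: flatten → assign → aggregate → suppress.

    Codewords are initialized uniformly in [−1/√n, 1/√n] and scaling factors
    uniformly in (0, 1], the common practice for residual encoding layers.
    """

    def __init__(self, channels: int, n_codewords: int = 8, alpha: float = 0.0,
                 rng=None, dtype=np.float32):
        super().__init__()
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(n_codewords)
        self.codewords = Parameter(
            rng.uniform(-bound, bound, size=(n_codewords, channels)).astype(dtype))
        self.scales = Parameter(
            rng.uniform(np.finfo(np.float32).tiny, 1.0, size=n_codewords).astype(dtype))
        self.n_codewords = n_codewords
        self.channels = channels
        self.alpha = alpha

    def forward(self, featmap: Tensor) -> Tensor:
        """featmap: (B, c, h, w) → suppressed encoding (B, n, c)."""
        featmap = as_tensor(featmap)
        B, c = featmap.shape[0], featmap.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        m = featmap.shape[2] * featmap.shape[3]
        X = featmap.reshape(B, c, m).transpose(0, 2, 1)        # (B, m, c)
        W = assign_weights(X, self.codewords, self.scales)
        E = residual_encode(X, self.codewords, W)
        return global_suppress(E, self.alpha)
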