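"""Stochastic local spatial feature suppression.

During training, each channel of the convolutional feature map is selected
independently with probability ``p`` (a Bernoulli draw).  A selected channel
undergoes ``ct`` successive peak-suppression passes, where ``ct`` is drawn
uniformly from {1, …, ct_max}: each pass builds a non-maximal mask that is
``beta`` at the positions attaining the channel maximum and 1 elsewhere, and
multiplies the channel by it.  Recomputing the mask from the running map each
pass means the ``ct`` largest peaks are each attenuated once, pushing the
network to spread attention beyond the most salient location.  At inference
the layer is the identity, so every feature contributes to the final score.

The alternative reading — applying the mask of the original map ``ct`` times,
i.e. scaling the single peak by ``beta**ct`` — is available via
``recompute_mask=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import Module

__all__ = ["LocalSuppressionConfig", "make_local_mask", "local_suppress",
           "LocalSuppression"]


@dataclass
class LocalSuppressionConfig:
    beta: float = 0.1
    p: float = 0.5
    ct_max: int = 3
    recompute_mask: bool = True

    def validate(self) -> "LocalSuppressionConfig":
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.ct_max < 1:
            raise ValueError(f"ct_max must be >= 1, got {self.ct_max}")
        return self


def make_local_mask(x: np.ndarray) -> np.ndarray:
    """Boolean mask marking every position attaining max(x) (ties included)."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("cannot build a suppression mask for an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("spatial map contains non-finite entries")
    return x == x.max(axis=-1, keepdims=True)


def _draw_plan(shape, cfg: LocalSuppressionConfig, rng: np.random.Generator):
    """Per-channel (selected?, loop count) draws for a (..., c, m) map."""
    lead = shape[:-1]
    selected = rng.random(lead) < cfg.p
    counts = rng.integers(1, cfg.ct_max + 1, size=lead)
    return selected, counts


def local_suppress(X, cfg: LocalSuppressionConfig, training: bool,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Apply stochastic peak suppression to a (..., c, m) spatial map.

    In eval mode (``training=False``) the input is returned unchanged.  All
    randomness comes from ``rng``; the caller owns the stream so runs are
    reproducible.
    """
    cfg.validate()
    X = as_tensor(X)
    if not training:
        return X
    if rng is None:
        rng = np.random.default_rng()
    selected, counts = _draw_plan(X.shape, cfg, rng)
    if cfg.beta == 1.0 or not selected.any():
        # no channel picked, or beta=1 makes every mask all-ones
        return X
    mask = np.ones(X.shape, dtype=X.dtype)
    running = X.data.copy()
    ct_eff = np.where(selected, counts, 0)
    for _ in range(int(ct_eff.max())):
        active = ct_eff > 0
        src = running if cfg.recompute_mask else X.data
        peak = make_local_mask(src) & active[..., None]
        step = np.where(peak, X.data.dtype.type(cfg.beta), X.data.dtype.type(1.0))
        mask *= step
        running *= step
        ct_eff = np.maximum(ct_eff - 1, 0)
    # mask is a constant of the backward pass: gradients at suppressed
    # positions are scaled by the applied attenuation, 1 elsewhere.
    return X * Tensor(mask)


class LocalSuppression(Module):
    """Module wrapper; the training loop injects the shared random stream."""

    def __init__(self, cfg: LocalSuppressionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = (cfg or LocalSuppressionConfig()).validate()
        self.rng = rng or np.random.default_rng()

    def forward(self, X: Tensor) -> Tensor:
        return local_suppress(X, self.cfg, training=self.training, rng=self.rng)
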