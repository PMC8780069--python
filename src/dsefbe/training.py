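"""Training protocol: transfer-learning parameter groups, Adam, plateau
learning-rate halving, and split construction.

The protocol: Adam at an initial learning rate of 1e-4, halved whenever the
loss fails to improve for two consecutive epochs; layers added on top of the
(possibly pretrained) backbone train at ten times the backbone rate.  Splits
are stratified by default — the public four-class dataset this emulates is
imbalanced (500 vs 937 per class), which makes unstratified small test sets
unstable.  No data augmentation is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from . import nn
from .network import DSEFBENet, normalize_images

__all__ = ["SplitSpec", "TrainConfig", "LRState", "make_split", "lr_step",
           "param_groups", "Adam", "train"]


# ---------------------------------------------------------------------- splits
@dataclass
class SplitSpec:
    mode: str = "ratio"                  # "ratio" or "kfold"
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    k: int = 5
    stratified: bool = True
    seed: int = 0

    def validate(self) -> "SplitSpec":
        if self.mode not in ("ratio", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "ratio":
            fr = (self.train_frac, self.val_frac, self.test_frac)
            if not all(0 < f < 1 for f in fr) or abs(sum(fr) - 1) > 1e-9:
                raise ValueError("fractions must lie in (0,1) and sum to 1")
        elif self.k < 2:
            raise ValueError("k-fold requires k >= 2")
        return self


def make_split(labels, spec: SplitSpec):
    """Deterministic index sets from class labels.

    Ratio mode returns ``(train_idx, val_idx, test_idx)``; k-fold mode returns
    a list of ``(train_idx, test_idx)`` pairs.  Stratification preserves class
    proportions within rounding.
    """
    spec.validate()
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    if spec.mode == "kfold":
        if spec.stratified and counts.min() < spec.k:
            raise ValueError(f"class with {counts.min()} samples cannot be "
                             f"stratified into {spec.k} folds")
        cv = (StratifiedKFold if spec.stratified else KFold)(
            n_splits=spec.k, shuffle=True, random_state=spec.seed)
        return [(tr, te) for tr, te in cv.split(np.zeros(n), labels)]
    min_needed = max(2, int(np.ceil(1.0 / min(spec.val_frac, spec.test_frac))))
    if spec.stratified and counts.min() < min_needed:
        raise ValueError(f"class with only {counts.min()} samples cannot fill "
                         f"all three subsets at the requested fractions")
    idx = np.arange(n)
    strat = labels if spec.stratified else None
    n_test = int(round(n * spec.test_frac))
    n_val = int(round(n * spec.val_frac))
    trainval, test = train_test_split(
        idx, test_size=n_test, stratify=strat, random_state=spec.seed)
    strat2 = labels[trainval] if spec.stratified else None
    train, val = train_test_split(
        trainval, test_size=n_val, stratify=strat2, random_state=spec.seed)
    return np.sort(train), np.sort(val), np.sort(test)


# ------------------------------------------------------------------ LR schedule
@dataclass
class TrainConfig:
    base_lr: float = 1e-4
    new_layer_lr_mult: float = 10.0
    plateau_patience: int = 2
    lr_decay: float = 0.5
    epochs: int = 50
    batch_size: int = 32
    early_stop_patience: int = 10
    improvement_tol: float = 1e-6
    schedule_on: str = "train_loss"        # or "val_loss"
    freeze_backbone: bool = False
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if min(self.base_lr, self.new_layer_lr_mult, self.epochs,
               self.batch_size, self.plateau_patience) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not 0 < self.lr_decay < 1:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.schedule_on not in ("train_loss", "val_loss"):
            raise ValueError("schedule_on must be 'train_loss' or 'val_loss'")
        return self


@dataclass
class LRState:
    current_lr: float
    epochs_without_improvement: int = 0
    best_loss: float = field(default=np.inf)


def lr_step(state: LRState, epoch_loss: float, cfg: TrainConfig) -> LRState:
    """Plateau rule: two consecutive non-improving epochs halve the rate."""
    if not np.isfinite(epoch_loss):
        raise ValueError("non-finite epoch loss")
    if epoch_loss < state.best_loss - cfg.improvement_tol:
        return LRState(state.current_lr, 0, epoch_loss)
    stalled = state.epochs_without_improvement + 1
    if stalled >= cfg.plateau_patience:
        return LRState(state.current_lr * cfg.lr_decay, 0, state.best_loss)
    return LRState(state.current_lr, stalled, state.best_loss)


# ------------------------------------------------------------------- optimizer
def param_groups(model: DSEFBENet, cfg: TrainConfig):
    """Two optimizer groups: backbone at base_lr, new head layers at 10×.

    Every trainable parameter lands in exactly one group.
    """
    backbone, head = [], []
    for name, p in model.named_parameters():
        (backbone if name.startswith("backbone.") else head).append((name, p))
    if not head:
        raise ValueError("model exposes no head parameters to train")
    groups = []
    if not cfg.freeze_backbone:
        groups.append({"name": "backbone", "params": backbone,
                       "lr_scale": 1.0})
    groups.append({"name": "head", "params": head,
                   "lr_scale": cfg.new_layer_lr_mult})
    return groups


class Adam:
    """Adaptive-moment optimizer over named parameter groups."""

    def __init__(self, groups, base_lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.groups = groups
        self.base_lr = base_lr
        self.betas, self.eps = betas, eps
        self.t = 0
        self.state = {}
        for g in groups:
            for name, p in g["params"]:
                self.state[name] = (np.zeros_like(p.data),
                                    np.zeros_like(p.data))

    def step(self, lr: float | None = None):
        lr = self.base_lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for g in self.groups:
            glr = lr * g["lr_scale"]
            for name, p in g["params"]:
                if p.grad is None:
                    continue
                m, v = self.state[name]
                grad = p.grad
                m[...] = b1 * m + (1 - b1) * grad
                v[...] = b2 * v + (1 - b2) * grad * grad
                p.data -= glr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for g in self.groups:
            for _, p in g["params"]:
                p.grad = None


# ------------------------------------------------------------------- train loop
def train(model: DSEFBENet, images, labels, split, cfg: TrainConfig,
          image_stats: tuple | None = None, verbose: bool = False):
    """Fit the model with cross-entropy and the plateau-halving Adam protocol.

    Parameters
    ----------
    images : (N, 1 or 3, H, W) array in [0, 255] or [0, 1].
    labels : (N,) integer class ids.
    split : (train_idx, val_idx, test_idx) or (train_idx, val_idx).
    image_stats : optional (mean, std) per channel for input normalization;
        defaults to ImageNet statistics (pretrained convention).

    Returns
    -------
    (model, history) — the model carries the best-validation weights; history
    is a list of dicts with epoch, train_loss, val_acc and lr.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    model.local_suppression.rng = np.random.default_rng(rng.integers(2 ** 31))
    labels = np.asarray(labels)
    train_idx, val_idx = np.asarray(split[0]), np.asarray(split[1])
    if image_stats is not None:
        mean, std = (np.atleast_1d(np.asarray(s, dtype=np.float32))
                     for s in image_stats)
        model.input_mean, model.input_std = mean, std
    elif not model.cfg.pretrained:
        # random-init backbone: normalize with training-set statistics
        sample = np.asarray(images[train_idx], dtype=np.float32)
        if sample.max() > 1.5:
            sample = sample / 255.0
        model.input_mean = sample.mean(axis=(0, 2, 3))
        model.input_std = np.maximum(sample.std(axis=(0, 2, 3)), 1e-6)
    X = model.normalize(images)

    groups = param_groups(model, cfg)
    opt = Adam(groups, cfg.base_lr)
    state = LRState(cfg.base_lr)
    history = []
    best_val, best_state, stall = -np.inf, None, 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = train_idx[order[start:start + cfg.batch_size]]
            logits = model.forward(X[batch])
            loss = nn.cross_entropy(logits, labels[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=state.current_lr)
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))

        model.eval()
        val_logits = model.predict_scores(X[val_idx])
        val_acc = float(np.mean(np.argmax(val_logits, axis=1) == labels[val_idx]))
        val_loss = float(nn.cross_entropy(_wrap(val_logits),
                                          labels[val_idx]).data)

        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_acc": val_acc, "val_loss": val_loss,
                        "lr": state.current_lr})
        if verbose:
            print(f"epoch {epoch:3d}  loss {train_loss:.4f}  "
                  f"val_acc {val_acc:.4f}  lr {state.current_lr:.2e}")

        sched_loss = train_loss if cfg.schedule_on == "train_loss" else val_loss
        state = lr_step(state, sched_loss, cfg)

        if val_acc > best_val:
            best_val, best_state, stall = val_acc, model.state_dict(), 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state, strict=True)
    return model, history


def _wrap(arr):
    from .autograd import Tensor
    return Tensor(arr)
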