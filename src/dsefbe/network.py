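"""End-to-end model assembly.

The classification network is: backbone CNN → dual-suppression encoding (DSE)
block → stretch → factorized bilinear encoding (FBE) fusion → linear
classifier.  For a 224×224 input the 50-layer backbone emits a 7×7×2048
feature map; the DSE block branches it into a spatially ordered local path
(49×2048, after stochastic local suppression in training) and an orderless
encoding path (8×2048 by default, after global suppression).  A learned
affine map along the codeword axis stretches the encoding to 49×2048 so the
two paths align position-wise for fusion; the fused 2048-vector is
L2-normalized and classified by a fully connected layer.

The contribution is the head, not the backbone: any module emitting a
``c × h × w`` map works, and the test suite uses a small random-init CNN so
no pretrained weights are ever required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, as_tensor
from . import nn
from .encoding import ResidualEncoding
from .fusion import FBEFusion
from .spatial import LocalSuppression, LocalSuppressionConfig

__all__ = ["ModelConfig", "StretchGlobal", "DSEFBENet", "build_model",
           "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1

# grayscale replication uses the same per-channel statistics
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class ModelConfig:
    backbone_name: str = "resnet50"
    n_classes: int = 4
    n_codewords: int = 8
    alpha: float = 0.0            # global suppression factor (best reported)
    beta: float = 0.1             # local suppression factor (best reported)
    p: float = 0.5                # per-channel Bernoulli selection probability
    ct_max: int = 3               # upper bound of suppression passes
    rank_k: int = 2
    output_dim_o: int | None = None   # None → backbone channel width
    lam: float = 0.01
    pretrained: bool = False
    input_size: int = 224
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        LocalSuppressionConfig(self.beta, self.p, self.ct_max).validate()
        if self.n_codewords < 1 or self.input_size < 32 or self.input_size % 32:
            raise ValueError("invalid n_codewords or input_size "
                             "(size must be a positive multiple of 32)")
        return self


# --------------------------------------------------------------------- backbones
class Bottleneck(nn.Module):
    """1×1 → 3×3 → 1×1 residual block with average-pool downsampling."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng, dtype):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(mid_ch, dtype=dtype)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=1, padding=1, rng=rng,
                               dtype=dtype)
        self.bn2 = nn.BatchNorm2d(mid_ch, dtype=dtype)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng=rng, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.stride = stride
        if stride > 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng=rng, dtype=dtype)
            self.bn_proj = nn.BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        if self.stride > 1:
            out = out.avg_pool2d(self.stride)
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        if self.proj is not None:
            sc = x.avg_pool2d(self.stride) if self.stride > 1 else x
            sc = self.bn_proj(self.proj(sc))
        else:
            sc = x
        return (out + sc).relu()


class ResNet50Backbone(nn.Module):
    """50-layer residual backbone with a deep 3-conv stem; 224 → 7×7×2048."""

    out_channels = 2048

    def __init__(self, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stem = nn.Sequential(
            nn.Conv2d(3, 32, 3, stride=2, padding=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(32, dtype=dtype), nn.ReLU(),
            nn.Conv2d(32, 32, 3, padding=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(32, dtype=dtype), nn.ReLU(),
            nn.Conv2d(32, 64, 3, padding=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(64, dtype=dtype), nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        )
        blocks = []
        in_ch = 64
        for n_blocks, mid, out_ch, first_stride in (
                (3, 64, 256, 1), (4, 128, 512, 2),
                (6, 256, 1024, 2), (3, 512, 2048, 2)):
            for b in range(n_blocks):
                blocks.append(Bottleneck(in_ch, mid, out_ch,
                                         first_stride if b == 0 else 1,
                                         rng, dtype))
                in_ch = out_ch
        self.blocks = blocks

    def forward(self, x):
        x = self.stem(x)
        for blk in self.blocks:
            x = blk(x)
        return x


class TinyBackbone(nn.Module):
    """Small strided CNN emitting a 32×7×7 map from 224×224 inputs.

    Stands in for the 50-layer backbone in tests and desk-scale training;
    all head shapes scale with its channel width.
    """

    out_channels = 32

    def __init__(self, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        # low-pass front end: a fixed 4×4 average pool preserves lesion
        # contrast at initialization, so the head sees class signal from the
        # first step even with a random-init backbone
        self.net = nn.Sequential(
            nn.AvgPool2d(4),
            nn.Conv2d(3, 24, 5, stride=2, padding=2, rng=rng, dtype=dtype),
            nn.BatchNorm2d(24, dtype=dtype), nn.ReLU(),
            nn.Conv2d(24, 32, 3, stride=2, padding=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(32, dtype=dtype), nn.ReLU(),
            nn.Conv2d(32, 32, 3, stride=2, padding=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(32, dtype=dtype), nn.ReLU(),
        )

    def forward(self, x):
        return self.net(x)


BACKBONES = {"resnet50": ResNet50Backbone, "tiny": TinyBackbone}


# ------------------------------------------------------------------------ head
class StretchGlobal(nn.Module):
    """Learned affine map along the codeword axis (n → L), shared across
    channels; aligns the orderless encoding with the L spatial positions."""

    def __init__(self, n_codewords: int, n_positions: int, rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(n_codewords)
        self.weight = nn.Parameter(
            rng.uniform(-bound, bound, size=(n_positions, n_codewords)).astype(dtype))
        self.bias = nn.Parameter(np.zeros(n_positions, dtype=dtype))
        self.n_codewords, self.n_positions = n_codewords, n_positions

    def forward(self, E: Tensor) -> Tensor:
        """(…, n, c) → (…, L, c)."""
        E = as_tensor(E)
        if E.shape[-2] != self.n_codewords:
            raise ValueError(f"expected {self.n_codewords} codewords, "
                             f"got {E.shape[-2]}")
        out = self.weight @ E
        return out + self.bias.reshape(self.n_positions, 1)


class DSEFBENet(nn.Module):
    """Backbone → DSE block → stretch → FBE fusion → classifier."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg = cfg.validate()
        if cfg.backbone_name not in BACKBONES:
            raise ValueError(f"unknown backbone '{cfg.backbone_name}'; "
                             f"available: {sorted(BACKBONES)}")
        rng = np.random.default_rng(cfg.seed)
        dtype = np.float32
        self.cfg = cfg
        self.backbone = BACKBONES[cfg.backbone_name](rng=rng, dtype=dtype)
        c = self.backbone.out_channels
        fh = cfg.input_size // 32
        self.n_positions = fh * fh
        self.encoding = ResidualEncoding(c, cfg.n_codewords, cfg.alpha,
                                         rng=rng, dtype=dtype)
        self.local_suppression = LocalSuppression(
            LocalSuppressionConfig(cfg.beta, cfg.p, cfg.ct_max),
            rng=np.random.default_rng(rng.integers(2 ** 31)))
        self.stretch = StretchGlobal(cfg.n_codewords, self.n_positions,
                                     rng=rng, dtype=dtype)
        o = cfg.output_dim_o if cfg.output_dim_o is not None else c
        self.fbe = FBEFusion(a=c, b=c, k=cfg.rank_k, o=o, lam=cfg.lam,
                             rng=rng, dtype=dtype)
        self.classifier = nn.Linear(o, cfg.n_classes, rng=rng, dtype=dtype)
        # input statistics (per channel); overwritten with dataset statistics
        # by the training loop when the backbone is not pretrained
        self.input_mean = np.array([IMAGENET_MEAN.mean()], dtype=np.float32)
        self.input_std = np.array([IMAGENET_STD.mean()], dtype=np.float32)
        self._last_featmap: Tensor | None = None

    # retained for class-activation mapping
    @property
    def last_featmap(self) -> Tensor | None:
        return self._last_featmap

    def dual_path(self, images) -> tuple[Tensor, Tensor]:
        """Return (local 49×c after LS+flatten, global n×c after encoding+GS)."""
        x = self._prepare(images)
        feat = self.backbone(x)                      # (B, c, h, w)
        self._last_featmap = feat
        B, c = feat.shape[0], feat.shape[1]
        m = feat.shape[2] * feat.shape[3]
        if m != self.n_positions:
            raise ValueError(f"backbone emitted {m} positions, "
                             f"expected {self.n_positions}")
        flat = feat.reshape(B, c, m)                 # channels × positions
        local = self.local_suppression(flat)         # LS acts per channel
        local = local.transpose(0, 2, 1)             # (B, m, c)
        global_ = self.encoding(feat)                # (B, n, c), GS applied
        return local, global_

    def forward(self, images) -> Tensor:
        local, global_ = self.dual_path(images)
        stretched = self.stretch(global_)            # (B, L, c)
        fused = self.fbe(local, stretched)           # (B, o), unit norm
        return self.classifier(fused)

    def _prepare(self, images) -> Tensor:
        """Validate and (for raw arrays) replicate grayscale to 3 channels."""
        x = as_tensor(images)
        if x.ndim != 4:
            raise ValueError("expected a batch of shape (B, C, H, W)")
        s = self.cfg.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"expected {s}×{s} inputs, got "
                             f"{x.shape[2]}×{x.shape[3]}")
        if x.shape[1] == 1:
            x = nn_concat_channels(x)
        elif x.shape[1] != 3:
            raise ValueError("inputs must have 1 or 3 channels")
        return x

    def normalize(self, images) -> np.ndarray:
        """Normalize raw images with the model's stored input statistics."""
        x = np.asarray(images)
        c = x.shape[1]
        mean, std = self.input_mean, self.input_std
        if c == 3 and mean.size == 1:
            mean, std = np.repeat(mean, 3), np.repeat(std, 3)
        return normalize_images(x, mean, std)

    def predict(self, images, batch_size: int = 32) -> np.ndarray:
        """Eval-mode class predictions for an array of images."""
        self.eval()
        return np.argmax(self.predict_scores(images, batch_size), axis=1)

    def predict_scores(self, images, batch_size: int = 32) -> np.ndarray:
        self.eval()
        images = np.asarray(images)
        outs = []
        for i in range(0, len(images), batch_size):
            outs.append(self.forward(images[i:i + batch_size]).data)
        return np.concatenate(outs, axis=0)


def nn_concat_channels(x: Tensor) -> Tensor:
    from .autograd import concatenate
    return concatenate([x, x, x], axis=1)


def normalize_images(images: np.ndarray, mean=None, std=None) -> np.ndarray:
    """Scale uint8/float images to zero-mean unit-variance float32.

    ``images``: (B, 1 or 3, H, W) in [0, 255] or [0, 1].  With no explicit
    statistics, ImageNet channel statistics are used (pretrained-backbone
    convention); grayscale uses their mean.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    c = x.shape[1]
    if mean is None:
        mean = IMAGENET_MEAN if c == 3 else np.array([IMAGENET_MEAN.mean()])
        std = IMAGENET_STD if c == 3 else np.array([IMAGENET_STD.mean()])
    mean = np.asarray(mean, dtype=np.float32).reshape(1, c, 1, 1)
    std = np.asarray(std, dtype=np.float32).reshape(1, c, 1, 1)
    return (x - mean) / std


def build_model(cfg: ModelConfig | dict | None = None, **overrides) -> DSEFBENet:
    if cfg is None:
        cfg = ModelConfig(**overrides)
    elif isinstance(cfg, dict):
        cfg = ModelConfig(**{**cfg, **overrides})
    elif overrides:
        cfg = ModelConfig(**{**asdict(cfg), **overrides})
    return DSEFBENet(cfg)


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(model: DSEFBENet, path) -> None:
    """Single-archive checkpoint: weights + JSON config + format version."""
    state = model.state_dict()
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(model.cfg)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path, n_classes: int | None = None) -> DSEFBENet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}; "
                         f"this build reads version {CHECKPOINT_VERSION}")
    cfg = ModelConfig(**meta["config"])
    if n_classes is not None and n_classes != cfg.n_classes:
        raise ValueError(f"checkpoint was trained with n_classes="
                         f"{cfg.n_classes}, requested {n_classes}")
    model = DSEFBENet(cfg)
    model.load_state_dict(state, strict=True)
    return model


def load_backbone_weights(model: DSEFBENet, state: dict[str, np.ndarray]) -> list[str]:
    """Transfer-learning partial load: copy backbone.* entries only; the new
    head layers stay at their initialization."""
    backbone_state = {k: v for k, v in state.items() if k.startswith("backbone.")}
    return model.load_state_dict(backbone_state, strict=False)
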