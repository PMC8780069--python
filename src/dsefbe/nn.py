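"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "AvgPool2d", "Sequential", "softmax", "log_softmax",
    "cross_entropy", "l2_normalize",
]


class Parameter(Tensor):
    """A trainable tensor (always requires_grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Container with named parameters, sub-modules and a train/eval flag."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        yield from u.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state I/O
    def _named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, np.ndarray):
                yield full, v
            elif isinstance(v, Module):
                yield from v._named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        yield from u._named_buffers(f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self._named_buffers():
            state[name] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        """Copy matching arrays into parameters/buffers.

        With ``strict=False`` missing entries are skipped (transfer-learning
        partial loads); shape mismatches always raise.
        """
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        loaded = []
        for name, arr in state.items():
            target = own.get(name)
            if target is not None:
                if target.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{target.data.shape} vs {arr.shape}")
                target.data = arr.astype(target.data.dtype).copy()
                loaded.append(name)
            elif name in bufs:
                if bufs[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for buffer {name}")
                bufs[name][...] = arr
                loaded.append(name)
            elif strict:
                raise KeyError(f"unexpected entry in state dict: {name}")
        if strict:
            missing = set(own) - set(loaded)
            if missing:
                raise KeyError(f"missing parameters: {sorted(missing)}")
        return loaded


def _uniform(rng, shape, bound, dtype):
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None,
                 dtype=np.float32, zero_bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(_uniform(rng, (out_features, in_features), bound, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype) if zero_bias
                              else _uniform(rng, (out_features,), bound, dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = False, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel)).astype(dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xm = x - mu
            var = (xm ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = xm / ((var + self.eps).sqrt())
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool2d(self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return x.avg_pool2d(self.kernel)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ------------------------------------------------------------------ functional
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # stability shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multi-class cross-entropy of logits against integer labels."""
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(log_softmax(logits, axis=1) * onehot).sum() * (1.0 / n)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x ** 2).sum(axis=axis, keepdims=True) + eps).sqrt()
    return x / norm
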