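"""Neural-network layers built on the autograd tape.

Layers hold their parameters as ``Tensor`` objects with ``requires_grad=True``
and expose ``named_parameters()`` for the optimizer and for checkpointing.
Initialisation: He-normal for convolutions (ReLU fan-in), Glorot-uniform for
dense layers; every layer takes the ``numpy.random.Generator`` that seeds it.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = False

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        return arr

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, child in self._children.items():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({"buffer:" + k: v.copy() for k, v in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                buffers[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = kernel * kernel * in_ch
        std = np.sqrt(2.0 / fan_in)
        self.w = self.register_parameter(
            "w", rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)))
        self.b = self.register_parameter("b", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.w = self.register_parameter("w", rng.uniform(-limit, limit, (in_dim, out_dim)))
        self.b = self.register_parameter("b", np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.w)
        return y if self.b is None else ag.add(y, self.b)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, NHWC layout.

    Training mode normalises by batch statistics and updates exponential
    running estimates; eval mode uses the running estimates, so inference
    is deterministic and batch-size independent.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ag.tmean(x, axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = ag.tmean(xc * xc, axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += m * (var.data.reshape(-1) - self.running_var)
            inv = ag.power(var + self.eps, -0.5)
            xn = xc * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = (x - self.running_mean) * Tensor(inv)
        return xn * self.gamma + self.beta


class LayerNorm(Module):
    """Layer normalisation over the trailing (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.register_parameter("gamma", np.ones(dim))
        self.beta = self.register_parameter("beta", np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = ag.tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = ag.tmean(xc * xc, axis=-1, keepdims=True)
        xn = xc * ag.power(var + self.eps, -0.5)
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the token axis.

    Input (N, T, C); per head d_k = C / heads; the four head outputs are
    concatenated and linearly projected back to C channels.  The attention
    weights of the most recent forward pass are kept on
    ``last_attention_weights`` (N, heads, T, T) for diagnostics.
    """

    def __init__(self, channels: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if channels % heads:
            raise ValueError(f"head count {heads} must divide channels {channels}")
        self.heads = heads
        self.d_k = channels // heads
        self.wq = Dense(channels, channels, rng)
        self.wk = Dense(channels, channels, rng)
        self.wv = Dense(channels, channels, rng)
        self.wo = Dense(channels, channels, rng)
        self.last_attention_weights: np.ndarray | None = None

    def _split_heads(self, t: Tensor, n: int, tokens: int) -> Tensor:
        # (N, T, C) -> (N, heads, T, d_k)
        return ag.transpose(ag.reshape(t, (n, tokens, self.heads, self.d_k)), (0, 2, 1, 3))

    def forward(self, x: Tensor) -> Tensor:
        n, tokens, channels = x.shape
        q = self._split_heads(self.wq(x), n, tokens)
        k = self._split_heads(self.wk(x), n, tokens)
        v = self._split_heads(self.wv(x), n, tokens)
        scores = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_k))
        attn = ag.softmax(scores, axis=-1)
        self.last_attention_weights = attn.data
        ctx = ag.matmul(attn, v)  # (N, heads, T, d_k)
        merged = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (n, tokens, channels))
        return self.wo(merged)


def global_average_pool(x: Tensor) -> Tensor:
    """(N, H, W, C) -> (N, C) spatial mean."""
    return ag.tmean(x, axis=(1, 2))
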