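"""Neural-network building blocks on top of the autograd engine.

Layers follow the familiar module idiom: a :class:`Module` owns
:class:`Parameter` leaves (and buffers such as batch-norm running statistics),
exposes them recursively, and switches between train and eval behaviour.
Initialization draws from an explicit ``numpy.random.Generator`` so that every
model build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, softmax

NEG_FILL = -1e30  # additive mask value; exp() underflows to exactly 0.0


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def __init__(self):
        self.training = True

    # -- recursive traversal --------------------------------------------------

    def _children(self):
        for name in sorted(vars(self)):
            value = vars(self)[name]
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params = []
        for name in sorted(vars(self)):
            value = vars(self)[name]
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, (list, tuple)):
                params.extend(v for v in value if isinstance(v, Parameter))
        for child in self._children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs = list(getattr(self, "_buffers", []))
        for child in self._children():
            bufs.extend(child.buffers())
        return bufs

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    # -- checkpointing --------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self.buffers()
        ]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        bufs = self.buffers()
        if len(state) != len(params) + len(bufs):
            raise ValueError("state does not match module structure")
        for p, s in zip(params, state[: len(params)]):
            p.data[...] = s
        for b, s in zip(bufs, state[len(params):]):
            b[...] = s

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._buffers = [self.running_mean, self.running_var]
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu.data.ravel()
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var.data.ravel()
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with a key padding mask."""

    def __init__(self, d_model: int, n_head: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_head:
            raise ValueError("d_model must be divisible by n_head")
        self.n_head = n_head
        self.d_head = d_model // n_head
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_head, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        q = self._split(self.q(x), B, L)
        k = self._split(self.k(x), B, L)
        v = self._split(self.v(x), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        pad = ~np.asarray(mask, dtype=bool)[:, None, None, :]
        scores = scores.masked_fill(np.broadcast_to(pad, scores.shape), NEG_FILL)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention and feed-forward sublayers with
    residual connections and layer normalization."""

    def __init__(self, d_model: int, n_head: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_head, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, mask)))
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class Conv2d(Module):
    """2-D convolution implemented by patch gathering + matmul (im2col)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: tuple[int, int], padding: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = c_in * kh * kw
        self.weight = Parameter(glorot(rng, fan_in, c_out, (fan_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        oh, ow = self.out_shape(H, W)
        if oh < 1 or ow < 1:
            raise ValueError(
                f"input {H}x{W} too small for kernel {self.kernel} "
                f"with stride {self.stride}, padding {self.padding}"
            )
        xp = x.pad2d(ph, pw)
        rows = (sh * np.arange(oh)[:, None, None, None]
                + np.arange(kh)[None, None, :, None])
        cols = (sw * np.arange(ow)[None, :, None, None]
                + np.arange(kw)[None, None, None, :])
        rows = np.broadcast_to(rows, (oh, ow, kh, kw))
        cols = np.broadcast_to(cols, (oh, ow, kh, kw))
        patches = xp[:, :, rows, cols]            # B,C,oh,ow,kh,kw
        patches = patches.transpose(0, 2, 3, 1, 4, 5).reshape(
            B, oh, ow, C * kh * kw
        )
        out = patches @ self.weight + self.bias   # B,oh,ow,c_out
        return out.transpose(0, 3, 1, 2)


class MLP(Module):
    """Fully connected stack with LeakyReLU; optional batch-norm + dropout."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 batchnorm: bool = False, dropout: float = 0.0,
                 slope: float = 0.01):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.norms = (
            [BatchNorm1d(w) for w in widths[1:-1]] if batchnorm else []
        )
        self.drop = Dropout(dropout, rng)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                if self.norms:
                    x = self.norms[i](x)
                x = self.drop(x.leaky_relu(self.slope))
        return x


__all__ = [
    "Parameter", "Module", "Linear", "Embedding", "LayerNorm", "BatchNorm1d",
    "Dropout", "MultiheadSelfAttention", "TransformerEncoderLayer", "Conv2d",
    "MLP", "concat", "NEG_FILL",
]
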