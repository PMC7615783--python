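"""Neural-network building blocks on top of the autodiff tensor.

Modules auto-register parameters (any ``Tensor`` attribute) and child
modules, torch-style, so optimizers and checkpointing can walk the tree.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "ModuleList", "Sequential", "Linear", "Conv2d", "LayerNorm",
    "BatchNorm1d", "trunc_normal", "conv2d",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped at two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        """Update a registered buffer in place of the attribute."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()   # dedupe shared submodules (e.g. a shared stem)
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._load_buffer(name[len("buffer:"):], value)
            else:
                if params[name].shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].shape} vs {value.shape}")
                params[name].data = value.astype(np.float64).copy()

    def _load_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod._set_buffer(leaf, value.astype(np.float64).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Linear(Module):
    """Affine map; weight initialized from a truncated normal (std 0.02)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True, std: float = 0.02):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (in_features, out_features), std),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int, padding: int) -> Tensor:
    """2-D convolution on a single image, via im2col.

    x: (Cin, H, W); weight: (Cout, Cin, kh, kw); returns (Cout, Hout, Wout).
    """
    cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    s, p = stride, padding
    hout = (h + 2 * p - kh) // s + 1
    wout = (w + 2 * p - kw) // s + 1

    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (Cin, H+2p-kh+1, W+2p-kw+1, kh, kw) -> strided -> cols
    win = win[:, ::s, ::s]                      # (Cin, Hout, Wout, kh, kw)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(hout * wout, cin * kh * kw)
    wmat = weight.data.reshape(cout, -1)

    out = cols @ wmat.T                         # (Hout*Wout, Cout)
    if bias is not None:
        out = out + bias.data
    out_data = out.T.reshape(cout, hout, wout)

    def backward(g):
        gmat = g.reshape(cout, -1).T            # (Hout*Wout, Cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(1, 2)))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(hout, wout, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + s * hout:s, j:j + s * wout:s] += \
                        gcols[:, :, :, i, j].transpose(2, 0, 1)
            x._accum(gxp[:, p:p + h, p:p + w] if p else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


class Conv2d(Module):
    """Single-image 2-D convolution layer (He-normal initialized)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels,
                                  kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class BatchNorm1d(Module):
    """Normalization over axis 0 of an (N, F) input.

    In this package the "batch" axis is the vertex axis of a token graph:
    statistics are taken over the N vertices of one image.  With a single
    vertex (or in eval mode) the running statistics are used instead.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        if self.training and n > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data.ravel())
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta
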