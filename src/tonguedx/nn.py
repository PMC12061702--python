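"""Layers, initialisation and the Adam optimiser used by the model.

Thin conveniences over :mod:`tonguedx.autodiff`: a Module tree with
parameter collection and train/eval mode, He-initialised linear and grouped
convolution layers, embeddings, dropout and layer normalisation.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-normal initialisation: N(0, 2/fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_init(rng, (n_out, n_in), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Tensor(
            he_init(rng, (c_out, c_in // groups, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0, size=(n_vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.weight.shape[0]:
            raise IndexError(
                f"index out of vocabulary (size {self.weight.shape[0]}): "
                f"range [{idx.min()}, {idx.max()}]"
            )
        return self.weight[idx]


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p, self.rng = p, rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2.0).mean(axis=-1, keepdims=True)
        return xc / ad.sqrt(var + self.eps) * self.gamma + self.beta


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
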