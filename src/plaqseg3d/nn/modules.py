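"""Layer modules and SGD for the 3D conv nets, built on the tape."""

from __future__ import annotations

import numpy as np

from . import tape
from .tape import Parameter, Tensor

__all__ = ["Module", "Conv3d", "BatchNorm3d", "BasicModule", "SGD"]


class Module:
    """Minimal module: named parameters, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_children(self, name: str, mods: list["Module"]) -> None:
        for i, m in enumerate(mods):
            self._children[f"{name}.{i}"] = m

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._children.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._children.items():
            out.update(m.named_state(prefix + name + "/"))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float32).copy()
        for k in list(self._buffers):
            arr = np.asarray(state[prefix + k], dtype=np.float32).copy()
            self._buffers[k][...] = arr
        for name, m in self._children.items():
            m.load_state(state, prefix + name + "/")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._children.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = (k - 1) // 2
        self.stride, self.pad, self.k = stride, pad, k
        self.W = Parameter(_he_normal(rng, (cout, cin, k, k, k), cin * k ** 3))
        self.b = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return tape.conv3d(x, self.W, self.b, self.stride, self.pad)


class BatchNorm3d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        return tape.batchnorm3d(x, self.gamma, self.beta, self.running_mean,
                                self.running_var, self.training,
                                self.momentum, self.eps)


class BasicModule(Module):
    """Two conv(3^3)-BN-ReLU blocks with a residual skip connection."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, rng=rng, bias=False)
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng=rng, bias=False)
        self.bn2 = BatchNorm3d(cout)
        if cin != cout:
            self.proj = Conv3d(cin, cout, 1, rng=rng, bias=False)
            self.bn_proj = BatchNorm3d(cout)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h = tape.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        s = self.bn_proj(self.proj(x)) if self.proj is not None else x
        return tape.relu(tape.add(h, s))


class SGD:
    """SGD with classic momentum and L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
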