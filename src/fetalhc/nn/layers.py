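"""Parameterized layers and a minimal module system.

Modules discover parameters and submodules by attribute inspection;
``state_dict`` / ``load_state_dict`` snapshot weights (and batch-norm
running statistics) as plain numpy arrays, which keeps checkpoints
text-free and framework-free. All initialization draws from an explicit
``numpy.random.Generator`` so training runs are reproducible bit-for-bit
on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self.named_children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self, flag: bool = True):
        for p in self.parameters():
            p.requires_grad = not flag
        return self

    # -- serialization --------------------------------------------------
    def _buffers(self):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield name, val

    def state_dict(self, prefix: str = "", out: dict | None = None) -> dict:
        out = {} if out is None else out
        for name, p in vars(self).items():
            if isinstance(p, Parameter):
                out[prefix + name] = p.data.copy()
            elif isinstance(p, np.ndarray):
                out[prefix + name] = p.copy()
        for cname, child in self.named_children():
            child.state_dict(prefix + cname + ".", out)
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in vars(self).items():
            if isinstance(p, Parameter):
                p.data = state[prefix + name].astype(np.float32).copy()
            elif isinstance(p, np.ndarray):
                p[...] = state[prefix + name]
        for cname, child in self.named_children():
            child.load_state_dict(state, prefix + cname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Convolution with TF-style "same" padding by default (even kernels
    pad one extra row/col at bottom/right)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, same: bool = True, bias: bool = True,
                 init_scale: float = 1.0):
        super().__init__()
        self.stride = stride
        if same:
            total = k - 1
            pt = total // 2
            self.pad = (pt, total - pt, pt, total - pt)
        else:
            self.pad = (0, 0, 0, 0)
        self.w = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k) * init_scale)
        self.b = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return ops.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Parameter(_he_init(rng, (cin, cout, 2, 2), cin * 4))
        self.b = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return ops.conv_transpose2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return ops.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.momentum, self.eps,
                               self.training)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Parameter(_he_init(rng, (dout, din), din))
        self.b = Parameter(np.zeros(dout)) if bias else None

    def forward(self, x):
        return ops.linear(x, self.w, self.b)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ops.relu(x)
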