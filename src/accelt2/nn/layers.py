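"""Neural-network layers on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, is_grad_enabled

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ReLU",
           "Sequential", "Parameter"]


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # parameters stay trainable even if created inside no_grad blocks
        self.requires_grad = True


class Module:
    """Minimal module: tracks parameters and submodules by attribute."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                pass  # running stats handled below
        # include batchnorm running statistics keyed by module path
        def walk(mod, prefix):
            if isinstance(mod, BatchNorm2d):
                out[f"{prefix}running_mean"] = mod.running_mean.copy()
                out[f"{prefix}running_var"] = mod.running_var.copy()
            for k, sub in mod._modules.items():
                walk(sub, f"{prefix}{k}.")
        walk(self, "")
        return out

    def load_state_dict(self, state: dict):
        for k, p in self.named_parameters():
            p.data = np.array(state[k], dtype=p.data.dtype)

        def walk(mod, prefix):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.array(state[f"{prefix}running_mean"])
                mod.running_var = np.array(state[f"{prefix}running_var"])
            for k, sub in mod._modules.items():
                walk(sub, f"{prefix}{k}.")
        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel),
                                         fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, kernel, kernel),
                                         fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)


class BatchNorm2d(Module):
    """Channel normalisation over (N, H, W) with trainable affine.

    Batch statistics are used at training *and* inference time: with the
    batch-of-one training regime used here, running-average statistics
    diverge badly from the per-image statistics the weights were trained
    against, so per-input normalisation (instance-norm semantics) is both
    more accurate and still deterministic.  Running statistics are tracked
    for introspection only.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(n_ch, dtype=dtype))
        self.beta = Parameter(np.zeros(n_ch, dtype=dtype))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean +
                                 m * x.data.mean(axis=(0, 2, 3)))
            self.running_var = ((1 - m) * self.running_var +
                                m * x.data.var(axis=(0, 2, 3)))
        return x.batchnorm2d(self.gamma, self.beta, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
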