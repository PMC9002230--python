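"""Layers and parameter containers for the segmentation network.

Mirrors the familiar torch.nn surface at a much smaller scale: ``Module``
holds named parameters and sub-modules, supports train/eval switching and
recursive parameter collection; concrete layers wrap the autodiff primitives.

Batch normalisation follows the usual two-regime semantics: batch statistics
(and a running-average update with momentum ``momentum``) in training mode,
frozen running statistics in evaluation mode. ``eps`` defaults to 1e-6 and
momentum to 0.1, the values used throughout the reference configuration.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A leaf tensor that optimisers update."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=ad.DEFAULT_DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in m._buffers().items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = {}
        for name, m in self._named_modules():
            for bname in m._buffers():
                buffers[f"{name}{bname}"] = (m, bname)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.astype(ad.DEFAULT_DTYPE).copy()
            elif key in buffers:
                m, bname = buffers[key]
                setattr(m, bname, value.copy())
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{name}.")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        setattr(self, str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


# ---------------------------------------------------------------------------
# initialisation helpers
# ---------------------------------------------------------------------------

def kaiming_conv(rng: np.random.Generator, c_out, c_in, kh, kw):
    fan_in = c_in * kh * kw
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=(c_out, c_in, kh, kw))


def xavier_fc(rng: np.random.Generator, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(kaiming_conv(rng, c_out, c_in, kernel, kernel))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2x2(Module):
    """Stride-2 'deconvolution' doubling the spatial extent."""

    def __init__(self, c_in, c_out, *, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_in, c_out, 2, 2)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x):
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, n_in, n_out, *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(xavier_fc(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x):
        return ad.matmul(x, self.weight) + self.bias


class _NormBase(Module):
    def __init__(self, num_features, eps, momentum):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _normalize(self, x, axes, shape):
        if self.training:
            mu = ad.mean(x, axes, keepdims=True)
            xc = x - mu
            var = ad.mean(xc * xc, axes, keepdims=True)
            n = int(np.prod([x.shape[a] for a in axes]))
            unbiased = n / max(n - 1, 1)
            self.running_mean += self.momentum * (mu.data.reshape(-1).astype(np.float64)
                                                  - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1).astype(np.float64) * unbiased
                                                 - self.running_var)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(shape).astype(ad.DEFAULT_DTYPE)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape).astype(ad.DEFAULT_DTYPE)
            xhat = (x - mu) * inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(_NormBase):
    """Per-channel batch normalisation of (N,C,H,W) maps."""

    def __init__(self, num_features, eps=1e-6, momentum=0.1):
        super().__init__(num_features, eps, momentum)

    def forward(self, x):
        c = x.shape[1]
        return self._normalize(x, (0, 2, 3), (1, c, 1, 1))


class BatchNorm1d(_NormBase):
    """Batch normalisation of (N,F) feature vectors."""

    def __init__(self, num_features, eps=1e-6, momentum=0.1):
        super().__init__(num_features, eps, momentum)

    def forward(self, x):
        return self._normalize(x, (0,), (1, x.shape[1]))


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis at every (n,h,w) site of a (N,C,H,W) map."""

    def __init__(self, num_channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))

    def forward(self, x):
        c = x.shape[1]
        mu = ad.mean(x, (1,), keepdims=True)
        xc = x - mu
        var = ad.mean(xc * xc, (1,), keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        shape = (1, c, 1, 1)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)
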