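"""Layer abstractions over the autograd primitives.

A :class:`Module` owns named :class:`Parameter` leaves and submodules,
exposes a flat, deterministically ordered registry (``named_parameters``,
``state_dict``) and supports a lightweight profiling mode used by the
complexity counter: while a profile recorder is active every leaf layer
appends one (name, type, params, ops) row as data flows through it.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "BilinearUpsample2x",
    "kaiming_normal_fan_out",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_normal_fan_out(shape, rng, groups=1):
    """He-style normal init with fan-out accounting (conv weights)."""
    out_ch, in_pg, kh, kw = shape
    fan_out = out_ch * kh * kw // groups
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


# active complexity recorder (list the leaf layers append rows to)
_PROFILE = None


class _ProfileRecorder:
    def __init__(self):
        self.rows = []

    def __enter__(self):
        global _PROFILE
        self._prev = _PROFILE
        _PROFILE = self
        return self

    def __exit__(self, *exc):
        global _PROFILE
        _PROFILE = self._prev
        return False


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_prof_name", "")

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ----------------------------------------------------
    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())

    # -- state --------------------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")

    def train(self, mode=True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- execution ----------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        if _PROFILE is not None and hasattr(self, "_count_ops"):
            _PROFILE.rows.append({
                "name": self._prof_name or type(self).__name__,
                "type": type(self).__name__,
                "params": self.num_parameters(),
                "macs": int(self._count_ops(args[0].data.shape, out.data.shape)),
            })
        return out


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module):
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self._list = []
        for m in modules:
            self._modules[str(len(self._list))] = m
            self._list.append(m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    """Stride-1 "same" convolution; bias disabled by default because every
    convolution in the network except the prediction head feeds a batch
    norm whose shift makes an additive bias redundant."""

    def __init__(self, in_channels, out_channels, kernel_size,
                 dilation=1, groups=1, bias=False, rng=None):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Parameter(kaiming_normal_fan_out(shape, rng, groups))
        if bias:
            self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias,
                         dilation=self.dilation, groups=self.groups)

    def _count_ops(self, in_shape, out_shape):
        # one MAC per output element per kernel tap per in-channel-per-group
        out_elems = int(np.prod(out_shape))
        return out_elems * (self.in_channels // self.groups) * self.kernel_size ** 2


class BatchNorm2d(Module):
    """Channelwise batch normalization.

    The running-statistics momentum defaults to 0.3 rather than the common
    0.1: this trainer works with small in-memory datasets where an epoch
    contributes only a handful of batches, and evaluation-mode statistics
    must track the training distribution within a few epochs."""

    def __init__(self, num_features, momentum=0.3, eps=1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x):
        return ag.batch_norm2d(x, self.weight, self.bias,
                               self.running_mean, self.running_var,
                               training=self.training,
                               momentum=self.momentum, eps=self.eps)

    def _count_ops(self, in_shape, out_shape):
        # scale and shift: two ops per element
        return 2 * int(np.prod(out_shape))


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)

    def _count_ops(self, in_shape, out_shape):
        return int(np.prod(out_shape))


class MaxPool2d(Module):
    """2x2 max pooling with stride 2."""

    def forward(self, x):
        return ag.max_pool2x2(x)

    def _count_ops(self, in_shape, out_shape):
        # one comparison per kernel tap per output element
        return 4 * int(np.prod(out_shape))


class BilinearUpsample2x(Module):
    def forward(self, x):
        return ag.upsample_bilinear2x(x)

    def _count_ops(self, in_shape, out_shape):
        return int(np.prod(out_shape))
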