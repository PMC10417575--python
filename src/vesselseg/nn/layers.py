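"""Layer primitives built on the autograd engine.

Every layer stores its trainable parameters as ``Tensor`` objects with
``requires_grad=True`` and any non-trainable state (the normalization
layers' moving statistics) as plain ndarrays registered as buffers, so
that parameter counting can distinguish — and include — both.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d, maxpool2d


class Module:
    """Base class: parameter/buffer registry and state (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name, array):
        t = Tensor(np.asarray(array), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name, array):
        self._buffers[name] = np.asarray(array)
        object.__setattr__(self, name, self._buffers[name])
        return self._buffers[name]

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def named_state(self, prefix=""):
        """(name, array, is_buffer) triples for every stored array."""
        for name, p in self._params.items():
            yield prefix + name, p.data, False
        for name, b in self._buffers.items():
            yield prefix + name, b, True
        for cname, child in self._children.items():
            yield from child.named_state(prefix + cname + ".")

    def state_dict(self):
        return {name: arr.copy() for name, arr, _ in self.named_state()}

    def load_state_dict(self, state):
        for m, prefix in self._walk():
            for name in m._params:
                m._params[name].data = np.array(state[prefix + name])
            for name in m._buffers:
                m._buffers[name][...] = state[prefix + name]

    def _walk(self, prefix=""):
        yield self, prefix
        for cname, child in self._children.items():
            yield from child._walk(prefix + cname + ".")

    def num_parameters(self):
        """Total stored scalars: trainable weights plus buffers."""
        return sum(arr.size for _, arr, _ in self.named_state())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod):
        setattr(self, str(len(self._list)), mod)
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _he_init(rng, shape, fan_in, dtype=np.float32):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding="same", bias=True, *, rng):
        super().__init__()
        self.stride, self.padding = stride, padding
        kh, kw = (k, k) if np.isscalar(k) else k
        self.register_param(
            "weight", _he_init(rng, (cout, cin, kh, kw), cin * kh * kw)
        )
        self.bias = None
        if bias:
            self.register_param("bias", np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """k x k, stride-k learned upsampling (kernel == stride)."""

    def __init__(self, cin, cout, k=2, bias=True, *, rng):
        super().__init__()
        self.k = k
        self.register_param("weight", _he_init(rng, (cin, cout, k, k), cin * k * k))
        self.bias = None
        if bias:
            self.register_param("bias", np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, stride=self.k)


class BatchNorm2d(Module):
    """Channel normalization with trainable scale/shift and moving statistics.

    Stored values per channel: weight, bias (trainable) and running mean,
    running variance (buffers) — four scalars per channel.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.register_param("weight", np.ones(c, dtype=np.float32))
        self.register_param("bias", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x, training=False):
        c = self.weight.shape[0]
        shape = (1, c, 1, 1)
        if training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - m
            v = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            xhat = centered * (v + self.eps) ** -0.5
            mom = self.momentum
            self._buffers["running_mean"] *= 1 - mom
            self._buffers["running_mean"] += mom * m.data.reshape(c)
            self._buffers["running_var"] *= 1 - mom
            self._buffers["running_var"] += mom * v.data.reshape(c)
        else:
            rm = self._buffers["running_mean"].reshape(shape)
            rv = self._buffers["running_var"].reshape(shape)
            xhat = (x - rm) * (rv + self.eps) ** -0.5
        return xhat * self.weight.reshape(*shape) + self.bias.reshape(*shape)


class Dropout(Module):
    """Inverted elementwise dropout; identity when rate is 0 or at eval."""

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * mask


class MaxPool2d(Module):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return maxpool2d(x, self.k)


def softmax_channels(x):
    """Per-pixel softmax over the channel axis of an NCHW tensor."""
    shifted = x - x.data.max(axis=1, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)
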