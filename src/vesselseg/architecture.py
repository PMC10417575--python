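"""The configurable U-Net family for six-class histology segmentation.

A single :class:`ArchitectureConfig` selects one member of the ablation
grid: the plain encoder/bridge/decoder U-Net, optionally extended by
additive attention gates on the skip connections, residual bypasses
around each block, and shared-weight recurrent unrolling of every
convolutional unit.  The module also provides closed-form receptive
field arithmetic for stacks of convolutions.

Stored-parameter accounting
---------------------------
Channel widths are 64 -> 128 -> 256 -> 512 on the encoder with a
1024-channel bridge, every 3x3 convolution is same-padded and biased and
followed by channel normalization holding four scalars per channel (two
trainable, two moving statistics), upsampling is a biased 2x2 stride-2
transposed convolution without normalization, and the head is a biased
1x1 six-class softmax.  Under this design the baseline variant stores
exactly 31,055,622 scalars.  The residual bypass (biased 1x1 projection
plus channel normalization per block) adds exactly 1,407,552.  Attention
gate internals and the recurrent-path wiring are under-determined by the
published totals; the defaults here (gate internal width equal to the
skip width; a biased 1x1 recurrent-path convolution per unit) land
within 0.1% and 3% of the published attention and recurrent totals
respectively while preserving the published ordering of all variants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

PATCH_PX = 128


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ArchitectureConfig:
    """Switch set selecting one network variant of the ablation grid."""

    levels: int = 4
    base_width: int = 64
    input_channels: int = 3
    num_classes: int = 6
    attention: bool = False
    residual: bool = False
    recurrent: bool = False
    recurrence_steps: int = 3
    dropout_rate: float = 0.125
    name: str = ""

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.recurrence_steps < 1:
            raise ValueError("recurrence_steps must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not self.name:
            object.__setattr__(self, "name", self._auto_name())

    def _auto_name(self):
        tags = [t for t, on in (
            ("attention", self.attention),
            ("residual", self.residual),
            ("recurrent", self.recurrent),
        ) if on]
        return "baseline" if not tags else "+".join(tags)

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def variant_grid():
    """The six ablation variants, each with its published dropout rate."""
    mk = ArchitectureConfig
    return [
        mk(),
        mk(attention=True),
        mk(residual=True),
        mk(recurrent=True, dropout_rate=0.25),
        mk(attention=True, residual=True),
        mk(attention=True, residual=True, recurrent=True),
    ]


def get_variant(name):
    for cfg in variant_grid():
        if cfg.name == name:
            return cfg
    names = [c.name for c in variant_grid()]
    raise KeyError(f"unknown variant {name!r}; choose from {names}")


# --------------------------------------------------------------------------
# receptive field arithmetic
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ReceptiveFieldStack:
    """Ordered (kernel, stride) list of the layers seen by one output pixel."""

    layers: tuple = field(default_factory=tuple)

    def __post_init__(self):
        layers = tuple((int(k), int(s)) for k, s in self.layers)
        for k, s in layers:
            if k < 1 or s < 1:
                raise ValueError(f"kernels and strides must be >= 1, got ({k},{s})")
        if not layers:
            raise ValueError("stack must contain at least one layer")
        object.__setattr__(self, "layers", layers)

    @classmethod
    def uniform(cls, n_units, kernel=3, stride=1, recurrence_steps=1):
        """``n_units`` identical units, each unrolled ``recurrence_steps`` times."""
        return cls(tuple((kernel, stride) for _ in range(n_units * recurrence_steps)))


def receptive_field(stack):
    """Side length in px of one output pixel's input footprint.

    r0 = 1 + sum_l (k_l - 1) * prod_{i<l} s_i  for the ordered layer stack.
    """
    if not isinstance(stack, ReceptiveFieldStack):
        stack = ReceptiveFieldStack(tuple(stack))
    r, jump = 1, 1
    for k, s in stack.layers:
        r += (k - 1) * jump
        jump *= s
    return r


# --------------------------------------------------------------------------
# network building blocks
# --------------------------------------------------------------------------
class ConvUnit(nn.Module):
    """3x3 convolution, channel normalization, ReLU.

    With recurrence the unit is unrolled ``steps`` times sharing the 3x3
    kernel; feedback enters through a dedicated biased 1x1 convolution:
    h_1 = act(norm(conv(x))), h_t = act(norm(conv(x) + rec(h_{t-1}))).
    An optional residual tensor is summed in before the final activation.
    """

    def __init__(self, cin, cout, recurrent=False, steps=1, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, rng=rng)
        self.norm = nn.BatchNorm2d(cout)
        self.steps = steps if recurrent else 1
        self.rec = nn.Conv2d(cout, cout, 1, rng=rng) if recurrent else None

    def forward(self, x, training=False, residual=None):
        z = self.conv(x)
        h = None
        for t in range(self.steps):
            pre = z if h is None else z + self.rec(h)
            a = self.norm(pre, training=training)
            if residual is not None and t == self.steps - 1:
                a = a + residual
            h = a.relu()
        return h


class Block(nn.Module):
    """Two convolutional units, optional residual bypass around both."""

    def __init__(self, cin, cout, cfg, *, rng):
        super().__init__()
        self.unit1 = ConvUnit(cin, cout, cfg.recurrent, cfg.recurrence_steps, rng=rng)
        self.unit2 = ConvUnit(cout, cout, cfg.recurrent, cfg.recurrence_steps, rng=rng)
        self.proj = self.proj_norm = None
        if cfg.residual:
            self.proj = nn.Conv2d(cin, cout, 1, rng=rng)
            self.proj_norm = nn.BatchNorm2d(cout)

    def forward(self, x, training=False):
        h = self.unit1(x, training=training)
        res = None
        if self.proj is not None:
            res = self.proj_norm(self.proj(x), training=training)
        return self.unit2(h, training=training, residual=res)


class AttentionGate(nn.Module):
    """Additive attention gate reweighting a skip connection.

    The skip tensor x and the upsampled decoder signal g (equal widths F)
    are projected by biased 1x1 convolutions to an internal width
    (default F), joined additively, passed through ReLU and a biased 1x1
    scalar map, and the sigmoid coefficient multiplies the skip.
    """

    def __init__(self, width, inter=None, *, rng):
        super().__init__()
        inter = width if inter is None else inter
        self.wg = nn.Conv2d(width, inter, 1, rng=rng)
        self.wx = nn.Conv2d(width, inter, 1, rng=rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng=rng)

    def forward(self, skip, gate):
        a = (self.wg(gate) + self.wx(skip)).relu()
        coef = self.psi(a).sigmoid()
        return skip * coef


class SegmentationModel(nn.Module):
    """Maps an RGB patch in [0,1] to a per-pixel class-probability map."""

    def __init__(self, config, seed=0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [config.base_width * 2 ** i for i in range(config.levels)]
        bridge_w = config.base_width * 2 ** config.levels

        enc, cin = [], config.input_channels
        for w in widths:
            enc.append(Block(cin, w, config, rng=rng))
            cin = w
        self.encoder = nn.ModuleList(enc)
        self.bridge = Block(cin, bridge_w, config, rng=rng)

        ups, dec, gates = [], [], []
        prev = bridge_w
        for w in reversed(widths):
            ups.append(nn.ConvTranspose2d(prev, w, 2, rng=rng))
            gates.append(AttentionGate(w, rng=rng) if config.attention else nn.Module())
            dec.append(Block(2 * w, w, config, rng=rng))
            prev = w
        self.ups = nn.ModuleList(ups)
        self.gates = nn.ModuleList(gates)
        self.decoder = nn.ModuleList(dec)
        self.head = nn.Conv2d(widths[0], config.num_classes, 1, rng=rng)
        self.pool = nn.MaxPool2d(2)
        self.dropout = nn.Dropout(config.dropout_rate)

    def forward(self, x, training=False, rng=None):
        """x: (N, C, H, W) array or Tensor; returns (N, classes, H, W) probs."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.config.levels
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^levels = {div}; pad first"
            )
        if rng is None:
            rng = np.random.default_rng(0)

        skips = []
        t = x
        for block in self.encoder:
            t = block(t, training=training)
            skips.append(t)
            t = self.pool(t)
            t = self.dropout(t, training=training, rng=rng)
        t = self.bridge(t, training=training)
        for up, gate, block, skip in zip(
            self.ups, self.gates, self.decoder, reversed(skips)
        ):
            u = up(t)
            s = gate(skip, u) if self.config.attention else skip
            t = block(nn.concat([u, s], axis=1), training=training)
            t = self.dropout(t, training=training, rng=rng)
        return nn.softmax_channels(self.head(t))

    def predict(self, image):
        """HWC float image in [0,1] -> HWC per-pixel class probabilities."""
        x = np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[None]
        probs = self.forward(x, training=False)
        return probs.data[0].transpose(1, 2, 0)


def build_model(config, seed=0):
    """Instantiate the network variant selected by ``config``."""
    if PATCH_PX // 2 ** config.levels < 1:
        raise ValueError(
            f"levels={config.levels} collapses the bottleneck below 1 px "
            f"for {PATCH_PX}-px inputs"
        )
    return SegmentationModel(config, seed=seed)


def count_parameters(model):
    """Total stored scalars, including normalization moving statistics."""
    return model.num_parameters()


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------
def save_checkpoint(model, path, **meta):
    state = model.state_dict()
    meta = dict(meta)
    meta.setdefault("init_seed", model.seed)
    header = json.dumps({"config": model.config.to_dict(), "meta": meta})
    np.savez_compressed(path, __header__=np.frombuffer(header.encode(), np.uint8), **state)


def load_checkpoint(path):
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__header__"}
    config = ArchitectureConfig.from_dict(header["config"])
    model = build_model(config, seed=header["meta"].get("init_seed", 0))
    model.load_state_dict(state)
    return model, header["meta"]
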