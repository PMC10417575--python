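"""Run configuration and the fixed six-class scheme.

The class table is an artifact-level convention (the underlying study
never assigns numeric indices): 0 background, 1 tissue, 2 destroyed
tissue, 3 debris, 4 vessel wall, 5 vessel lumen, with 255 reserved as
the *unlabeled* sentinel.  Overlay colors follow the usual presentation
of such segmentations: lumen purple, wall dark blue, tissue green,
destroyed tissue red, background yellow; debris (never shown in the
published overlays) is drawn orange-brown.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .architecture import ArchitectureConfig
from .augmentation import AugmentationParams
from .training import TrainingConfig

SENTINEL = 255


@dataclass(frozen=True)
class ClassScheme:
    names: tuple = (
        "background", "tissue", "destroyed_tissue", "debris",
        "vessel_wall", "vessel_lumen",
    )
    colors: tuple = (
        (240, 220, 60),   # background: yellow
        (80, 170, 90),    # tissue: green
        (210, 50, 50),    # destroyed tissue: red
        (170, 110, 40),   # debris: orange-brown
        (40, 50, 130),    # vessel wall: dark blue
        (150, 70, 180),   # vessel lumen: purple
    )
    sentinel: int = SENTINEL

    def __post_init__(self):
        if len(self.names) != len(self.colors):
            raise ValueError("one color per class required")
        if self.sentinel in range(len(self.names)):
            raise ValueError("sentinel must not collide with a class index")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(
            self, "colors", tuple(tuple(int(v) for v in c) for c in self.colors)
        )

    @property
    def classes(self):
        return tuple(range(len(self.names)))

    def color_of(self, index):
        if not 0 <= index < len(self.colors):
            raise KeyError(f"unknown class index {index}")
        return self.colors[index]


@dataclass(frozen=True)
class DataConfig:
    patch_px: int = 128
    fractions: tuple = (0.6, 0.2, 0.2)
    split_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fractions", tuple(self.fractions))


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    data: DataConfig = field(default_factory=DataConfig)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    classes: ClassScheme = field(default_factory=ClassScheme)

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        def tup(x):
            return tuple(tup(v) if isinstance(v, (list, tuple)) else v for v in x)

        arch = ArchitectureConfig(**d.get("architecture", {}))
        tcfg = TrainingConfig(**d.get("training", {}))
        data = d.get("data", {})
        dcfg = DataConfig(**{**data, **({"fractions": tup(data["fractions"])}
                                        if "fractions" in data else {})})
        aug = {k: tup(v) if isinstance(v, (list, tuple)) else v
               for k, v in d.get("augmentation", {}).items()}
        acfg = AugmentationParams(**aug)
        cl = {k: tup(v) if isinstance(v, (list, tuple)) else v
              for k, v in d.get("classes", {}).items()}
        return cls(arch, tcfg, dcfg, acfg, ClassScheme(**cl))

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
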