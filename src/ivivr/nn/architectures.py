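"""The six CNN regression architectures.

Three own designs of increasing depth mixing convolutions, max pooling,
dropout and batch normalisation, plus three inspired by canonical image
networks: an inception-style net (parallel 1x1/3x3/5x5/pooled branches),
a VGG-style net (three blocks of two 3x3 convolutions + max pool, then
flatten and dense), and a ResNet-style net (stem convolution, one
identity-shortcut residual block, global pooling).  Every hidden
activation is ReLU and every net ends in a single linear output unit.

Filter counts are deliberately small (8-32 per stage) so the nets train
in minutes on one CPU; the figures these topologies follow specify
connectivity, not widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ivivr.nn.layers import (BatchNorm2D, Conv2D, Dense, Dropout, Flatten,
                             GlobalAvgPool, InceptionModule, MaxPool2D, ReLU,
                             Residual, Sequential)
from ivivr.nn.net import Network, plan_hash

ARCHITECTURE_NAMES = ("own1", "own2", "own3", "inception_like", "vgg_like",
                      "resnet_like")

DROPOUT_P = 0.25


@dataclass(frozen=True)
class ArchitectureSpec:
    """Serializable, hashable description of a built architecture."""

    name: str
    input_layout: tuple[int, int, int]  # (planes, height, width)
    layer_plan: dict
    parameter_count: int

    @property
    def hash(self) -> str:
        return plan_hash(self.layer_plan)

    def to_dict(self) -> dict:
        return {"name": self.name, "input_layout": list(self.input_layout),
                "layer_plan": self.layer_plan,
                "parameter_count": self.parameter_count,
                "hash": self.hash}


class _Builder:
    """Tracks the running (C, H, W) shape while layers are appended."""

    def __init__(self, layout: tuple[int, int, int],
                 rng: np.random.Generator):
        self.shape = layout
        self.rng = rng
        self.layers: list = []

    def add(self, layer) -> None:
        self.shape = layer.out_shape(self.shape)
        if min(self.shape[1:]) < 1:
            raise ValueError("input layout too small for this plan's downsampling")
        self.layers.append(layer)

    def conv(self, cout: int, k: int = 3, stride: int = 1) -> None:
        self.add(Conv2D(self.shape[0], cout, k, stride=stride, rng=self.rng))

    def pool(self) -> None:
        if self.shape[1] % 2 or self.shape[2] % 2:
            raise ValueError(
                f"input layout too small/odd for pooling at {self.shape}")
        self.add(MaxPool2D())

    def dense(self, units: int) -> None:
        self.add(Dense(self.shape[0], units, rng=self.rng))


def build_architecture(name: str, input_layout: tuple[int, int, int],
                       seed: int = 0) -> Network:
    """Build one of the six architectures with seeded initialisation."""
    if name not in ARCHITECTURE_NAMES:
        raise ValueError(f"unknown architecture {name!r}; "
                         f"expected one of {ARCHITECTURE_NAMES}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    b = _Builder(tuple(int(v) for v in input_layout), rng)
    if name == "own1":
        b.conv(8); b.add(ReLU()); b.pool()
        b.conv(16); b.add(ReLU()); b.pool()
        b.add(GlobalAvgPool()); b.dense(1)
    elif name == "own2":
        for w in (8, 16, 32):
            b.conv(w); b.add(BatchNorm2D(w)); b.add(ReLU()); b.pool()
        b.add(GlobalAvgPool()); b.dense(1)
    elif name == "own3":
        for w in (8, 16, 32):
            b.conv(w); b.add(ReLU()); b.pool(); b.add(Dropout(DROPOUT_P))
        b.add(Flatten()); b.dense(32); b.add(ReLU())
        b.add(Dropout(DROPOUT_P)); b.dense(1)
    elif name == "vgg_like":
        for w in (8, 16, 32):
            b.conv(w); b.add(ReLU()); b.conv(w); b.add(ReLU()); b.pool()
        b.add(Flatten()); b.dense(32); b.add(ReLU()); b.dense(1)
    elif name == "resnet_like":
        b.conv(16, stride=2); b.add(BatchNorm2D(16)); b.add(ReLU())
        body = Sequential([
            Conv2D(16, 16, 3, rng=rng), BatchNorm2D(16), ReLU(),
            Conv2D(16, 16, 3, rng=rng), BatchNorm2D(16),
        ])
        b.add(Residual(body))
        b.add(GlobalAvgPool()); b.dense(1)
    elif name == "inception_like":
        b.conv(16, stride=2); b.add(ReLU()); b.pool()
        b.add(InceptionModule(16, 8, 8, 16, 4, 8, 8, rng))
        b.add(InceptionModule(40, 16, 16, 32, 8, 16, 16, rng))
        b.add(GlobalAvgPool()); b.dense(1)
    root = Sequential(b.layers)
    net = Network(root, spec=None)
    spec = ArchitectureSpec(name=name,
                            input_layout=tuple(int(v) for v in input_layout),
                            layer_plan=root.plan(),
                            parameter_count=net.parameter_count)
    net.spec = spec
    return net
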