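"""The MSE-VGG classifier: a VGG-16-shape backbone (13 convolutional
layers, 3 fully connected layers, 5 max-pooling stages) with one
squeeze-and-excitation block after each pooling stage.

A ``width_multiplier`` scales every stage width (and the FC width) down
for desk-scale experiments while preserving the layer census; setting
``se_enabled=False`` builds the plain-VGG ablation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ConfigurationError
from .layers import Conv2d, Flatten, Linear, MaxPool2, Network, ReLU, SEBlock

#: VGG-16 convolution plan: (stage width, number of 3x3 convs)
STAGE_PLAN: tuple[tuple[int, int], ...] = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

FC_WIDTH = 4096


@dataclass
class SeBlockConfig:
    channels: int
    reduction: int = 16

    @property
    def hidden(self) -> int:
        return max(1, self.channels // self.reduction)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by 32 (five 2x down-samplings);
    224 is the full-scale default, 64 or 32 for desk-scale runs.
    """

    input_size: int = 224
    in_channels: int = 3
    n_classes: int = 2
    width_multiplier: float = 1.0
    se_reduction: int = 16
    se_enabled: bool = True
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 32 or self.input_size % 32 != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} is not compatible with 5 halvings"
            )
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")

    def stage_widths(self) -> list[int]:
        return [max(1, int(round(w * self.width_multiplier))) for w, _ in STAGE_PLAN]

    def fc_width(self) -> int:
        return max(2, int(round(FC_WIDTH * self.width_multiplier)))


def build_model(cfg: ModelConfig) -> Network:
    """Build the (M)SE-VGG network with seeded initialization."""
    rng = np.random.default_rng(cfg.init_seed)
    layers = []
    in_ch = cfg.in_channels
    for (base_w, n_convs), width in zip(STAGE_PLAN, cfg.stage_widths()):
        for _ in range(n_convs):
            layers.append(Conv2d(in_ch, width, rng))
            layers.append(ReLU())
            in_ch = width
        layers.append(MaxPool2())
        if cfg.se_enabled:
            layers.append(SEBlock(width, cfg.se_reduction, rng))
    layers.append(Flatten())
    spatial = cfg.input_size // 32
    fc_w = cfg.fc_width()
    layers.append(Linear(in_ch * spatial * spatial, fc_w, rng))
    layers.append(ReLU())
    layers.append(Linear(fc_w, fc_w, rng))
    layers.append(ReLU())
    layers.append(Linear(fc_w, cfg.n_classes, rng))
    return Network(layers)


def layer_census(network: Network) -> dict:
    """Introspect the architecture: layer counts and kernel sizes."""
    convs = [l for l in network.layers if isinstance(l, Conv2d)]
    return {
        "conv": len(convs),
        "fc": sum(isinstance(l, Linear) for l in network.layers),
        "pool": sum(isinstance(l, MaxPool2) for l in network.layers),
        "se": sum(isinstance(l, SEBlock) for l in network.layers),
        "kernel_sizes": sorted({l.kernel_size for l in convs}),
    }


def se_parameter_count(cfg: ModelConfig) -> int:
    """Parameters added by the SE gates: per stage 2*C*hidden + hidden + C."""
    total = 0
    for width in cfg.stage_widths():
        hidden = max(1, width // cfg.se_reduction)
        total += width * hidden * 2 + hidden + width
    return total


def set_se_identity(network: Network, identity: bool = True) -> None:
    """Force every SE gate to behave as multiplication by 1."""
    for layer in network.layers:
        if isinstance(layer, SEBlock):
            layer.force_identity = identity


def save_checkpoint(network: Network, cfg: ModelConfig, path: str | Path) -> None:
    """Single-file weight archive with the config echoed alongside."""
    state = network.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[Network, ModelConfig]:
    with np.load(path) as archive:
        cfg = ModelConfig(**json.loads(bytes(archive["__config__"]).decode()))
        network = build_model(cfg)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    network.load_state_dict(state)
    return network, cfg
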