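"""Perceptual feature extractors for the feature-space loss.

The extractor interface is a frozen mapping from a grayscale image to
the activations of a chosen convolutional layer of a 16-layer VGG-style
network (conv layers counted post-ReLU; layer 8 by default). Production
use can load externally supplied pretrained weights from a checkpoint
file; the in-repo implementation draws seeded random weights of the same
topology, which exercises the loss machinery identically and keeps the
package self-contained and offline.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import autograd as ag

# VGG16 feature stack: conv widths with 'M' marking 2x2 max-pool
VGG16_LAYOUT = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                512, 512, 512, "M", 512, 512, 512)


class RandomVGGExtractor(nn.Module):
    """Frozen random-weight VGG16-topology feature extractor.

    ``layer_index`` counts convolutional layers (1-based); features are
    taken after that layer's rectifier. ``width_scale`` shrinks every
    conv width proportionally (minimum 1 channel) for desk-scale runs.
    """

    def __init__(self, layer_index: int = 8, width_scale: float = 1.0,
                 seed: int = 0):
        super().__init__()
        if layer_index < 1 or layer_index > sum(1 for v in VGG16_LAYOUT if v != "M"):
            raise ValueError("layer_index must address a VGG16 conv layer")
        rng = np.random.default_rng(seed)
        self.layer_index = int(layer_index)
        self.width_scale = float(width_scale)
        self.convs = nn.ModuleList()
        self.plan: list[str] = []  # 'conv' / 'pool' execution order
        in_ch, n_conv, self.n_pools = 3, 0, 0
        for item in VGG16_LAYOUT:
            if item == "M":
                self.plan.append("pool")
                self.n_pools += 1
                continue
            width = max(1, int(round(item * width_scale)))
            self.convs.append(nn.Conv2d(in_ch, width, 3, rng))
            self.plan.append("conv")
            in_ch = width
            n_conv += 1
            if n_conv == self.layer_index:
                break
        self.out_channels = in_ch
        for p in self.parameters():
            p.requires_grad = False  # frozen during loss computation

    def min_input_size(self) -> int:
        return 2 ** self.n_pools

    def layer_dims(self, height: int, width: int) -> tuple[int, int, int]:
        """(Hi, Wi, channels) of the feature stack for a given input size."""
        f = 2 ** self.n_pools
        return height // f, width // f, self.out_channels

    def features(self, x: nn.Tensor) -> nn.Tensor:
        """x: (N, 1, H, W) grayscale in [0,1]; replicated to 3 channels."""
        n, c, h, w = x.shape
        if c != 1:
            raise ValueError("extractor expects single-channel input")
        m = self.min_input_size()
        if h < m or w < m:
            raise ValueError(
                f"input {h}x{w} too small for layer {self.layer_index} "
                f"features (needs >= {m}x{m})"
            )
        y = ag.concat_channels([x, x, x])
        it = iter(self.convs)
        for step in self.plan:
            if step == "pool":
                y = ag.maxpool2(y)
            else:
                y = ag.relu(next(it)(y))
        return y


def load_pretrained_extractor(path) -> RandomVGGExtractor:
    """Load an externally supplied VGG16-topology weight checkpoint."""
    state, config, _ = nn.load_checkpoint(path)
    model = RandomVGGExtractor(
        layer_index=config["layer_index"],
        width_scale=config.get("width_scale", 1.0),
    )
    model.load_state_dict(state)
    for p in model.parameters():
        p.requires_grad = False
    return model


def save_extractor(path, model: RandomVGGExtractor) -> None:
    nn.save_checkpoint(
        path, model,
        {"kind": "perceptual_extractor", "layer_index": model.layer_index,
         "width_scale": model.width_scale},
    )
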