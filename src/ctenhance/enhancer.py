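"""Residual-dense-inception network for joint denoising + super-resolution.

The degraded image is concatenated with its (t+1)-channel degradation
maps and mapped through: a pre-processing convolution into feature space
(128 channels by default), a series of residual-dense-inception (RDI)
blocks, a convolution to base*r^2 channels followed by sub-pixel
rearrangement (learned x r upscaling), and a 3x3 reconstruction
convolution with a sigmoid squashing the output into (0, 1).

An RDI block is a residual-dense block in which every skip-connection
routing and the block-level residual connection first passes through an
inception block (parallel 1x1/3x3/5x5 branches, concatenated and 1x1-
projected back to the routed feature's channel count) — the intent is
to forward structural features through the skips while filtering noise
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import TrainConfig
from .degradation import (
    DegradationMaps,
    KernelProjector,
    SRPair,
    build_degradation_maps,
)
from .images import as_image, clip01
from .metrics import LossWeights, joint_loss_tensor
from .nn import autograd as ag


@dataclass(frozen=True)
class EnhancerConfig:
    base_channels: int = 128
    n_rdi_blocks: int = 3
    convs_per_block: int = 4
    growth: int = 32
    inception_widths: tuple = (32, 32, 32)
    scale_factor: int = 2
    t: int = 15
    global_residual: bool = True

    def __post_init__(self):
        if self.base_channels < 1 or self.growth < 1:
            raise ValueError("channel counts must be >= 1")
        if self.n_rdi_blocks < 1 or self.convs_per_block < 1:
            raise ValueError("need at least one block and one conv per block")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        object.__setattr__(
            self, "inception_widths", tuple(int(w) for w in self.inception_widths)
        )

    @property
    def in_channels(self) -> int:
        return self.t + 2  # degraded image + t kernel channels + noise channel


class InceptionBlock(nn.Module):
    """Parallel 1x1/3x3/5x5 convolutions, channel-concatenated and
    projected back to the source channel count by a 1x1 convolution."""

    def __init__(self, channels, widths, rng):
        super().__init__()
        w1, w3, w5 = widths
        self.branch1 = nn.Conv2d(channels, w1, 1, rng)
        self.branch3 = nn.Conv2d(channels, w3, 3, rng)
        self.branch5 = nn.Conv2d(channels, w5, 5, rng)
        self.proj = nn.Conv2d(w1 + w3 + w5, channels, 1, rng)

    def forward(self, x):
        cat = ag.concat_channels([
            ag.relu(self.branch1(x)),
            ag.relu(self.branch3(x)),
            ag.relu(self.branch5(x)),
        ])
        return self.proj(cat)


class RDIBlock(nn.Module):
    """Residual-dense block with inception-filtered routings.

    Internal convolution j consumes base + (j-1)*growth channels: the
    concatenation of the (inception-routed) block input and all prior
    internal outputs. A 1x1 fusion returns to base channels and the
    inception-filtered block input is added as the residual.
    """

    def __init__(self, cfg: EnhancerConfig, rng):
        super().__init__()
        base, g, m = cfg.base_channels, cfg.growth, cfg.convs_per_block
        self.route_inceptions = nn.ModuleList(
            [InceptionBlock(base, cfg.inception_widths, rng)]
            + [InceptionBlock(g, cfg.inception_widths, rng) for _ in range(m - 1)]
        )
        self.convs = nn.ModuleList(
            [nn.Conv2d(base + j * g, g, 3, rng) for j in range(m)]
        )
        self.fusion = nn.Conv2d(base + m * g, base, 1, rng)
        self.residual_inception = InceptionBlock(base, cfg.inception_widths, rng)

    def forward(self, x):
        routed = [self.route_inceptions[0](x)]
        outputs = []
        for j, conv in enumerate(self.convs):
            cat = routed[0] if len(routed) == 1 else ag.concat_channels(routed)
            y = ag.relu(conv(cat))
            outputs.append(y)
            if j + 1 < len(self.convs):
                routed.append(self.route_inceptions[j + 1](y))
        fused = self.fusion(ag.concat_channels([routed[0], *outputs]))
        return ag.add(fused, self.residual_inception(x))


class Enhancer(nn.Module):
    def __init__(self, config: EnhancerConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        base, r = cfg.base_channels, cfg.scale_factor
        self.pre = nn.Conv2d(cfg.in_channels, base, 3, rng)
        self.blocks = nn.ModuleList([RDIBlock(cfg, rng) for _ in range(cfg.n_rdi_blocks)])
        self.upscale = nn.Conv2d(base, base * r * r, 3, rng)
        self.reconstruct = nn.Conv2d(base, 1, 3, rng)
        # damp the reconstruction logits at init: the output sigmoid then
        # starts near mid-gray instead of saturating, which keeps its
        # gradient alive early in training
        self.reconstruct.weight.data *= 0.1

    def forward(self, x):
        """x: (N, t+2, H, W) -> (N, 1, rH, rW), values in (0, 1)."""
        feat = ag.relu(self.pre(x))
        out = feat
        for block in self.blocks:
            out = block(out)
        if self.config.global_residual:
            out = ag.add(out, feat)
        up = ag.pixel_shuffle(self.upscale(out), self.config.scale_factor)
        return ag.sigmoid(self.reconstruct(up))


def build_enhancer(config: EnhancerConfig | None = None, seed: int = 0) -> Enhancer:
    return Enhancer(config or EnhancerConfig(), seed=seed)


def pixel_shuffle(features: np.ndarray, r: int) -> np.ndarray:
    """Sub-pixel rearrangement on a plain (C*r^2, H, W) array.

    out[c, r*h+dy, r*w+dx] = in[c*r^2 + dy*r + dx, h, w]; a bijective
    re-indexing, so the multiset of values is conserved.
    """
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a (C, H, W) feature stack")
    return ag.pixel_shuffle(nn.Tensor(arr[None]), r).data[0]


def _stack_input(degraded: np.ndarray, maps: DegradationMaps) -> np.ndarray:
    if maps.channels.shape[1:] != degraded.shape:
        raise ValueError(
            f"degradation maps {maps.channels.shape[1:]} do not match "
            f"image {degraded.shape}"
        )
    return np.concatenate([degraded[None], maps.channels], axis=0)


def enhance(
    model: Enhancer,
    degraded: np.ndarray,
    maps: DegradationMaps,
    tile: int = 40,
    overlap: int = 8,
) -> np.ndarray:
    """Run the enhancer on a full image, tiling with overlap-and-blend
    when the input exceeds ``tile`` pixels on a side. Deterministic in
    evaluation mode."""
    degraded = as_image(degraded)
    cfg = model.config
    if maps.t != cfg.t:
        raise ValueError(f"maps have t={maps.t}, model expects t={cfg.t}")
    stack = _stack_input(degraded, maps)
    h, w = degraded.shape
    was_training = model.training
    model.eval()
    try:
        if h <= tile and w <= tile:
            with nn.no_grad():
                out = model(nn.Tensor(stack[None])).data[0, 0]
            return clip01(out)
        return _tiled_forward(model, stack, tile, overlap)
    finally:
        model.train(was_training)


def _tiled_forward(model, stack, tile, overlap):
    r = model.config.scale_factor
    _, h, w = stack.shape
    step = max(1, tile - overlap)
    out = np.zeros((h * r, w * r))
    weight = np.zeros((h * r, w * r))
    ys = _tile_origins(h, tile, step)
    xs = _tile_origins(w, tile, step)
    for y0 in ys:
        for x0 in xs:
            th, tw = min(tile, h - y0), min(tile, w - x0)
            patch = stack[:, y0:y0 + th, x0:x0 + tw]
            with nn.no_grad():
                pred = model(nn.Tensor(patch[None])).data[0, 0]
            wgt = np.outer(_ramp(th * r, overlap * r), _ramp(tw * r, overlap * r))
            out[y0 * r:(y0 + th) * r, x0 * r:(x0 + tw) * r] += pred * wgt
            weight[y0 * r:(y0 + th) * r, x0 * r:(x0 + tw) * r] += wgt
    return clip01(out / np.maximum(weight, 1e-12))


def _tile_origins(extent, tile, step):
    if extent <= tile:
        return [0]
    origins = list(range(0, extent - tile, step))
    origins.append(extent - tile)
    return origins


def _ramp(length, margin):
    """Linear blend weights: ramp up/down across the overlap margin."""
    w = np.ones(length)
    m = min(margin, length // 2)
    if m > 0:
        edge = (np.arange(1, m + 1)) / (m + 1)
        w[:m] = edge
        w[-m:] = edge[::-1]
    return w


def train_enhancer(
    model: Enhancer,
    pairs: list[SRPair],
    projector: KernelProjector,
    train_cfg: TrainConfig | None = None,
    loss_weights: LossWeights | None = None,
    extractor=None,
    seed: int = 0,
) -> tuple[Enhancer, list[float]]:
    """Optimize the joint (pixel + mu * perceptual) loss on random
    aligned crops of the training pairs.

    Each step samples ``batch_size`` degraded crops of ``crop_size``
    pixels with the matching target crops at crop_size * r, rebuilds the
    (spatially uniform) degradation maps at crop size from each pair's
    degradation parameters, and takes one Adam step. Returns the model
    and the per-step joint-loss history.
    """
    if not pairs:
        raise ValueError("training pairs list is empty")
    cfg = train_cfg or TrainConfig(learning_rate=1e-2, batch_size=20, steps=200_000)
    weights = loss_weights or LossWeights()
    r = model.config.scale_factor
    crop = cfg.crop_size
    for i, pair in enumerate(pairs):
        if pair.degraded.shape[0] < crop or pair.degraded.shape[1] < crop:
            raise ValueError(
                f"pair {i}: degraded image {pair.degraded.shape} smaller than "
                f"crop size {crop}"
            )
    if weights.mu > 0 and extractor is None:
        raise ValueError("perceptual weight mu > 0 requires an extractor")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2,
                  weight_decay=cfg.weight_decay)
    map_cache: dict[int, np.ndarray] = {}
    history: list[float] = []
    model.train()
    for step in range(cfg.steps):
        if cfg.lr_decay_every:
            opt.lr = cfg.learning_rate * cfg.lr_decay_factor ** (step // cfg.lr_decay_every)
        lo_batch, hi_batch = [], []
        for _ in range(cfg.batch_size):
            i = int(rng.integers(len(pairs)))
            pair = pairs[i]
            if i not in map_cache:
                map_cache[i] = build_degradation_maps(
                    pair.spec.kernel, pair.spec.sigma, crop, crop, projector
                ).channels
            y = int(rng.integers(pair.degraded.shape[0] - crop + 1))
            x = int(rng.integers(pair.degraded.shape[1] - crop + 1))
            lo = pair.degraded[y:y + crop, x:x + crop]
            hi = pair.target[y * r:(y + crop) * r, x * r:(x + crop) * r]
            lo_batch.append(np.concatenate([lo[None], map_cache[i]], axis=0))
            hi_batch.append(hi[None])
        pred = model(nn.Tensor(np.stack(lo_batch)))
        loss = joint_loss_tensor(pred, nn.Tensor(np.stack(hi_batch)),
                                 extractor, weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
    model.eval()
    return model, history


def save_enhancer(path, model: Enhancer, projector: KernelProjector,
                  loss_weights: LossWeights | None = None) -> None:
    cfg = model.config
    config = {
        "kind": "enhancer",
        "base_channels": cfg.base_channels,
        "n_rdi_blocks": cfg.n_rdi_blocks,
        "convs_per_block": cfg.convs_per_block,
        "growth": cfg.growth,
        "inception_widths": list(cfg.inception_widths),
        "scale_factor": cfg.scale_factor,
        "t": cfg.t,
        "global_residual": cfg.global_residual,
    }
    extra = {
        "projector_basis": np.asarray(projector.basis).tolist(),
        "projector_kernel_size": projector.kernel_size,
    }
    if loss_weights is not None:
        extra["mu"] = loss_weights.mu
        extra["perceptual_layer"] = loss_weights.perceptual_layer
    nn.save_checkpoint(path, model, config, extra)


def load_enhancer(path) -> tuple[Enhancer, KernelProjector]:
    state, config, extra = nn.load_checkpoint(path)
    if config.get("kind") != "enhancer":
        raise ValueError("checkpoint is not an enhancer checkpoint")
    cfg = EnhancerConfig(
        base_channels=config["base_channels"],
        n_rdi_blocks=config["n_rdi_blocks"],
        convs_per_block=config["convs_per_block"],
        growth=config["growth"],
        inception_widths=tuple(config["inception_widths"]),
        scale_factor=config["scale_factor"],
        t=config["t"],
        global_residual=config["global_residual"],
    )
    model = Enhancer(cfg)
    model.load_state_dict(state)
    model.eval()
    projector = KernelProjector(
        basis=np.asarray(extra["projector_basis"]),
        kernel_size=extra["projector_kernel_size"],
    )
    return model, projector
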