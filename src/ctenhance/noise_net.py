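"""Dense-inception network for blind noise-level classification.

A noisy patch is mapped to a probability distribution over a discrete
set of noise levels. The network is a convolutional stem (conv 96 ->
batch-norm -> ReLU -> 2x2 max-pool) followed by three inception-residual
blocks wired densely: the input of block n is the channel concatenation
of the stem output and all previous block outputs, reduced by a 1x1
bottleneck so parameter counts stay flat. Global average pooling and a
fully-connected softmax head produce the class probabilities; the argmax
class is the estimated noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import TrainConfig
from .degradation import LabeledPatch, NoiseLevelClassSet
from .images import as_image
from .nn import autograd as ag


@dataclass(frozen=True)
class NoiseEstimatorConfig:
    pre_channels: int = 96
    n_inception_blocks: int = 3
    branch_widths: tuple = (32, 32, 32)
    reduction_channels: int = 32
    bottleneck_channels: int = 96
    n_classes: int = 10
    input_size: int = 100

    def __post_init__(self):
        if min(self.pre_channels, self.reduction_channels,
               self.bottleneck_channels, *self.branch_widths) < 1:
            raise ValueError("all channel counts must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_inception_blocks < 1:
            raise ValueError("need at least 1 inception-residual block")
        if self.input_size < 4 or self.input_size % 2:
            raise ValueError("input_size must be even and >= 4")
        object.__setattr__(self, "branch_widths", tuple(int(w) for w in self.branch_widths))


@dataclass(frozen=True)
class ClassPrediction:
    """Softmax probabilities, the argmax class, and its noise level."""

    probabilities: np.ndarray
    class_index: int
    level: float


class InceptionResidualBlock(nn.Module):
    """Parallel 1x1/3x3/5x5 branches behind a shared 1x1 reduction,
    channel-concatenated, projected back to the input width by a 1x1
    convolution, and added to the block input (short-cut). Spatial size
    is preserved throughout (same padding). With all convolution weights
    and biases zero the block is the identity map."""

    def __init__(self, channels, branch_widths, reduction_channels, rng):
        super().__init__()
        self.in_channels = self.out_channels = int(channels)
        self.reduce = nn.ConvBNReLU(channels, reduction_channels, 1, rng)
        w1, w3, w5 = branch_widths
        self.branch1 = nn.ConvBNReLU(reduction_channels, w1, 1, rng)
        self.branch3 = nn.ConvBNReLU(reduction_channels, w3, 3, rng)
        self.branch5 = nn.ConvBNReLU(reduction_channels, w5, 5, rng)
        self.proj = nn.Conv2d(w1 + w3 + w5, channels, 1, rng)
        self.proj_bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        r = self.reduce(x)
        cat = ag.concat_channels([self.branch1(r), self.branch3(r), self.branch5(r)])
        return ag.add(self.proj_bn(self.proj(cat)), x)


class NoiseEstimator(nn.Module):
    def __init__(self, config: NoiseEstimatorConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        self.stem = nn.ConvBNReLU(1, cfg.pre_channels, 3, rng)
        self.bottlenecks = nn.ModuleList()
        self.blocks = nn.ModuleList()
        # concat_channels[n] = channels entering the 1x1 bottleneck of block n:
        # stem output plus every previous block output (dense wiring)
        self.concat_channels: list[int] = []
        for n in range(cfg.n_inception_blocks):
            in_ch = cfg.pre_channels + n * cfg.bottleneck_channels
            self.concat_channels.append(in_ch)
            self.bottlenecks.append(
                nn.ConvBNReLU(in_ch, cfg.bottleneck_channels, 1, rng)
            )
            self.blocks.append(
                InceptionResidualBlock(
                    cfg.bottleneck_channels, cfg.branch_widths,
                    cfg.reduction_channels, rng,
                )
            )
        self.fc = nn.Linear(cfg.bottleneck_channels, cfg.n_classes, rng)

    def forward(self, x):
        """x: (N, 1, input_size, input_size) -> logits (N, n_classes)."""
        stem = ag.maxpool2(self.stem(x))
        stack = [stem]
        out = stem
        for bottleneck, block in zip(self.bottlenecks, self.blocks):
            cat = stack[0] if len(stack) == 1 else ag.concat_channels(stack)
            out = block(bottleneck(cat))
            stack.append(out)
        pooled = ag.global_avg_pool(out)
        return self.fc(pooled)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a (N, H, W) batch, evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(nn.Tensor(patches[:, None, :, :]))
        finally:
            self.train(was_training)
        return ag.softmax(logits.data)


def build_noise_estimator(config: NoiseEstimatorConfig | None = None,
                          seed: int = 0) -> NoiseEstimator:
    return NoiseEstimator(config or NoiseEstimatorConfig(), seed=seed)


def classify_noise(model: NoiseEstimator, patch: np.ndarray,
                   classes: NoiseLevelClassSet | None = None) -> ClassPrediction:
    """Classify one patch; the largest softmax probability wins."""
    patch = as_image(patch)
    s = model.config.input_size
    if patch.shape != (s, s):
        raise ValueError(
            f"expected a {s}x{s} patch (model input size), got {patch.shape}"
        )
    probs = model.predict_proba(patch[None])[0]
    idx = int(np.argmax(probs))
    if classes is None:
        classes = NoiseLevelClassSet()
    level = classes.levels[idx] if idx < classes.n_classes else float(idx)
    return ClassPrediction(probabilities=probs, class_index=idx, level=level)


def train_noise_estimator(
    model: NoiseEstimator,
    dataset: list[LabeledPatch],
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[NoiseEstimator, list[float]]:
    """Minimize cross-entropy + L2 weight penalty with Adam.

    Returns the model and the per-epoch mean training loss. Reproducible
    under a fixed seed (shuffling is the only randomness).
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    cfg = train_cfg or TrainConfig(weight_decay=1e-4)
    n_classes = model.config.n_classes
    labels = np.array([item.class_index for item in dataset])
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels must lie in [0, {n_classes}); got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    patches = np.stack([item.patch for item in dataset])[:, None, :, :]
    rng = np.random.default_rng(seed)
    opt = nn.Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    history: list[float] = []
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:  # batch-norm needs more than one sample
                continue
            logits = model(nn.Tensor(patches[idx]))
            loss = ag.softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)) if losses else float("nan"))
    model.eval()
    return model, history


def save_noise_estimator(path, model: NoiseEstimator,
                         classes: NoiseLevelClassSet | None = None) -> None:
    cfg = model.config
    config = {
        "kind": "noise_estimator",
        "pre_channels": cfg.pre_channels,
        "n_inception_blocks": cfg.n_inception_blocks,
        "branch_widths": list(cfg.branch_widths),
        "reduction_channels": cfg.reduction_channels,
        "bottleneck_channels": cfg.bottleneck_channels,
        "n_classes": cfg.n_classes,
        "input_size": cfg.input_size,
    }
    extra = {}
    if classes is not None:
        extra["class_levels"] = list(classes.levels)
        extra["level_is_variance"] = classes.level_is_variance
    nn.save_checkpoint(path, model, config, extra)


def load_noise_estimator(path) -> tuple[NoiseEstimator, NoiseLevelClassSet | None]:
    state, config, extra = nn.load_checkpoint(path)
    if config.get("kind") != "noise_estimator":
        raise ValueError("checkpoint is not a noise-estimator checkpoint")
    cfg = NoiseEstimatorConfig(
        pre_channels=config["pre_channels"],
        n_inception_blocks=config["n_inception_blocks"],
        branch_widths=tuple(config["branch_widths"]),
        reduction_channels=config["reduction_channels"],
        bottleneck_channels=config["bottleneck_channels"],
        n_classes=config["n_classes"],
        input_size=config["input_size"],
    )
    model = NoiseEstimator(cfg)
    model.load_state_dict(state)
    model.eval()
    classes = None
    if "class_levels" in extra:
        classes = NoiseLevelClassSet(
            levels=tuple(extra["class_levels"]),
            level_is_variance=extra.get("level_is_variance", False),
        )
    return model, classes
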