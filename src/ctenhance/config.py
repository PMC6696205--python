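"""Shared training-hyperparameter container."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class TrainConfig:
    """Adaptive-moment optimizer settings.

    ``epochs`` drives epoch-based training (the classifier); ``steps``
    drives step-based training (the enhancer). ``weight_decay`` is the
    L2 penalty coefficient. The learning rate is multiplied by
    ``lr_decay_factor`` every ``lr_decay_every`` steps (0 disables).
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 40
    epochs: int = 40
    steps: int = 0
    weight_decay: float = 0.0
    lr_decay_every: int = 0
    lr_decay_factor: float = 0.5
    crop_size: int = 40

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0 or self.steps < 0:
            raise ValueError("epochs/steps must be >= 0")


def classifier_defaults() -> TrainConfig:
    """Reference training recipe for the noise classifier: lr 1e-3,
    betas (0.9, 0.999), batch 40, 40 epochs, L2 coefficient 1e-4."""
    return TrainConfig(
        learning_rate=1e-3,
        beta1=0.9,
        beta2=0.999,
        batch_size=40,
        epochs=40,
        weight_decay=1e-4,
    )


def enhancer_defaults() -> TrainConfig:
    """Reference training recipe for the enhancement network: lr 1e-2,
    batch 20, 200 000 steps, 40x40 training crops."""
    return TrainConfig(
        learning_rate=1e-2,
        beta1=0.9,
        beta2=0.999,
        batch_size=20,
        epochs=0,
        steps=200_000,
        lr_decay_every=50_000,
        lr_decay_factor=0.5,
        crop_size=40,
    )
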