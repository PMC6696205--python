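"""Joint loss and evaluation statistics.

The training objective is L_joint = L_pix + mu * L_perc, where L_pix is
the per-pixel mean square error on [0,1] intensities and L_perc is the
squared Euclidean distance between deep features of the reconstruction
and the target, normalized by the feature-map area. Evaluation side:
PSNR (0-255 convention), SSIM (11x11 Gaussian window, sigma 1.5),
absolute-difference maps, and the confusion-matrix statistics
(precision / recall / F1 / confusion rate / accuracy) for the noise
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from . import nn
from .degradation import LabeledPatch, NoiseLevelClassSet
from .images import as_image
from .nn import autograd as ag


@dataclass(frozen=True)
class LossWeights:
    """mu weighs the perceptual term; perceptual_layer is the VGG-style
    conv layer (1-based, post-ReLU) whose features define L_perc."""

    mu: float = 0.01
    perceptual_layer: int = 8

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.perceptual_layer < 1:
            raise ValueError("perceptual_layer must be >= 1")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# losses (NumPy surface + tensor versions used during training)
# ---------------------------------------------------------------------------

def pixel_loss(reconstructed: np.ndarray, target: np.ndarray) -> float:
    """(1/(W*H)) * ||F(y) - x||^2 on [0,1] intensities."""
    a, b = np.asarray(reconstructed, float), np.asarray(target, float)
    _check_same_shape(a, b)
    return float(np.mean((a - b) ** 2))


def perceptual_loss(reconstructed: np.ndarray, target: np.ndarray,
                    extractor) -> float:
    """(1/(Wi*Hi)) * ||phi_i(F(y)) - phi_i(x)||^2 under a frozen extractor."""
    a, b = as_image(reconstructed), as_image(target)
    _check_same_shape(a, b)
    with nn.no_grad():
        fa = extractor.features(nn.Tensor(a[None, None]))
        fb = extractor.features(nn.Tensor(b[None, None]))
        _, _, hi, wi = fa.shape
        return ag.scaled_sq_error(fa, fb, float(hi * wi)).item()


def joint_loss(reconstructed: np.ndarray, target: np.ndarray, extractor,
               weights: LossWeights) -> float:
    """L_pix + mu * L_perc."""
    total = pixel_loss(reconstructed, target)
    if weights.mu > 0:
        total += weights.mu * perceptual_loss(reconstructed, target, extractor)
    return total


def pixel_loss_tensor(pred: nn.Tensor, target: nn.Tensor) -> nn.Tensor:
    n, _, h, w = pred.shape
    return ag.scaled_sq_error(pred, target, float(n * h * w))


def perceptual_loss_tensor(pred: nn.Tensor, target: nn.Tensor,
                           extractor) -> nn.Tensor:
    fa = extractor.features(pred)
    fb = extractor.features(target)
    n, _, hi, wi = fa.shape
    return ag.scaled_sq_error(fa, fb, float(n * hi * wi))


def joint_loss_tensor(pred: nn.Tensor, target: nn.Tensor, extractor,
                      weights: LossWeights) -> nn.Tensor:
    loss = pixel_loss_tensor(pred, target)
    if weights.mu > 0:
        loss = ag.add(loss, ag.scale(
            perceptual_loss_tensor(pred, target, extractor), weights.mu))
    return loss


def calibrate_mu(sample_pairs, extractor, target_ratio: float = 1.0) -> float:
    """Choose mu so mu * L_perc has ``target_ratio`` times the magnitude
    of L_pix on a sample of (reconstructed, target) image pairs."""
    pix, perc = [], []
    for rec, tgt in sample_pairs:
        pix.append(pixel_loss(rec, tgt))
        perc.append(perceptual_loss(rec, tgt, extractor))
    mean_perc = float(np.mean(perc))
    if mean_perc == 0:
        return 0.0
    return target_ratio * float(np.mean(pix)) / mean_perc


# ---------------------------------------------------------------------------
# image quality metrics
# ---------------------------------------------------------------------------

def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 255.0,
         cap: float = 100.0) -> float:
    """10*log10(max^2 / MSE) with [0,1] intensities mapped to 0-max_value.

    Identical images return the configured cap (infinity is unrepresentable).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    _check_same_shape(a, b)
    mse = np.mean(((a - b) * max_value) ** 2)
    if mse == 0:
        return float(cap)
    return float(min(cap, 10.0 * np.log10(max_value ** 2 / mse)))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local SSIM, 11x11 Gaussian window (sigma 1.5), K1=0.01,
    K2=0.03, dynamic range 255."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    _check_same_shape(a, b)
    if min(a.shape) < 11:
        raise ValueError("SSIM needs images of at least 11x11")
    return float(structural_similarity(
        a * 255.0, b * 255.0,
        win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=255.0,
    ))


def difference_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference |a - b|."""
    a, b = as_image(a), as_image(b)
    _check_same_shape(a, b)
    return np.abs(a - b)


# ---------------------------------------------------------------------------
# classification statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = samples of actual class i predicted as class j."""

    counts: np.ndarray
    class_levels: NoiseLevelClassSet

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.shape[0] != self.class_levels.n_classes:
            raise ValueError("matrix size does not match the class set")
        object.__setattr__(self, "counts", c.astype(np.int64))


@dataclass(frozen=True)
class ClassReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion_rate: np.ndarray
    accuracy: float
    zero_precision_flag: np.ndarray  # True where the column sum was zero
    class_levels: NoiseLevelClassSet

    def as_dict(self) -> dict:
        return {
            "levels": list(self.class_levels.levels),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "confusion_rate": self.confusion_rate.tolist(),
            "accuracy": self.accuracy,
        }


def classification_report(matrix: ConfusionMatrix) -> ClassReport:
    """Per-class precision, recall, F1 and confusion rate (1 - recall),
    plus overall accuracy (trace / total). Values are kept at full
    precision; rounding is a display concern."""
    counts = matrix.counts.astype(np.float64)
    if counts.sum() == 0:
        raise ValueError("confusion matrix has no samples")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    zero_col = col == 0
    precision = np.where(zero_col, 0.0, diag / np.where(zero_col, 1.0, col))
    zero_row = row == 0
    recall = np.where(zero_row, 0.0, diag / np.where(zero_row, 1.0, row))
    denom = precision + recall
    f1 = np.where(denom > 0, 2.0 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return ClassReport(
        precision=precision,
        recall=recall,
        f1=f1,
        confusion_rate=1.0 - recall,
        accuracy=float(diag.sum() / counts.sum()),
        zero_precision_flag=zero_col,
        class_levels=matrix.class_levels,
    )


def evaluate_classifier(model, dataset: list[LabeledPatch],
                        classes: NoiseLevelClassSet,
                        batch_size: int = 100) -> ConfusionMatrix:
    """Count argmax predictions of ``model`` against the dataset labels."""
    if not dataset:
        raise ValueError("evaluation dataset is empty")
    n = classes.n_classes
    counts = np.zeros((n, n), dtype=np.int64)
    patches = np.stack([item.patch for item in dataset])
    labels = np.array([item.class_index for item in dataset])
    for start in range(0, len(dataset), batch_size):
        probs = model.predict_proba(patches[start:start + batch_size])
        preds = probs.argmax(axis=1)
        for actual, pred in zip(labels[start:start + batch_size], preds):
            counts[actual, pred] += 1
    return ConfusionMatrix(counts=counts, class_levels=classes)


def format_class_report(report: ClassReport) -> str:
    """Plain-text table in the customary classification-report
    layout: per-level P / R / F1 / confusion rate plus overall accuracy."""
    levels = report.class_levels.levels
    header = "Level    " + "".join(f"{lv:>8g}" for lv in levels)
    rows = [
        ("P", report.precision),
        ("R", report.recall),
        ("F1", report.f1),
        ("Conf", report.confusion_rate),
    ]
    lines = [header]
    for name, values in rows:
        lines.append(f"{name:<9}" + "".join(f"{v:>8.3f}" for v in values))
    lines.append(f"accuracy {report.accuracy:.4f}")
    return "\n".join(lines)
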