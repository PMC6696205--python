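"""Shared fixtures.

The expensive seeded training runs (toy classifier, toy enhancer,
desk-scale end-to-end experiment) are session-scoped so that the unit
smoke tests and the acceptance suite share one execution each.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import ctenhance as ce
from ctenhance.degradation import build_degradation_maps, delta_kernel
from ctenhance.pipeline import _blur_kernel_family


# Reference worked example: confusion matrix of a trained 10-class noise
# classifier (200 test samples per class, levels 0..18 step 2) together
# with the precision / recall / F1 and confusion-rate rows printed next
# to it. The printed level-2 confusion rate (0.160) disagrees with the
# matrix row (31/200 = 0.155) and is excluded from comparisons.
REFERENCE_COUNTS = np.array([
    [192, 8, 0, 0, 0, 0, 0, 0, 0, 0],
    [31, 169, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 200, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 200, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 3, 196, 1, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 198, 2, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 200, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 200, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 1, 199, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 200],
])
REFERENCE_PRINTED = {
    "precision": [0.86, 0.955, 1.00, 0.985, 1.00, 0.995, 0.99, 0.995, 1.00, 1.00],
    "recall": [0.96, 0.84, 1.00, 1.00, 0.98, 0.99, 1.00, 1.00, 0.995, 1.00],
    "f1": [0.91, 0.89, 1.00, 0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 1.00],
    "confusion_rate": [0.040, 0.160, 0.000, 0.000, 0.020, 0.010, 0.000,
                       0.000, 0.005, 0.000],
}


@pytest.fixture(scope="session")
def reference_confusion():
    classes = ce.NoiseLevelClassSet(tuple(float(v) for v in range(0, 19, 2)))
    return {
        "matrix": ce.ConfusionMatrix(counts=REFERENCE_COUNTS, class_levels=classes),
        "printed": REFERENCE_PRINTED,
    }


@pytest.fixture(scope="session")
def phantom_sources():
    return [ce.generate_phantom(128, seed=100 + i) for i in range(12)]


@pytest.fixture(scope="session")
def toy_estimator_run(phantom_sources):
    """3-class (sigma 0/9/18) classifier: 2000 training patches, 300
    held-out, 3 epochs, seeded."""
    classes = ce.NoiseLevelClassSet((0.0, 9.0, 18.0))
    patches = ce.make_noise_patch_dataset(
        phantom_sources, 32, 2300, classes, seed=1
    )
    train, held = patches[:2000], patches[2000:]
    cfg = ce.NoiseEstimatorConfig(
        pre_channels=12, branch_widths=(6, 6, 6), reduction_channels=8,
        bottleneck_channels=12, n_classes=3, input_size=32,
    )
    model = ce.build_noise_estimator(cfg, seed=0)
    train_cfg = ce.TrainConfig(
        learning_rate=1e-3, batch_size=32, epochs=3, weight_decay=1e-4
    )
    model, history = ce.train_noise_estimator(model, train, train_cfg, seed=0)
    matrix = ce.evaluate_classifier(model, held, classes)
    report = ce.classification_report(matrix)
    return {
        "model": model,
        "classes": classes,
        "history": history,
        "held": held,
        "matrix": matrix,
        "accuracy": report.accuracy,
    }


@pytest.fixture(scope="session")
def toy_enhancer_run(request):
    """Toy enhancer: 20 training pairs, 10 held-out, 300 steps, seeded.

    Returns the model, loss history, and held-out PSNR for the enhanced
    outputs and the bicubic baseline.
    """
    sources = [ce.generate_phantom(128, seed=200 + i) for i in range(30)]
    pairs = ce.make_sr_pairs(sources, [5, 10, 15], 2, seed=2)
    train, held = pairs[:20], pairs[20:]
    projector = ce.fit_kernel_projector(_blur_kernel_family(), t=3)
    cfg = ce.EnhancerConfig(
        base_channels=12, n_rdi_blocks=1, convs_per_block=2, growth=6,
        inception_widths=(4, 4, 4), scale_factor=2, t=3,
    )
    model = ce.build_enhancer(cfg, seed=0)
    extractor = ce.RandomVGGExtractor(layer_index=8, width_scale=1 / 16, seed=0)
    train_cfg = ce.TrainConfig(
        learning_rate=3e-3, batch_size=8, epochs=0, steps=300, crop_size=24
    )
    model, history = ce.train_enhancer(
        model, train, projector, train_cfg, ce.LossWeights(mu=0.01),
        extractor=extractor, seed=0,
    )
    psnr_enh, psnr_bicubic = [], []
    for pair in held:
        h, w = pair.degraded.shape
        maps = build_degradation_maps(
            delta_kernel(15), pair.spec.sigma, w, h, projector
        )
        out = ce.enhance(model, pair.degraded, maps, tile=64)
        psnr_enh.append(ce.psnr(out, pair.target))
        psnr_bicubic.append(ce.psnr(ce.bicubic_upsample(pair.degraded, 2), pair.target))
    return {
        "model": model,
        "projector": projector,
        "history": history,
        "held": held,
        "psnr_enhanced": psnr_enh,
        "psnr_bicubic": psnr_bicubic,
    }


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """The desk-scale experiment executed twice with the same seed."""
    base = tmp_path_factory.mktemp("desk")
    cfg = ce.desk_scale(seed=7)
    report_a = ce.run_experiment(cfg, base / "a", log=lambda m: None)
    report_b = ce.run_experiment(cfg, base / "b", log=lambda m: None)
    return {
        "dir_a": Path(base / "a"),
        "dir_b": Path(base / "b"),
        "report_a": report_a,
        "report_b": report_b,
        "config": cfg,
    }
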