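"""End-to-end blind enhancement pipeline.

Wires the two networks together: the classifier estimates the noise
level of a degraded image, the estimate is stretched into degradation
maps, and the enhancement network reconstructs the clean high-resolution
image. Also hosts dataset splitting, run configuration (desk-scale and
full-scale presets), and the four-stage experiment driver: build
datasets -> train both networks -> evaluate the classifier -> evaluate
the enhancement against the bicubic baseline. Every random draw flows
from one seed, so a rerun with the same config reproduces all reports
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import TrainConfig, classifier_defaults, enhancer_defaults
from .degradation import (
    KernelProjector,
    NoiseLevelClassSet,
    build_degradation_maps,
    delta_kernel,
    fit_kernel_projector,
    gaussian_kernel,
    make_noise_patch_dataset,
    make_sr_pairs,
)
from .enhancer import (
    Enhancer,
    EnhancerConfig,
    build_enhancer,
    enhance,
    save_enhancer,
    train_enhancer,
)
from .images import as_image, bicubic_upsample, load_image
from .metrics import (
    LossWeights,
    classification_report,
    evaluate_classifier,
    format_class_report,
    psnr,
    ssim,
)
from .noise_net import (
    NoiseEstimator,
    NoiseEstimatorConfig,
    build_noise_estimator,
    save_noise_estimator,
    train_noise_estimator,
)
from .perceptual import RandomVGGExtractor
from .phantom import generate_phantom


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(items, fractions, seed=None):
    """Seeded shuffle, then split into len(fractions) disjoint, exhaustive
    parts whose sizes are the rounded cumulative fractions."""
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty dataset")
    fractions = [float(f) for f in fractions]
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n = len(items)
    edges = [0] + [int(round(c * n)) for c in np.cumsum(fractions)]
    edges[-1] = n
    parts = tuple(
        [items[i] for i in order[lo:hi]] for lo, hi in zip(edges[:-1], edges[1:])
    )
    return parts


# ---------------------------------------------------------------------------
# blind enhancement
# ---------------------------------------------------------------------------

def estimate_noise_level(
    model: NoiseEstimator,
    image: np.ndarray,
    classes: NoiseLevelClassSet,
    n_crops: int = 5,
    seed=0,
) -> tuple[float, int, np.ndarray]:
    """Average class probabilities over seeded crops of the estimator's
    input size (a single center crop when the image matches it exactly)."""
    image = as_image(image)
    s = model.config.input_size
    h, w = image.shape
    if h < s or w < s:
        raise ValueError(f"image {h}x{w} smaller than estimator input {s}x{s}")
    if h == s and w == s:
        crops = image[None]
    else:
        rng = np.random.default_rng(seed)
        crops = np.stack([
            image[y:y + s, x:x + s]
            for y, x in zip(
                rng.integers(h - s + 1, size=n_crops),
                rng.integers(w - s + 1, size=n_crops),
            )
        ])
    probs = model.predict_proba(crops).mean(axis=0)
    idx = int(np.argmax(probs))
    return classes.sigma_for(idx), idx, probs


def blind_enhance(
    noise_model: NoiseEstimator,
    enhancer_model: Enhancer,
    projector: KernelProjector,
    degraded: np.ndarray,
    classes: NoiseLevelClassSet,
    kernel: np.ndarray | None = None,
    sigma: float | None = None,
    n_crops: int = 5,
    seed=0,
    tile: int = 40,
    overlap: int = 8,
) -> tuple[np.ndarray, dict]:
    """Estimate the noise level, build degradation maps, and enhance.

    Passing ``sigma`` explicitly bypasses the estimator (non-blind
    operation); the enhancement path is bit-for-bit identical whenever
    the estimate equals the supplied value.
    """
    degraded = as_image(degraded)
    t0 = time.perf_counter()
    diagnostics: dict = {"bypass": sigma is not None}
    if sigma is None:
        sigma, idx, probs = estimate_noise_level(
            noise_model, degraded, classes, n_crops=n_crops, seed=seed
        )
        diagnostics.update(
            {"class_index": idx, "probabilities": probs.tolist()}
        )
    diagnostics["sigma"] = float(sigma)
    kern = delta_kernel(projector.kernel_size) if kernel is None else kernel
    h, w = degraded.shape
    maps = build_degradation_maps(kern, sigma, w, h, projector)
    out = enhance(enhancer_model, degraded, maps, tile=tile, overlap=overlap)
    diagnostics["seconds"] = time.perf_counter() - t0
    return out, diagnostics


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full experiment configuration; every random draw descends from ``seed``."""

    seed: int = 0
    source_dir: str | None = None  # PNG/TIFF sources; None -> phantoms
    n_sources: int = 16
    source_size: int = 128
    class_levels: tuple = (0.0, 5.0, 10.0, 15.0)
    level_is_variance: bool = False
    patch_size: int = 32
    n_patches: int = 900
    patch_split: tuple = (8 / 9, 1 / 9)
    sr_sigmas: tuple = (5.0, 10.0, 15.0)
    pair_split: tuple = (0.875, 0.125)
    blur_t: int = 3
    noise_cfg: NoiseEstimatorConfig = field(default_factory=NoiseEstimatorConfig)
    noise_train: TrainConfig = field(default_factory=classifier_defaults)
    enhance_cfg: EnhancerConfig = field(default_factory=EnhancerConfig)
    enhance_train: TrainConfig = field(default_factory=enhancer_defaults)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    extractor_width_scale: float = 1.0
    eval_tile: int = 40
    eval_crops: int = 5

    @property
    def classes(self) -> NoiseLevelClassSet:
        return NoiseLevelClassSet(
            levels=self.class_levels, level_is_variance=self.level_is_variance
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("noise_cfg", NoiseEstimatorConfig),
            ("enhance_cfg", EnhancerConfig),
            ("noise_train", TrainConfig),
            ("enhance_train", TrainConfig),
            ("loss_weights", LossWeights),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = sub(**sub_d)
        for key in ("class_levels", "patch_split", "sr_sigmas", "pair_split"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path, preset: str | None = None) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if preset is not None:
            data = data[preset]
        return cls.from_dict(data)


def desk_scale(seed: int = 0) -> RunConfig:
    """Small phantom-based preset sized for a single CPU: 16 phantoms of
    128 px, a 4-class classifier on 32 px patches, and a narrow enhancer
    trained for a few hundred steps."""
    return RunConfig(
        seed=seed,
        n_sources=16,
        source_size=128,
        class_levels=(0.0, 5.0, 10.0, 15.0),
        patch_size=32,
        n_patches=900,
        patch_split=(8 / 9, 1 / 9),
        sr_sigmas=(5.0, 10.0, 15.0),
        pair_split=(0.75, 0.25),
        blur_t=3,
        noise_cfg=NoiseEstimatorConfig(
            pre_channels=12, n_inception_blocks=3, branch_widths=(6, 6, 6),
            reduction_channels=8, bottleneck_channels=12, n_classes=4,
            input_size=32,
        ),
        noise_train=TrainConfig(
            learning_rate=1e-3, batch_size=32, epochs=3, weight_decay=1e-4
        ),
        enhance_cfg=EnhancerConfig(
            base_channels=12, n_rdi_blocks=1, convs_per_block=2, growth=6,
            inception_widths=(4, 4, 4), scale_factor=2, t=3,
        ),
        enhance_train=TrainConfig(
            learning_rate=3e-3, batch_size=8, epochs=0, steps=300,
            crop_size=24,
        ),
        loss_weights=LossWeights(mu=0.01, perceptual_layer=8),
        extractor_width_scale=1 / 16,
        eval_tile=64,
    )


def full_scale(seed: int = 0) -> RunConfig:
    """Reference-scale preset: 1600 sources of 512 px, 42 000 patches over
    10 classes (levels 0-18), batch 40 / 40 epochs for the classifier and
    batch 20 / 200 000 steps for the enhancer."""
    return RunConfig(
        seed=seed,
        n_sources=1600,
        source_size=512,
        class_levels=tuple(float(v) for v in range(0, 19, 2)),
        patch_size=100,
        n_patches=42_000,
        patch_split=(40_000 / 42_000, 2_000 / 42_000),
        sr_sigmas=(5.0, 10.0, 15.0),
        pair_split=(0.875, 0.125),
        blur_t=15,
        noise_cfg=NoiseEstimatorConfig(),
        noise_train=classifier_defaults(),
        enhance_cfg=EnhancerConfig(),
        enhance_train=enhancer_defaults(),
        loss_weights=LossWeights(mu=0.01, perceptual_layer=8),
        extractor_width_scale=1.0,
        eval_tile=40,
    )


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _blur_kernel_family(side: int = 15, n: int = 24):
    """Delta kernel plus isotropic Gaussians, sigma_blur in [0.2, 3]."""
    family = [delta_kernel(side)]
    for s in np.linspace(0.2, 3.0, n - 1):
        family.append(gaussian_kernel(side, s))
    return family


def run_experiment(config: RunConfig, out_dir, log=print) -> dict:
    """Execute the experiment at the configured scale and write reports.

    Writes ``report.json`` and ``tables.txt`` (fully deterministic under
    the config seed), model checkpoints, and ``run.log`` (with wall-clock
    timings, excluded from determinism guarantees). Returns the report
    dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(msg):
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")
        log(msg)

    seeds = np.random.SeedSequence(config.seed).generate_state(10).tolist()
    classes = config.classes
    report: dict = {"config": _jsonable(config.to_dict()), "stages": {}}
    try:
        t0 = time.perf_counter()
        stage("stage 1: building datasets")
        if config.source_dir:
            paths = sorted(Path(config.source_dir).glob("*"))
            sources = [load_image(p) for p in paths[: config.n_sources]]
        else:
            sources = [
                generate_phantom(config.source_size, seed=seeds[0] + i)
                for i in range(config.n_sources)
            ]
        patches = make_noise_patch_dataset(
            sources, config.patch_size, config.n_patches, classes, seed=seeds[1]
        )
        train_patches, test_patches = split_dataset(
            patches, config.patch_split, seed=seeds[2]
        )
        pairs = make_sr_pairs(
            sources, config.sr_sigmas, config.enhance_cfg.scale_factor,
            seed=seeds[3],
        )
        train_pairs, test_pairs = split_dataset(
            pairs, config.pair_split, seed=seeds[4]
        )
        report["stages"]["datasets"] = {
            "n_sources": len(sources),
            "n_patches_train": len(train_patches),
            "n_patches_test": len(test_patches),
            "n_pairs_train": len(train_pairs),
            "n_pairs_test": len(test_pairs),
        }

        stage("stage 2: training the noise classifier")
        noise_model = build_noise_estimator(config.noise_cfg, seed=seeds[5])
        noise_model, noise_history = train_noise_estimator(
            noise_model, train_patches, config.noise_train, seed=seeds[6]
        )
        save_noise_estimator(out / "noise_estimator.npz", noise_model, classes)
        report["stages"]["noise_training"] = {
            "epoch_loss": noise_history,
            "hyperparameters": dataclasses.asdict(config.noise_train),
        }

        stage("stage 3: evaluating the classifier")
        cm = evaluate_classifier(noise_model, test_patches, classes)
        class_report = classification_report(cm)
        report["stages"]["classification"] = {
            "confusion_matrix": cm.counts.tolist(),
            **class_report.as_dict(),
        }

        stage("stage 4: training the enhancement network")
        projector = fit_kernel_projector(
            _blur_kernel_family(), t=config.enhance_cfg.t
        )
        extractor = None
        if config.loss_weights.mu > 0:
            extractor = RandomVGGExtractor(
                layer_index=config.loss_weights.perceptual_layer,
                width_scale=config.extractor_width_scale,
                seed=seeds[7],
            )
        enh = build_enhancer(config.enhance_cfg, seed=seeds[8])
        enh, enh_history = train_enhancer(
            enh, train_pairs, projector, config.enhance_train,
            config.loss_weights, extractor=extractor, seed=seeds[9],
        )
        save_enhancer(out / "enhancer.npz", enh, projector, config.loss_weights)
        report["stages"]["enhancer_training"] = {
            "step_loss_first10": enh_history[:10],
            "step_loss_last10": enh_history[-10:],
            "hyperparameters": dataclasses.asdict(config.enhance_train),
            "mu": config.loss_weights.mu,
        }

        stage("stage 5: evaluating enhancement vs bicubic")
        per_level: dict[float, dict[str, list[float]]] = {}
        for i, pair in enumerate(test_pairs):
            enhanced, _ = blind_enhance(
                noise_model, enh, projector, pair.degraded, classes,
                seed=seeds[0] + 1000 + i, tile=config.eval_tile,
                n_crops=config.eval_crops,
            )
            baseline = bicubic_upsample(pair.degraded, pair.spec.scale_factor)
            bucket = per_level.setdefault(
                pair.spec.sigma,
                {"psnr": [], "ssim": [], "psnr_bicubic": [], "ssim_bicubic": []},
            )
            bucket["psnr"].append(psnr(enhanced, pair.target))
            bucket["ssim"].append(ssim(enhanced, pair.target))
            bucket["psnr_bicubic"].append(psnr(baseline, pair.target))
            bucket["ssim_bicubic"].append(ssim(baseline, pair.target))
        report["stages"]["enhancement"] = {
            f"{lv:g}": {
                k: {"mean": float(np.mean(v)), "std": float(np.std(v)),
                    "n": len(v)}
                for k, v in bucket.items()
            }
            for lv, bucket in sorted(per_level.items())
        }
        report["elapsed_note"] = "wall-clock timings are in run.log"

        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "tables.txt").write_text(_format_tables(class_report, report))
        stage(f"done in {time.perf_counter() - t0:.1f}s")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:  # preserve partial artifacts, then re-raise
        log_lines.append(f"FAILED: {exc!r}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise


def _format_tables(class_report, report) -> str:
    parts = ["Noise-level classification", format_class_report(class_report), ""]
    parts.append("Enhancement quality (mean +/- std)")
    parts.append(f"{'level':>6} {'PSNR':>14} {'SSIM':>14} "
                 f"{'PSNR bicubic':>14} {'SSIM bicubic':>14}")
    for lv, bucket in report["stages"]["enhancement"].items():
        parts.append(
            f"{lv:>6} "
            f"{bucket['psnr']['mean']:7.2f}+/-{bucket['psnr']['std']:4.2f} "
            f"{bucket['ssim']['mean']:7.3f}+/-{bucket['ssim']['std']:5.3f} "
            f"{bucket['psnr_bicubic']['mean']:7.2f}+/-{bucket['psnr_bicubic']['std']:4.2f} "
            f"{bucket['ssim_bicubic']['mean']:7.3f}+/-{bucket['ssim_bicubic']['std']:5.3f}"
        )
    return "\n".join(parts) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
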