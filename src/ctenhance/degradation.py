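"""Degradation simulator for CT image enhancement experiments.

Models the acquisition/compression degradation of a clean image as

    y = (x * kernel) downsampled by r, plus additive white Gaussian noise

where the noise parameter ("noise level") lives on the 0-255 intensity
scale. Also provides the SRMD-style degradation maps: the blur kernel is
vectorized, projected onto a t-dimensional PCA space, and the projection
coefficients plus the normalized noise level are stretched into t+1
spatially uniform channels that the enhancement network consumes
alongside the degraded image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import as_image, bicubic_resize, clip01, save_image


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def delta_kernel(size: int = 15) -> np.ndarray:
    """Identity blur kernel (a centered unit impulse)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel side must be odd and >= 1")
    k = np.zeros((size, size))
    k[size // 2, size // 2] = 1.0
    return k


def gaussian_kernel(size: int = 15, sigma_blur: float = 1.0) -> np.ndarray:
    """Isotropic Gaussian blur kernel normalized to unit sum."""
    if sigma_blur <= 0:
        raise ValueError("sigma_blur must be positive")
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma_blur ** 2))
    k = np.outer(g, g)
    return k / k.sum()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationSpec:
    """Degradation parameters: noise level sigma (0-255 scale), blur
    kernel (non-negative, unit sum), integer scale factor, and whether
    noise is injected after (default) or before down-sampling."""

    sigma: float = 0.0
    kernel: np.ndarray = field(default_factory=delta_kernel)
    scale_factor: int = 1
    noise_order: str = "after_downsample"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.ndim != 2 or (k < 0).any():
            raise ValueError("kernel must be a non-negative 2-D array")
        if abs(k.sum() - 1.0) > 1e-9:
            raise ValueError("kernel entries must sum to 1 (within 1e-9)")
        if int(self.scale_factor) < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.noise_order not in ("after_downsample", "before_downsample"):
            raise ValueError("noise_order must be 'after_downsample' or 'before_downsample'")
        object.__setattr__(self, "kernel", k)
        object.__setattr__(self, "scale_factor", int(self.scale_factor))


@dataclass(frozen=True)
class KernelProjector:
    """Orthonormal PCA basis for vectorized blur kernels.

    ``basis`` has shape (t, k*k); rows are principal directions of the
    kernel family (uncentered PCA, so a rank-1 family is represented
    exactly by its normalized member).
    """

    basis: np.ndarray
    kernel_size: int

    @property
    def t(self) -> int:
        return self.basis.shape[0]

    def __post_init__(self):
        b = np.asarray(self.basis, dtype=np.float64)
        if b.ndim != 2 or b.shape[0] < 1:
            raise ValueError("basis must be a (t, k^2) matrix with t >= 1")
        gram = b @ b.T
        if not np.allclose(gram, np.eye(b.shape[0]), atol=1e-8):
            raise ValueError("basis rows must be mutually orthonormal (within 1e-8)")
        object.__setattr__(self, "basis", b)

    def project(self, kernel: np.ndarray) -> np.ndarray:
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.shape != (self.kernel_size, self.kernel_size):
            raise ValueError(
                f"kernel side {kernel.shape} does not match projector side "
                f"{self.kernel_size}"
            )
        return self.basis @ kernel.ravel()

    def back_project(self, coeffs: np.ndarray) -> np.ndarray:
        return (self.basis.T @ np.asarray(coeffs)).reshape(
            self.kernel_size, self.kernel_size
        )


@dataclass(frozen=True)
class DegradationMaps:
    """(t+1) spatially uniform channels: t projected-kernel coefficients
    followed by the normalized noise level sigma/255."""

    channels: np.ndarray  # (t+1, H, W)

    def __post_init__(self):
        c = np.asarray(self.channels, dtype=np.float64)
        if c.ndim != 3 or c.shape[0] < 2:
            raise ValueError("channels must be a (t+1, H, W) stack with t >= 1")
        object.__setattr__(self, "channels", c)

    @property
    def t(self) -> int:
        return self.channels.shape[0] - 1

    @property
    def noise_channel(self) -> np.ndarray:
        return self.channels[-1]


@dataclass(frozen=True)
class NoiseLevelClassSet:
    """Ordered noise levels used as classification labels.

    By default the level parameterizes the Gaussian standard deviation on
    the 0-255 scale; set ``level_is_variance=True`` for the literal
    variance reading (sigma = sqrt(level)).
    """

    levels: tuple = tuple(range(0, 19, 2))
    level_is_variance: bool = False

    def __post_init__(self):
        lv = tuple(float(v) for v in self.levels)
        if len(lv) < 1 or any(v < 0 for v in lv):
            raise ValueError("levels must be non-negative")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    def sigma_for(self, class_index: int) -> float:
        level = self.levels[class_index]
        return math.sqrt(level) if self.level_is_variance else level


@dataclass(frozen=True)
class LabeledPatch:
    patch: np.ndarray
    class_index: int


@dataclass(frozen=True)
class SRPair:
    degraded: np.ndarray
    target: np.ndarray
    spec: DegradationSpec


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def gaussian_pdf(x: float, sigma: float) -> float:
    """Zero-mean Gaussian probability density at ``x``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return math.exp(-(x * x) / (2.0 * sigma * sigma)) / (math.sqrt(2.0 * math.pi) * sigma)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Additive white Gaussian noise with std ``sigma`` on the 0-255 scale.

    The image stays on [0,1]; the per-pixel draws are divided by 255 and
    the result is clipped back to [0,1].
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = as_image(image)
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=img.shape)
    return clip01(img + noise / 255.0)


def degrade(image: np.ndarray, spec: DegradationSpec, seed=None) -> np.ndarray:
    """Apply blur -> bicubic down-sample -> noise (order configurable)."""
    img = as_image(image)
    r = spec.scale_factor
    h, w = img.shape
    if h % r or w % r:
        raise ValueError(
            f"image dimensions {h}x{w} must be divisible by scale factor {r}"
        )
    blurred = img if _is_delta(spec.kernel) else clip01(
        ndimage.convolve(img, spec.kernel, mode="reflect")
    )
    if spec.noise_order == "before_downsample":
        blurred = add_gaussian_noise(blurred, spec.sigma, seed)
    out = blurred if r == 1 else bicubic_resize(blurred, (h // r, w // r))
    if spec.noise_order == "after_downsample":
        out = add_gaussian_noise(out, spec.sigma, seed)
    return out


def _is_delta(kernel: np.ndarray) -> bool:
    size = kernel.shape[0]
    if kernel.shape[0] != kernel.shape[1] or size % 2 == 0:
        return False
    return np.array_equal(kernel, delta_kernel(size))


def fit_kernel_projector(kernels, t: int) -> KernelProjector:
    """PCA basis (top-t principal directions) of a vectorized kernel family."""
    kernels = [np.asarray(k, dtype=np.float64) for k in kernels]
    if not kernels:
        raise ValueError("need at least one kernel")
    side = kernels[0].shape[0]
    if any(k.shape != (side, side) for k in kernels):
        raise ValueError("all kernels must share the same (square) side length")
    if t < 1:
        raise ValueError("t must be >= 1")
    if t > side * side:
        raise ValueError(f"t = {t} exceeds kernel dimensionality {side * side}")
    if len(kernels) < t:
        raise ValueError(f"need at least t = {t} kernels, got {len(kernels)}")
    mat = np.stack([k.ravel() for k in kernels])  # (n, k^2)
    # uncentered PCA: right singular vectors of the kernel matrix
    _, _, vt = np.linalg.svd(mat, full_matrices=True)
    return KernelProjector(basis=vt[:t], kernel_size=side)


def build_degradation_maps(
    kernel: np.ndarray,
    sigma: float,
    width: int,
    height: int,
    projector: KernelProjector,
) -> DegradationMaps:
    """Stretch projected kernel coefficients + sigma/255 into t+1 uniform maps."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    coeffs = projector.project(kernel)
    maps = np.empty((projector.t + 1, height, width), dtype=np.float64)
    maps[:-1] = coeffs[:, None, None]
    maps[-1] = sigma / 255.0
    return DegradationMaps(channels=maps)


def make_noise_patch_dataset(
    sources,
    patch_size: int,
    n_patches: int,
    classes: NoiseLevelClassSet,
    seed=None,
) -> list[LabeledPatch]:
    """Randomly crop ``n_patches`` patches and corrupt each at a random class level.

    Every patch gets a uniformly drawn source image, crop location and
    class; the label is the class index. Reproducible under a fixed seed.
    """
    sources = [as_image(s) for s in sources]
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    for i, s in enumerate(sources):
        if s.shape[0] < patch_size or s.shape[1] < patch_size:
            raise ValueError(
                f"source image {i} with shape {s.shape} is smaller than "
                f"patch size {patch_size}"
            )
    if n_patches and not sources:
        raise ValueError("need at least one source image")
    rng = np.random.default_rng(seed)
    out: list[LabeledPatch] = []
    for _ in range(n_patches):
        src = sources[rng.integers(len(sources))]
        y = rng.integers(src.shape[0] - patch_size + 1)
        x = rng.integers(src.shape[1] - patch_size + 1)
        cls = int(rng.integers(classes.n_classes))
        patch = src[y:y + patch_size, x:x + patch_size]
        sigma = classes.sigma_for(cls)
        if sigma > 0:
            patch = clip01(patch + rng.normal(0.0, sigma, patch.shape) / 255.0)
        out.append(LabeledPatch(patch=patch, class_index=cls))
    return out


def make_sr_pairs(
    sources,
    sigmas,
    r: int,
    seed=None,
    kernel: np.ndarray | None = None,
    noise_order: str = "after_downsample",
) -> list[SRPair]:
    """One (degraded, target) pair per source, sigma drawn from ``sigmas``."""
    sigmas = [float(s) for s in sigmas]
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    sources = [as_image(s) for s in sources]
    rng = np.random.default_rng(seed)
    kern = delta_kernel() if kernel is None else kernel
    pairs: list[SRPair] = []
    for src in sources:
        sigma = sigmas[rng.integers(len(sigmas))]
        spec = DegradationSpec(
            sigma=sigma, kernel=kern, scale_factor=r, noise_order=noise_order
        )
        degraded = degrade(src, spec, seed=rng)
        pairs.append(SRPair(degraded=degraded, target=src, spec=spec))
    return pairs


# ---------------------------------------------------------------------------
# dataset export (PNG directory + line-oriented manifest)
# ---------------------------------------------------------------------------

def write_patch_dataset(path, patches: list[LabeledPatch],
                        classes: NoiseLevelClassSet) -> None:
    """Write patches as PNGs plus ``manifest.tsv``: filename, class index, level."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["filename\tclass_index\tlevel"]
    for i, item in enumerate(patches):
        name = f"patch_{i:06d}.png"
        save_image(path / name, item.patch)
        lines.append(f"{name}\t{item.class_index}\t{classes.levels[item.class_index]:g}")
    (path / "manifest.tsv").write_text("\n".join(lines) + "\n")


def write_pair_dataset(path, pairs: list[SRPair]) -> None:
    """Write SR pairs as PNGs plus ``manifest.tsv``: files, sigma, scale factor."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["degraded\ttarget\tsigma\tscale_factor"]
    for i, pair in enumerate(pairs):
        dname, tname = f"pair_{i:06d}_lr.png", f"pair_{i:06d}_hr.png"
        save_image(path / dname, pair.degraded)
        save_image(path / tname, pair.target)
        lines.append(f"{dname}\t{tname}\t{pair.spec.sigma:g}\t{pair.spec.scale_factor}")
    (path / "manifest.tsv").write_text("\n".join(lines) + "\n")
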