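"""Grayscale image handling.

Images are plain 2-D float64 NumPy arrays with intensities in [0, 1]
(the nominal 8-bit 0-255 dynamic range is used only for noise-level and
PSNR conventions). Readers accept 8-/16-bit PNG and TIFF, and optionally
single-frame DICOM with rescale slope/intercept applied followed by
min-max normalization.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize


def as_image(pixels) -> np.ndarray:
    """Validate and return a [0,1] grayscale image as float64."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]; clip first")
    return np.clip(arr, 0.0, 1.0)


def clip01(arr: np.ndarray) -> np.ndarray:
    return np.clip(arr, 0.0, 1.0)


def load_image(path) -> np.ndarray:
    """Read a grayscale image file to a [0,1] float array."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _load_dicom(path)
    arr = iio.imread(path)
    maxval = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else 1.0
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return clip01(arr.astype(np.float64) / maxval)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("only single-frame DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def save_image(path, image: np.ndarray) -> None:
    """Write a [0,1] image as 8-bit grayscale PNG/TIFF."""
    img = as_image(image)
    iio.imwrite(Path(path), (np.round(img * 255.0)).astype(np.uint8))


def bicubic_resize(image: np.ndarray, out_shape: tuple[int, int],
                   antialias: bool | None = None) -> np.ndarray:
    """Bicubic resampling to ``out_shape`` (rows, cols).

    Anti-aliasing defaults on when down-sampling and off when up-sampling,
    the convention of standard bicubic dataset pipelines.
    """
    if antialias is None:
        antialias = out_shape[0] < image.shape[0] or out_shape[1] < image.shape[1]
    out = _sk_resize(
        image,
        out_shape,
        order=3,
        mode="reflect",
        anti_aliasing=antialias,
        preserve_range=True,
    )
    return clip01(out)


def bicubic_upsample(image: np.ndarray, r: int) -> np.ndarray:
    """Classical bicubic x``r`` up-scaling baseline."""
    h, w = image.shape
    return bicubic_resize(image, (h * r, w * r), antialias=False)
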