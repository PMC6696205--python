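"""Synthetic chest-CT-like phantoms.

A phantom emulates the gross geometry of an axial lung CT slice: an
elliptical soft-tissue body, two low-attenuation lung fields, a bright
vertebral body, vessel-like curvilinear structures inside the lungs, and
a few small nodules. The goal is a deterministic, edge-rich grayscale
test image family — not anatomical realism (no Hounsfield calibration,
no streak/beam-hardening physics).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import clip01


def _ellipse_mask(yy, xx, cy, cx, ry, rx, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    yr = (yy - cy) * ca + (xx - cx) * sa
    xr = -(yy - cy) * sa + (xx - cx) * ca
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def _paint_disk(canvas, cy, cx, radius, value):
    n = canvas.shape[0]
    y0, y1 = max(0, int(cy - radius)), min(n, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(n, int(cx + radius) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    canvas[y0:y1, x0:x1][mask] = value


def generate_phantom(size: int, seed=None) -> np.ndarray:
    """Generate a ``size`` x ``size`` grayscale phantom in [0, 1].

    Deterministic under a fixed seed; distinct seeds vary geometry,
    vessel layout and nodule placement.
    """
    if size < 64:
        raise ValueError("phantom size must be >= 64")
    rng = np.random.default_rng(seed)
    n = size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64) / (n - 1) * 2.0 - 1.0

    img = np.zeros((n, n), dtype=np.float64)

    # soft-tissue body
    body_ry = 0.78 + 0.08 * rng.random()
    body_rx = 0.88 + 0.06 * rng.random()
    body_val = 0.50 + 0.08 * rng.random()
    body = _ellipse_mask(yy, xx, 0.02 * rng.standard_normal(), 0.0, body_ry, body_rx)
    img[body] = body_val

    # subcutaneous rim, slightly brighter
    rim = body & ~_ellipse_mask(yy, xx, 0.0, 0.0, body_ry * 0.93, body_rx * 0.93)
    img[rim] = body_val + 0.18

    # lung fields
    lung_val = 0.10 + 0.06 * rng.random()
    lungs = np.zeros_like(body)
    for side in (-1.0, 1.0):
        cy = -0.05 + 0.05 * rng.standard_normal()
        cx = side * (0.38 + 0.04 * rng.random())
        ang = side * (0.15 + 0.1 * rng.random())
        lung = _ellipse_mask(yy, xx, cy, cx, 0.48 + 0.05 * rng.random(),
                             0.26 + 0.04 * rng.random(), ang)
        lungs |= lung & body
    img[lungs] = lung_val

    # vertebral body: small bright ellipse at the posterior midline
    spine = _ellipse_mask(yy, xx, 0.55, 0.0, 0.12, 0.10) & body
    img[spine] = 0.85

    # vessel-like curves inside the lungs (random quadratic Bezier arcs)
    lung_idx = np.argwhere(lungs)
    n_vessels = rng.integers(4, 9)
    for _ in range(n_vessels):
        if len(lung_idx) == 0:
            break
        p0 = lung_idx[rng.integers(len(lung_idx))].astype(np.float64)
        p2 = p0 + rng.normal(0.0, n * 0.12, size=2)
        p1 = (p0 + p2) / 2 + rng.normal(0.0, n * 0.05, size=2)
        width = 0.8 + 1.8 * rng.random()
        for t in np.linspace(0.0, 1.0, 4 * n // 3):
            pt = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
            cy, cx = pt
            if 0 <= cy < n and 0 <= cx < n and lungs[int(cy), int(cx)]:
                _paint_disk(img, cy, cx, width, lung_val + 0.45)

    # nodules
    for _ in range(rng.integers(2, 6)):
        if len(lung_idx) == 0:
            break
        cy, cx = lung_idx[rng.integers(len(lung_idx))]
        _paint_disk(img, float(cy), float(cx), 2.0 + 4.0 * rng.random(),
                    lung_val + 0.35)

    # mild smoothing keeps edges while avoiding single-pixel staircase
    img = ndimage.gaussian_filter(img, sigma=max(1.0, n / 512))
    return clip01(img)
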