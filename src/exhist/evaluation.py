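"""Evaluation metrics: RMSE, circular hue RMSE, difference image, profiles."""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared per-element difference (channels pooled for color)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def hue_angles(img: np.ndarray):
    """Hexagonal HSV hue in degrees [0, 360) and a validity mask.

    Hue is undefined at achromatic pixels (R = G = B); the mask is False there.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (m, n, 3) image")
    hsv = rgb2hsv(arr / 255.0)
    defined = arr.max(axis=2) != arr.min(axis=2)
    return hsv[:, :, 0] * 360.0, defined


def hue_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMSE of the circular hue difference, in degrees.

    Delta = min(|hA - hB|, 360 - |hA - hB|) per pixel; pixels where hue is
    undefined in either image are excluded from the mean.
    """
    ha, ma = hue_angles(a)
    hb, mb = hue_angles(b)
    if ha.shape != hb.shape:
        raise ValueError("shape mismatch")
    mask = ma & mb
    if not mask.any():
        raise ValueError("no pixel with a defined hue in both images")
    diff = np.abs(ha[mask] - hb[mask])
    diff = np.minimum(diff, 360.0 - diff)
    return float(np.sqrt(np.mean(diff ** 2)))


def difference_image(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed difference offset to neutral gray: clip(A - B + 127, 0, 255)."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("expected two same-shape grayscale images")
    return np.clip(a - b + 127, 0, 255).astype(np.int64)


def horizontal_profile(img: np.ndarray, row: int) -> np.ndarray:
    """Values of one row (1-based index) in column order, length n."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("expected a grayscale image")
    if not 1 <= row <= arr.shape[0]:
        raise ValueError(f"row {row} outside 1..{arr.shape[0]}")
    return arr[row - 1, :].copy()
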