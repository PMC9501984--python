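"""Raster I/O and index conventions.

Images are 8-bit integer arrays: grayscale ``(m, n)`` or RGB ``(m, n, 3)``,
values in ``[0, L]`` with ``L = 255``.  Internally everything is 0-based and
row-major numpy; the 1-based column-major linear-index convention (pixel
``(i, j)`` of an m-row image has index ``(j-1)*m + i``; a color element adds
``m*n*(k-1)`` for channel ``k``) is honored by :func:`encode_index` /
:func:`decode_index` and in exported orderings, because tie-breaking and
ordering reports are defined in that convention.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

L_DEFAULT = 255

_GRAY_MODES = {"L"}
_RGB_MODES = {"RGB"}
_ALPHA_MODES = {"RGBA", "LA"}


def validate_image(img: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Check an array is a valid 8-bit gray or RGB image; return it as int."""
    arr = np.asarray(img)
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(f"expected (m, n) or (m, n, 3) array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("image values must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > L:
        raise ValueError(f"image values must lie in [0, {L}]")
    return arr


def read_image(path, strip_alpha: bool = False) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as a grayscale (m, n) or RGB (m, n, 3) array.

    Palette images and bit depths above 8 are rejected rather than converted,
    because silent requantization would change the histogram the algorithms
    operate on.  An alpha channel is an error unless ``strip_alpha`` is set.
    """
    with Image.open(path) as im:
        mode = im.mode
        if mode == "P":
            raise ValueError(f"{path}: palette image; convert to L or RGB first")
        if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise ValueError(f"{path}: bit depth above 8 is not supported")
        if mode in _ALPHA_MODES:
            if not strip_alpha:
                raise ValueError(f"{path}: alpha channel present (pass strip_alpha=True to drop)")
            im = im.convert("RGB" if mode == "RGBA" else "L")
        elif mode not in _GRAY_MODES | _RGB_MODES:
            raise ValueError(f"{path}: unsupported image mode {mode!r}")
        arr = np.asarray(im, dtype=np.uint8)
    return arr


def write_image(img: np.ndarray, path) -> None:
    """Write an integer image losslessly as 8-bit PNG/TIFF.

    Raises on non-integer or out-of-range values; never clips.
    """
    arr = np.asarray(img)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("refusing to write a non-integer image (quantize explicitly first)")
    arr = validate_image(arr).astype(np.uint8)
    Image.fromarray(arr, mode="L" if arr.ndim == 2 else "RGB").save(path)


def encode_index(i: int, j: int, m: int, n: int, k: int | None = None) -> int:
    """1-based column-major linear index of pixel (i, j) (channel k for color)."""
    if not (1 <= i <= m and 1 <= j <= n):
        raise ValueError(f"position ({i}, {j}) outside {m}x{n} image")
    mu = (j - 1) * m + i
    if k is None:
        return mu
    if not 1 <= k <= 3:
        raise ValueError(f"channel {k} outside 1..3")
    return m * n * (k - 1) + mu


def decode_index(idx: int, m: int, n: int, color: bool = False):
    """Invert :func:`encode_index`: returns (i, j) or (i, j, k), 1-based."""
    top = 3 * m * n if color else m * n
    if not 1 <= idx <= top:
        raise ValueError(f"linear index {idx} outside 1..{top}")
    idx0 = idx - 1
    k, mu0 = divmod(idx0, m * n)
    j, i = divmod(mu0, m)
    if color:
        return i + 1, j + 1, k + 1
    return i + 1, j + 1


def export_ordering(ordering: np.ndarray, path) -> None:
    """Write an ordering as text: one 1-based column-major index per line, rank order."""
    idx = np.asarray(ordering, dtype=np.int64) + 1
    np.savetxt(path, idx, fmt="%d")
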