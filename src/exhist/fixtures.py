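"""Programmatic test-image generators.

Everything the test suite and acceptance checks run on is generated here, so
no external dataset is needed: the two-level step image that exposes the
stripe artifact of value-only orderings, seeded uniform-random images,
mirror-symmetric images that force exact filtered-value collisions (the tie
case the index tie-break must resolve), and smooth correlated-channel color
fields for hue-preservation comparisons (hue on white noise is
uninformative, so the color battery uses low-frequency fields).
"""

from __future__ import annotations

import numpy as np

from .gaussian import gaussian_filter
from .io import L_DEFAULT


def make_two_level(m: int = 200, n: int = 282, bright: int = 200, dark: int = 100,
                   split: int | None = None, L: int = L_DEFAULT) -> np.ndarray:
    """Two-level step image: columns 1..split bright, the rest dark.

    Defaults give the 200x282 image with values 200 (left) and 100 (right),
    28,200 pixels each at the central split.
    """
    if not 0 <= dark < bright <= L:
        raise ValueError("need 0 <= dark < bright <= L")
    if split is None:
        split = n // 2
    if not 0 < split < n:
        raise ValueError(f"split {split} outside 1..{n - 1}")
    img = np.full((m, n), dark, dtype=np.int64)
    img[:, :split] = bright
    return img


def make_seeded_random(m: int, n: int, channels: int = 1, seed: int = 0,
                       L: int = L_DEFAULT) -> np.ndarray:
    """Uniform integer levels in [0, L]; identical output for identical seed."""
    rng = np.random.default_rng(seed)
    shape = (m, n) if channels == 1 else (m, n, channels)
    return rng.integers(0, L + 1, size=shape).astype(np.int64)


def make_mirror_symmetric(m: int, n: int, seed: int = 0, L: int = L_DEFAULT) -> np.ndarray:
    """Left half seeded random, right half its mirror (column j == column n+1-j).

    The Gaussian weight matrices are symmetric Toeplitz, so the filtered image
    inherits the mirror symmetry up to summation-order rounding (~1e-14 with
    blocked/FMA matmul); in practice most mirrored pairs collide bit-exactly,
    which exercises the index tie-break of the ordering.
    """
    if n % 2 != 0:
        raise ValueError("n must be even")
    rng = np.random.default_rng(seed)
    half = rng.integers(0, L + 1, size=(m, n // 2))
    return np.concatenate([half, half[:, ::-1]], axis=1).astype(np.int64)


def make_smooth_color(m: int, n: int, seed: int = 0, smooth_sigma: float = 4.0,
                      channel_mix: float = 0.7, L: int = L_DEFAULT) -> np.ndarray:
    """Smooth synthetic color image with correlated channels.

    Per-channel fields are Gaussian-smoothed white noise blended with a shared
    smoothed field (weight ``channel_mix`` on the shared part), then rescaled
    to span [0, L] jointly.  Correlated channels give structured hue; the
    smoothness keeps hue locally coherent, which is what makes hue-drift
    comparisons between color-equalization strategies meaningful.
    """
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.normal(size=(m, n)), smooth_sigma)
    chans = []
    for _ in range(3):
        own = gaussian_filter(rng.normal(size=(m, n)), smooth_sigma)
        chans.append(channel_mix * base + (1.0 - channel_mix) * own)
    field = np.stack(chans, axis=2)
    lo, hi = field.min(), field.max()
    scaled = (field - lo) / (hi - lo) * L
    return np.rint(scaled).astype(np.int64)
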