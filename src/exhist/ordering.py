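"""Strict pixel ordering and exact histogram specification.

The core procedure: partition the pixels into the L+1 groups sharing each
gray level, sort each group by local contrast ascending, concatenate the
groups in level order into a total order over all mn pixels (3mn elements
for unified color), then assign output levels by walking the target's
cumulative histogram: rank iota gets level l when H_hat[l-1] < iota <=
H_hat[l].  Because exactly h_hat[l] ranks fall in each bracket, the output
histogram equals the target in exact integer counts — for any image and any
valid target.

Exact ties in contrast (possible on symmetric patterns) are broken by the
1-based column-major linear index, making the ordering a deterministic total
order.  Equivalently the whole ordering is one stable lexicographic sort on
(value, contrast, index), which is how it is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import L_DEFAULT, validate_image
from .gaussian import gaussian_filter, local_contrast
from .histograms import build_uniform_target


def _check_target(target: np.ndarray, budget: int, L: int) -> np.ndarray:
    t = np.asarray(target, dtype=np.int64)
    if t.shape != (L + 1,):
        raise ValueError(f"target must have length {L + 1}")
    if np.any(t < 0):
        raise ValueError("target counts must be nonnegative")
    if int(t.sum()) != budget:
        raise ValueError(f"target total {t.sum()} != required budget {budget}")
    return t


def order_pixels(img: np.ndarray, d: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Total order of all pixels by (value, local contrast, column-major index).

    Returns the 0-based column-major linear indices in rank order; adding 1
    gives the 1-based indices mu_1..mu_mn of the reporting convention.
    np.lexsort is stable, so equal (value, contrast) pairs keep their
    column-major position order.
    """
    arr = validate_image(img, L)
    dd = np.asarray(d, dtype=float)
    if dd.shape != arr.shape:
        raise ValueError(f"contrast shape {dd.shape} != image shape {arr.shape}")
    f = arr.ravel(order="F")
    return np.lexsort((dd.ravel(order="F"), f))


def order_elements_color(img: np.ndarray, d: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Unified-channel ordering over all 3mn RGB elements.

    Groups pool the three channels (one group per level l over all cijk = l);
    within a group the per-channel contrasts sort ascending, ties broken by
    the eta-index  eta = mn(k-1) + m(j-1) + i, which is exactly the
    column-major raveling of the (m, n, 3) array.
    """
    arr = validate_image(img, L)
    if arr.ndim != 3:
        raise ValueError("order_elements_color expects an (m, n, 3) image")
    dd = np.asarray(d, dtype=float)
    if dd.shape != arr.shape:
        raise ValueError(f"contrast shape {dd.shape} != image shape {arr.shape}")
    return np.lexsort((dd.ravel(order="F"), arr.ravel(order="F")))


def _assign_levels(ordering: np.ndarray, target: np.ndarray, shape, L: int) -> np.ndarray:
    """Walk the target cumulative histogram: rank iota -> level l with
    H_hat[l-1] < iota <= H_hat[l]."""
    levels = np.repeat(np.arange(L + 1, dtype=np.int64), target)
    flat = np.empty(ordering.size, dtype=np.int64)
    flat[ordering] = levels
    return flat.reshape(shape, order="F")


def specify_exact(img: np.ndarray, ordering: np.ndarray, target: np.ndarray,
                  L: int = L_DEFAULT) -> np.ndarray:
    """Assign target levels along a grayscale pixel ordering.

    The output histogram equals the target bin-for-bin; the assigned level is
    nondecreasing along the ordering by construction.
    """
    arr = validate_image(img, L)
    if arr.ndim != 2:
        raise ValueError("specify_exact expects a grayscale image")
    t = _check_target(target, arr.size, L)
    ordering = np.asarray(ordering)
    if ordering.shape != (arr.size,):
        raise ValueError("ordering length must equal the pixel count")
    return _assign_levels(ordering, t, arr.shape, L)


def specify_exact_color(img: np.ndarray, ordering: np.ndarray, target: np.ndarray,
                        L: int = L_DEFAULT) -> np.ndarray:
    """Assign target levels along a unified 3mn-element ordering."""
    arr = validate_image(img, L)
    if arr.ndim != 3:
        raise ValueError("specify_exact_color expects an (m, n, 3) image")
    t = _check_target(target, arr.size, L)
    ordering = np.asarray(ordering)
    if ordering.shape != (arr.size,):
        raise ValueError("ordering length must equal 3*m*n")
    return _assign_levels(ordering, t, arr.shape, L)


def specify_lc(img: np.ndarray, target: np.ndarray, sigma: float = 50.0,
               L: int = L_DEFAULT) -> np.ndarray:
    """Full LC pipeline: filter, contrast, order, assign (gray or unified color)."""
    arr = validate_image(img, L)
    d = local_contrast(arr, sigma)
    if arr.ndim == 2:
        return specify_exact(arr, order_pixels(arr, d, L), target, L)
    return specify_exact_color(arr, order_elements_color(arr, d, L), target, L)


def equalize_exact(img: np.ndarray, sigma: float = 50.0, L: int = L_DEFAULT) -> np.ndarray:
    """Exact histogram equalization: uniform-with-remainder target + specify_lc."""
    arr = validate_image(img, L)
    return specify_lc(arr, build_uniform_target(arr.size, L), sigma, L)


def rank_image(img: np.ndarray, sigma: float = 50.0, L: int = L_DEFAULT) -> np.ndarray:
    """Diagnostic rank image F^I: pixel (i, j) holds its 1-based rank iota."""
    arr = validate_image(img, L)
    d = local_contrast(arr, sigma)
    if arr.ndim == 2:
        ordering = order_pixels(arr, d, L)
    else:
        ordering = order_elements_color(arr, d, L)
    flat = np.empty(arr.size, dtype=np.int64)
    flat[ordering] = np.arange(1, arr.size + 1)
    return flat.reshape(arr.shape, order="F")


@dataclass
class OrderingReport:
    """Strict-ordering diagnostics of the Gaussian-filtered values."""

    sorted_values: np.ndarray       # filtered values ascending
    differences: np.ndarray         # consecutive differences (length N-1)
    min_difference: float           # min over consecutive differences
    tie_count: int                  # elements whose (value, contrast) collides
    sigma: float = field(default=50.0)


def ordering_report(img: np.ndarray, sigma: float = 50.0, L: int = L_DEFAULT) -> OrderingReport:
    """Diagnose how strictly the filter separates same-valued pixels.

    ``min_difference`` is the smallest gap between consecutive sorted filtered
    values over the whole image; ``tie_count`` counts pixels whose filtered
    value exactly collides (bit-equal doubles) with another pixel of the same
    gray level — the cases the index tie-break must resolve.
    """
    arr = validate_image(img, L)
    if arr.ndim != 2:
        raise ValueError("ordering_report expects a grayscale image")
    filt = gaussian_filter(arr, sigma)
    vals = np.sort(filt.ravel())
    diffs = np.diff(vals)
    f = arr.ravel(order="F")
    d = (arr - filt).ravel(order="F")
    ties = 0
    for k in np.unique(f):
        grp = d[f == k]
        ties += grp.size - np.unique(grp).size
    return OrderingReport(
        sorted_values=vals,
        differences=diffs,
        min_difference=float(diffs.min()) if diffs.size else 0.0,
        tie_count=int(ties),
        sigma=sigma,
    )
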