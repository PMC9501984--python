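"""Histograms, conventional (inexact) equalization/specification, targets.

Histograms here are raw integer count vectors of length L+1 (index = gray
level), never normalized: the total is the pixel budget mn (3mn for the
unified color histogram pooling all RGB values).  A *target* histogram is a
count vector whose total equals the budget exactly; exact specification then
guarantees the output histogram equals it bin-for-bin.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import L_DEFAULT, validate_image


def compute_histogram(img: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Count vector h with h[k] = number of pixels at level k; total = m*n."""
    arr = validate_image(img, L)
    if arr.ndim != 2:
        raise ValueError("compute_histogram expects a grayscale image; "
                         "use compute_unified_histogram for color")
    return np.bincount(arr.ravel(), minlength=L + 1).astype(np.int64)


def compute_unified_histogram(img: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """One histogram pooling all 3mn R, G, B values; total = 3*m*n."""
    arr = validate_image(img, L)
    if arr.ndim != 3:
        raise ValueError("compute_unified_histogram expects an RGB image")
    return np.bincount(arr.ravel(), minlength=L + 1).astype(np.int64)


def cumulative(hist: np.ndarray) -> np.ndarray:
    """Running sum H with H[l] = h[0] + ... + h[l] (the convention H[-1] = 0)."""
    h = np.asarray(hist)
    if h.ndim != 1 or np.any(h < 0):
        raise ValueError("histogram must be a 1-D nonnegative count vector")
    return np.cumsum(h.astype(np.int64))


def round_half_away(x):
    """Round toward the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _equalize_map(hist: np.ndarray, L: int) -> np.ndarray:
    """The monotone staircase phi(l) = round(L * (H_l - H_lmin) / (H_lmax - H_lmin)).

    Evaluated for every level l in 0..L (levels below the lowest occupied bin
    get negative values, which only matters for bracketing searches).
    Raises ZeroDivisionError-like ValueError when the histogram has a single
    occupied bin.
    """
    h = np.asarray(hist, dtype=np.int64)
    nz = np.flatnonzero(h)
    if nz.size == 0:
        raise ValueError("empty histogram")
    if nz.size == 1:
        raise ValueError("single-level histogram: equalization map undefined")
    H = np.cumsum(h)
    Hmin, Hmax = H[nz[0]], H[nz[-1]]
    return round_half_away(L * (H - Hmin) / (Hmax - Hmin))


def conventional_equalize(img: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Classical histogram equalization (cumulative-histogram linearization).

    Each pixel value f maps to round(L * (H_f - H_fmin) / (H_fmax - H_fmin)).
    A constant image leaves the map undefined (zero denominator); it is
    returned unchanged with a warning.
    """
    arr = validate_image(img, L)
    h = compute_histogram(arr, L)
    try:
        phi = _equalize_map(h, L)
    except ValueError:
        warnings.warn("constant image: equalization is undefined; returning input unchanged",
                      stacklevel=2)
        return arr.copy()
    return phi[arr].astype(np.int64)


def conventional_specify(img: np.ndarray, target: np.ndarray, L: int = L_DEFAULT) -> np.ndarray:
    """Classical (inexact) histogram specification by staircase interpolation.

    The input's equalization staircase phi is matched against the target's
    staircase phi_hat: for each input level, the bracketing output level l
    satisfies phi_hat(l-1) < phi(f) <= phi_hat(l) (with phi_hat(-1) = 0), and
    the output is the rounded linear interpolation between max{l-1, 0} and l.
    Only the cumulative histogram is matched; bin counts are generally not.
    """
    arr = validate_image(img, L)
    target = np.asarray(target, dtype=np.int64)
    if target.sum() != arr.size:
        raise ValueError("target total must equal the pixel count")
    h = compute_histogram(arr, L)
    try:
        phi = _equalize_map(h, L)
    except ValueError:
        # constant input: every pixel shares one phi value; treat phi = 0
        phi = np.zeros(L + 1, dtype=np.int64)
    try:
        phi_hat = _equalize_map(target, L)
    except ValueError:
        lvl = int(np.flatnonzero(target)[0])
        return np.full_like(arr, lvl)

    out_map = np.empty(L + 1, dtype=np.int64)
    for f in range(L + 1):
        p = phi[f]
        l = int(np.searchsorted(phi_hat, p, side="left"))
        l = min(l, L)
        prev = phi_hat[l - 1] if l >= 1 else 0
        den = phi_hat[l] - prev
        if den == 0:
            out_map[f] = l
        else:
            lo = max(l - 1, 0)
            out_map[f] = round_half_away(((phi_hat[l] - p) * lo + (p - prev) * l) / den)
    return out_map[arr].astype(np.int64)


def build_uniform_target(budget: int, L: int = L_DEFAULT) -> np.ndarray:
    """Uniform target with remainder: base floor(budget/(L+1)) per bin, the
    first Q = budget - (L+1)*base bins get one extra so the total is exact."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base, Q = divmod(int(budget), L + 1)
    t = np.full(L + 1, base, dtype=np.int64)
    t[:Q] += 1
    return t


def largest_remainder(weights: np.ndarray, budget: int) -> np.ndarray:
    """Integerize nonnegative weights to counts summing exactly to budget.

    Floor of the scaled weights, then one extra count to the bins with the
    largest fractional remainders (ties resolved toward lower bin index).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    scaled = w * (budget / w.sum())
    counts = np.floor(scaled).astype(np.int64)
    short = int(budget - counts.sum())
    if short > 0:
        frac = scaled - counts
        # largest remainders first, ties resolved toward the lower bin index
        order = np.argsort(-frac, kind="stable")
        counts[order[:short]] += 1
    return counts


def build_gaussian_target(budget: int, L: int = L_DEFAULT,
                          mean: float = 127.5, sd: float = 50.0) -> np.ndarray:
    """Discretized Gaussian target: weights exp(-(k-mean)^2 / (2 sd^2)) at
    integer levels, integerized by largest remainder to sum to budget."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    k = np.arange(L + 1, dtype=float)
    w = np.exp(-((k - mean) ** 2) / (2.0 * sd * sd))
    return largest_remainder(w, budget)


def load_target(path, budget: int | None = None, rescale: bool = False,
                L: int = L_DEFAULT) -> np.ndarray:
    """Load a target histogram file: L+1 lines of "level,count" (or bare counts).

    If a budget is given and the file total differs, the counts are rescaled
    by largest remainder when ``rescale`` is set, otherwise it is an error.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            rows.append(int(parts[-1]))
    counts = np.asarray(rows, dtype=np.int64)
    if counts.size != L + 1:
        raise ValueError(f"expected {L + 1} counts, found {counts.size}")
    if np.any(counts < 0):
        raise ValueError("negative counts in target histogram")
    if budget is not None and counts.sum() != budget:
        if not rescale:
            raise ValueError(f"target total {counts.sum()} != budget {budget} "
                             "(pass rescale=True to renormalize)")
        counts = largest_remainder(counts, budget)
    return counts


def save_target(hist: np.ndarray, path) -> None:
    """Write a histogram as "level,count" lines."""
    h = np.asarray(hist, dtype=np.int64)
    with open(path, "w") as fh:
        for k, c in enumerate(h):
            fh.write(f"{k},{c}\n")
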