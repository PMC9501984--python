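"""Shared fixtures and independent oracles.

The oracles deliberately avoid the implementation's code paths: the filter
oracle evaluates the non-separable weighted-mean double sum directly, the
difference-operator oracle assembles the dense Kronecker matrix, and the
ordering oracle builds per-level groups with explicit Python sorting.
"""

import math

import numpy as np
import pytest

from exhist import fixtures


def gaussian_filter_bruteforce(img, sigma):
    """Direct quadruple-loop weighted mean with the joint 2-D Gaussian weight."""
    arr = np.asarray(img, dtype=float)
    m, n = arr.shape
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            num = den = 0.0
            for k in range(m):
                for l in range(n):
                    w = math.exp(-((i - k) ** 2 + (j - l) ** 2) / (2.0 * sigma * sigma))
                    num += w * arr[k, l]
                    den += w
            out[i, j] = num / den
    return out


def dense_difference_operator(m, n):
    """Dense [I_n (x) D_m ; D_n (x) I_m] for tiny images (test-only)."""
    def fwd(sz):
        d = np.zeros((sz - 1, sz))
        for i in range(sz - 1):
            d[i, i] = -1.0
            d[i, i + 1] = 1.0
        return d

    blocks = []
    if m > 1:
        blocks.append(np.kron(np.eye(n), fwd(m)))
    if n > 1:
        blocks.append(np.kron(fwd(n), np.eye(m)))
    return np.vstack(blocks) if blocks else np.zeros((0, m * n))


def order_pixels_grouped(img, d, L=255):
    """Group-then-sort ordering oracle: explicit level groups, sorted by
    (contrast, column-major index), concatenated in level order."""
    f = np.asarray(img).ravel(order="F")
    dd = np.asarray(d).ravel(order="F")
    seq = []
    for k in range(L + 1):
        group = [i for i in range(f.size) if f[i] == k]
        group.sort(key=lambda i: (dd[i], i))
        seq.extend(group)
    return np.asarray(seq, dtype=np.int64)


def spiky_target(budget, L=255):
    """Multimodal target concentrated on a few bins (sums exactly to budget)."""
    from exhist.histograms import largest_remainder
    w = np.zeros(L + 1)
    w[[0, 17, 128, 201, 255]] = [1.0, 5.0, 2.0, 7.0, 3.0]
    return largest_remainder(w, budget)


@pytest.fixture(scope="session")
def two_level():
    return fixtures.make_two_level()


@pytest.fixture
def small_gray():
    return fixtures.make_seeded_random(5, 7, seed=11)


@pytest.fixture
def small_color():
    return fixtures.make_seeded_random(4, 4, channels=3, seed=7)
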