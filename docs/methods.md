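# Methods

## Exact specification by strict ordering

An 8-bit image `F = [f_ij]` with `m` rows, `n` columns and levels in
`{0, …, L}`, `L = 255`, has histogram `h_k = #{(i,j) : f_ij = k}` and
cumulative histogram `H_l = Σ_{k≤l} h_k` (with the convention `H_{−1} = 0`).
Exact specification toward a target `ĥ` (with `Σ ĥ_k` equal to the pixel
budget) needs a total order `μ_1, …, μ_mn` over pixels that refines the value
order; level `l` is then assigned to ranks `Ĥ_{l−1} < ι ≤ Ĥ_l`. Since exactly
`ĥ_l` ranks fall in each bracket, `histogram(output) = ĥ` holds with integer
equality by construction, and the output level is nondecreasing along the
ordering. Specifying an image to its own histogram is the identity: the
pixels of value `k` occupy exactly ranks `H_{k−1}+1 … H_k` and are reassigned
level `k`, independently of how the ordering arranged them within the group.

### Local-contrast ordering

The primary sort key is the pixel value; the secondary key is the local
contrast `d_ij = f_ij − f^GF_ij` against the non-truncated Gaussian filter

    f^GF = (G_L F G_R) ⊘ (G_L E G_R),
    G_L[i,k] = exp(−(i−k)²/(2σ²)),  G_R[j,l] = exp(−(j−l)²/(2σ²)),

the exact weighted mean of *all* pixels (`E` the all-ones matrix; `⊘`
elementwise). Every output is a convex combination of the inputs, so the
filtered range is contained in the input range, and a constant image is a
fixed point (up to last-ulp rounding of the matrix products). The separable
matrix form costs `O(mn(m+n)) = O(N^{3/2})` time and `O(N)` space and is the
reason no kernel truncation is needed; truncation would collapse distinct
weighted means back into ties.

The final tie-break key is the 1-based column-major linear index
`μ = (j−1)m + i` (for color, `η = mn(k−1) + m(j−1) + i` with channel
`k ∈ {1,2,3}`). The whole ordering is implemented as one stable lexicographic
sort on `(value, contrast, index)`; a per-group sort concatenated in level
order is provably equivalent and is kept as an independent test oracle. Tie
*detection* uses exact double equality — an epsilon would itself need a
tie-break rule, while bit-equality is reproducible.

### σ (spatial scale)

Default `σ = 50` pixels. Any `σ > 0` yields an exact output histogram; σ
only moves *which* pixel of a value group receives which level within the
group's bracket. Above about `10⁸` the weights become numerically
indistinguishable from 1 and the contrast degenerates, so the filter warns
(without refusing) beyond that scale. There is no principled selection rule
for σ below that limit; the minimum sorted-difference diagnostic
(`ordering_report`) shows no monotone trend in σ.

## The fully smoothed ℓ1-TV baseline

The alternative ordering smooths `f` by `T` fixed-point iterations of

    u ← f − ξ(β Gᵀ θ′(G u)),   u⁽⁰⁾ = f,

where `θ(t) = |t| − α log(1+|t|/α)` (smooth `|·|` surrogate), `θ′(t) =
t/(α+|t|)`, `ξ = (θ′)⁻¹`, `ξ(z) = αz/(1−|z|)`, and `G = [Iₙ⊗D_m; Dₙ⊗I_m]`
stacks the vertical then horizontal forward differences of the column-major
vectorized image (`r = 2mn − m − n` rows). Defaults `α = 0.05`, `β = 0.1`,
`T = 5`; the iteration is run for exactly `T` steps with no convergence
check, matching how the scheme is normally used. `G` and `Gᵀ` are applied as
±1 stencils on the 2-D grid — the dense matrix for a 256×256 image would
hold `r·mn ≈ 8.56×10⁹` entries and exists only inside the test oracle at
sizes ≤ 4×4.

Because `|θ′| < 1` and each column of `G` has at most four ±1 entries, the
update moves each pixel by less than `ξ(4β)` (defaults: `ξ(0.4) = 0.0333…`).
The iterate's ordering therefore refines the integer value order, which is
why the NS route enjoys the same exactness and self-specification
guarantees; only the within-group arrangement differs from the LC route.
Exact ties in `u` are broken by the same column-major index rule.

## Color

Unified mode builds one histogram pooling all `3mn` RGB values, filters each
channel with shared `G_L/G_R`, and runs a single ordering over all
pixel-channel elements; one exact specification then constrains the pooled
histogram while leaving the per-pixel channel *ratios* — hence hue — much
less disturbed than processing channels independently. The separable
baseline applies the NS grayscale algorithm per channel with a budget-`mn`
target each: per-channel histograms are exact but hue drifts.

## Conventional (inexact) methods

Equalization maps through the monotone staircase
`φ(f) = round(L(H_f − H_fmin)/(H_fmax − H_fmin))`; rounding is
half-away-from-zero throughout (banker's rounding would silently differ at
exact halves). A constant image leaves the map undefined (zero denominator);
it is returned unchanged with a warning. Specification matches the input
staircase `φ` against the target staircase `φ̂` and interpolates linearly
between the bracketing levels `max{l−1, 0}` and `l` where
`φ̂(l−1) < φ(f) ≤ φ̂(l)`, `φ̂(−1) = 0`. The bracketing level is found by a
left-bisection search (smallest `l` with `φ̂(l) ≥ φ(f)`), which also settles
the edge case `φ(f) = 0`, where the strict lower bracket is unsatisfiable;
a zero interpolation denominator assigns `l` directly.

## Targets

* **Uniform with remainder**: base count `⌊budget/(L+1)⌋` per bin; the first
  `Q = budget − (L+1)·base` bins take one extra. Total exact; spread ≤ 1.
* **Discretized Gaussian** (default mean 127.5, sd 50): weights
  `exp(−(k−mean)²/2sd²)` at integer levels, integerized by the
  largest-remainder method (floor the scaled weights, give the shortfall to
  the largest fractional remainders, ties toward the lower bin). The method
  keeps the total exact and the symmetric mean-127.5 target symmetric to ±1.
* **File / reference-image targets**: 256-line `level,count` text; totals
  that do not match the pixel budget are rescaled by largest remainder only
  on request.

## Synthetic data

All test inputs are generated programmatically:

* `make_two_level` — the 200×282 step image (left half 200, right half 100;
  the split column is not dictated by anything, so the even 141/141 split is
  used). It isolates the flat-region behavior of orderings: value-only or
  TV-based orderings fluctuate inside flat regions (stripes), the LC
  ordering keeps every horizontal profile monotone within each region.
* `make_seeded_random` — i.i.d. uniform levels; the stress case for
  exactness (no spatial structure helps the ordering).
* `make_mirror_symmetric` — forces near-exact filtered-value collisions at
  mirrored positions. With blocked/FMA matrix kernels, mirrored sums round
  differently in the last ulp, so collisions are frequent (most pairs) but
  not guaranteed per pair; tests that need *exact* ties construct contrast
  arrays directly.
* `make_smooth_color` — Gaussian-smoothed noise fields, 70 % shared across
  channels, rescaled to [0, 255]. Smooth, correlated channels give spatially
  coherent hue, which makes hue-drift comparisons meaningful; white-noise
  color images would not.

What these do **not** emulate: sensor noise models, texture statistics of
natural or biological images, saturation clipping, or any correlation
between value and local contrast found in real scenes. Passing tests
demonstrate the algorithmic guarantees (exactness, ordering invariants,
direction of the hue and stripe effects), not enhancement quality on real
data.

## Numerical choices and limitations

* All filtering in double precision; comparisons of filtered values are
  exact (no epsilon).
* `ξ∘θ′ = id` holds to 1e−12 absolute for `|t| ≤ 10`; the round trip's
  condition number is `(α+|t|)²/α`, so the identity degrades to relative
  accuracy for large `|t|`. The iteration only evaluates `ξ` on
  `(−4β, 4β)`, deep inside the well-conditioned range.
* Problem sizes in the test battery (up to 64×64, with the 200×282 step
  image and 40×40 color fields) were chosen as the smallest sizes at which
  every asserted phenomenon is stable; all suites run in seconds.
* Images with more than 8 bits per channel are rejected, not rescaled —
  rescaling would silently change the histogram being specified.
* Exactness guarantees assume the target totals the pixel budget; helpers
  enforce this and the largest-remainder rescaler is opt-in.
* Hue is the hexagonal HSV hue in degrees with circular differences;
  achromatic pixels (R=G=B) have no hue and are excluded pairwise from the
  RMSE. Hue comparisons between methods are directional under this one
  definition, not absolute.
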