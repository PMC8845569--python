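# Methods

## Data model

A PolSAR pixel is summarised by its 3×3 Hermitian sample covariance C3 of
the lexicographic scattering vector `[S_hh, √2 S_hv, S_vv]`, in linear
power units, together with the nominal number of looks *n* (independent
samples averaged per pixel). The Pauli coherency matrix is the unitary
rotation `T3 = A C3 A†` with

```
A = 1/√2 · [[1, 0,  1],
            [1, 0, −1],
            [0, √2, 0]]
```

whose diagonal square roots are the surface, double-bounce and volume
scattering amplitudes. Because A is unitary the transform preserves total
power (trace), which the test suite asserts. Features are kept in linear
amplitude rather than dB: the mean-shift range kernel then measures
physical amplitude contrast, and the values match the usual Pauli-RGB
convention. The grid is 0-based, row-major `(row, col)` everywhere.

## Mean-shift over-segmentation

Mode seeking runs in the 5-D joint space `(row/h_s, col/h_s, f/h_r)` with a
separable Gaussian profile `exp(−u/2)` and uniform sample weights. Numerical
choices:

- **Kernel truncation** at spatial distance `3 h_s` (Gaussian weight
  < 1e-4), making one update O(h_s²) instead of O(N).
- **Convergence**: joint displacement `< tol = 1e-3` (bandwidth-normalised)
  or `max_iter = 100`.
- **Mode grouping**: convergence points within `h_s/2` spatially *and*
  `h_r/2` in range are transitively grouped (half-bandwidth is the common
  convention); groups are split into 4-connected components.
- **Minimum region size M**: regions below M pixels are merged into the
  4-adjacent region with the closest mean Pauli vector, smallest region
  first, ties to the lowest id, so the result is deterministic.

Defaults `h_s = 7`, `h_r = 6.5` target full-scene satellite data in its own
amplitude units; bandwidths are *not* portable across data sets, and the
canned synthetic scene uses `h_s = 2`, `h_r = 0.3`, `M = 40` (see below).
An optional extra 5×5 mean-shift filtering pass (`prefilter`) emulates a
speckle pre-filter; it is off by default because over-segmentation already
tolerates speckle and the extra smoothing mainly blurs boundaries.

## Cross-date merging

Two pixels share a merged region iff they share a region on **every** date
and are 4-connected through pixels satisfying the same condition; i.e. the
merged map is the connected-component relabelling of the per-date label
tuples. 4-connectivity was chosen for consistency with the rest of the
pipeline (the alternative 8-connectivity would only join diagonal slivers).
The merge is a refinement of every input, commutative up to renaming, and
pixel conserving — all asserted as properties.

## Wishart edge detector

The likelihood-ratio statistic for equality of two population covariances,
with half-window sample means Σ̂ᵢ, Σ̂ⱼ over Nᵢ, Nⱼ pixels and pooled
Σ̂ = (NᵢΣ̂ᵢ + NⱼΣ̂ⱼ)/(Nᵢ+Nⱼ), is

D = (Nᵢ+Nⱼ) ln|Σ̂| − Nᵢ ln|Σ̂ᵢ| − Nⱼ ln|Σ̂ⱼ|.

The pooled weighted mean is the maximum-likelihood estimate under the null
for Wishart-distributed samples. D is symmetric, non-negative, zero iff
the two means coincide, independent of the look count (the 1/n
normalisation of the log-ratio cancels the n in the likelihood exponents),
and invariant to a global rescaling of the data — the last two properties
make per-date maps comparable, so fusion takes the raw pointwise maximum
without normalisation (an optional percentile normalisation is deliberately
*not* applied by default).

Geometry: the window (default 7×7) is split by the edge line itself —
θ = 0° means a horizontal edge separating the rows above from the rows
below; 45°/135° split along the anti-/main diagonal with the diagonal
excluded. Note this is the *edge-line* convention, not the gradient
convention. Borders use reflect padding. Oriented NMS keeps a pixel iff
its strength is ≥ both neighbours one step perpendicular to θ\* (diagonal
neighbours for 45°/135°), with ties kept so plateaus survive; NMS runs per
date before fusion. Log-determinants are regularised as
`ln det(M + δI)`, `δ = 1e-10·max(tr(M)/3, 1e-30)`, via Cholesky (batched
LU for whole images), which keeps rank-deficient half-means finite without
visibly perturbing well-conditioned values.

## Region graph

Each merged region is represented by the pixel maximising the
extensibility `E(p) = Π L(α·i)` over `360/α` rays (default α = 10°, fine
enough to break symmetry on elongated parcels at negligible cost), with
0.5-pixel ray steps; a ray starting at the boundary still counts L = 0.5,
so E never vanishes and the product (accumulated in log space) is always
defined. Ties go to the smallest `(row, col)`.

Dissimilarity `D_c` is the maximum thinned fused edge strength along the
Bresenham segment between two centres, endpoints included; because
Bresenham is direction dependent, both directions are rasterised and the
larger maximum taken, making `D_c` exactly symmetric. The affinity is
`W = exp(−D_c²/2σ_C²)` with unit diagonal; `σ_C` defaults to 0.1× the
largest pairwise `D_c` (a standard normalized-cuts kernel heuristic; 1.0
if all `D_c` are zero). The dense N×N matrix is fine at the intended scale
(N ≈ 10³).

## Normalized cuts

Self-loops are excluded from both `cut` and `assoc` sums. The k-way
default is the spectral relaxation: bottom k eigenvectors of the
symmetric-normalised Laplacian (dense `eigh` with subset selection up to
N = 2000, exact and fast at this scale; sparse shift-invert `eigsh`,
tolerance 1e-8, beyond), row-normalised and clustered by k-means with 10
restarts and a fixed seed — giving direct control of k and deterministic
output. A recursive two-way variant (Fiedler-vector sweep, splitting the
segment whose candidate split has the largest Ncut until k segments) is
provided for comparison. Exact Ncut optimality is not guaranteed by the
relaxation and is not asserted; the tests check brute-force equality of
the criterion itself and a relaxation sanity bound (spectral 2-way cut ≤
median over all bipartitions).

The final projection assigns each pixel its region's segment. Segments may
be spatially disconnected (two parcels of the same crop class can
legitimately share a segment), so the final label map relaxes the
per-region connectivity invariant that holds everywhere earlier.

## Evaluation

For each reference region SS, the candidate with the largest overlap
(ties: lowest id) is tested against the under-segmentation ratio
`USR = 1 − |A∩SS|/|A|`; if it passes, the region scores `|A∩SS|/|SS|`,
else 0; the image score is the unweighted mean. By default |A| counts only
pixels inside the evaluated area so the metric stays well defined when the
reference covers the scene partially; `full_candidate_size=True` restores
whole-image candidate sizes. Accuracies are exact internally and rounded
to two decimals only when printed.

## Synthetic scenes — what they do and do not show

The generator draws each pixel independently from the complex Wishart
model: `(1/L) Σ z_k z_k†`, `z_k ~ CN(0, Σ_class,date)`, via the Cholesky
factor of Σ applied to standard complex-normal draws; one shared RNG
stream (classes iterated in sorted order) makes whole scenes bit-identical
under a fixed seed.

The canned fixture is 3 dates, 120×120 pixels, a 4×4 parcel grid,
4 looks — sizes chosen so the full pipeline runs in tens of seconds per
scene. Four classes combine two base Hermitian structures (surface-like
diag(1, 0.2, 0.6) with HH–VV correlation 0.3; volume-like
diag(0.5, 1, 0.5)) with per-date power factors 1–4, a realistic seasonal
dynamic range for crops. Classes 1/2 are identical on dates 0 and 1 and
separate only on date 2; classes 3/4 are identical only on date 2; the
class layout makes every confusable pair spatially adjacent. No single
date therefore separates all 16 parcels while the union of dates does —
the regime the method exists for, and the acceptance test confirms the
multi-temporal run beats every single-date run on five independent scenes.

Not emulated: spatially correlated speckle, registration error, incidence
angle/topography, mixed boundary pixels, irregular parcel shapes (although
any user label map is accepted as ground truth). Passing tests therefore
demonstrate the algorithmic contracts under ideal Wishart statistics, not
performance on real co-registered satellite scenes.

## Known limitations

- Mean-shift bandwidths and M must be re-tuned per data set; no automatic
  selection rule is provided (none is established for this pipeline).
- The affinity uses edge evidence only; two regions whose connecting line
  leaves their parcels (strongly non-convex layouts) can be under-linked.
- Dense affinity memory grows as N²; beyond ~10⁴ regions a sparsification
  strategy would be needed (out of scope).
- k, the number of final segments, is a user choice.
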