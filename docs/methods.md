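# Methods

## Model and procedure

`mesfda` detects anomalous curves in a sample of functional data observed on
a shared time grid. The procedure has three stages.

**1. Representation.** Each observed curve `y = (x(t_1), …, x(t_m))` is
smoothed by Gaussian-kernel ridge regression: with Gram matrix
`K_{kl} = exp(-σ (t_k - t_l)^2)` the expansion coefficients solve

    (γ m I + K) a = y,

a strictly positive-definite system for any γ > 0, so the fit is unique.
The fitted curve `x̃(t) = Σ_i a_i K(t, t_i)` is then projected onto the
leading eigenvectors of `K`: with eigenpairs `(λ_j, v_j)` (eigenvalues
non-increasing), the representation coefficients are

    z_j = λ_j Σ_i a_i v_{ij},   j = 1 … d.

The `z` vector plays the role of a truncated Karhunen–Loève score vector:
for a second-order process the entropy of the full process is approximated
by the entropy of its leading d expansion coefficients, and the kernel
eigenbasis is the empirical surrogate for the covariance eigenfunctions.
All curves share one grid and hence one Gram factorization; ragged
per-curve grids are rejected because eigenbases of different Gram matrices
are not comparable without an alignment step we do not define.

**2. Entropy.** Two estimators of the Rényi α-entropy
`H_α = (1-α)^{-1} log E[f^{α-1}]` of the coefficient distribution:

* *Parametric plug-in*: fit a Gaussian `N(μ, Σ)` to the coefficient rows
  (robustly or by moments) and use the closed form
  `H_α = (d/2) ln 2π + ½ ln det Σ + (d/2) ln(α)/(α-1)`, with the Shannon
  limit `½ ln((2πe)^d det Σ)` at α = 1. Values are in nats.
* *Local (non-parametric)*: `h_i = exp(d̄_k(z_i))`, the exponential of the
  mean Euclidean distance from `z_i` to its k nearest neighbours among the
  other points. Large `h_i` means `z_i` sits in a low-density region.
  The estimator does not depend on α; α is carried as metadata.

**3. Minimum-entropy sets.** The ν-minimum-entropy set is the Borel set of
probability ≥ 1-ν minimizing set-restricted entropy; it coincides with a
high-density set, so its complement defines anomalies.

* *Parametric (PA)*: the set is the Mahalanobis ellipsoid
  `(z-μ̂)ᵀ Σ̂⁻¹ (z-μ̂) ≤ c` with `c` either the χ²_d(1-ν) quantile or — when
  ν is treated as known — the empirical (1-ν) quantile of the training
  distances, i.e. the `⌈(1-ν)n⌉`-th order statistic. Boundary points are
  inside the set.
* *Non-parametric (NPA)*: threshold `h` at ρ*, the solution of
  `max_{ρ,ε≥0} (1-ν)ρ - (1/n)Σε_i  s.t.  h_i ≥ ρ - ε_i`. The objective is
  concave piecewise-linear in ρ with slope `(1-ν) - #{h_i < ρ}/n`, so its
  smallest maximizer is the `⌈(1-ν)n⌉`-th smallest training `h`; the
  package uses this closed form (the test suite verifies it against a
  generic LP solver). The decision rule is `sign(ρ* - h)` with
  `sign(0) := +1`, which makes the in-sample fraction classified normal
  exactly `⌈(1-ν)n⌉/n` whenever the `h` values are distinct.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| σ | inverse squared kernel width (1/time²) | 10 | reference value for the unit interval; selectable by 10-fold CV over time points |
| γ | ridge weight (dimensionless) | 0.15 | reference value; CV ties break toward larger γ (stronger smoothing) |
| truncation | order d | smallest d with cumulative eigenvalue fraction ≥ 0.999 | fixed-d override available; d is a property of the kernel and grid only |
| ν | contamination level | 0.10 | probability mass excluded from the estimated set |
| k | neighbour count (NPA) | max(5, ⌈√n⌉) | standard bias–variance compromise; recorded in outputs |
| support fraction | MCD robust subset | 0.75 | robust fit falls back to sample moments with a warning when n < 2(d+1) |

## Numerical choices

* **Eigenvector signs** are fixed so the largest-magnitude component of each
  eigenvector is positive (first such component on ties), and tied
  eigenvalues keep their natural order; this makes the representation
  bit-reproducible. Any consistent convention leaves Mahalanobis and
  nearest-neighbour distances unchanged.
* **Numerical rank** counts eigenvalues above `10⁻¹² λ₁`; truncation beyond
  it is rejected.
* **λ-scaling.** The coefficients are scaled by λ_j as printed in the
  defining formula. A Mercer-series argument suggests a √λ_j convention
  may have been intended; because the induced center-outward ordering is
  equivariant under per-coordinate scaling (and the PA detector's
  Mahalanobis distance is exactly invariant), the choice does not affect
  detection with a fixed d. Both conventions are exposed
  (`coefficient_scaling="lambda" | "sqrt_lambda"`).
* **Quantile convention.** The empirical (1-ν) quantile of n values is the
  `⌈(1-ν)n⌉`-th order statistic; ties at the threshold are classified
  inside the set. Combined with `sign(0) := +1` this gives the exact
  finite-sample training fraction.
* **kNN self-handling.** In-sample local entropy excludes the point itself;
  duplicate points contribute distance 0. Out-of-sample points are scored
  against the training rows without self-exclusion.
* **Degenerate inputs.** A single curve can be represented but not
  classified (no distribution to estimate); an all-identical coefficient
  sample raises a zero-scatter error; a rank-deficient fitted covariance
  raises an error advising a lower d.

## Synthetic data

The scenario generator draws n = 400 curves on m = 50 equispaced points of
[0, 1]: inliers `Σ_{j=1..4} ξ_j sin(jπt) + ε(t)` with
`ξ ~ N((4,2,4,1), diag(5,2,2,1))`; magnitude outliers (scenario A) scale
mean and standard deviation by 2.5; shape outliers (scenario B) move the
coefficient mean to (4, −2, 1, 3) at unchanged covariance; scenario C
splits the ⌈νn⌋ outliers half-and-half (⌊νn/2⌋ magnitude). The outlier
count is ν·n rounded half-up.

The additive error is specified only as smooth autocorrelated noise in the
study design this generator emulates; the package fixes a zero-mean
Gaussian process with squared-exponential covariance, variance 0.25 and
length-scale 0.1, as the default `NoiseSpec` (jitter 10⁻¹⁰ for the
Cholesky factorization). All Monte-Carlo outputs echo the noise settings
used.

What the generator does **not** emulate: measurement error that is rough at
the grid scale (white noise), heavy-tailed or skewed coefficient
distributions, irregular or per-curve sampling designs, and missing data.
Passing Monte-Carlo checks therefore demonstrate correct behaviour under
smooth Gaussian contamination of a four-harmonic signal, not performance on
arbitrary real data.

A second generator draws two groups of noiseless Gaussian-process curves on
the first three orthonormal Fourier elements (√2 sin 2πt, √2 cos 2πt,
√2 sin 4πt — configurable) with i.i.d. coefficient variances 0.5 and 2,
used to check that estimated entropy orders processes by dispersion.

## Design choices on open points

* **Truncation rule.** The truncation order is a property of the kernel and
  grid (cumulative eigenvalue fraction ≥ 0.999 by default). Under the
  default noise this yields d = 7 for the scenario generator. Trailing
  eigen-coordinates carry mostly observation noise, and including more of
  them measurably dilutes the Mahalanobis separation of shape outliers;
  the shipped defaults accept this in exchange for a data-independent,
  reproducible rule. Scenario-B sensitivity therefore depends strongly on
  the noise process; the Monte-Carlo tests compare detection rates on the
  scale of replicate standard deviations for this reason.
* **Ordering robustness across kernel settings** is assessed at a common
  truncation order (the smaller of the two per-setting orders): with
  different d the comparison would mix the kernel-parameter effect with the
  number of noise coordinates included, which is a separate choice.
* **Entropy ordering of the Fourier-GP example** is computed at d = 2: on
  the symmetric default grid the Gram eigenvectors alternate even/odd about
  t = ½, both sine elements are odd and alias into the single odd leading
  coordinate, and the cosine's two even coordinates are collinear — so the
  noiseless sample's coefficient covariance has rank 2 and the Gaussian
  plug-in is singular beyond it.
* **d̄_k** is read as the mean distance to the k nearest neighbours
  (the convention of the kNN-entropy literature); `neighbor_rule="kth"`
  exposes the distance-to-k-th-neighbour alternative. Both agree at k = 1.
* **Robust fit.** Any affine-equivariant robust location/scatter estimator
  fits the framework; the package uses the minimum covariance determinant
  with support fraction 0.75 and a seedable subset search.

## Problem sizes

The shipped Monte-Carlo configuration uses M = 100 replicates per cell
(n = 400, m = 50); per-replicate seeds are `base_seed + r` for
auditability, and means are reported with standard errors (SD/√M) and
replicate SDs. Dispersions printed in parentheses by comparable studies
are treated as replicate SDs, the conservative choice when comparing
means.

## Known limitations

* Only the Gaussian kernel is built in; the kernel functions are isolated
  so other positive-definite kernels could be added, but no interface
  guarantees are made.
* No automatic choice of ν (scan it externally) and no post-processing of
  the NPA region beyond thresholding (a convex hull drawn around retained
  points is a visualization device, not part of the decision rule).
* Entropy values depend on the kernel parameters through the coefficient
  scale; only entropy *orderings* and detection decisions are
  parameter-robust, and only orderings are asserted for the GP example.
* The empirical-quantile threshold assumes ν is known; when it is not, the
  χ² threshold requires the Gaussian model to be approximately correct.
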