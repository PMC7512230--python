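"""Synthetic curve generators for the Monte-Carlo study.

The contaminated-sample generator draws n curves on an equispaced grid of
[0, 1].  Inliers follow

    X(t) = sum_{j=1..4} xi_j sin(j pi t) + eps(t),

with xi ~ N((4, 2, 4, 1), diag(5, 2, 2, 1)); a fraction nu of the sample are
outliers of one of two kinds:

* **Scenario A (magnitude)** — coefficients zeta ~ N(2.5 mu, 2.5^2 Sigma):
  same oscillation pattern, inflated level and spread.
* **Scenario B (shape)** — zeta ~ N((4, -2, 1, 3), Sigma): comparable level
  but a different mix of harmonics.
* **Scenario C** — floor(nu*n/2) magnitude outliers, the rest shape.

The additive error eps(t) is a zero-mean Gaussian process with
squared-exponential covariance (variance 0.25, length-scale 0.1 by default),
giving smooth autocorrelated noise paths.  A separate small generator draws
two groups of Gaussian-process curves on a three-element Fourier basis with
coefficient variances 0.5 and 2, used to illustrate the entropy ordering of
low- versus high-variance processes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .representation import SampledCurveSet

__all__ = [
    "NoiseSpec",
    "ScenarioSpec",
    "gp_noise_path",
    "simulate_scenario",
    "simulate_gp_example",
]

_SCENARIOS = ("A", "B", "C")


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean squared-exponential Gaussian-process observation noise.

    covariance(s, t) = variance * exp(-(s - t)^2 / (2 length_scale^2)).
    """

    kind: str = "gaussian-process"
    variance: float = 0.25
    length_scale: float = 0.1

    def __post_init__(self):
        if self.kind != "gaussian-process":
            raise ValueError(f"unsupported noise kind {self.kind!r}")
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")
        if not self.length_scale > 0:
            raise ValueError("noise length_scale must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one contamination scenario.

    ``outlier_mean`` / ``outlier_cov_diag`` default to the scenario's
    standard values (A: 2.5x the inlier mean with 2.5^2-scaled covariance;
    B: mean (4, -2, 1, 3) with the inlier covariance) and may be overridden.
    """

    scenario: str = "A"
    n: int = 400
    nu: float = 0.10
    m: int = 50
    inlier_mean: Tuple[float, ...] = (4.0, 2.0, 4.0, 1.0)
    inlier_cov_diag: Tuple[float, ...] = (5.0, 2.0, 2.0, 1.0)
    outlier_mean: Optional[Tuple[float, ...]] = None
    outlier_cov_diag: Optional[Tuple[float, ...]] = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}")
        if self.n < 1 or self.m < 2:
            raise ValueError("need n >= 1 curves and m >= 2 grid points")
        if not 0.0 <= self.nu < 1.0:
            raise ValueError(f"nu must be in [0, 1), got {self.nu}")

    @property
    def n_outliers(self) -> int:
        """Round-half-up of nu * n."""
        return int(math.floor(self.nu * self.n + 0.5))

    def outlier_params(self, kind: str) -> Tuple[np.ndarray, np.ndarray]:
        """Coefficient mean and covariance diagonal for outlier type A or B."""
        mu = np.asarray(self.inlier_mean, dtype=float)
        var = np.asarray(self.inlier_cov_diag, dtype=float)
        if kind == "A":
            mean = 2.5 * mu if self.outlier_mean is None else np.asarray(self.outlier_mean, float)
            cov = 2.5**2 * var if self.outlier_cov_diag is None else np.asarray(
                self.outlier_cov_diag, float)
        elif kind == "B":
            mean = (np.array([4.0, -2.0, 1.0, 3.0]) if self.outlier_mean is None
                    else np.asarray(self.outlier_mean, float))
            cov = var if self.outlier_cov_diag is None else np.asarray(self.outlier_cov_diag, float)
        else:
            raise ValueError(f"outlier kind must be 'A' or 'B', got {kind!r}")
        return mean, cov


def _sq_exp_covariance(grid: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    diff = grid[:, None] - grid[None, :]
    return noise.variance * np.exp(-(diff**2) / (2.0 * noise.length_scale**2))


def _gp_noise_paths(grid: np.ndarray, noise: NoiseSpec, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    """n smooth noise paths on the grid, as an n x m matrix."""
    m = grid.size
    if noise.variance == 0.0:
        return np.zeros((n, m))
    cov = _sq_exp_covariance(grid, noise) + 1e-10 * np.eye(m)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - jitter suffices in practice
        raise ValueError("noise covariance not positive definite after jitter") from exc
    return (chol @ rng.standard_normal((m, n))).T


def gp_noise_path(grid: Sequence[float], noise: NoiseSpec = NoiseSpec(),
                  seed: Optional[int] = None) -> np.ndarray:
    """One zero-mean squared-exponential Gaussian-process path on the grid."""
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    return _gp_noise_paths(grid, noise, rng, 1)[0]


def _sine_basis(grid: np.ndarray, n_terms: int = 4) -> np.ndarray:
    """Rows j = sin((j+1) pi t) for the generating model."""
    j = np.arange(1, n_terms + 1)
    return np.sin(np.pi * j[:, None] * grid[None, :])


def simulate_scenario(spec: ScenarioSpec) -> SampledCurveSet:
    """Draw one contaminated curve sample per the scenario specification.

    Returns a :class:`SampledCurveSet` whose labels mark outliers (1) versus
    inliers (0).  Inlier rows come first, then magnitude-type, then
    shape-type outliers; draws are reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.linspace(0.0, 1.0, spec.m)
    basis = _sine_basis(grid)

    n_out = spec.n_outliers
    if spec.nu > 0 and n_out == 0:
        warnings.warn(
            f"nu={spec.nu} with n={spec.n} rounds to zero outliers", UserWarning
        )
    n_in = spec.n - n_out
    if spec.scenario == "A":
        kinds = [("A", n_out)]
    elif spec.scenario == "B":
        kinds = [("B", n_out)]
    else:
        n_a = n_out // 2
        kinds = [("A", n_a), ("B", n_out - n_a)]

    mu_in = np.asarray(spec.inlier_mean, dtype=float)
    sd_in = np.sqrt(np.asarray(spec.inlier_cov_diag, dtype=float))
    blocks = [mu_in + sd_in * rng.standard_normal((n_in, mu_in.size))]
    for kind, count in kinds:
        mean, cov_diag = spec.outlier_params(kind)
        blocks.append(mean + np.sqrt(cov_diag) * rng.standard_normal((count, mean.size)))
    coeffs = np.vstack(blocks)
    values = coeffs @ basis + _gp_noise_paths(grid, spec.noise, rng, spec.n)
    labels = np.concatenate([np.zeros(n_in, dtype=int), np.ones(n_out, dtype=int)])
    return SampledCurveSet(grid=grid, values=values, labels=labels)


def _fourier_basis(grid: np.ndarray, elements: Sequence[int] = (1, 2, 3)) -> np.ndarray:
    """Orthonormal Fourier elements on [0, 1].

    Element 2r-1 is sqrt(2) sin(2 pi r t), element 2r is sqrt(2) cos(2 pi r t);
    the defaults (1, 2, 3) give sin(2 pi t), cos(2 pi t), sin(4 pi t).
    """
    rows = []
    for e in elements:
        r = (e + 1) // 2
        if e % 2 == 1:
            rows.append(np.sqrt(2.0) * np.sin(2 * np.pi * r * grid))
        else:
            rows.append(np.sqrt(2.0) * np.cos(2 * np.pi * r * grid))
    return np.vstack(rows)


def simulate_gp_example(
    n_per_group: int = 50,
    seed: Optional[int] = None,
    m: int = 50,
    variances: Tuple[float, float] = (0.5, 2.0),
    basis_elements: Sequence[int] = (1, 2, 3),
) -> SampledCurveSet:
    """Two groups of Gaussian-process curves with different coefficient variance.

    Each curve is a combination of three orthonormal Fourier basis elements
    with i.i.d. N(0, variance) coefficients — variance ``variances[0]`` for
    the first group (label 0) and ``variances[1]`` for the second (label 1).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 curves per group")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, m)
    basis = _fourier_basis(grid, basis_elements)
    p = basis.shape[0]
    values = []
    for var in variances:
        coeffs = np.sqrt(var) * rng.standard_normal((n_per_group, p))
        values.append(coeffs @ basis)
    labels = np.concatenate([np.full(n_per_group, g, dtype=int)
                             for g in range(len(variances))])
    return SampledCurveSet(grid=grid, values=np.vstack(values), labels=labels)
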