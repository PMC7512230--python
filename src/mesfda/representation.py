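"""Finite-dimensional representation of sampled curves.

Discretely observed curves are smoothed by Gaussian-kernel ridge regression
(the regularized curve-fitting problem whose solution, by the representer
theorem, is a finite kernel expansion), and the fitted curves are then
projected onto the leading eigenvectors of the kernel Gram matrix.  The
resulting n x d coefficient matrix is the working representation for all
entropy and minimum-entropy-set computation downstream: each curve becomes a
point z in R^d whose coordinates play the role of truncated Karhunen-Loeve
scores.

The central estimator class is :class:`KernelCurveRepresenter`, a
scikit-learn transformer; the module-level functions expose the individual
steps (Gram matrix, ridge solve, eigendecomposition, projection) for direct
use and testing.
"""

from __future__ import annotations

import numbers
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SampledCurveSet",
    "KernelSpec",
    "GramFactorization",
    "CoefficientSet",
    "gaussian_gram",
    "fit_ridge_coefficients",
    "eigendecompose",
    "project_coefficients",
    "represent_sample",
    "reconstruct_curve",
    "select_kernel_params_cv",
    "KernelCurveRepresenter",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledCurveSet:
    """A sample of n curves observed on a shared time grid.

    Parameters
    ----------
    grid : array of shape (m,)
        Strictly increasing observation times (m >= 2).
    values : array of shape (n, m)
        Row ``l`` holds the observed values of curve ``l`` on ``grid``.
    labels : array of shape (n,), optional
        Ground-truth anomaly flags (1 = anomalous, 0 = normal); used for
        evaluation only, never by the detectors.
    """

    grid: np.ndarray
    values: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be a 1-d array with at least 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing (no duplicates)")
        if values.shape[1] != grid.size:
            raise ValueError(
                f"values has {values.shape[1]} columns but grid has {grid.size} points"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain missing or non-finite entries")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape[0] != values.shape[0]:
                raise ValueError("labels length must match the number of curves")
            object.__setattr__(self, "labels", labels)

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel and ridge configuration.

    ``sigma`` is the inverse squared width of the kernel
    K(s, t) = exp(-sigma * (s - t)^2) and ``gamma`` the ridge regularization
    weight of the curve-fitting problem.
    """

    sigma: float = 10.0
    gamma: float = 0.15

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class GramFactorization:
    """Eigendecomposition of an m x m kernel Gram matrix.

    Eigenvalues are sorted non-increasing; eigenvector signs are fixed so the
    largest-magnitude component of each column is positive (first such
    component on ties), which makes the factorization fully reproducible.
    ``numerical_rank`` counts eigenvalues above ``rank_tolerance * lambda_1``.
    """

    gram: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    numerical_rank: int


@dataclass(frozen=True)
class CoefficientSet:
    """Truncated representation coefficients of a curve sample.

    ``coefficients`` is the n x d matrix Z whose row l is the coefficient
    vector z_l of curve l; ``ridge_coefficients`` the n x m matrix of kernel
    expansion coefficients (one a-vector per curve), kept so the fitted
    curves can be reconstructed or re-truncated.
    """

    coefficients: np.ndarray
    d: int
    ridge_coefficients: np.ndarray
    kernel_spec: KernelSpec
    eigenvalues_used: np.ndarray
    grid: np.ndarray = field(default=None, repr=False)

    @property
    def n_curves(self) -> int:
        return self.coefficients.shape[0]


# ---------------------------------------------------------------------------
# Component operations
# ---------------------------------------------------------------------------

def gaussian_gram(grid: Sequence[float], sigma: float) -> np.ndarray:
    """Gaussian-kernel Gram matrix on a time grid.

    Entry (k, l) is exp(-sigma * (t_k - t_l)^2); symmetric with unit diagonal.
    """
    if not (isinstance(sigma, numbers.Real) and sigma > 0):
        raise ValueError(f"sigma must be a positive real, got {sigma!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1:
        raise ValueError("grid must be one-dimensional")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing (duplicate or unsorted points)")
    diff = grid[:, None] - grid[None, :]
    return np.exp(-sigma * diff**2)


def fit_ridge_coefficients(y: np.ndarray, gram: np.ndarray, gamma: float) -> np.ndarray:
    """Solve the kernel ridge system (gamma*m*I + K) a = y for one curve.

    The system matrix is positive definite for any PSD Gram matrix and
    gamma > 0, so the solution is unique.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    y = np.asarray(y, dtype=float)
    gram = np.asarray(gram, dtype=float)
    m = gram.shape[0]
    if gram.shape != (m, m):
        raise ValueError("gram must be square")
    if y.shape != (m,):
        raise ValueError(f"curve has length {y.shape} but gram is {m}x{m}")
    system = gamma * m * np.eye(m) + gram
    return scipy.linalg.solve(system, y, assume_a="pos")


def _fit_ridge_matrix(values: np.ndarray, gram: np.ndarray, gamma: float) -> np.ndarray:
    """Ridge coefficients for all curves at once: rows of the returned n x m
    matrix solve (gamma*m*I + K) a = y_l."""
    m = gram.shape[0]
    system = gamma * m * np.eye(m) + gram
    return scipy.linalg.solve(system, values.T, assume_a="pos").T


def eigendecompose(gram: np.ndarray, rank_tolerance: float = 1e-12) -> GramFactorization:
    """Eigendecompose a symmetric PSD Gram matrix with a fixed sign convention.

    Eigenvalues are returned in non-increasing order.  Each eigenvector is
    flipped, if needed, so that its largest-magnitude component is positive
    (ties broken toward the first such component).  ``numerical_rank`` is the
    number of eigenvalues exceeding ``rank_tolerance`` times the largest.
    """
    gram = np.asarray(gram, dtype=float)
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ValueError("gram must be square")
    asym = np.max(np.abs(gram - gram.T))
    if asym > 1e-8 * max(1.0, np.max(np.abs(gram))):
        raise ValueError(f"gram is not symmetric (max asymmetry {asym:.3e})")
    sym = 0.5 * (gram + gram.T)
    w, v = np.linalg.eigh(sym)
    # stable descending sort keeps the natural order among tied eigenvalues
    order = np.argsort(-w, kind="stable")
    w = w[order]
    v = v[:, order]
    # sign convention: largest-|.| component positive, first index on ties
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            v[:, j] = -col
    lam1 = max(w[0], 0.0)
    rank = int(np.sum(w > rank_tolerance * lam1)) if lam1 > 0 else 0
    return GramFactorization(gram=sym, eigenvalues=w, eigenvectors=v, numerical_rank=rank)


def project_coefficients(
    a: np.ndarray,
    factorization: GramFactorization,
    d: int,
    scaling: str = "lambda",
) -> np.ndarray:
    """Project one curve's ridge coefficients onto the leading d eigenvectors.

    The coefficient in coordinate j is ``z_j = lambda_j * sum_i a_i v_{i,j}``;
    with ``scaling="sqrt_lambda"`` the factor is sqrt(lambda_j) instead (see
    the package methods note for why both conventions are exposed).
    """
    a = np.asarray(a, dtype=float)
    if not 1 <= d <= factorization.numerical_rank:
        raise ValueError(
            f"truncation d={d} must be between 1 and the numerical rank "
            f"{factorization.numerical_rank}"
        )
    proj = factorization.eigenvectors[:, :d].T @ a
    return _eigenvalue_scale(factorization.eigenvalues[:d], scaling) * proj


def _eigenvalue_scale(eigenvalues: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "lambda":
        return eigenvalues
    if scaling == "sqrt_lambda":
        return np.sqrt(np.clip(eigenvalues, 0.0, None))
    raise ValueError(f"unknown coefficient scaling {scaling!r}")


def _resolve_truncation(
    rule: Union[int, str, None],
    factorization: GramFactorization,
) -> int:
    """Turn a truncation rule into a concrete order d.

    ``rule`` may be an integer (fixed d), a string ``"ev:<fraction>"``
    selecting the smallest d whose cumulative eigenvalue fraction reaches the
    target, or None for the default ``"ev:0.999"``.
    """
    rank = factorization.numerical_rank
    if rank < 1:
        raise ValueError("Gram matrix has numerical rank 0; cannot truncate")
    if rule is None:
        rule = "ev:0.999"
    if isinstance(rule, numbers.Integral):
        d = int(rule)
        if not 1 <= d <= rank:
            raise ValueError(f"fixed truncation d={d} outside [1, rank={rank}]")
        return d
    if isinstance(rule, str) and rule.startswith("ev:"):
        frac = float(rule[3:])
        if not 0 < frac <= 1:
            raise ValueError(f"explained-variance fraction must be in (0, 1], got {frac}")
        lam = np.clip(factorization.eigenvalues[:rank], 0.0, None)
        cum = np.cumsum(lam) / np.sum(lam)
        d = int(np.searchsorted(cum, frac - 1e-15) + 1)
        return min(d, rank)
    raise ValueError(f"unrecognized truncation rule {rule!r}")


def represent_sample(
    curves: SampledCurveSet,
    spec: KernelSpec = KernelSpec(),
    truncation_rule: Union[int, str, None] = None,
    scaling: str = "lambda",
    rank_tolerance: float = 1e-12,
) -> CoefficientSet:
    """Full representation pipeline for a curve sample.

    Builds the shared Gram matrix on the common grid, eigendecomposes it,
    fits the ridge coefficients of every curve, and projects each onto the
    leading d eigenvectors (d resolved from ``truncation_rule``).
    """
    gram = gaussian_gram(curves.grid, spec.sigma)
    fact = eigendecompose(gram, rank_tolerance)
    d = _resolve_truncation(truncation_rule, fact)
    a = _fit_ridge_matrix(curves.values, gram, spec.gamma)
    scale = _eigenvalue_scale(fact.eigenvalues[:d], scaling)
    z = (a @ fact.eigenvectors[:, :d]) * scale[None, :]
    return CoefficientSet(
        coefficients=z,
        d=d,
        ridge_coefficients=a,
        kernel_spec=spec,
        eigenvalues_used=fact.eigenvalues[:d].copy(),
        grid=curves.grid.copy(),
    )


def reconstruct_curve(
    a: np.ndarray,
    grid: np.ndarray,
    eval_points: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Evaluate the fitted curve x~(t) = sum_i a_i K(t, t_i) at query times."""
    a = np.asarray(a, dtype=float)
    grid = np.asarray(grid, dtype=float)
    eval_points = np.asarray(eval_points, dtype=float)
    if a.shape != grid.shape:
        raise ValueError("ridge coefficients and grid must have the same length")
    cross = np.exp(-sigma * (eval_points[:, None] - grid[None, :]) ** 2)
    return cross @ a


def select_kernel_params_cv(
    curves: SampledCurveSet,
    sigma_grid: Sequence[float],
    gamma_grid: Sequence[float],
    n_folds: int = 10,
    seed: Optional[int] = None,
) -> KernelSpec:
    """Choose (sigma, gamma) by cross-validation over time points.

    Folds partition the grid points; for each candidate pair the curves are
    refitted on the training points of each fold and the mean squared
    prediction error on the held-out points, averaged over folds and curves,
    is the selection criterion.  Ties break toward larger gamma (stronger
    smoothing).
    """
    sigma_grid = list(sigma_grid)
    gamma_grid = list(gamma_grid)
    if not sigma_grid or not gamma_grid:
        raise ValueError("candidate grids must be non-empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    m = curves.n_points
    if m < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} grid points, got {m}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, n_folds)
    if any(f.size == 0 for f in folds):
        raise ValueError("cross-validation produced an empty fold")

    best: Optional[KernelSpec] = None
    best_err = np.inf
    for sigma in sigma_grid:
        gram = gaussian_gram(curves.grid, sigma)
        for gamma in gamma_grid:
            fold_errs = []
            for test_idx in folds:
                mask = np.ones(m, dtype=bool)
                mask[test_idx] = False
                k_tr = gram[np.ix_(mask, mask)]
                m_tr = int(mask.sum())
                system = gamma * m_tr * np.eye(m_tr) + k_tr
                a_tr = scipy.linalg.solve(system, curves.values[:, mask].T, assume_a="pos")
                pred = gram[np.ix_(test_idx, mask)] @ a_tr  # |test| x n
                resid = pred.T - curves.values[:, test_idx]
                fold_errs.append(np.mean(resid**2))
            err = float(np.mean(fold_errs))
            if err < best_err or (err == best_err and best is not None and gamma > best.gamma):
                best_err = err
                best = KernelSpec(sigma=sigma, gamma=gamma)
    return best


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class KernelCurveRepresenter(TransformerMixin, BaseEstimator):
    """Transformer mapping sampled curves to truncated kernel coefficients.

    Each row of the input matrix X is one curve observed on a common time
    grid; ``transform`` returns the n x d matrix of representation
    coefficients.  The eigenbasis and truncation order are determined by the
    kernel and the grid alone (the Gram matrix does not depend on the curve
    values), so ``fit`` only needs the grid; it accepts X to validate shapes
    and to conform to the scikit-learn API.

    Parameters
    ----------
    sigma : float, default=10.0
        Inverse squared width of the Gaussian kernel.
    gamma : float, default=0.15
        Ridge regularization weight.
    truncation : int or str, default="ev:0.999"
        Either a fixed order d or ``"ev:<fraction>"`` for the smallest d
        capturing that cumulative eigenvalue fraction.
    coefficient_scaling : {"lambda", "sqrt_lambda"}, default="lambda"
        Eigenvalue scaling applied to the projected coefficients.
    rank_tolerance : float, default=1e-12
        Relative eigenvalue threshold defining the numerical rank.

    Attributes
    ----------
    grid_ : ndarray of shape (m,)
        Time grid used at fit time.
    eigenvalues_ : ndarray of shape (m,)
        Gram eigenvalues, non-increasing.
    eigenvectors_ : ndarray of shape (m, m)
        Sign-fixed orthonormal eigenvectors.
    d_ : int
        Truncation order actually used.
    numerical_rank_ : int
        Numerical rank of the Gram matrix.
    """

    def __init__(
        self,
        sigma: float = 10.0,
        gamma: float = 0.15,
        truncation: Union[int, str] = "ev:0.999",
        coefficient_scaling: str = "lambda",
        rank_tolerance: float = 1e-12,
    ):
        self.sigma = sigma
        self.gamma = gamma
        self.truncation = truncation
        self.coefficient_scaling = coefficient_scaling
        self.rank_tolerance = rank_tolerance

    def fit(self, X, y=None, grid: Optional[np.ndarray] = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[1]
        if grid is None:
            grid = np.linspace(0.0, 1.0, m)
        grid = np.asarray(grid, dtype=float)
        if grid.size != m:
            raise ValueError(f"grid has {grid.size} points but curves have {m} samples")
        self.grid_ = grid
        self.gram_ = gaussian_gram(grid, self.sigma)
        fact = eigendecompose(self.gram_, self.rank_tolerance)
        self.eigenvalues_ = fact.eigenvalues
        self.eigenvectors_ = fact.eigenvectors
        self.numerical_rank_ = fact.numerical_rank
        self._factorization_ = fact
        self.d_ = _resolve_truncation(self.truncation, fact)
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "d_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"curves have {X.shape[1]} samples; representer was fitted on "
                f"{self.n_features_in_}-point grid"
            )
        a = _fit_ridge_matrix(X, self.gram_, self.gamma)
        scale = _eigenvalue_scale(self.eigenvalues_[: self.d_], self.coefficient_scaling)
        return (a @ self.eigenvectors_[:, : self.d_]) * scale[None, :]

    def ridge_coefficients(self, X) -> np.ndarray:
        """The n x m kernel-expansion coefficient matrix for the given curves."""
        check_is_fitted(self, "d_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _fit_ridge_matrix(X, self.gram_, self.gamma)
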