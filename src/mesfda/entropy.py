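"""Renyi entropy computations for the coefficient representation.

Three estimators are provided:

* closed-form Renyi alpha-entropy of a multivariate Gaussian model,
  including the Shannon limit at alpha = 1 (all values in nats);
* parametric plug-in entropy of a coefficient sample: fit a Gaussian
  (robustly or by sample moments) and evaluate the closed form;
* the exp-kNN local-entropy profile, h_i = exp(mean distance from z_i to
  its k nearest neighbours), which scores how far each point sits from the
  high-density bulk and drives the non-parametric detector.

The local-entropy estimator is free of alpha as printed; alpha is carried
in the profile purely as metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .representation import CoefficientSet, KernelSpec, SampledCurveSet, represent_sample

__all__ = [
    "GaussianModel",
    "EntropyValue",
    "LocalEntropyProfile",
    "renyi_entropy_gaussian",
    "parametric_entropy",
    "knn_local_entropy",
    "kernel_entropy",
    "default_neighbor_count",
]


@dataclass(frozen=True)
class GaussianModel:
    """A d-variate Gaussian N(mean, covariance) with SPD covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        d = mean.size
        if cov.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d}, got {cov.shape}")
        if np.max(np.abs(cov - cov.T)) > 1e-8 * max(1.0, np.max(np.abs(cov))):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class EntropyValue:
    """An entropy of order alpha, in nats."""

    alpha: float
    value: float


@dataclass(frozen=True)
class LocalEntropyProfile:
    """Per-point local-entropy values h_i = exp(mean kNN distance).

    ``h`` is >= 1 whenever distances are non-negative.  ``k`` records the
    neighbour count; ``alpha`` is nominal metadata only.
    """

    h: np.ndarray
    k: int
    alpha: float = 1.0

    @property
    def n(self) -> int:
        return self.h.size


def renyi_entropy_gaussian(model: GaussianModel, alpha: float) -> EntropyValue:
    """Closed-form Renyi alpha-entropy of a Gaussian, in nats.

    For N(mu, Sigma) in dimension d,

        H_alpha = (d/2) ln(2 pi) + (1/2) ln det Sigma + (d/2) ln(alpha)/(alpha - 1)

    for alpha != 1, with the Shannon limit H_1 = (1/2) ln((2 pi e)^d det Sigma)
    as alpha -> 1.  The value does not depend on the mean.  At alpha = 0 the
    entropy of an unbounded-support density is infinite.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    d = model.dim
    sign, logdet = np.linalg.slogdet(model.covariance)
    if sign <= 0:
        raise ValueError("covariance is numerically singular")
    if alpha == 0:
        return EntropyValue(alpha=0.0, value=np.inf)
    if alpha == 1:
        value = 0.5 * (d * np.log(2 * np.pi * np.e) + logdet)
    else:
        value = 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet + 0.5 * d * np.log(alpha) / (alpha - 1)
    return EntropyValue(alpha=float(alpha), value=float(value))


def _fit_gaussian(
    x: np.ndarray,
    robust: bool,
    support_fraction: float = 0.75,
    random_state: Optional[int] = None,
) -> GaussianModel:
    """Fit a Gaussian to sample rows, robustly (MCD) or by moments.

    With too few points for a meaningful robust subset (n < 2(d+1)) the
    robust path falls back to sample moments with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if np.allclose(x, x[0], atol=0.0):
        raise ValueError("all points identical: scatter matrix is zero")
    if robust and n < 2 * (d + 1):
        warnings.warn(
            f"n={n} too small for a robust fit in dimension {d}; "
            "falling back to sample moments",
            UserWarning,
        )
        robust = False
    if robust:
        from sklearn.covariance import MinCovDet

        if not n > d / support_fraction:
            raise ValueError(
                f"robust fit needs n > d/support_fraction = {d / support_fraction:.1f}, got n={n}"
            )
        with warnings.catch_warnings():
            # the MCD subset search emits chatty internal warnings on
            # near-degenerate coordinates; the fitted scatter is validated below
            warnings.filterwarnings("ignore", message="Determinant has increased")
            warnings.filterwarnings("ignore", message="The covariance matrix associated")
            mcd = MinCovDet(support_fraction=support_fraction, random_state=random_state).fit(x)
        mean, cov = mcd.location_, mcd.covariance_
    else:
        mean = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1).reshape(d, d)
    try:
        return GaussianModel(mean=mean, covariance=cov)
    except ValueError as exc:
        raise ValueError(
            "fitted scatter matrix is rank deficient; lower the truncation order d"
        ) from exc


def parametric_entropy(
    coefficients: Union[CoefficientSet, np.ndarray],
    alpha: float = 1.0,
    robust: bool = False,
    support_fraction: float = 0.75,
    random_state: Optional[int] = None,
) -> EntropyValue:
    """Plug-in Gaussian entropy of a coefficient sample.

    Fits N(mu, Sigma) to the rows (robust location/scatter when requested)
    and returns the closed-form Renyi entropy of the fit.
    """
    x = coefficients.coefficients if isinstance(coefficients, CoefficientSet) else coefficients
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if n <= d:
        raise ValueError(f"need n > d to estimate a covariance; got n={n}, d={d}")
    model = _fit_gaussian(x, robust=robust, support_fraction=support_fraction,
                          random_state=random_state)
    return renyi_entropy_gaussian(model, alpha)


def default_neighbor_count(n: int) -> int:
    """Default k = max(5, ceil(sqrt(n))), a standard bias-variance compromise."""
    return max(5, int(np.ceil(np.sqrt(n))))


def knn_local_entropy(
    coefficients: Union[CoefficientSet, np.ndarray],
    k: Optional[int] = None,
    neighbor_rule: str = "mean",
    alpha: float = 1.0,
    reference: Optional[np.ndarray] = None,
) -> LocalEntropyProfile:
    """exp-kNN local entropy of each coefficient row.

    For each point, h_i = exp(dbar_k) where dbar_k is either the mean of the
    Euclidean distances to the k nearest neighbours (``neighbor_rule="mean"``,
    the default) or the distance to the k-th neighbour alone
    (``neighbor_rule="kth"``).  Without a ``reference`` sample the neighbours
    are sought among the other rows of the input (self excluded); with one,
    distances are measured against the reference rows, self not excluded —
    the convention for scoring out-of-sample points against a training set.
    """
    z = coefficients.coefficients if isinstance(coefficients, CoefficientSet) else coefficients
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if neighbor_rule not in ("mean", "kth"):
        raise ValueError(f"neighbor_rule must be 'mean' or 'kth', got {neighbor_rule!r}")
    if reference is None:
        n = z.shape[0]
        if k is None:
            k = default_neighbor_count(n)
        if not 1 <= k <= n - 1:
            raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
        dist, _ = nn.kneighbors(z)
        # drop one zero per row (self or an identical duplicate — same multiset)
        dist = dist[:, 1:]
    else:
        reference = np.atleast_2d(np.asarray(reference, dtype=float))
        if k is None:
            k = default_neighbor_count(reference.shape[0])
        if not 1 <= k <= reference.shape[0]:
            raise ValueError(
                f"k must satisfy 1 <= k <= n_reference = {reference.shape[0]}, got {k}"
            )
        nn = NearestNeighbors(n_neighbors=k).fit(reference)
        dist, _ = nn.kneighbors(z)
    dbar = dist.mean(axis=1) if neighbor_rule == "mean" else dist[:, -1]
    return LocalEntropyProfile(h=np.exp(dbar), k=int(k), alpha=float(alpha))


def kernel_entropy(
    curves: SampledCurveSet,
    spec: KernelSpec = KernelSpec(),
    alpha: float = 1.0,
    truncation_rule=None,
    robust: bool = False,
    scaling: str = "lambda",
    support_fraction: float = 0.75,
    random_state: Optional[int] = None,
) -> EntropyValue:
    """End-to-end kernel entropy of a curve sample.

    Composition of the representation pipeline with the parametric plug-in
    entropy: the estimated entropy of the d-truncated coefficient vector.
    """
    coeffs = represent_sample(curves, spec, truncation_rule=truncation_rule, scaling=scaling)
    return parametric_entropy(
        coeffs, alpha=alpha, robust=robust,
        support_fraction=support_fraction, random_state=random_state,
    )
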