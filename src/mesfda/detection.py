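"""Minimum-entropy-set estimation and functional anomaly detection.

A nu-minimum-entropy set is the Borel set of probability mass >= 1 - nu that
minimizes set-restricted entropy; it coincides with a high-density set, so
curves whose representation coefficients fall outside it are anomalies.  Two
estimators are provided:

* **Parametric (PA)** — fit a robust Gaussian to the coefficient rows and
  threshold the squared Mahalanobis distance, either at the chi-square
  (1 - nu) quantile with d degrees of freedom or at the empirical (1 - nu)
  quantile of the training distances (the choice when nu is known a priori).

* **Non-parametric (NPA)** — threshold the exp-kNN local entropy h_i at
  rho*, the solution of the concave piecewise-linear program

      max_{rho, eps}  (1 - nu) rho - (1/n) sum_i eps_i
      s.t.            h_i >= rho - eps_i,   eps_i >= 0,

  whose smallest maximizer is the ceil((1 - nu) n)-th smallest h value.  The
  decision function is D(z) = sign(rho* - h(z)) with sign(0) := +1, so on a
  training sample with distinct h values and integer (1 - nu) n exactly that
  fraction is classified as normal.

Both are exposed as scikit-learn outlier estimators (+1 = inlier, -1 =
anomaly) plus thin functional wrappers, and composed end-to-end with the
curve representation step in :func:`detect_anomalies`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.linalg
from scipy.stats import chi2
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from . import __version__ as _pkg_version
from .entropy import (
    GaussianModel,
    LocalEntropyProfile,
    _fit_gaussian,
    default_neighbor_count,
    knn_local_entropy,
)
from .representation import KernelSpec, SampledCurveSet, represent_sample

__all__ = [
    "ParametricMES",
    "NonParametricMES",
    "DetectionResult",
    "robust_location_scatter",
    "fit_parametric_mes",
    "classify_parametric",
    "fit_nonparametric_mes",
    "classify_nonparametric",
    "detect_anomalies",
    "ParametricMESDetector",
    "NonParametricMESDetector",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricMES:
    """Fitted parametric minimum-entropy set: Mahalanobis ellipsoid."""

    model: GaussianModel
    nu: float
    threshold: float
    threshold_mode: str


@dataclass(frozen=True)
class NonParametricMES:
    """Fitted non-parametric minimum-entropy set: local-entropy threshold."""

    rho_star: float
    nu: float
    k: int
    training_profile: LocalEntropyProfile
    training_points: np.ndarray = field(repr=False)
    neighbor_rule: str = "mean"


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a detection run.

    ``scores`` are per-curve abnormality scores (squared Mahalanobis
    distance for PA, local entropy h for NPA); ``labels`` are +1 for curves
    inside the minimum-entropy set (normal), -1 outside (anomalous);
    ``flagged`` lists the anomalous indices.
    """

    scores: np.ndarray
    labels: np.ndarray
    flagged: np.ndarray
    method: str
    settings: dict

    def __post_init__(self):
        if not np.array_equal(np.flatnonzero(self.labels == -1), np.sort(self.flagged)):
            raise ValueError("flagged indices inconsistent with labels")


def _order_statistic_quantile(values: np.ndarray, nu: float) -> float:
    """The (1-nu) empirical quantile: the ceil((1-nu)*n)-th smallest value."""
    n = values.size
    r = int(np.ceil((1.0 - nu) * n))
    r = min(max(r, 1), n)
    return float(np.sort(values)[r - 1])


def _check_nu(nu: float) -> float:
    if not 0.0 < nu < 1.0:
        raise ValueError(f"contamination nu must be in (0, 1), got {nu}")
    return float(nu)


# ---------------------------------------------------------------------------
# Parametric approach
# ---------------------------------------------------------------------------

def robust_location_scatter(
    coefficients: np.ndarray,
    support_fraction: float = 0.75,
    seed: Optional[int] = None,
) -> GaussianModel:
    """Robust mean vector and covariance matrix of the coefficient rows.

    Minimum-covariance-determinant estimate (with the usual consistency
    correction and reweighting step); deterministic given ``seed``.  Falls
    back to sample moments with a warning when n < 2(d+1).
    """
    return _fit_gaussian(
        coefficients, robust=True, support_fraction=support_fraction, random_state=seed
    )


def _mahalanobis_sq(x: np.ndarray, model: GaussianModel) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.dim:
        raise ValueError(f"points have dimension {x.shape[1]}, model has {model.dim}")
    delta = x - model.mean
    sol = scipy.linalg.solve(model.covariance, delta.T, assume_a="pos")
    return np.einsum("ij,ji->i", delta, sol)


def fit_parametric_mes(
    coefficients: np.ndarray,
    nu: float,
    threshold_mode: str = "chi2",
    support_fraction: float = 0.75,
    seed: Optional[int] = None,
    robust: bool = True,
) -> ParametricMES:
    """Fit the robust-Gaussian ellipsoidal minimum-entropy set.

    ``threshold_mode="chi2"`` sets the cutoff at the chi-square (1 - nu)
    quantile with d degrees of freedom; ``"empirical"`` at the (1 - nu)
    empirical quantile of the training squared Mahalanobis distances (used
    when the contamination fraction is known a priori).
    """
    nu = _check_nu(nu)
    x = np.atleast_2d(np.asarray(coefficients, dtype=float))
    model = _fit_gaussian(x, robust=robust, support_fraction=support_fraction,
                          random_state=seed)
    if threshold_mode == "chi2":
        threshold = float(chi2.ppf(1.0 - nu, df=model.dim))
    elif threshold_mode == "empirical":
        threshold = _order_statistic_quantile(_mahalanobis_sq(x, model), nu)
    else:
        raise ValueError(f"threshold_mode must be 'chi2' or 'empirical', got {threshold_mode!r}")
    return ParametricMES(model=model, nu=nu, threshold=threshold, threshold_mode=threshold_mode)


def classify_parametric(mes: ParametricMES, coefficients: np.ndarray) -> DetectionResult:
    """Label points by the fitted ellipsoid; boundary points are inside."""
    scores = _mahalanobis_sq(coefficients, mes.model)
    labels = np.where(scores <= mes.threshold, 1, -1)
    return DetectionResult(
        scores=scores,
        labels=labels,
        flagged=np.flatnonzero(labels == -1),
        method="PA",
        settings={"nu": mes.nu, "threshold": mes.threshold,
                  "threshold_mode": mes.threshold_mode, "d": mes.model.dim},
    )


# ---------------------------------------------------------------------------
# Non-parametric approach
# ---------------------------------------------------------------------------

def fit_nonparametric_mes(
    coefficients: np.ndarray,
    nu: float,
    k: Optional[int] = None,
    neighbor_rule: str = "mean",
) -> NonParametricMES:
    """Fit the local-entropy threshold rho*.

    rho* is the smallest maximizer of the concave piecewise-linear objective
    (1-nu) rho - (1/n) sum max(0, rho - h_i), which is the
    ceil((1-nu) n)-th smallest training h value; this closed form solves the
    linear program exactly.
    """
    nu = _check_nu(nu)
    x = np.atleast_2d(np.asarray(coefficients, dtype=float))
    profile = knn_local_entropy(x, k=k, neighbor_rule=neighbor_rule)
    rho_star = _order_statistic_quantile(profile.h, nu)
    return NonParametricMES(
        rho_star=rho_star,
        nu=nu,
        k=profile.k,
        training_profile=profile,
        training_points=x,
        neighbor_rule=neighbor_rule,
    )


def classify_nonparametric(mes: NonParametricMES, profile: LocalEntropyProfile) -> DetectionResult:
    """Apply the decision rule D = sign(rho* - h), with sign(0) := +1."""
    if profile.k != mes.k:
        raise ValueError(
            f"profile was computed with k={profile.k} but the fitted set uses k={mes.k}"
        )
    labels = np.where(profile.h <= mes.rho_star, 1, -1)
    return DetectionResult(
        scores=profile.h.copy(),
        labels=labels,
        flagged=np.flatnonzero(labels == -1),
        method="NPA",
        settings={"nu": mes.nu, "rho_star": mes.rho_star, "k": mes.k,
                  "neighbor_rule": mes.neighbor_rule},
    )


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class ParametricMESDetector(OutlierMixin, BaseEstimator):
    """Robust-Gaussian ellipsoidal anomaly detector on coefficient vectors.

    Fits a robust location/scatter to the rows of X and classifies points by
    their squared Mahalanobis distance against a (1 - nu) threshold.
    ``predict`` returns +1 for inliers, -1 for anomalies (boundary inside).

    Parameters
    ----------
    nu : float, default=0.1
        Assumed contamination fraction.
    threshold_mode : {"chi2", "empirical"}, default="chi2"
        Chi-square quantile, or empirical quantile of training distances.
    robust : bool, default=True
        Robust MCD fit (True) or plain sample moments (False).
    support_fraction : float, default=0.75
        Fraction of points supporting the robust scatter.
    random_state : int, optional
        Seed for the robust-subset search.
    """

    def __init__(self, nu: float = 0.1, threshold_mode: str = "chi2",
                 robust: bool = True, support_fraction: float = 0.75,
                 random_state: Optional[int] = None):
        self.nu = nu
        self.threshold_mode = threshold_mode
        self.robust = robust
        self.support_fraction = support_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        mes = fit_parametric_mes(
            X, nu=self.nu, threshold_mode=self.threshold_mode,
            support_fraction=self.support_fraction, seed=self.random_state,
            robust=self.robust,
        )
        self.mes_ = mes
        self.location_ = mes.model.mean
        self.covariance_ = mes.model.covariance
        self.threshold_ = mes.threshold
        self.n_features_in_ = mes.model.dim
        return self

    def mahalanobis(self, X) -> np.ndarray:
        check_is_fitted(self, "mes_")
        return _mahalanobis_sq(X, self.mes_.model)

    def score_samples(self, X) -> np.ndarray:
        """Negative squared Mahalanobis distance (higher = more normal)."""
        return -self.mahalanobis(X)

    def decision_function(self, X) -> np.ndarray:
        return self.threshold_ - self.mahalanobis(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


class NonParametricMESDetector(OutlierMixin, BaseEstimator):
    """Local-entropy (exp-kNN) anomaly detector on coefficient vectors.

    Fit computes the in-sample local-entropy profile (self excluded) and the
    threshold rho*; ``fit_predict`` labels the training sample from that
    profile.  For new points, ``predict`` measures local entropy against the
    training rows (self not excluded).

    Parameters
    ----------
    nu : float, default=0.1
        Assumed contamination fraction.
    k : int, optional
        Neighbour count; defaults to max(5, ceil(sqrt(n))) at fit time.
    neighbor_rule : {"mean", "kth"}, default="mean"
        Average distance over the k nearest neighbours, or distance to the
        k-th neighbour alone.
    """

    def __init__(self, nu: float = 0.1, k: Optional[int] = None,
                 neighbor_rule: str = "mean"):
        self.nu = nu
        self.k = k
        self.neighbor_rule = neighbor_rule

    def fit(self, X, y=None):
        mes = fit_nonparametric_mes(X, nu=self.nu, k=self.k,
                                    neighbor_rule=self.neighbor_rule)
        self.mes_ = mes
        self.k_ = mes.k
        self.rho_star_ = mes.rho_star
        self.local_entropy_ = mes.training_profile.h
        self.labels_ = np.where(self.local_entropy_ <= mes.rho_star, 1, -1)
        self.n_features_in_ = mes.training_points.shape[1]
        return self

    def _local_entropy(self, X) -> np.ndarray:
        check_is_fitted(self, "mes_")
        profile = knn_local_entropy(
            X, k=self.k_, neighbor_rule=self.neighbor_rule,
            reference=self.mes_.training_points,
        )
        return profile.h

    def score_samples(self, X) -> np.ndarray:
        """Negative local entropy (higher = more normal)."""
        return -self._local_entropy(X)

    def decision_function(self, X) -> np.ndarray:
        return self.rho_star_ - self._local_entropy(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def fit_predict(self, X, y=None):
        """Training-sample labels from the self-excluded profile."""
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# End-to-end composition
# ---------------------------------------------------------------------------

def detect_anomalies(
    curves: SampledCurveSet,
    method: str = "pa",
    nu: float = 0.1,
    spec: KernelSpec = KernelSpec(),
    truncation_rule=None,
    k: Optional[int] = None,
    threshold_mode: str = "empirical",
    support_fraction: float = 0.75,
    seed: Optional[int] = None,
    scaling: str = "lambda",
) -> DetectionResult:
    """Represent a curve sample and flag anomalies with PA or NPA.

    The curves are mapped to coefficient vectors (shared Gram factorization)
    and the chosen minimum-entropy-set detector is fitted and applied
    in-sample.  Deterministic given ``seed``.
    """
    if curves.n_curves < 2:
        raise ValueError("detection needs at least 2 curves")
    method_lc = method.lower()
    if method_lc not in ("pa", "npa"):
        raise ValueError(f"method must be 'pa' or 'npa', got {method!r}")
    coeffs = represent_sample(curves, spec, truncation_rule=truncation_rule, scaling=scaling)
    z = coeffs.coefficients
    if method_lc == "pa":
        mes = fit_parametric_mes(z, nu=nu, threshold_mode=threshold_mode,
                                 support_fraction=support_fraction, seed=seed)
        result = classify_parametric(mes, z)
    else:
        mes = fit_nonparametric_mes(z, nu=nu, k=k)
        result = classify_nonparametric(mes, mes.training_profile)
    settings = dict(result.settings)
    settings.update({
        "method": method_lc, "sigma": spec.sigma, "gamma": spec.gamma,
        "d": coeffs.d, "n": curves.n_curves, "m": curves.n_points,
        "seed": seed, "scaling": scaling, "version": _pkg_version,
    })
    return DetectionResult(scores=result.scores, labels=result.labels,
                           flagged=result.flagged, method=result.method,
                           settings=settings)
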