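"""Two-class linear discriminant analysis with shrinkage regularization.

The classifier is the linear rule ``dval = w^T x + b`` with
``class = sign(dval)`` (ties map to +1). The weight vector is the
regularized Fisher discriminant

    w = Sigma_hat^{-1} (mu_+ - mu_-),    b = -w^T (mu_+ + mu_-) / 2,

with equal class priors and a convex shrinkage of the pooled within-class
covariance toward a scaled identity,

    Sigma_hat = (1 - lambda) Sigma_pooled + lambda nu I,

where ``nu`` is the mean pooled variance (trace / dim). With ~10^2 channels
and a few hundred training trials the pooled covariance is ill-conditioned or
singular; the shrinkage intensity defaults to the analytic Ledoit-Wolf
estimate computed on the within-class-centered training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LDAModel", "fit_lda", "lda_predict", "ledoit_wolf_lambda"]


@dataclass
class LDAModel:
    """Fitted linear discriminant: weights, bias, shrinkage used, class means."""

    w: np.ndarray
    b: float
    shrinkage: float
    class_means: np.ndarray  # 2 x n_features, rows ordered (+1, -1)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("non-finite LDA parameters")


def ledoit_wolf_lambda(Z: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity for already-centered rows.

    ``Z`` holds the within-class-centered training samples. Writing
    ``S = Z^T Z / n`` and ``nu = tr(S)/d``, the intensity is

        lambda = [ (1/n^2) sum_i || z_i z_i^T - S ||_F^2 ] / || S - nu I ||_F^2

    clipped to [0, 1]; the numerator reduces to
    ``(sum_i ||z_i||^4 - n ||S||_F^2) / n^2``.
    """
    Z = np.asarray(Z, dtype=float)
    n, d = Z.shape
    S = Z.T @ Z / n
    nu = np.trace(S) / d
    delta = ((S - nu * np.eye(d)) ** 2).sum()
    if delta <= 0:
        return 0.0
    beta = ((Z**2).sum(axis=1) ** 2).sum() - n * (S**2).sum()
    return float(np.clip(beta / (n**2 * delta), 0.0, 1.0))


def fit_lda(X: np.ndarray, y: np.ndarray,
            shrinkage: float | str = "ledoit") -> LDAModel:
    """Fit the shrinkage LDA at a single time point.

    Parameters
    ----------
    X : ndarray, shape (n_trials, n_channels)
        Single-time-point channel patterns.
    y : ndarray
        Labels in {+1, -1}; both classes must be present.
    shrinkage : float in [0, 1] or "ledoit"
        Fixed shrinkage intensity, or the analytic Ledoit-Wolf estimate
        computed on the within-class-centered training data.

    Notes
    -----
    The pooled covariance is the maximum-likelihood (1/n) estimate. With
    ``shrinkage=0`` a singular pooled covariance is inverted in the
    least-squares (pseudo-inverse) sense.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_trials, n_channels) matching y")
    if not np.isin(y, [-1, 1]).all():
        raise ValueError("labels must be +1 or -1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training data")

    n, d = X.shape
    mu_p = X[y == 1].mean(axis=0)
    mu_m = X[y == -1].mean(axis=0)
    Z = X - np.where(y[:, None] == 1, mu_p, mu_m)
    S = Z.T @ Z / n

    lam = ledoit_wolf_lambda(Z) if shrinkage == "ledoit" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage must lie in [0, 1], got {lam}")
    nu = np.trace(S) / d
    sigma = (1 - lam) * S + lam * nu * np.eye(d)

    diff = mu_p - mu_m
    try:
        w = np.linalg.solve(sigma, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(sigma) @ diff
    if not np.all(np.isfinite(w)):  # singular unregularized covariance
        w = np.linalg.pinv(sigma) @ diff
    b = float(-w @ (mu_p + mu_m) / 2)
    return LDAModel(w=w, b=b, shrinkage=lam, class_means=np.stack([mu_p, mu_m]))


def lda_predict(model: LDAModel, x: np.ndarray):
    """Decision values and predicted classes for one or many patterns.

    Returns ``(predicted_class, dval)`` with ``dval = w^T x + b`` and
    ``class = +1`` if ``dval >= 0`` else ``-1`` (a decision value of exactly
    zero is assigned to the first class, near = +1). Scalar in, scalar out.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.w):
        raise ValueError(
            f"pattern has {X.shape[1]} channels, model expects {len(model.w)}")
    dval = X @ model.w + model.b
    cls = np.where(dval >= 0, 1, -1)
    if single:
        return int(cls[0]), float(dval[0])
    return cls, dval
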