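"""Weighted logistic regression via iteratively reweighted least squares.

One small solver backs every model in the pipeline: the treatment model
behind the IP treatment weights, the per-arm censoring models behind the
IP censoring weights, and the pooled logistic outcome model. The response
may be a 0/1 indicator or an event *proportion* in [0, 1] paired with a
"number of trials" weight, which lets the outcome model be fitted on
person-period data aggregated by (strategy, interval) — identical
estimates at a fraction of the cost, which matters inside the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import FitError, SeparationError

__all__ = ["LogisticFit", "fit_weighted_logistic"]

_EPS = 1e-12


@dataclass
class LogisticFit:
    """Result of a weighted logistic maximum-likelihood fit."""

    params: np.ndarray
    converged: bool
    n_iter: int
    deviance: float
    column_names: tuple[str, ...] | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.params)

    def coef(self, name: str) -> float:
        if self.column_names is None:
            raise KeyError("fit carries no column names")
        return float(self.params[self.column_names.index(name)])


def _deviance(y, mu, w):
    # binomial deviance up to a constant; supports fractional y
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = w * (y * np.log(np.clip(mu, _EPS, None))
                  + (1.0 - y) * np.log(np.clip(1.0 - mu, _EPS, None)))
    return -2.0 * float(np.sum(ll))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    column_names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    on_nonconvergence: str = "raise",
) -> LogisticFit:
    """Fit logit(E[y]) = X beta by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) design matrix (caller supplies the intercept column).
    y : (n,) response in [0, 1]; fractional values are event proportions.
    weights : (n,) non-negative prior/frequency weights (default all 1).
    on_nonconvergence : "raise" or "return"; bootstrap replicates use
        "return" and count the failure instead of aborting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = w > 0
    if not np.all(keep):
        X, y, w = X[keep], y[keep], w[keep]

    beta = np.zeros(p)
    # warm start for a leading constant column
    if X.shape[0] and np.all(X[:, 0] == 1.0):
        ybar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
        beta[0] = np.log(ybar / (1.0 - ybar))

    mu = expit(X @ beta)
    dev = _deviance(y, mu, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wt = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        H = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving on deviance increase
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            mu_c = expit(X @ cand)
            dev_c = _deviance(y, mu_c, w)
            if dev_c <= dev + 1e-10:
                break
            factor *= 0.5
        else:
            cand, mu_c, dev_c = beta, mu, dev
        delta = float(np.max(np.abs(cand - beta))) if p else 0.0
        dev_drop = dev - dev_c
        beta, mu, dev = cand, mu_c, dev_c
        # parameter or deviance convergence: under quasi-separation some
        # coefficients drift to +/-inf while the likelihood plateaus and
        # the fitted probabilities (all that the weights use) are stable
        if delta < tol or abs(dev) < 1e-12 or dev_drop < 1e-9 * (1.0 + abs(dev)):
            converged = True
            break

    if not np.all(np.isfinite(beta)):
        raise FitError("logistic fit produced non-finite coefficients")
    if not converged and on_nonconvergence == "raise":
        raise FitError(f"logistic fit did not converge in {max_iter} iterations")
    return LogisticFit(params=beta, converged=converged, n_iter=it,
                       deviance=dev, column_names=column_names)


def check_overlap(p_hat: np.ndarray, labels=None, eps: float = 1e-10) -> None:
    """Raise :class:`SeparationError` when fitted probabilities hit 0/1.

    `labels` (optional) annotates the offending rows in the message.
    """
    bad = (p_hat < eps) | (p_hat > 1.0 - eps)
    if np.any(bad):
        idx = np.flatnonzero(bad)
        shown = idx[:10].tolist()
        extra = "" if labels is None else f" (e.g. {[labels[i] for i in shown]})"
        raise SeparationError(
            f"non-overlap: {idx.size} fitted probabilities are 0 or 1 to machine "
            f"precision at rows {shown}{extra}"
        )
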