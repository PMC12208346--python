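"""Model comparison: PSIS-LOO elpd, delta-elpd ranking, Bayesian stacking.

Candidate models are compared on out-of-sample predictive accuracy via the
expected log pointwise predictive density (elpd), estimated by leave-one-out
cross-validation with Pareto-smoothed importance sampling (PSIS).  Stacking
finds the simplex-constrained mixture of the models' predictive
distributions maximising the pooled LOO log score.  Following common
practice, models within 2 elpd of the best are "strong" and models more
than 10 behind are "poor".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from arviz.stats import psislw
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "LooEstimate",
    "StackingResult",
    "psis_loo",
    "delta_elpd",
    "stacking_weights",
    "classify_models",
    "PARETO_K_WARN",
]

PARETO_K_WARN = 0.7


@dataclass
class LooEstimate:
    """PSIS-LOO estimate: total elpd, its SE, and pointwise contributions."""

    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n(self) -> int:
        return self.pointwise.size


def psis_loo(pointwise_loglik: np.ndarray) -> LooEstimate:
    """PSIS-LOO from an (S, N) pointwise log-likelihood matrix.

    Importance ratios 1/p(y_i | theta_s) are smoothed per observation by
    fitting a generalised Pareto tail to the largest ratios; elpd_i is the
    log of the smoothed-weighted mean predictive density.  Observations with
    Pareto k above 0.7 trigger a logged reliability warning.
    """
    ll = np.asarray(pointwise_loglik, float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    s, n = ll.shape
    if s < 100:
        raise ValueError(f"need >= 100 draws for PSIS-LOO, got {s}")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite values")
    lw, k = psislw(-ll.T)  # arviz wants (..., n_samples); returns normalised lw
    lw, k = np.asarray(lw), np.asarray(k)
    pointwise = logsumexp(lw + ll.T, axis=1)
    n_bad = int((k > PARETO_K_WARN).sum())
    if n_bad:
        logger.warning(
            "PSIS-LOO: %d of %d observations have Pareto k > %.1f; "
            "elpd estimate may be unreliable",
            n_bad,
            n,
            PARETO_K_WARN,
        )
    return LooEstimate(
        elpd=float(pointwise.sum()),
        se=float(np.sqrt(n * pointwise.var())),
        pointwise=pointwise,
        pareto_k=k,
    )


def delta_elpd(loos: list[LooEstimate]) -> np.ndarray:
    """elpd differences from the best model: best gets 0, others <= 0."""
    if not loos:
        raise ValueError("need at least one LOO estimate")
    ns = {loo.n for loo in loos}
    if len(ns) != 1:
        raise ValueError(f"models were evaluated on different N: {sorted(ns)}")
    elpds = np.array([loo.elpd for loo in loos])
    return elpds - elpds.max()


@dataclass
class StackingResult:
    """Simplex weights over candidate models."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("stacking weights must lie on the simplex")
        self.weights = np.clip(w, 0.0, None)


def stacking_weights(
    pointwise: np.ndarray, method: str = "log", y: np.ndarray | None = None
) -> StackingResult:
    """Optimal model weights on the simplex.

    ``pointwise`` is (N, K): per-observation LOO elpd contributions
    (``method="log"``, the default log-score stacking of predictive
    distributions) or LOO predictive means (``method="mse"``, which needs
    the observed ``y`` and minimises squared error of the weighted mean).

    The optimisation is deterministic: softmax parametrisation from a fixed
    uniform start with a tiny ridge, so exchangeable models receive equal
    weights (two identical models give (0.5, 0.5)).
    """
    lpd = np.asarray(pointwise, float)
    if lpd.ndim != 2 or lpd.shape[1] < 2:
        raise ValueError("pointwise matrix must be (N, K) with K >= 2")
    n, k = lpd.shape

    if method == "log":
        shift = lpd.max(axis=1, keepdims=True)
        dens = np.exp(lpd - shift)  # rescaled per-row; argmax of objective unchanged

        def objective(alpha):
            w = softmax(alpha)
            mix = dens @ w
            obj = -np.sum(np.log(mix)) + 1e-9 * alpha @ alpha
            grad_w = -(dens / mix[:, None]).sum(axis=0)
            grad = w * (grad_w - w @ grad_w) + 2e-9 * alpha
            return obj, grad

    elif method == "mse":
        if y is None:
            raise ValueError("method='mse' requires the observed outcome y")
        y = np.asarray(y, float)

        def objective(alpha):
            w = softmax(alpha)
            r = lpd @ w - y
            obj = r @ r + 1e-9 * alpha @ alpha
            grad_w = 2.0 * lpd.T @ r
            grad = w * (grad_w - w @ grad_w) + 2e-9 * alpha
            return obj, grad

    else:
        raise ValueError("method must be 'log' or 'mse'")

    res = minimize(objective, np.zeros(k), jac=True, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"stacking optimisation failed: {res.message}")
    w = softmax(res.x)
    return StackingResult(weights=w / w.sum())


def classify_models(deltas: np.ndarray) -> list[str]:
    """Label each model strong (delta > -2), poor (delta < -10) or
    intermediate from its elpd difference to the best model."""
    deltas = np.asarray(deltas, float)
    if np.any(deltas > 1e-9):
        raise ValueError("delta elpd values must be <= 0")
    labels = []
    for d in deltas:
        if d > -2.0:
            labels.append("strong")
        elif d < -10.0:
            labels.append("poor")
        else:
            labels.append("intermediate")
    return labels
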