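"""The R statistic: heavy-tailedness of a task's initial-estimate distribution.

R is the normalized relative log-likelihood of a log-normal versus a normal
fit to the pooled initial estimates of a task,

    R = 1 / (1 + exp(L_N - L_LN)) = softmax over the two models,

where L_LN and L_N are the total log-likelihoods at the maximum-likelihood
estimates.  R = 0 says the estimates are decisively thin-tailed (normal fits
better), R = 1 decisively heavy-tailed (log-normal fits better), R = 0.5
indifferent.  Both families have two free parameters, so no complexity
penalty is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DegenerateFitError",
    "FitResult",
    "TaskFeature",
    "fit_normal_mle",
    "fit_lognormal_mle",
    "compute_R",
]


class DegenerateFitError(ValueError):
    """Raised when a maximum-likelihood fit is degenerate (e.g. zero variance)."""


@dataclass(frozen=True)
class FitResult:
    family: str  # "normal" or "lognormal"
    param1: float  # mean (normal) or meanlog (lognormal)
    param2: float  # sd / sdlog, MLE with divisor n
    loglik: float  # total log-likelihood at the MLE
    n_obs: int


@dataclass(frozen=True)
class TaskFeature:
    """Heavy-tailedness feature of one task's pooled initial estimates."""

    R: float
    loglik_lognormal: float
    loglik_normal: float
    n_obs: int
    task_id: object = None


def _check(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("observations must be finite")
    return x


def _normal_mle(x: np.ndarray) -> tuple[float, float, float]:
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        raise DegenerateFitError("constant sample: normal MLE is degenerate")
    n = x.size
    # total log-likelihood at the MLE: -(n/2) (log 2pi + 2 log sd + 1)
    loglik = -0.5 * n * (np.log(2.0 * np.pi) + 2.0 * np.log(sd) + 1.0)
    return mean, sd, float(loglik)


def fit_normal_mle(x) -> FitResult:
    """Normal maximum-likelihood fit (sd with divisor n)."""
    x = _check(x)
    mean, sd, loglik = _normal_mle(x)
    return FitResult("normal", mean, sd, loglik, x.size)


def fit_lognormal_mle(x) -> FitResult:
    """Log-normal maximum-likelihood fit: normal MLE on log(x).

    The total log-likelihood includes the change-of-variables Jacobian,
    ``L_LN(x) = L_N(log x) - sum(log x)``.
    """
    x = _check(x)
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires strictly positive data")
    logx = np.log(x)
    meanlog, sdlog, loglik_logspace = _normal_mle(logx)
    loglik = loglik_logspace - float(logx.sum())
    return FitResult("lognormal", meanlog, sdlog, loglik, x.size)


def compute_R(x, task_id=None) -> TaskFeature:
    """R statistic for one task's pooled positive initial estimates.

    Computed overflow-safely as ``expit(L_LN - L_N)`` on the *total*
    log-likelihoods; saturates to 0/1 for decisive samples.
    """
    ln = fit_lognormal_mle(x)
    no = fit_normal_mle(np.asarray(x, dtype=float).ravel())
    r = float(expit(ln.loglik - no.loglik))
    return TaskFeature(
        R=r,
        loglik_lognormal=ln.loglik,
        loglik_normal=no.loglik,
        n_obs=ln.n_obs,
        task_id=task_id,
    )
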