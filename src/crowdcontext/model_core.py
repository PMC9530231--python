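"""Generative model of initial estimates and the centralized aggregation operator.

A group of ``n`` agents independently estimates an unknown positive quantity
``theta``.  Their initial estimates are i.i.d. draws from an *estimation
context*: a distribution family parametrized by the truth ``theta``, a
systematic (log-scale) bias ``mu`` and a dispersion/shape ``sigma``.  Social
influence is summarized by a single centralization parameter ``omega`` that
interpolates between equal-voice averaging (``omega = 0``) and a dictatorial
aggregate dominated by one agent (``omega = 1``):

    a_n(omega) = omega * a_1 + (1 - omega) * mean(a)

where agent 1 is, by exchangeability of the i.i.d. draws, the central agent.
On the star/lattice/complete network class this ``omega`` coincides with
Freeman's degree centralization.

Parameterization of the families is multiplicative, ``a = theta * exp(mu +
noise)``, so that the comparison statistics downstream are invariant to the
scale of the truth; the Pareto tail index maps as ``alpha = 1/sigma`` so that
larger ``sigma`` always means a heavier tail.  The normal family is the one
additive exception (``a = theta + mu + sigma Z``) and is truncated to the
positive half-line by resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "EstimationContext",
    "InfluenceWeights",
    "interpolation_weights",
    "freeman_centralization",
    "collective_estimate",
    "sample_initial_estimates",
    "sample_estimate_matrix",
    "context_distribution",
]

_WEIGHT_TOL = 1e-12


class Family(str, Enum):
    """Distribution family of the initial estimates."""

    LOGNORMAL = "lognormal"
    PARETO = "pareto"
    LOGLAPLACE = "loglaplace"
    NORMAL = "normal"


@dataclass(frozen=True)
class EstimationContext:
    """Distribution of a population's initial estimates for one task.

    Parameters
    ----------
    family
        One of ``lognormal``, ``pareto``, ``loglaplace``, ``normal``.
    theta
        The unknown positive truth being estimated.
    mu
        Systematic bias: location offset on the log scale (multiplicative
        families) or on the natural scale (normal family).
    sigma
        Dispersion / shape.  For the Pareto family the tail index is
        ``1/sigma``, so larger ``sigma`` means a heavier tail.
    """

    family: Family
    theta: float
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class InfluenceWeights:
    """Ordered influence weights ``w1 >= ... >= wn`` and their centralization."""

    w: np.ndarray
    omega: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("weight vector must be 1-d with length >= 2")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if np.any(np.diff(w) > _WEIGHT_TOL):
            raise ValueError("weights must be non-increasing")
        omega = freeman_centralization(w)
        if self.omega is None:
            object.__setattr__(self, "omega", omega)
        elif abs(self.omega - omega) > 1e-9:
            raise ValueError(
                f"declared omega {self.omega} inconsistent with weights ({omega})"
            )

    @property
    def n(self) -> int:
        return self.w.size


def interpolation_weights(n: int, omega: float) -> InfluenceWeights:
    """Weight vector of the omega-indexed influence class.

    The central agent receives ``omega + (1 - omega)/n`` and every other
    agent ``(1 - omega)/n``, interpolating between equal voice (``omega=0``)
    and a dictator (``omega=1``).
    """
    if n < 2:
        raise ValueError(f"need at least 2 agents, got n={n}")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    w = np.full(n, (1.0 - omega) / n)
    w[0] += omega
    return InfluenceWeights(w=w, omega=omega)


def freeman_centralization(w: np.ndarray) -> float:
    """Centralization ``(n * max(w) - 1) / (n - 1)`` of a weight vector.

    Inverse of :func:`interpolation_weights` on its image; 0 for equal
    weights, 1 for a dictator.
    """
    w = np.asarray(w, dtype=float)
    n = w.size
    if n < 2:
        raise ValueError("centralization needs at least 2 weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return float((n * w.max() - 1.0) / (n - 1.0))


def collective_estimate(a: np.ndarray, omega: float) -> float:
    """Collective estimate ``omega * a[0] + (1 - omega) * mean(a)``.

    ``a[0]`` is the central agent's initial estimate; with ``omega = 0`` this
    is the plain average (the classical wisdom-of-crowds aggregate).
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("estimate vector is empty")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    return float(omega * a[0] + (1.0 - omega) * a.mean())


def sample_initial_estimates(
    ctx: EstimationContext, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. initial estimates from the context.

    Multiplicative families draw ``theta * exp(mu + noise)``; the normal
    family draws ``theta + mu + sigma Z`` and resamples non-positive values
    (logged) so the estimate vector stays strictly positive.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    return sample_estimate_matrix(ctx, 1, n, rng)[0]


def sample_estimate_matrix(
    ctx: EstimationContext, reps: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized sampler: a ``(reps, n)`` matrix of i.i.d. initial estimates."""
    shape = (reps, n)
    theta, mu, sigma = ctx.theta, ctx.mu, ctx.sigma
    if ctx.family is Family.LOGNORMAL:
        return theta * np.exp(mu + sigma * rng.standard_normal(shape))
    if ctx.family is Family.LOGLAPLACE:
        return theta * np.exp(mu + rng.laplace(0.0, sigma, shape))
    if ctx.family is Family.PARETO:
        # numpy's pareto is the Lomax form; 1 + Lomax is Pareto with scale 1
        return theta * np.exp(mu) * (1.0 + rng.pareto(1.0 / sigma, shape))
    if ctx.family is Family.NORMAL:
        a = theta + mu + sigma * rng.standard_normal(shape)
        n_resampled = 0
        bad = a <= 0
        while bad.any():
            k = int(bad.sum())
            n_resampled += k
            a[bad] = theta + mu + sigma * rng.standard_normal(k)
            bad = a <= 0
        if n_resampled:
            logger.info(
                "resampled %d non-positive normal draws (theta=%g, mu=%g, sigma=%g)",
                n_resampled, theta, mu, sigma,
            )
        return a
    raise ValueError(f"unsupported family: {ctx.family}")  # pragma: no cover


def context_distribution(ctx: EstimationContext):
    """Frozen scipy distribution of the initial estimates (CDF/SF provider)."""
    theta, mu, sigma = ctx.theta, ctx.mu, ctx.sigma
    if ctx.family is Family.LOGNORMAL:
        return stats.lognorm(s=sigma, scale=theta * np.exp(mu))
    if ctx.family is Family.LOGLAPLACE:
        return stats.loglaplace(c=1.0 / sigma, scale=theta * np.exp(mu))
    if ctx.family is Family.PARETO:
        return stats.pareto(b=1.0 / sigma, scale=theta * np.exp(mu))
    if ctx.family is Family.NORMAL:
        loc = theta + mu
        return stats.truncnorm(a=(0.0 - loc) / sigma, b=np.inf, loc=loc, scale=sigma)
    raise ValueError(f"unsupported family: {ctx.family}")  # pragma: no cover
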