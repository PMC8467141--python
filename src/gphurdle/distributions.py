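"""Generalized Poisson (GP2) distribution, its zero-truncated form, and the
generalized Poisson hurdle (GPH) mixture.

The GP2 distribution has two parameters: a mean ``mu > 0`` and a dispersion
parameter ``alpha``.  Its pmf is

    Pr(Y = y) = [mu/(1+alpha*mu)]^y (1+alpha*y)^(y-1) / y!
                * exp(-mu*(1+alpha*y)/(1+alpha*mu)),   y = 0, 1, 2, ...

with mean ``mu`` and variance ``mu*(1+alpha*mu)^2``.  ``alpha > 0`` gives
over-dispersion (variance > mean), ``alpha < 0`` under-dispersion, and
``alpha = 0`` recovers the Poisson distribution.  For ``alpha < 0`` the pmf is
defined to be zero whenever ``1 + alpha*y <= 0``, which truncates the support
at the largest integer ``y`` with ``1 + alpha*y > 0``; the total mass then
falls slightly short of one.  We follow that definition literally (no
renormalisation) and expose the shortfall through :func:`gp_mass_deficit`.

The hurdle mixture places probability ``w`` on zero and distributes the
remaining ``1 - w`` over the positive integers in proportion to the
zero-truncated GP2 pmf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ParameterError",
    "GPParams",
    "HurdleParams",
    "gp_logpmf",
    "gp_pmf",
    "gp_moments",
    "gp1_from_gp2",
    "gp_support",
    "gp_mass_deficit",
    "gp_sample",
    "gphr_pmf",
    "gphr_moments",
    "truncgp_sample",
]

#: summation/sampling stops once cumulative mass exceeds 1 - SUPPORT_TAIL
SUPPORT_TAIL = 1e-12
#: hard ceiling on the enumerated support
SUPPORT_CEILING = 10**6


class ParameterError(ValueError):
    """Raised when distribution parameters violate their domain."""


@dataclass(frozen=True)
class GPParams:
    """GP2 parameters: untruncated mean ``mu`` and dispersion ``alpha``.

    Requires ``mu > 0`` and ``1 + alpha*mu > 0``.
    """

    mu: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.alpha)):
            raise ParameterError("mu and alpha must be finite")
        if self.mu <= 0:
            raise ParameterError(f"mu must be positive, got {self.mu}")
        if 1.0 + self.alpha * self.mu <= 0:
            raise ParameterError(
                f"1 + alpha*mu must be positive, got {1.0 + self.alpha * self.mu}"
            )


@dataclass(frozen=True)
class HurdleParams:
    """Hurdle parameters: zero probability ``w`` and GP2 positive process."""

    w: float
    gp: GPParams

    def __post_init__(self) -> None:
        if not (0.0 < self.w < 1.0):
            raise ParameterError(f"w must lie in (0, 1), got {self.w}")


def gp_logpmf(y, params: GPParams):
    """Log pmf of GP2 at integer point(s) ``y`` (``-inf`` off the support)."""
    y = np.asarray(y)
    mu, alpha = params.mu, params.alpha
    denom = 1.0 + alpha * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = 1.0 + alpha * y
        logp = np.where(
            (y >= 0) & (factor > 0),
            y * np.log(mu / denom)
            + np.where(factor > 0, (y - 1) * np.log(np.where(factor > 0, factor, 1.0)), 0.0)
            - gammaln(y + 1.0)
            - mu * factor / denom,
            -np.inf,
        )
    return logp if logp.shape else float(logp)


def gp_pmf(y, params: GPParams):
    """GP2 pmf; zero beyond the negative-``alpha`` truncation point."""
    return np.exp(gp_logpmf(y, params))


def gp_moments(params: GPParams) -> tuple[float, float]:
    """Closed-form (mean, variance) = (mu, mu*(1+alpha*mu)^2)."""
    mu, alpha = params.mu, params.alpha
    return mu, mu * (1.0 + alpha * mu) ** 2


def gp1_from_gp2(params: GPParams) -> tuple[float, float]:
    """Convert to the rate/dispersion (lambda1, lambda2) parameterisation.

    lambda1 = mu/(1+alpha*mu), lambda2 = alpha*mu/(1+alpha*mu); the mean
    round-trips as mu = lambda1/(1-lambda2).
    """
    mu, alpha = params.mu, params.alpha
    denom = 1.0 + alpha * mu
    return mu / denom, alpha * mu / denom


def gp_support(params: GPParams, tail: float = SUPPORT_TAIL) -> np.ndarray:
    """Pmf over the enumerated support ``0..y_max``.

    ``y_max`` is the smallest y where cumulative mass exceeds ``1 - tail``,
    the truncation point for ``alpha < 0``, or ``SUPPORT_CEILING``, whichever
    comes first.
    """
    mu, alpha = params.mu, params.alpha
    if alpha < 0:
        # pmf vanishes once 1 + alpha*y <= 0: largest valid y is ceil(-1/alpha)-1
        hard_max = min(int(math.ceil(-1.0 / alpha)) - 1, SUPPORT_CEILING)
    else:
        hard_max = SUPPORT_CEILING

    # grow the enumerated support geometrically until the tail condition holds
    block = max(32, int(8 * mu))
    y_hi = min(block, hard_max)
    while True:
        y = np.arange(y_hi + 1)
        p = gp_pmf(y, params)
        if p.sum() >= 1.0 - tail or y_hi >= hard_max:
            break
        y_hi = min(2 * y_hi, hard_max)
    cum = np.cumsum(p)
    idx = np.searchsorted(cum, 1.0 - tail)
    cut = min(int(idx), y_hi)
    return p[: cut + 1]


def gp_mass_deficit(params: GPParams) -> float:
    """1 minus the total pmf mass over the full support.

    Strictly positive for ``alpha < 0`` (literal truncated definition);
    numerically ~0 otherwise.
    """
    if params.alpha < 0:
        hard = gp_support(params, tail=0.0)
        return float(1.0 - hard.sum())
    return float(1.0 - gp_support(params).sum())


def _inverse_cdf_sample(pmf: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(pmf)
    # scaling u by the enumerated mass conditions on the support; the deficit
    # (negative-alpha truncation plus the 1e-12 tail) is below sampling noise
    u = rng.random(n) * min(float(cdf[-1]), 1.0)
    return np.searchsorted(cdf, u, side="right").clip(0, len(pmf) - 1)


def gp_sample(n: int, params: GPParams, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. GP2 draws by inverse CDF over the enumerated support."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = gp_support(params)
    return _inverse_cdf_sample(pmf, n, rng)


def gphr_pmf(j, params: HurdleParams):
    """Hurdle pmf: ``w`` at zero, ``(1-w) g(j)/(1-g(0))`` for ``j >= 1``."""
    j = np.asarray(j)
    gp = params.gp
    g0 = math.exp(-gp.mu / (1.0 + gp.alpha * gp.mu))
    pos = (1.0 - params.w) * gp_pmf(j, gp) / (1.0 - g0)
    out = np.where(j == 0, params.w, pos)
    return out if out.shape else float(out)


def gphr_moments(params: HurdleParams) -> tuple[float, float]:
    """Closed-form (mean, variance) of the hurdle mixture.

    With hurdle factor c = (1-w)/(1-exp(-mu/(1+alpha*mu))):
    mean = c*mu, E[Y^2] = c*(mu*(1+alpha*mu)^2 + mu^2), var = E[Y^2] - mean^2.
    """
    w, gp = params.w, params.gp
    mu, alpha = gp.mu, gp.alpha
    c = (1.0 - w) / -math.expm1(-mu / (1.0 + alpha * mu))
    mean = c * mu
    raw2 = c * (mu * (1.0 + alpha * mu) ** 2 + mu**2)
    return mean, raw2 - mean**2


def truncgp_sample(n: int, params: GPParams, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. draws from the zero-truncated GP2 (support ``j >= 1``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = gp_support(params)
    if len(pmf) < 2:
        raise ParameterError("truncated support is empty for these parameters")
    trunc = pmf[1:] / (1.0 - pmf[0])
    return _inverse_cdf_sample(trunc, n, rng) + 1
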