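"""Log-likelihoods, ML fitting, and AIC for the three competing models.

* ``gphr`` — generalized Poisson hurdle regression: logit zero part, zero-
  truncated GP2 count part with dispersion alpha.
* ``ph``   — Poisson hurdle: the alpha = 0 special case.
* ``gp``   — GP2 regression with no zero process.

All fits minimize the negative log-likelihood with the package's simplex
optimizer; infeasible parameter regions contribute a large finite penalty so
the search remains unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from .neldermead import NMConfig, nelder_mead
from .regression import PENALTY, CountDataset, ThetaVector, linpred_to_params

__all__ = [
    "FitResult",
    "loglik_gphr",
    "loglik_ph",
    "loglik_gp",
    "aic",
    "fit_ml",
    "default_init",
    "n_free_params",
    "model_loglik",
]

MODEL_TAGS = ("gphr", "ph", "gp")


@dataclass
class FitResult:
    """Estimates plus fit diagnostics for one (model, estimator) pair."""

    model_tag: str
    estimator_tag: str  # "ML" or "GMM"
    theta_hat: ThetaVector
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int
    aic_kind: str = "ml"  # "quasi" when loglik is evaluated at GMM estimates
    objective: float | None = None  # GMM: Q_n at the optimum
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    p_values: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def packed(self) -> np.ndarray:
        """Free-parameter vector in reporting order."""
        return pack_free(self.model_tag, self.theta_hat)


def _gp_terms(y, mu, alpha):
    """Vector of log GP2 pmf values at per-observation mu (shared alpha)."""
    denom = 1.0 + alpha * mu
    factor = 1.0 + alpha * y
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (
            y * np.log(mu / denom)
            + (y - 1) * np.log(np.where(factor > 0, factor, np.nan))
            - gammaln(y + 1.0)
            - mu * factor / denom
        )
    return np.where(factor > 0, lp, -np.inf)


def loglik_gphr(theta: ThetaVector, dataset: CountDataset) -> float:
    """Hurdle log-likelihood: sum over zeros of log w_i plus, over positives,
    log(1-w_i) + log g(y_i) - log(1-g(0)); -PENALTY when infeasible."""
    w, mu, feasible = linpred_to_params(theta, dataset)
    if not feasible:
        return -PENALTY
    y = dataset.y
    zero = y == 0
    denom = 1.0 + theta.alpha * mu
    log_trunc = np.log(-np.expm1(-mu / denom))
    lp_pos = np.log1p(-w) + _gp_terms(y.astype(float), mu, theta.alpha) - log_trunc
    ll = np.sum(np.log(w[zero])) + np.sum(lp_pos[~zero])
    return float(ll) if np.isfinite(ll) else -PENALTY


def loglik_ph(theta: ThetaVector, dataset: CountDataset) -> float:
    """Poisson hurdle log-likelihood (alpha pinned to 0)."""
    return loglik_gphr(ThetaVector(0.0, theta.beta, theta.delta), dataset)


def loglik_gp(theta: ThetaVector, dataset: CountDataset) -> float:
    """GP2 regression log-likelihood; the zero part of ``theta`` is unused."""
    beta = np.asarray(theta.beta, float)
    if dataset.x_design.shape[1] != len(beta):
        raise ValueError("beta dimension does not match x_design")
    with np.errstate(over="ignore"):
        mu = np.exp(dataset.x_design @ beta)
    if not (np.all(np.isfinite(mu)) and np.all(1.0 + theta.alpha * mu > 1e-12)):
        return -PENALTY
    ll = np.sum(_gp_terms(dataset.y.astype(float), mu, theta.alpha))
    return float(ll) if np.isfinite(ll) else -PENALTY


_LOGLIK = {"gphr": loglik_gphr, "ph": loglik_ph, "gp": loglik_gp}


def model_loglik(model_tag: str, theta: ThetaVector, dataset: CountDataset) -> float:
    return _LOGLIK[model_tag](theta, dataset)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, -2*loglik + 2*n_params (lower is better)."""
    return -2.0 * loglik + 2.0 * n_params


def n_free_params(model_tag: str, dataset: CountDataset) -> int:
    p1 = dataset.x_design.shape[1]
    q1 = dataset.z_design.shape[1]
    if model_tag == "gphr":
        return p1 + q1 + 1
    if model_tag == "ph":
        return p1 + q1
    if model_tag == "gp":
        return p1 + 1
    raise ValueError(f"unknown model {model_tag!r}")


def pack_free(model_tag: str, theta: ThetaVector) -> np.ndarray:
    """Free parameters only: gphr (alpha,beta,delta); ph (beta,delta); gp (alpha,beta)."""
    if model_tag == "gphr":
        return theta.pack()
    if model_tag == "ph":
        return np.concatenate([theta.beta, theta.delta])
    if model_tag == "gp":
        return np.concatenate([[theta.alpha], theta.beta])
    raise ValueError(f"unknown model {model_tag!r}")


def unpack_free(model_tag: str, vec: np.ndarray, dataset: CountDataset) -> ThetaVector:
    p1 = dataset.x_design.shape[1]
    q1 = dataset.z_design.shape[1]
    vec = np.asarray(vec, float)
    if model_tag == "gphr":
        return ThetaVector.unpack(vec, p1, q1)
    if model_tag == "ph":
        return ThetaVector(0.0, vec[:p1].copy(), vec[p1:].copy())
    if model_tag == "gp":
        return ThetaVector(float(vec[0]), vec[1:].copy(), np.zeros(q1))
    raise ValueError(f"unknown model {model_tag!r}")


def free_labels(model_tag: str, dataset: CountDataset) -> list[str]:
    bx = [f"beta[{c}]" for c in dataset.column_names_x]
    bz = [f"delta[{c}]" for c in dataset.column_names_z]
    if model_tag == "gphr":
        return ["alpha"] + bx + bz
    if model_tag == "ph":
        return bx + bz
    if model_tag == "gp":
        return ["alpha"] + bx
    raise ValueError(f"unknown model {model_tag!r}")


def default_init(model_tag: str, dataset: CountDataset) -> ThetaVector:
    """Moment-style starting values.

    Count-part intercept at log of the positive-response mean (log of the
    overall mean for the no-hurdle GP model), zero-part intercept at the
    empirical logit of the zero fraction, slopes 0, alpha 0.01.
    """
    y = dataset.y
    p1 = dataset.x_design.shape[1]
    q1 = dataset.z_design.shape[1]
    pos_mean = y[y > 0].mean() if np.any(y > 0) else 1.0
    beta = np.zeros(p1)
    beta[0] = np.log(max(y.mean(), 0.1)) if model_tag == "gp" else np.log(max(pos_mean, 0.1))
    delta = np.zeros(q1)
    zf = np.clip((y == 0).mean(), 1.0 / (len(y) + 1), 1.0 - 1.0 / (len(y) + 1))
    delta[0] = np.log(zf / (1.0 - zf))
    return ThetaVector(0.01, beta, delta)


def fit_ml(
    model_tag: str,
    dataset: CountDataset,
    init: ThetaVector | None = None,
    nm_config: NMConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit via the simplex optimizer.

    Deterministic given (init, nm_config); on non-convergence one restart is
    attempted from a 10%-jittered start (fixed jitter stream), and the better
    of the two runs is kept with ``converged`` reported honestly.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model {model_tag!r}")
    cfg = nm_config or NMConfig()
    theta0 = init or default_init(model_tag, dataset)
    x0 = pack_free(model_tag, theta0)
    ll_fun = _LOGLIK[model_tag]

    def negll(v: np.ndarray) -> float:
        return -ll_fun(unpack_free(model_tag, v, dataset), dataset)

    res = nelder_mead(negll, x0, cfg)
    n_iter = res.n_iter
    if not res.converged:
        jitter = np.random.default_rng(0).uniform(-0.1, 0.1, size=len(x0))
        x0b = x0 + jitter * np.maximum(np.abs(x0), 1.0)
        res_b = nelder_mead(negll, x0b, cfg)
        n_iter += res_b.n_iter
        if res_b.fun < res.fun:
            res = res_b

    theta_hat = unpack_free(model_tag, res.x, dataset)
    ll = -res.fun
    p = n_free_params(model_tag, dataset)
    return FitResult(
        model_tag=model_tag,
        estimator_tag="ML",
        theta_hat=theta_hat,
        loglik=ll,
        aic=aic(ll, p),
        n_params=p,
        converged=res.converged,
        n_iter=n_iter,
        labels=free_labels(model_tag, dataset),
    )
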