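"""Generalized method of moments for the hurdle regression models.

The moment conditions pair each stacked covariate vector X_i = (x_i', z_i')'
with the first- and second-raw-moment residuals:

    h(Y_i, X_i, theta) = [ X_i (Y_i   - g1_i) ]
                         [ X_i (Y_i^2 - g2_i) ]

so E[h] = 0 at the true parameter.  The estimator minimizes the quadratic
form Q_n = h_n' W h_n in the sample moment average h_n, using the package's
simplex optimizer.  When the count-part and zero-part covariates coincide
the two blocks of h duplicate rows and the system is under-identified
(2(p+1) distinct moments against 2(p+1)+1 parameters); the optional
``augment_zero_moment`` appends z_i (1{Y_i=0} - w_i) to restore
identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import (
    FitResult,
    aic,
    fit_ml,
    free_labels,
    model_loglik,
    n_free_params,
    pack_free,
    unpack_free,
)
from .neldermead import NMConfig, nelder_mead
from .regression import PENALTY, CountDataset, ThetaVector, linpred_to_params, moment_g1_g2

__all__ = [
    "GMMSpec",
    "GMMDiagnostics",
    "moment_vector",
    "moment_matrix",
    "sample_moments",
    "gmm_objective",
    "make_weight",
    "fit_gmm",
    "gmm_asymptotic_variance",
]

#: singular values below PINV_RTOL * s_max are treated as zero
PINV_RTOL = 1e-10
#: relative step for central finite differences on the moment Jacobian
FD_REL_STEP = 1e-5


@dataclass
class GMMSpec:
    """Weighting strategy for the GMM quadratic form.

    ``identity`` uses W = I; ``two_step`` re-weights by the pseudo-inverse of
    the moment covariance estimated at a first-stage identity-weight fit;
    ``fixed`` uses the supplied PSD matrix ``W``.
    """

    weight_strategy: str = "identity"
    W: np.ndarray | None = None
    augment_zero_moment: bool = False
    raw2_form: str = "eq10"

    def __post_init__(self) -> None:
        if self.weight_strategy not in ("identity", "two_step", "fixed"):
            raise ValueError(f"unknown weight strategy {self.weight_strategy!r}")
        if self.weight_strategy == "fixed":
            if self.W is None:
                raise ValueError("fixed strategy requires W")
            W = np.asarray(self.W, float)
            if not np.allclose(W, W.T):
                raise ValueError("W must be symmetric")
            if np.linalg.eigvalsh(W).min() < -1e-10:
                raise ValueError("W must be positive semi-definite")
            self.W = W


@dataclass
class GMMDiagnostics:
    """Sandwich-variance ingredients at the GMM estimate."""

    G: np.ndarray          # Jacobian of h_n w.r.t. theta (dim h x dim theta)
    Sigma_hat: np.ndarray  # (1/n) sum h_i h_i'
    Gamma_hat: np.ndarray  # (G'WG)^+ G'W Sigma W G (G'WG)^+
    jacobian_rank: int


def _model_moments(model_tag: str, theta: ThetaVector, dataset: CountDataset, raw2_form: str):
    """Per-observation (g1, g2, feasible) for the requested model."""
    if model_tag == "gphr":
        return moment_g1_g2(theta, dataset, raw2_form)
    if model_tag == "ph":
        return moment_g1_g2(ThetaVector(0.0, theta.beta, theta.delta), dataset, raw2_form)
    if model_tag == "gp":
        with np.errstate(over="ignore"):
            mu = np.exp(dataset.x_design @ np.asarray(theta.beta, float))
        if not (np.all(np.isfinite(mu)) and np.all(1.0 + theta.alpha * mu > 1e-12)):
            return None, None, False
        denom = 1.0 + theta.alpha * mu
        return mu, mu * denom**2 + mu**2, True
    raise ValueError(f"unknown model {model_tag!r}")


def _design(model_tag: str, dataset: CountDataset) -> np.ndarray:
    return dataset.x_design if model_tag == "gp" else dataset.stacked_design


def moment_matrix(
    dataset: CountDataset,
    theta: ThetaVector,
    model_tag: str = "gphr",
    spec: GMMSpec | None = None,
):
    """n x dim(h) matrix of per-observation moment conditions.

    Returns ``(H, feasible)``; rows are h(Y_i, X_i, theta).
    """
    spec = spec or GMMSpec()
    g1, g2, feasible = _model_moments(model_tag, theta, dataset, spec.raw2_form)
    if not feasible:
        return None, False
    X = _design(model_tag, dataset)
    y = dataset.y.astype(float)
    H = np.hstack([X * (y - g1)[:, None], X * (y**2 - g2)[:, None]])
    if spec.augment_zero_moment and model_tag in ("gphr", "ph"):
        th = theta if model_tag == "gphr" else ThetaVector(0.0, theta.beta, theta.delta)
        w, _, _ = linpred_to_params(th, dataset)
        H = np.hstack([H, dataset.z_design * ((y == 0).astype(float) - w)[:, None]])
    return H, True


def moment_vector(y_i, X_i, theta: ThetaVector, g1_i: float, g2_i: float) -> np.ndarray:
    """Single-observation moment condition h = [X_i(y-g1); X_i(y^2-g2)]."""
    X_i = np.asarray(X_i, float)
    return np.concatenate([X_i * (y_i - g1_i), X_i * (y_i**2 - g2_i)])


def sample_moments(
    dataset: CountDataset,
    theta: ThetaVector,
    model_tag: str = "gphr",
    spec: GMMSpec | None = None,
):
    """Sample average h_n = (1/n) sum_i h_i; returns ``(h_n, feasible)``."""
    H, feasible = moment_matrix(dataset, theta, model_tag, spec)
    if not feasible:
        return None, False
    return H.mean(axis=0), True


def moment_dim(model_tag: str, dataset: CountDataset, spec: GMMSpec | None = None) -> int:
    spec = spec or GMMSpec()
    d = 2 * _design(model_tag, dataset).shape[1]
    if spec.augment_zero_moment and model_tag in ("gphr", "ph"):
        d += dataset.z_design.shape[1]
    return d


def gmm_objective(
    dataset: CountDataset,
    theta: ThetaVector,
    spec: GMMSpec | None = None,
    model_tag: str = "gphr",
    W: np.ndarray | None = None,
) -> float:
    """Quadratic form Q_n = h_n' W h_n (PENALTY on infeasible theta)."""
    spec = spec or GMMSpec()
    h_n, feasible = sample_moments(dataset, theta, model_tag, spec)
    if not feasible:
        return PENALTY
    if W is None:
        W = spec.W if spec.weight_strategy == "fixed" else np.eye(len(h_n))
    if W.shape != (len(h_n), len(h_n)):
        raise ValueError("weight matrix not conformable with the moment vector")
    q = float(h_n @ W @ h_n)
    return q if np.isfinite(q) else PENALTY


def make_weight(
    dataset: CountDataset,
    theta: ThetaVector,
    strategy: str = "identity",
    model_tag: str = "gphr",
    spec: GMMSpec | None = None,
) -> np.ndarray:
    """Weight matrix: identity, or the pseudo-inverse of the empirical moment
    covariance Sigma_hat = (1/n) sum h_i h_i' (pseudo-inverse because x = z
    duplicates moment rows and makes Sigma_hat singular)."""
    spec = spec or GMMSpec()
    dim = moment_dim(model_tag, dataset, spec)
    if strategy == "identity":
        return np.eye(dim)
    if strategy == "two_step":
        H, feasible = moment_matrix(dataset, theta, model_tag, spec)
        if not feasible:
            return np.eye(dim)
        Sigma = (H.T @ H) / dataset.n
        return np.linalg.pinv(Sigma, rcond=PINV_RTOL, hermitian=True)
    raise ValueError(f"unknown strategy {strategy!r}")


def fit_gmm(
    dataset: CountDataset,
    init: ThetaVector | None = None,
    spec: GMMSpec | None = None,
    nm_config: NMConfig | None = None,
    model_tag: str = "gphr",
) -> FitResult:
    """GMM fit; by default initialized at the ML estimate.

    For ``two_step`` weighting the objective is first minimized under the
    identity weight, the covariance-based weight is rebuilt at that first-
    stage estimate, and Q_n is re-minimized once.  The reported log-likelihood
    and AIC are quasi versions, evaluated at the GMM estimates.
    """
    spec = spec or GMMSpec()
    cfg = nm_config or NMConfig()
    if init is None:
        init = fit_ml(model_tag, dataset, nm_config=nm_config).theta_hat
    x0 = pack_free(model_tag, init)

    # minimize n*Q_n rather than Q_n: same minimizer, but the objective stays
    # O(1) near the optimum so the absolute spread stopping rule is meaningful
    scale = float(dataset.n)

    def _minimize(W, start):
        def obj(v):
            return scale * gmm_objective(dataset, unpack_free(model_tag, v, dataset), spec, model_tag, W)

        return nelder_mead(obj, start, cfg)

    n_iter = 0
    if spec.weight_strategy == "fixed":
        res = _minimize(spec.W, x0)
    elif spec.weight_strategy == "identity":
        res = _minimize(np.eye(moment_dim(model_tag, dataset, spec)), x0)
    else:  # two_step
        stage1 = _minimize(np.eye(moment_dim(model_tag, dataset, spec)), x0)
        n_iter += stage1.n_iter
        W2 = make_weight(
            dataset, unpack_free(model_tag, stage1.x, dataset), "two_step", model_tag, spec
        )
        res = _minimize(W2, stage1.x)
    n_iter += res.n_iter

    theta_hat = unpack_free(model_tag, res.x, dataset)
    ll = model_loglik(model_tag, theta_hat, dataset)
    p = n_free_params(model_tag, dataset)
    return FitResult(
        model_tag=model_tag,
        estimator_tag="GMM",
        theta_hat=theta_hat,
        loglik=ll,
        aic=aic(ll, p),
        n_params=p,
        converged=res.converged,
        n_iter=n_iter,
        aic_kind="quasi",
        objective=res.fun / scale,
        labels=free_labels(model_tag, dataset),
    )


def gmm_asymptotic_variance(
    dataset: CountDataset,
    theta_hat: ThetaVector,
    spec: GMMSpec | None = None,
    model_tag: str = "gphr",
) -> GMMDiagnostics:
    """Sandwich variance Gamma = (G'WG)^+ G'W Sigma W G (G'WG)^+ at theta_hat.

    G is a central finite-difference Jacobian of the sample moments;
    pseudo-inverses are used throughout and the Jacobian rank is reported so
    under-identification (e.g. x = z) is visible rather than fatal.
    """
    spec = spec or GMMSpec()
    x_hat = pack_free(model_tag, theta_hat)
    dim_h = moment_dim(model_tag, dataset, spec)
    k = len(x_hat)

    G = np.zeros((dim_h, k))
    for j in range(k):
        step = FD_REL_STEP * max(abs(x_hat[j]), 1.0)
        hi = x_hat.copy(); hi[j] += step
        lo = x_hat.copy(); lo[j] -= step
        h_hi, f1 = sample_moments(dataset, unpack_free(model_tag, hi, dataset), model_tag, spec)
        h_lo, f2 = sample_moments(dataset, unpack_free(model_tag, lo, dataset), model_tag, spec)
        if f1 and f2:
            G[:, j] = (h_hi - h_lo) / (2.0 * step)

    H, feasible = moment_matrix(dataset, theta_hat, model_tag, spec)
    Sigma = (H.T @ H) / dataset.n if feasible else np.full((dim_h, dim_h), np.nan)

    if spec.weight_strategy == "fixed":
        W = spec.W
    elif spec.weight_strategy == "two_step":
        W = make_weight(dataset, theta_hat, "two_step", model_tag, spec)
    else:
        W = np.eye(dim_h)

    GtWG = G.T @ W @ G
    bread = np.linalg.pinv(GtWG, rcond=PINV_RTOL)
    Gamma = bread @ G.T @ W @ Sigma @ W @ G @ bread
    rank = int(np.linalg.matrix_rank(G, tol=PINV_RTOL * max(1.0, np.abs(G).max())))
    return GMMDiagnostics(G=G, Sigma_hat=Sigma, Gamma_hat=Gamma, jacobian_rank=rank)
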