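"""Bootstrap variance, Wald intervals/p-values, and AIC model comparison.

Bootstrap standard errors are the default for GMM estimates, whose closed-
form sandwich variance is awkward in practice; ML fits may alternatively use
the numerically-differenced observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .regression import CountDataset
from .likelihood import FitResult

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_variance",
    "wald_inference",
    "observed_information_se",
    "compare_models",
    "attach_wald",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Number of resamples B (default 50), resample size (default n), seed."""

    B: int = 50
    resample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2 (variance divides by B-1)")


@dataclass
class BootstrapResult:
    variances: np.ndarray
    se: np.ndarray
    replicates: np.ndarray  # B x k
    n_redraws: int


def bootstrap_variance(
    dataset: CountDataset,
    estimator,
    config: BootstrapConfig,
) -> BootstrapResult:
    """Componentwise variance of ``estimator`` over B with-replacement
    resamples of the rows: (1/(B-1)) sum_b (theta_b - mean_b)^2.

    ``estimator`` maps a CountDataset to a fixed-length vector.  A resample
    on which it raises is redrawn (at most 5*B attempts in total).
    """
    rng = np.random.default_rng(config.seed)
    n = dataset.n
    size = config.resample_size or n
    reps = []
    n_redraws = 0
    attempts = 0
    while len(reps) < config.B:
        if attempts >= 5 * config.B:
            raise RuntimeError(f"bootstrap exceeded {5 * config.B} attempts")
        attempts += 1
        idx = rng.integers(0, n, size=size)
        try:
            reps.append(np.asarray(estimator(dataset.subset(idx)), dtype=float))
        except Exception:
            n_redraws += 1
    replicates = np.vstack(reps)
    center = replicates.mean(axis=0)
    variances = np.sum((replicates - center) ** 2, axis=0) / (config.B - 1)
    return BootstrapResult(variances, np.sqrt(variances), replicates, n_redraws)


def wald_inference(est: np.ndarray, se: np.ndarray, level: float = 0.05):
    """Normal-reference CIs est +/- z_{1-level/2} se and two-sided p-values.

    Degenerate se = 0 gives p = 0 for a nonzero estimate and p = 1 otherwise.
    """
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(1.0 - level / 2.0)
    ci_low = est - z * se
    ci_high = est + z * se
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(est) / se
    p = np.where(se > 0, 2.0 * norm.sf(np.where(se > 0, stat, 0.0)), np.where(est != 0, 0.0, 1.0))
    return ci_low, ci_high, p


def observed_information_se(negll, x_hat: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """SEs from the numerically-differenced observed information matrix.

    ``negll`` is the negative log-likelihood over the free-parameter vector;
    the Hessian is built by central second differences and inverted by
    pseudo-inverse, so near-singular information yields large (not NaN) SEs.
    """
    k = len(x_hat)
    steps = rel_step * np.maximum(np.abs(x_hat), 1.0)
    Hmat = np.zeros((k, k))
    f0 = negll(x_hat)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                val = (negll(x_hat + ei) - 2.0 * f0 + negll(x_hat - ei)) / steps[i] ** 2
            else:
                val = (
                    negll(x_hat + ei + ej) - negll(x_hat + ei - ej)
                    - negll(x_hat - ei + ej) + negll(x_hat - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
            Hmat[i, j] = Hmat[j, i] = val
    cov = np.linalg.pinv(Hmat, rcond=1e-12)
    var = np.clip(np.diag(cov), 0.0, None)
    return np.sqrt(var)


def attach_wald(fit: FitResult, se: np.ndarray, level: float = 0.05) -> FitResult:
    """Fill a FitResult's se/CI/p fields from the given standard errors."""
    ci_low, ci_high, p = wald_inference(fit.packed(), se, level)
    fit.se = np.asarray(se, float)
    fit.ci_low, fit.ci_high, fit.p_values = ci_low, ci_high, p
    return fit


def compare_models(fits) -> pd.DataFrame:
    """AIC ranking table, ascending (lower AIC fits better); ties keep input
    order; delta_aic is relative to the best model."""
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    rows = [
        {
            "model": f.model_tag,
            "estimator": f.estimator_tag,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "aic": f.aic,
            "aic_kind": f.aic_kind,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows)
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
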