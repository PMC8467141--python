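"""Covariate-to-parameter maps for the hurdle regression.

The count part uses a log link, ``ln(mu_i) = x_i' beta``, and the zero part a
logit link, ``logit(w_i) = z_i' delta``.  Parameters are packed as
``theta = (alpha, beta', delta')'``.  Both design matrices carry an intercept
as their first column; the two covariate sets may coincide (as in the
ear-infection application) or differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountDataset", "ThetaVector", "linpred_to_params", "moment_g1_g2", "PENALTY"]

#: large finite value added to objectives on infeasible parameter regions,
#: so an unconstrained simplex search backs away instead of crashing
PENALTY = 1e10


@dataclass
class CountDataset:
    """Response vector plus the count-part (x) and zero-part (z) designs.

    Both design matrices must have an all-ones first column and full column
    rank; the response must be non-negative integers.
    """

    y: np.ndarray
    x_design: np.ndarray
    z_design: np.ndarray
    column_names_x: list[str] = field(default_factory=list)
    column_names_z: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.x_design = np.atleast_2d(np.asarray(self.x_design, dtype=float))
        self.z_design = np.atleast_2d(np.asarray(self.z_design, dtype=float))
        n = len(self.y)
        if n < 1:
            raise ValueError("empty response")
        if not np.all(np.isfinite(self.y)) or np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("response must be finite non-negative integers")
        self.y = self.y.astype(np.int64)
        for name, mat in (("x_design", self.x_design), ("z_design", self.z_design)):
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows, expected {n}")
            if not np.all(mat[:, 0] == 1.0):
                raise ValueError(f"first column of {name} must be all ones")
            if np.linalg.matrix_rank(mat) < mat.shape[1]:
                raise ValueError(f"{name} is column-rank deficient")
        if not self.column_names_x:
            self.column_names_x = [f"x{j}" for j in range(self.x_design.shape[1])]
        if not self.column_names_z:
            self.column_names_z = [f"z{j}" for j in range(self.z_design.shape[1])]

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def stacked_design(self) -> np.ndarray:
        """Row-wise stacked covariates X_i = (x_i', z_i')' as an n x (p+q+2) matrix."""
        return np.hstack([self.x_design, self.z_design])

    def subset(self, idx: np.ndarray) -> "CountDataset":
        return CountDataset(
            self.y[idx], self.x_design[idx], self.z_design[idx],
            self.column_names_x, self.column_names_z,
        )

    def summary(self) -> dict:
        y = self.y
        return {
            "n": int(len(y)),
            "n_zero": int((y == 0).sum()),
            "zero_fraction": float((y == 0).mean()),
            "mean": float(y.mean()),
            "variance": float(y.var(ddof=1)) if len(y) > 1 else 0.0,
        }


@dataclass(frozen=True)
class ThetaVector:
    """Packed hurdle parameters ``theta = (alpha, beta', delta')'``."""

    alpha: float
    beta: np.ndarray
    delta: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate([[self.alpha], np.asarray(self.beta, float), np.asarray(self.delta, float)])

    @staticmethod
    def unpack(vec: np.ndarray, n_beta: int, n_delta: int) -> "ThetaVector":
        vec = np.asarray(vec, dtype=float)
        if len(vec) != 1 + n_beta + n_delta:
            raise ValueError(f"expected {1 + n_beta + n_delta} entries, got {len(vec)}")
        return ThetaVector(float(vec[0]), vec[1 : 1 + n_beta].copy(), vec[1 + n_beta :].copy())

    def labels(self, dataset: CountDataset) -> list[str]:
        return (
            ["alpha"]
            + [f"beta[{c}]" for c in dataset.column_names_x]
            + [f"delta[{c}]" for c in dataset.column_names_z]
        )


def linpred_to_params(theta: ThetaVector, dataset: CountDataset):
    """Per-observation ``(w_i, mu_i)`` from the link functions.

    Returns ``(w, mu, feasible)`` where ``feasible`` is False whenever some
    ``1 + alpha*mu_i <= 0`` or a linear predictor overflows; callers add
    :data:`PENALTY` to their objective rather than raising, because the
    simplex optimizer is unconstrained.
    """
    beta = np.asarray(theta.beta, float)
    delta = np.asarray(theta.delta, float)
    if dataset.x_design.shape[1] != len(beta) or dataset.z_design.shape[1] != len(delta):
        raise ValueError("theta dimensions do not match the design matrices")
    eta_x = dataset.x_design @ beta
    eta_z = dataset.z_design @ delta
    with np.errstate(over="ignore"):
        mu = np.exp(eta_x)
        w = 1.0 / (1.0 + np.exp(-eta_z))
    feasible = bool(
        np.all(np.isfinite(mu))
        and np.all(mu > 0)
        and np.all(1.0 + theta.alpha * mu > 1e-12)
    )
    return w, mu, feasible


def moment_g1_g2(theta: ThetaVector, dataset: CountDataset, raw2_form: str = "eq10"):
    """First and second raw moments of each observation's hurdle law.

    g1_i = c_i * mu_i and g2_i = c_i * (mu_i*(1+alpha*mu_i)^2 + mu_i^2) with
    hurdle factor c_i = (1-w_i)/(1-exp(-mu_i/(1+alpha*mu_i))).

    ``raw2_form='linear'`` switches the bracket to mu*(1+alpha*mu) + mu^2, a
    variant useful for sensitivity checks only.

    Returns ``(g1, g2, feasible)``.
    """
    w, mu, feasible = linpred_to_params(theta, dataset)
    if not feasible:
        n = dataset.n
        return np.full(n, np.nan), np.full(n, np.nan), False
    alpha = theta.alpha
    denom = 1.0 + alpha * mu
    c = (1.0 - w) / -np.expm1(-mu / denom)
    g1 = c * mu
    if raw2_form == "eq10":
        g2 = c * (mu * denom**2 + mu**2)
    elif raw2_form == "linear":
        g2 = c * (mu * denom + mu**2)
    else:
        raise ValueError(f"unknown raw2_form {raw2_form!r}")
    return g1, g2, True
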