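"""Derivative-free simplex minimizer (Nelder-Mead).

Implements the classic reflection / expansion / contraction / shrink cycle
with coefficients eta (reflection, default 1), gamma (expansion, 2),
xi (contraction, 1/2) and kappa (shrink, 1/2).  Iteration stops when the
root-mean-square spread of the objective over the best m vertices falls
below ``eps``, when the simplex diameter collapses, or at ``max_iter``.

The implementation is deliberately self-contained: the GMM objective it
serves is not differentiable in any convenient closed form, and the exact
update formulas and stopping rule are part of the estimation procedure being
reproduced, so no library optimizer is substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMConfig", "initial_simplex", "nelder_mead", "NMResult"]


@dataclass(frozen=True)
class NMConfig:
    """Simplex coefficients and stopping parameters.

    Constraints: eta > 0, gamma > 1, 0 < xi < 1, 0 < kappa < 1.
    """

    eta: float = 1.0
    gamma: float = 2.0
    xi: float = 0.5
    kappa: float = 0.5
    eps: float = 1e-8
    xtol: float = 1e-6
    max_iter: int = 5000
    init_step: float = 0.05

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.gamma > 1 and 0 < self.xi < 1 and 0 < self.kappa < 1):
            raise ValueError("require eta>0, gamma>1, 0<xi<1, 0<kappa<1")


@dataclass
class NMResult:
    x: np.ndarray
    fun: float
    n_iter: int
    converged: bool
    n_fev: int


def initial_simplex(x0: np.ndarray, step: float = 0.05) -> np.ndarray:
    """(m+1) x m simplex: x0 plus one vertex per coordinate, displaced by
    ``step * max(|x0_i|, 1)`` so the edge scales with the coordinate."""
    x0 = np.asarray(x0, dtype=float)
    m = len(x0)
    vertices = np.tile(x0, (m + 1, 1))
    for i in range(m):
        vertices[i + 1, i] += step * max(abs(x0[i]), 1.0)
    return vertices


def nelder_mead(f, x0: np.ndarray, config: NMConfig | None = None) -> NMResult:
    """Minimize ``f`` from ``x0``; deterministic given identical inputs.

    Ties in the vertex ordering are broken by insertion order (stable sort).
    """
    cfg = config or NMConfig()
    simplex = initial_simplex(x0, cfg.init_step)
    m = simplex.shape[1]
    fvals = np.array([f(v) for v in simplex], dtype=float)
    n_fev = m + 1

    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]

        # stopping: RMS spread of f over the whole simplex below eps AND the
        # simplex diameter below a relative xtol.  The f-spread alone cannot
        # certify the argmin (vertices can equalize f on a level set around
        # the minimum), so a spatial tolerance is required as well; an exactly
        # flat simplex (constant objective) stops immediately.
        fbar = fvals.mean()
        spread = np.sqrt(np.mean((fvals - fbar) ** 2))
        diam = np.max(np.abs(simplex[1:] - simplex[0]))
        if spread == 0.0 or (
            spread < cfg.eps and diam < cfg.xtol * (1.0 + np.linalg.norm(simplex[0]))
        ):
            converged = True
            break

        centroid = simplex[:m].mean(axis=0)
        xr = (1.0 + cfg.eta) * centroid - cfg.eta * simplex[m]
        fr = f(xr)
        n_fev += 1

        if fvals[0] <= fr <= fvals[m - 1]:
            simplex[m], fvals[m] = xr, fr
        elif fr < fvals[0]:
            xe = (1.0 - cfg.gamma) * centroid + cfg.gamma * xr
            fe = f(xe)
            n_fev += 1
            if fe <= fr:
                simplex[m], fvals[m] = xe, fe
            else:
                simplex[m], fvals[m] = xr, fr
        else:
            if fr < fvals[m]:
                # outside contraction, between worst-but-one and worst
                xc = (1.0 - cfg.xi) * centroid + cfg.xi * xr
                fc = f(xc)
                n_fev += 1
                accept = fc <= fr
            else:
                # inside contraction
                xc = (1.0 + cfg.xi) * centroid - cfg.xi * xr
                fc = f(xc)
                n_fev += 1
                accept = fc <= fvals[m]
            if accept:
                simplex[m], fvals[m] = xc, fc
            else:
                # shrink every vertex toward the best
                simplex[1:] = (1.0 - cfg.kappa) * simplex[0] + cfg.kappa * simplex[1:]
                fvals[1:] = [f(v) for v in simplex[1:]]
                n_fev += m

    order = np.argsort(fvals, kind="stable")
    best = order[0]
    return NMResult(simplex[best].copy(), float(fvals[best]), it, converged, n_fev)
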