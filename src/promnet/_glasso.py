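"""Numba-compiled block coordinate-descent solver for the graphical lasso.

Solves, for a correlation/covariance matrix S and penalty lam >= 0,

    maximize  log det(Theta) - trace(S Theta) - lam * sum_{i != j} |Theta_ij|

over symmetric positive-definite Theta. The diagonal is unpenalized. The
algorithm sweeps columns of the working covariance W, solving each column's
lasso subproblem by coordinate descent (Friedman-style), and supports warm
starts across a descending penalty path via (W, B) state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_iter, inner_max_iter):
    """One glasso solve. W and B are modified in place (warm-start state).

    W is the working covariance (diagonal held at S_jj since the diagonal
    of Theta is unpenalized), B[:, j] the
    lasso coefficients of column j. Returns (Theta, n_sweeps, converged).
    """
    p = S.shape[0]
    # off-diagonal mean |S| sets the convergence scale, as in glasso
    s_scale = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_scale += abs(S[i, j])
    s_scale /= p * (p - 1) if p > 1 else 1.0
    if s_scale <= 0.0:
        s_scale = 1.0
    thr = tol * s_scale
    inner_thr = 0.1 * thr

    converged = False
    sweeps = 0
    for _ in range(max_iter):
        sweeps += 1
        max_dw = 0.0
        for j in range(p):
            # lasso: minimize .5 b' W11 b - s12' b + lam |b|_1
            for _ in range(inner_max_iter):
                max_db = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    if r > lam:
                        bnew = (r - lam) / W[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W[k, k]
                    else:
                        bnew = 0.0
                    d = abs(bnew - B[k, j])
                    if d > max_db:
                        max_db = d
                    B[k, j] = bnew
                if max_db < inner_thr:
                    break
            # w12 <- W11 beta
            for k in range(p):
                if k == j:
                    continue
                wnew = 0.0
                for l in range(p):
                    if l != j:
                        wnew += W[k, l] * B[l, j]
                d = abs(wnew - W[k, j])
                if d > max_dw:
                    max_dw = d
                W[k, j] = wnew
                W[j, k] = wnew
        if max_dw < thr:
            converged = True
            break

    # recover Theta from (W, B): theta_jj = 1/(w22 - w12' beta),
    # theta_12 = -beta * theta_jj
    Theta = np.zeros((p, p))
    for j in range(p):
        q = W[j, j]
        for l in range(p):
            if l != j:
                q -= W[l, j] * B[l, j]
        tjj = 1.0 / q
        Theta[j, j] = tjj
        for k in range(p):
            if k != j:
                Theta[k, j] = -B[k, j] * tjj
    # symmetrize (columns are solved separately); exact zeros survive only
    # if both directions are zero, matching the support of B
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] == 0.0 or Theta[j, i] == 0.0:
                v = 0.0
            else:
                v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return Theta, sweeps, converged


def glasso_path_state(S: np.ndarray, lam: float):
    """Fresh warm-start state (W, B) for a penalty path starting at lam."""
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    return W, B


def glasso_solve(
    S: np.ndarray,
    lam: float,
    state: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    inner_max_iter: int = 200,
):
    """Solve one glasso problem, optionally warm-starting from `state`.

    Returns (Theta, state, converged); pass `state` back in for the next
    (smaller) penalty on the same S.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if state is None:
        W, B = glasso_path_state(S, lam)
    else:
        W, B = state
        np.fill_diagonal(W, np.diag(S))
    Theta, _, converged = _glasso_cd(
        S, float(lam), W, B, float(tol), int(max_iter), int(inner_max_iter)
    )
    return Theta, (W, B), converged
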