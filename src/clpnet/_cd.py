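"""Numba kernels: cyclic coordinate descent for the LASSO on Gram matrices.

The objective is ``(1/(2n))‖y − Xβ‖² + λ Σ_j pf_j |β_j|`` with per-column
penalty factors (pf_j = 0 leaves a column unpenalized, used for adjustment
covariates). Working on ``G = XᵀX/n`` and ``c = Xᵀy/n`` (glmnet's
"covariance updates") makes a full sweep O(p²), independent of n, which is
what lets the bootstrap and case-dropping procedures re-run the whole
cross-validated fit thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_gram(G, c, lam, pf, beta, max_sweeps, tol):
    """Cyclic coordinate descent on the Gram form; updates ``beta`` in place.

    Returns the number of sweeps used, or -1 on non-convergence.
    Convergence: max absolute coefficient change in a sweep < tol.
    """
    p = c.shape[0]
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            s = 0.0
            for k in range(p):
                s += G[j, k] * beta[k]
            rho = c[j] - s + gjj * beta[j]
            t = lam * pf[j]
            if rho > t:
                bj = (rho - t) / gjj
            elif rho < -t:
                bj = (rho + t) / gjj
            else:
                bj = 0.0
            d = bj - beta[j]
            if d < 0.0:
                d = -d
            if d > max_delta:
                max_delta = d
            beta[j] = bj
        if max_delta < tol:
            return sweep + 1
    return -1


@njit(cache=True)
def path_gram(G, c, lams, pf, tol, max_sweeps):
    """Warm-started solution path over a descending λ grid.

    Returns ``(betas, fail)`` with ``betas[l]`` the solution at ``lams[l]``
    and ``fail`` the first grid index that failed to converge (-1 if none).
    """
    p = c.shape[0]
    nl = lams.shape[0]
    betas = np.zeros((nl, p))
    beta = np.zeros(p)
    for l in range(nl):
        ok = cd_gram(G, c, lams[l], pf, beta, max_sweeps, tol)
        if ok < 0:
            return betas, l
        betas[l] = beta
    return betas, -1
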