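"""Minimum-residual exploratory factor analysis with promax rotation and
the Schmid-Leiman orthogonalization, on numpy/scipy only.

These are the standard EFA building blocks: minres fits uniquenesses by
minimizing the off-diagonal residual sum of squares; varimax/promax give
an oblique primary solution; Schmid-Leiman re-expresses it as one general
factor plus orthogonalized group factors via a second-order one-factor
model on the primary-factor correlations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, n_factors: int) -> np.ndarray:
    Rr = R - np.diag(psi)
    vals, vecs = np.linalg.eigh(Rr)
    idx = np.argsort(vals)[::-1][:n_factors]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)[None, :]


def minres_efa(R: np.ndarray, n_factors: int):
    """Minres factor analysis of a correlation matrix.

    Returns (loadings p x m, uniquenesses). Starting uniquenesses are
    1 - SMC (squared multiple correlations).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    off = ~np.eye(p, dtype=bool)

    def objective(psi):
        L = _loadings_from_psi(R, psi, n_factors)
        resid = R - L @ L.T
        return float((resid[off] ** 2).sum())

    res = minimize(objective, psi0, method="L-BFGS-B",
                   bounds=[(0.005, 1.0)] * p, options={"maxiter": 500})
    psi = res.x
    L = _loadings_from_psi(R, psi, n_factors)
    # sign convention: each factor's largest-|loading| item loads positively
    for f in range(L.shape[1]):
        j = np.argmax(np.abs(L[:, f]))
        if L[j, f] < 0:
            L[:, f] = -L[:, f]
    return L, psi


def varimax(L: np.ndarray) -> np.ndarray:
    """Orthogonal varimax rotation (via statsmodels' GPA rotation)."""
    if L.shape[1] < 2:
        return L.copy()
    from statsmodels.multivariate.factor_rotation import rotate_factors

    V, _ = rotate_factors(L, "varimax")
    return V


def promax(L: np.ndarray, power: int = 4):
    """Oblique promax rotation.

    Returns (pattern matrix, factor correlation matrix Phi).
    """
    p, m = L.shape
    if m < 2:
        return L.copy(), np.eye(1)
    V = varimax(L)
    # target: varimax loadings raised to `power`, signs kept
    target = V * np.abs(V) ** (power - 1)
    coef = np.linalg.lstsq(V, target, rcond=None)[0]
    diag_inv = np.diag(np.linalg.pinv(coef.T @ coef))
    coef = coef @ np.diag(np.sqrt(diag_inv))
    pattern = V @ coef
    Phi = np.linalg.inv(coef.T @ coef)
    for f in range(m):
        j = np.argmax(np.abs(pattern[:, f]))
        if pattern[j, f] < 0:
            pattern[:, f] = -pattern[:, f]
            Phi[f, :] *= -1
            Phi[:, f] *= -1
    return pattern, Phi


def schmid_leiman(pattern: np.ndarray, Phi: np.ndarray):
    """Schmid-Leiman orthogonalization of an oblique primary solution.

    A one-factor model on the primary-factor correlations ``Phi`` gives
    second-order loadings gamma; general loadings are ``pattern @ gamma``
    and group loadings ``pattern * sqrt(1 - gamma^2)`` per factor.
    Returns (general p-vector, group p x m matrix).
    """
    m = Phi.shape[0]
    if m == 1:
        return pattern[:, 0].copy(), np.zeros((pattern.shape[0], 1))
    if m == 2:
        # one factor on two variables is underdetermined; the standard
        # convention splits the correlation equally
        phi = np.clip(Phi[0, 1], 0.0, 1.0)
        gamma = np.full(2, np.sqrt(phi))
    else:
        L2, _ = minres_efa(Phi, 1)
        gamma = np.clip(L2[:, 0], -0.999, 0.999)
        if gamma.sum() < 0:
            gamma = -gamma
    general = pattern @ gamma
    group = pattern * np.sqrt(np.clip(1.0 - gamma**2, 0.0, 1.0))[None, :]
    return general, group
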