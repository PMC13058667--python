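"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route independent of the library
implementation it checks: brute-force grid search for the tetrachoric MLE
and MAP factor scores, a plain eigenvalue-clipping iteration for the
nearest correlation matrix, and the two-way mean-squares decomposition for
the agreement ICC.
"""

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import multivariate_normal


def bvn_cdf_genz(h: float, k: float, rho: float) -> float:
    """Bivariate normal CDF via scipy's Genz quadrature (independent route)."""
    return float(multivariate_normal(mean=[0.0, 0.0],
                                     cov=[[1.0, rho], [rho, 1.0]]).cdf([h, k]))


def tetrachoric_grid(n00, n01, n10, n11, step=1e-4, zero_cell_add=0.5):
    """Brute-force tetrachoric MLE: grid search of the likelihood over rho.

    Uses the same cell-probability construction as the library (thresholds
    fixed at the margin probits) but a dense grid instead of an optimizer,
    so disagreements isolate the optimization step.
    """
    from spectra.tetra import pair_loglik, PairTable

    cells = (n00, n01, n10, n11)
    if zero_cell_add and any(c == 0 for c in cells):
        cells = tuple(c + zero_cell_add for c in cells)
    table = PairTable(*cells)
    n = table.total
    tau_x = ndtri(1.0 - (table.n10 + table.n11) / n)
    tau_y = ndtri(1.0 - (table.n01 + table.n11) / n)
    grid = np.arange(-0.999, 0.999 + step / 2, step)
    ll = pair_loglik(table, tau_x, tau_y, grid)
    return float(grid[int(np.argmax(ll))])


def nearest_corr_clip_iteration(R, tol=1e-10, max_iter=2000):
    """Alternating eigenvalue clipping / unit-diagonal reset, run to a tight
    tolerance (independent of the library's smoother)."""
    X = np.asarray(R, dtype=float).copy()
    for _ in range(max_iter):
        prev = X.copy()
        w, v = np.linalg.eigh(X)
        X = (v * np.maximum(w, 0.0)) @ v.T
        X = (X + X.T) / 2.0
        np.fill_diagonal(X, 1.0)
        if np.max(np.abs(X - prev)) < tol:
            break
    return X


def icc_a1_mean_squares(x, y):
    """ICC(A,1) by explicit two-way mean squares (McGraw & Wong)."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = data - data.mean(axis=1, keepdims=True) \
        - data.mean(axis=0, keepdims=True) + grand
    ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))


def map_score_grid(y, lam, tau, uniq, lo=-4.0, hi=4.0, step=1e-3):
    """Dense 1-D grid search for the MAP factor score of one response
    pattern under a single-factor probit measurement model."""
    eta = np.arange(lo, hi + step / 2, step)
    z = (np.outer(eta, lam) - tau[None, :]) / np.sqrt(uniq)[None, :]
    s = 2.0 * np.asarray(y, float) - 1.0
    ll = log_ndtr(s[None, :] * z).sum(axis=1) - 0.5 * eta ** 2
    return float(eta[int(np.argmax(ll))])


def dichotomized_bvn_sample(rho, n, rng, tau1=0.0, tau2=0.0):
    """Sample a 2x2 table by dichotomizing correlated normals."""
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
    return (x > tau1).astype(int), (y > tau2).astype(int)
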