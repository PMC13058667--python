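"""Tetrachoric correlation estimation.

The tetrachoric correlation treats each binary diagnosis as a dichotomized
standard-normal liability: diagnosis present iff liability > threshold tau,
with tau = probit(1 - prevalence).  For a pair of diagnoses the 2x2 table of
joint counts identifies the correlation of the two liabilities.

Estimation is two-step: thresholds are fixed at the univariate probit
estimates from the margins, then rho maximizes the bivariate-normal
likelihood of the four cell counts (a 1-D problem).  Pairwise matrices
assembled this way can be indefinite, so a nearest-correlation-matrix
smoother (alternating projections) is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

logger = logging.getLogger(__name__)

__all__ = [
    "PairTable",
    "PairEstimate",
    "TetrachoricResult",
    "bvn_cdf",
    "tetrachoric_mle",
    "pair_tables",
    "correlation_matrix",
    "nearest_pd",
    "heatmap_order",
    "plot_heatmap",
]

#: estimates are clipped to +/- (1 - RHO_EPS)
RHO_EPS = 1e-3
RHO_BOUND = 1.0 - RHO_EPS


@dataclass(frozen=True)
class PairTable:
    """Joint 2x2 counts for a pair of binary variables.

    ``n10`` counts rows with x = 1, y = 0; margins follow from the cells.
    """

    n00: float
    n01: float
    n10: float
    n11: float

    @property
    def total(self) -> float:
        return self.n00 + self.n01 + self.n10 + self.n11

    def __post_init__(self) -> None:
        cells = (self.n00, self.n01, self.n10, self.n11)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell count in {cells}")
        if self.total <= 0:
            raise ValueError("empty 2x2 table")

    @classmethod
    def from_binary(cls, x: np.ndarray, y: np.ndarray) -> "PairTable":
        x = np.asarray(x, dtype=bool)
        y = np.asarray(y, dtype=bool)
        n11 = float(np.sum(x & y))
        n10 = float(np.sum(x & ~y))
        n01 = float(np.sum(~x & y))
        n00 = float(np.sum(~x & ~y))
        return cls(n00=n00, n01=n01, n10=n10, n11=n11)


@dataclass(frozen=True)
class PairEstimate:
    rho: float
    tau_row: float
    tau_col: float
    converged: bool
    corrected: bool = False
    message: str = ""


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)``.

    Evaluated through Owen's T function (absolute error ~1e-15), with the
    degenerate cases |rho| = 1 and h = k = 0 handled in closed form.
    Broadcasts over array inputs.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    hi = rho >= 1.0
    lo = rho <= -1.0
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):
        out[lo] = np.maximum(ndtr(h[lo]) + ndtr(k[lo]) - 1.0, 0.0)
    if np.any(mid):
        out[mid] = _bvn_owen(h[mid], k[mid], rho[mid])
    if out.ndim == 0:
        return float(out)
    return np.clip(out, 0.0, 1.0)


def _owens_t_term(x, a_num, a_den):
    """Owen's T(x, a) with a = a_num / a_den, robust to a_den == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = a_num / a_den
    finite = np.isfinite(a)
    t = np.empty(x.shape, dtype=float)
    if np.any(finite):
        t[finite] = owens_t(x[finite], a[finite])
    inf = ~finite
    if np.any(inf):
        # T(x, +/-inf) = sign(a) * Phi(-|x|)/2 ; when x == 0 this is +/- 1/4
        sign = np.sign(a_num[inf])
        sign[sign == 0.0] = 1.0
        t[inf] = sign * 0.5 * ndtr(-np.abs(x[inf]))
    return t


def _bvn_owen(h, k, rho):
    """Owen (1956): Phi2(h,k,rho) for |rho| < 1, array inputs."""
    denom = np.sqrt(1.0 - rho * rho)
    t_h = _owens_t_term(h, k - rho * h, h * denom)
    t_k = _owens_t_term(k, h - rho * k, k * denom)
    hk = h * k
    beta = np.where((hk < 0) | ((hk == 0) & (h + k < 0)), 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - t_h - t_k - beta
    # both arguments exactly at the median: closed form
    origin = (h == 0) & (k == 0)
    if np.any(origin):
        out[origin] = 0.25 + np.arcsin(rho[origin]) / (2.0 * np.pi)
    return np.clip(out, 0.0, 1.0)


def _cell_probs(tau_x, tau_y, rho):
    """Cell probabilities (p00, p01, p10, p11) of the dichotomized BVN."""
    p11 = bvn_cdf(-tau_x, -tau_y, rho)
    px = ndtr(-tau_x)
    py = ndtr(-tau_y)
    p10 = px - p11
    p01 = py - p11
    p00 = 1.0 - px - py + p11
    return p00, p01, p10, p11


def pair_loglik(table: PairTable, tau_x: float, tau_y: float, rho) -> np.ndarray:
    """Multinomial log-likelihood of the 2x2 counts at correlation(s) rho."""
    rho = np.asarray(rho, dtype=float)
    p00, p01, p10, p11 = _cell_probs(tau_x, tau_y, rho)
    eps = 1e-300
    ll = (
        table.n00 * np.log(np.maximum(p00, eps))
        + table.n01 * np.log(np.maximum(p01, eps))
        + table.n10 * np.log(np.maximum(p10, eps))
        + table.n11 * np.log(np.maximum(p11, eps))
    )
    return ll


def _grid_argmax(table: PairTable, tau_x: float, tau_y: float,
                 step: float = 1e-4) -> float:
    grid = np.arange(-RHO_BOUND, RHO_BOUND + step / 2, step)
    ll = pair_loglik(table, tau_x, tau_y, grid)
    return float(grid[int(np.argmax(ll))])


def tetrachoric_mle(table: PairTable, zero_cell_add: float = 0.5) -> PairEstimate:
    """Two-step tetrachoric MLE for one 2x2 table.

    Thresholds come from the margins (probit of 1 - prevalence); rho then
    maximizes the bivariate-normal likelihood over [-0.999, 0.999].  Tables
    containing a zero cell get ``zero_cell_add`` added to every cell (margins
    recomputed) before estimation.  A degenerate raw margin yields a flagged
    NaN estimate.  If the 1-D optimizer fails, a grid search takes over.
    """
    n = table.total
    raw_px = (table.n10 + table.n11) / n
    raw_py = (table.n01 + table.n11) / n
    if raw_px in (0.0, 1.0) or raw_py in (0.0, 1.0):
        return PairEstimate(
            rho=float("nan"), tau_row=float("nan"), tau_col=float("nan"),
            converged=False, message="degenerate margin",
        )

    corrected = False
    cells = (table.n00, table.n01, table.n10, table.n11)
    if zero_cell_add and any(c == 0 for c in cells):
        table = PairTable(*(c + zero_cell_add for c in cells))
        corrected = True
        n = table.total

    px = (table.n10 + table.n11) / n
    py = (table.n01 + table.n11) / n
    tau_x = float(ndtri(1.0 - px))
    tau_y = float(ndtri(1.0 - py))

    # Canonical sign handling: estimate a non-negative rho on the (possibly
    # reflected) table, then restore the sign.  This makes the estimate
    # exactly antisymmetric under recoding 0<->1 of either variable.
    if table.n00 * table.n11 == table.n01 * table.n10:
        # odds ratio exactly 1: rho-hat is exactly 0 given margin thresholds
        return PairEstimate(rho=0.0, tau_row=tau_x, tau_col=tau_y,
                            converged=True, corrected=corrected)
    flip = table.n00 * table.n11 < table.n01 * table.n10
    if flip:
        work = PairTable(n00=table.n01, n01=table.n00, n10=table.n11, n11=table.n10)
        w_tau_y = float(ndtri(1.0 - (work.n01 + work.n11) / n))
    else:
        work, w_tau_y = table, tau_y

    def neg_ll(r: float) -> float:
        return -float(pair_loglik(work, tau_x, w_tau_y, r))

    res = minimize_scalar(neg_ll, bounds=(0.0, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-10})
    converged = bool(res.success)
    rho = float(res.x)
    if not converged:
        rho = abs(_grid_argmax(work, tau_x, w_tau_y))
        converged = True
    rho = float(np.clip(rho, 0.0, RHO_BOUND))
    if flip:
        rho = -rho
    # snap tiny interior optima to zero boundary noise only via clipping; keep value
    return PairEstimate(rho=rho, tau_row=tau_x, tau_col=tau_y,
                        converged=converged, corrected=corrected)


def pair_tables(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All pairwise 2x2 counts of a 0/1 matrix, as four d x d arrays."""
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    n11 = y.T @ y
    ones = y.sum(axis=0)
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01
    return n00, n01, n10, n11


@dataclass
class TetrachoricResult:
    """Assembled tetrachoric correlation matrix with diagnostics."""

    corr: pd.DataFrame
    tau: pd.Series
    converged: pd.DataFrame
    corrected: pd.DataFrame
    smoothed: bool
    min_eig_before: float
    min_eig_after: float
    excluded: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def labels(self) -> list[str]:
        return list(self.corr.columns)


def correlation_matrix(m, smooth: bool = True,
                       zero_cell_add: float = 0.5) -> TetrachoricResult:
    """Estimate the full tetrachoric matrix of a binary diagnosis matrix.

    Diagnoses with degenerate margins (prevalence 0 or 1) are excluded and
    reported.  If the assembled matrix is indefinite and ``smooth`` is set,
    it is projected to the nearest correlation matrix.
    """
    values = np.asarray(m.values, dtype=np.int8)
    labels = list(m.labels)
    n = values.shape[0]
    prev = values.mean(axis=0)
    keep = (prev > 0.0) & (prev < 1.0)
    excluded = [lab for lab, k in zip(labels, keep) if not k]
    if excluded:
        logger.warning("excluding %d degenerate diagnoses: %s",
                       len(excluded), excluded)
    labels = [lab for lab, k in zip(labels, keep) if k]
    values = values[:, keep]
    d = len(labels)
    if d < 2:
        raise ValueError("need at least 2 non-degenerate diagnoses")

    tau = pd.Series(ndtri(1.0 - values.mean(axis=0)), index=labels, name="tau")
    n00, n01, n10, n11 = pair_tables(values)
    R = np.eye(d)
    conv = np.ones((d, d), dtype=bool)
    corr_flag = np.zeros((d, d), dtype=bool)
    for i in range(d):
        for j in range(i + 1, d):
            est = tetrachoric_mle(
                PairTable(n00=n00[i, j], n01=n01[i, j],
                          n10=n10[i, j], n11=n11[i, j]),
                zero_cell_add=zero_cell_add,
            )
            R[i, j] = R[j, i] = est.rho
            conv[i, j] = conv[j, i] = est.converged
            corr_flag[i, j] = corr_flag[j, i] = est.corrected

    if np.isnan(R).any():
        raise ValueError("NaN tetrachoric estimates despite margin screening")
    eigs = np.linalg.eigvalsh(R)
    min_before = float(eigs[0])
    smoothed = False
    min_after = min_before
    if smooth and min_before < 0.0:
        R = nearest_pd(R)
        smoothed = True
        min_after = float(np.linalg.eigvalsh(R)[0])

    return TetrachoricResult(
        corr=pd.DataFrame(R, index=labels, columns=labels),
        tau=tau,
        converged=pd.DataFrame(conv, index=labels, columns=labels),
        corrected=pd.DataFrame(corr_flag, index=labels, columns=labels),
        smoothed=smoothed,
        min_eig_before=min_before,
        min_eig_after=min_after,
        excluded=excluded,
        n=n,
    )


def nearest_pd(R: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by alternating projections.

    Alternates projection onto the PSD cone (eigenvalue clipping) with
    projection onto the unit-diagonal affine set, stopping when the max
    elementwise change between iterates falls below ``tol``.
    """
    A = np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    X = A.copy()
    for _ in range(max_iter):
        prev = X
        w, v = np.linalg.eigh(X)
        X = (v * np.maximum(w, 0.0)) @ v.T
        X = (X + X.T) / 2.0
        np.fill_diagonal(X, 1.0)
        if np.max(np.abs(X - prev)) < tol:
            break
    return X


def heatmap_order(R: pd.DataFrame, spec) -> tuple[list[str], list[int]]:
    """Order diagnoses into factor blocks for a partitioned heatmap.

    Diagnoses are grouped by their primary factor (spec order); within each
    block they are sorted by descending mean correlation with the other
    members of the block.  Returns the label order and the cumulative block
    boundaries (for drawing partition lines).
    """
    labels = list(R.columns)
    assigned = set()
    blocks: list[list[str]] = []
    for fname, inds in spec.factors:
        block = [i for i in inds if i not in assigned]
        assigned.update(block)
        blocks.append(block)
    missing = [lab for lab in labels if lab not in assigned]
    if missing:
        raise ValueError(f"diagnoses absent from model spec: {missing}")

    order: list[str] = []
    boundaries: list[int] = []
    for block in blocks:
        if len(block) > 1:
            sub = R.loc[block, block].to_numpy()
            means = (sub.sum(axis=1) - 1.0) / (len(block) - 1)
            block = [b for _, b in sorted(zip(-means, block))]
        order.extend(block)
        boundaries.append(len(order))
    return order, boundaries


def plot_heatmap(R: pd.DataFrame, order: list[str], boundaries: list[int],
                 path: str) -> None:
    """Render the block-partitioned correlation heatmap to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = R.loc[order, order].to_numpy()
    fig, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(M, vmin=-1, vmax=1, cmap="RdBu_r")
    for b in boundaries[:-1]:
        ax.axhline(b - 0.5, color="black", lw=0.8)
        ax.axvline(b - 0.5, color="black", lw=0.8)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=5)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7, label="tetrachoric r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
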