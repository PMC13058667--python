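"""External validation of the latent dimensions.

Persons are scored on the fitted factors by maximum a posteriori estimation
under the probit measurement model implied by the standardized loadings,
thresholds and uniquenesses; each external correlate is then regressed on
each standardized factor score (linear for continuous/ordinal correlates,
probit for binary ones) with person-level bootstrap standard errors, and a
Wald-type statistic (referred to Hotelling's T-squared, since the covariance
is bootstrap-estimated) tests whether a correlate's coefficient profile is
flat across dimensions.

Factor-score regression is an attenuated stand-in for joint SEM estimation
with covariates: scores are shrunken posterior modes, so coefficients are
biased toward zero relative to latent-variable regressions.  Comparative
profiles across factors remain interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.stats import chi2

from .cfa import FitResult
from .ehr_prep import BinaryDiagnosisMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FactorScores",
    "factor_scores",
    "RegressionResult",
    "regress_correlates",
    "profile_difference_test",
]

MIN_UNIQUENESS = 0.01     # scoring floor for Heywood-flagged indicators


@dataclass
class FactorScores:
    person_ids: np.ndarray
    factor_names: list[str]
    scores: np.ndarray                # n x K, liability scale
    converged: np.ndarray             # n bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.factor_names)
        df.insert(0, "person_id", self.person_ids)
        return df


def _inv_mills(a: np.ndarray) -> np.ndarray:
    """phi(a) / Phi(a), numerically stable for very negative a."""
    return np.exp(-0.5 * a * a - 0.5 * np.log(2.0 * np.pi) - log_ndtr(a))


def score_loglik(eta: np.ndarray, y: np.ndarray, L: np.ndarray,
                 phi_inv: np.ndarray, tau: np.ndarray,
                 sqrt_u: np.ndarray) -> np.ndarray:
    """Log posterior (up to a constant) of factor scores given responses."""
    z = (eta @ L.T - tau[None, :]) / sqrt_u[None, :]
    s = 2.0 * y - 1.0
    ll = log_ndtr(s * z).sum(axis=1)
    prior = -0.5 * np.einsum("nk,kl,nl->n", eta, phi_inv, eta)
    return ll + prior


def factor_scores(fit_result: FitResult, m: BinaryDiagnosisMatrix,
                  tau, max_iter: int = 50, tol: float = 1e-8) -> FactorScores:
    """Maximum a posteriori factor scores under the probit measurement model.

    For each person the mode of N(eta; 0, Phi) * prod_j P(y_j | eta) is
    found by a safeguarded Newton iteration (the posterior is log-concave,
    so this is globally convergent); P(y_j = 1 | eta) =
    Phi((lambda_j' eta - tau_j) / sqrt(u_j)).  Persons whose iteration does
    not reach tolerance are flagged and keep their best iterate.
    """
    if not fit_result.converged:
        raise ValueError("factor scores require a converged fit")
    labels = list(fit_result.loadings.index)
    L = fit_result.loadings.to_numpy()
    Phi = fit_result.factor_corr.to_numpy()
    u = np.maximum(fit_result.uniquenesses.to_numpy(), MIN_UNIQUENESS)
    sqrt_u = np.sqrt(u)
    if isinstance(tau, pd.Series):
        tau = tau.loc[labels].to_numpy()
    tau = np.asarray(tau, dtype=float)
    sub = m.subset_diagnoses(labels)
    y = sub.values.astype(float)
    n, d = y.shape
    K = L.shape[1]
    phi_inv = np.linalg.inv(Phi)

    eta = np.zeros((n, K))
    ll = score_loglik(eta, y, L, phi_inv, tau, sqrt_u)
    active = np.ones(n, dtype=bool)
    s = 2.0 * y - 1.0
    for _ in range(max_iter):
        if not active.any():
            break
        ea = eta[active]
        ya = s[active]
        z = (ea @ L.T - tau[None, :]) / sqrt_u[None, :]
        a = ya * z
        r = _inv_mills(a)
        grad = ((ya * r) / sqrt_u[None, :]) @ L - ea @ phi_inv
        w = r * (a + r)                       # -d2 log Phi(a) / dz2, >= 0
        H = phi_inv[None, :, :] + np.einsum("nj,jp,jq->npq", w / u[None, :], L, L)
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # backtracking on the log posterior (safeguard)
        ll_a = ll[active]
        new_eta = ea + step
        new_ll = score_loglik(new_eta, y[active], L, phi_inv, tau, sqrt_u)
        shrink = new_ll < ll_a - 1e-12
        t = 1.0
        for _ in range(20):
            if not shrink.any():
                break
            t *= 0.5
            new_eta[shrink] = ea[shrink] + t * step[shrink]
            new_ll[shrink] = score_loglik(new_eta[shrink], y[active][shrink],
                                          L, phi_inv, tau, sqrt_u)
            shrink = new_ll < ll_a - 1e-12
        eta_act = eta[active]
        done = np.max(np.abs(new_eta - eta_act), axis=1) < tol
        eta[active] = new_eta
        ll[active] = new_ll
        idx_active = np.flatnonzero(active)
        active[idx_active[done]] = False
    converged = ~active
    if active.any():
        logger.warning("%d persons did not reach scoring tolerance",
                       int(active.sum()))
    return FactorScores(person_ids=sub.person_ids,
                        factor_names=list(fit_result.loadings.columns),
                        scores=eta, converged=converged)


@dataclass
class RegressionResult:
    table: pd.DataFrame                       # correlate x factor coefficients
    boot: dict[str, np.ndarray]               # correlate -> (B, K) replicates
    skipped: list[str]
    attenuation_note: str = (
        "Coefficients are regressions on MAP factor scores and are "
        "attenuated relative to latent-variable regressions.")


def _linear_slopes(yv: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Simple-regression slopes of y on each column of S (with intercept)."""
    yc = yv - yv.mean()
    Sc = S - S.mean(axis=0)
    return (Sc * yc[:, None]).sum(axis=0) / (Sc ** 2).sum(axis=0)


def _probit_slopes(yv: np.ndarray, S: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    out = np.empty(S.shape[1])
    for f in range(S.shape[1]):
        X = sm.add_constant(S[:, f])
        res = sm.Probit(yv, X).fit(disp=0, maxiter=100)
        out[f] = res.params[1]
    return out


def regress_correlates(scores: FactorScores, correlates: pd.DataFrame,
                       B: int = 200, seed: int = 0) -> RegressionResult:
    """Simple regressions of each correlate on each standardized factor score.

    Continuous and ordinal correlates use OLS slopes; binary correlates use
    probit regression.  SEs and the cross-factor coefficient covariance come
    from a person-level bootstrap (the same resample is used for all factors
    of a correlate, so profiles can be tested jointly).
    """
    if correlates.empty:
        raise ValueError("no correlates supplied")
    # population SD: standardization is then invariant to row duplication
    S = scores.scores / scores.scores.std(axis=0)
    sid = pd.Index(scores.person_ids)
    rng = np.random.default_rng(seed)
    rows, boot, skipped = [], {}, []
    for name, grp in correlates.groupby("correlate", sort=False):
        grp = grp.drop_duplicates(subset="person_id")
        pos = sid.get_indexer(grp["person_id"].to_numpy())
        ok = pos >= 0
        if ok.sum() < 30:
            raise ValueError(f"correlate {name!r}: fewer than 30 overlapping persons")
        yv = grp["value"].to_numpy(dtype=float)[ok]
        Sv = S[pos[ok]]
        kind = str(grp["type"].iloc[0])
        if np.std(yv) == 0:
            skipped.append(name)
            logger.warning("correlate %r has zero variance; skipped", name)
            continue
        slope_fn = _probit_slopes if kind == "binary" else _linear_slopes
        coefs = slope_fn(yv, Sv)
        reps = np.empty((B, len(scores.factor_names)))
        nn = len(yv)
        for b in range(B):
            idx = rng.integers(0, nn, nn)
            yb = yv[idx]
            if yb.min() == yb.max():      # degenerate resample
                reps[b] = np.nan
                continue
            reps[b] = slope_fn(yb, Sv[idx])
        reps = reps[~np.isnan(reps).any(axis=1)]
        ses = reps.std(axis=0, ddof=1)
        boot[name] = reps
        for f, fname in enumerate(scores.factor_names):
            rows.append({"correlate": name, "factor": fname, "type": kind,
                         "coef": float(coefs[f]), "se": float(ses[f]),
                         "n": int(nn)})
    table = pd.DataFrame(rows)
    return RegressionResult(table=table, boot=boot, skipped=skipped)


def profile_difference_test(result: RegressionResult) -> pd.DataFrame:
    """Wald-type test that a correlate's coefficients are equal across
    factors, using the bootstrap covariance of the coefficient vector.

    Because the covariance is estimated from B bootstrap replicates rather
    than known, the statistic is referred to Hotelling's T-squared
    distribution (an F with q and B - q degrees of freedom) instead of a
    chi-square; treating the covariance as known is anti-conservative at
    moderate B.  A singular bootstrap covariance is handled by a
    generalized inverse (flagged); per-pair contrasts are reported
    separately by ``pairwise_contrasts``.
    """
    from scipy.stats import f as f_dist

    rows = []
    for name, reps in result.boot.items():
        sub = result.table[result.table["correlate"] == name]
        b = sub.sort_index()["coef"].to_numpy()
        K = len(b)
        if K < 2:
            raise ValueError(f"correlate {name!r}: need >= 2 factors")
        B = reps.shape[0]
        V = np.cov(reps.T)
        C = np.eye(K)[1:] - np.eye(K)[0]           # differences vs first factor
        M = C @ V @ C.T
        rank = int(np.linalg.matrix_rank(M))
        singular = rank < K - 1
        Minv = np.linalg.pinv(M)
        cb = C @ b
        stat = float(cb @ Minv @ cb)
        q = rank
        if B > q + 1:
            f_stat = stat * (B - q) / (q * (B - 1))
            p = float(f_dist.sf(f_stat, q, B - q))
        else:   # too few replicates for the T^2 reference; fall back
            p = float(chi2.sf(stat, q))
        rows.append({"correlate": name, "stat": stat, "df": q,
                     "n_boot": B, "p_value": p,
                     "singular_cov": singular})
    return pd.DataFrame(rows)


def pairwise_contrasts(result: RegressionResult) -> pd.DataFrame:
    """z-tests of coefficient differences for every factor pair."""
    from scipy.stats import norm

    rows = []
    for name, reps in result.boot.items():
        sub = result.table[result.table["correlate"] == name]
        factors = sub["factor"].tolist()
        b = sub["coef"].to_numpy()
        V = np.cov(reps.T)
        for i in range(len(factors)):
            for j in range(i + 1, len(factors)):
                diff = b[i] - b[j]
                se = float(np.sqrt(max(V[i, i] + V[j, j] - 2 * V[i, j], 0.0)))
                z = diff / se if se > 0 else float("inf") * np.sign(diff)
                rows.append({"correlate": name, "factor_a": factors[i],
                             "factor_b": factors[j], "diff": float(diff),
                             "se": se, "z": float(z),
                             "p_value": float(2 * norm.sf(abs(z)))})
    return pd.DataFrame(rows)
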