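"""Confirmatory factor analysis on a tetrachoric correlation matrix.

Models are expressed in a small SEM-style text language::

    Fear =~ agoraphobia + panic disorder + OCD
    Distress =~ MDD + dysthymia
    MDD ~~ dysthymia          # correlated residual
    general: on               # bifactor: add a general factor on everything

An indicator's primary factor is the first factor on which it appears;
later appearances are cross-loadings.  Correlated-factors models leave the
factor correlation matrix Phi free; bifactor models make all factors
(general and specifics) mutually orthogonal by default.

Fitting minimizes the weighted least-squares discrepancy

    F(theta) = sum_{i<j} w_ij (r_ij - sigma_ij(theta))^2

over the unique off-diagonal cells, where Sigma(theta) = Lambda Phi Lambda'
+ Theta and Theta's diagonal is set so diag(Sigma) = 1 (standardized
solution).  ULS uses w = 1; DWLS uses reciprocal sampling variances of the
tetrachorics estimated by a person-level jackknife of batches.  T =
(n - 1) * F is reported as a pseudo-chi-square for comparative index
computation only; it is not calibrated to a chi-square distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ehr_prep import BinaryDiagnosisMatrix

__all__ = [
    "ModelSpec",
    "FitIndices",
    "FitResult",
    "BootstrapResult",
    "parse_model",
    "implied_matrix",
    "fit",
    "fit_indices",
    "bootstrap_se",
    "pairwise_variance_jackknife",
]

GENERAL_FACTOR = "G"

#: deterministic multi-start loading values; Phi starts at 0.3, residuals at 0
START_LOADINGS = (0.3, 0.4, 0.5, 0.6, 0.7)
HEYWOOD_UNIQUENESS = -0.05  # soft flag bound; optimizer itself bounds loadings


@dataclass(frozen=True)
class ModelSpec:
    """Parsed factor model: loading pattern, residual pairs, bifactor flag."""

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    residual_pairs: tuple[tuple[str, str], ...] = ()
    bifactor: bool = False

    def __post_init__(self) -> None:
        names = [f for f, _ in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if GENERAL_FACTOR in names and self.bifactor:
            raise ValueError(f"factor name {GENERAL_FACTOR!r} is reserved")
        seen = set()
        for a, b in self.residual_pairs:
            if a == b:
                raise ValueError(f"residual pair ({a!r}, {a!r}) is degenerate")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate residual pair ({a!r}, {b!r})")
            seen.add(key)
        for fname, inds in self.factors:
            if len(set(inds)) != len(inds):
                raise ValueError(f"duplicate indicator on factor {fname!r}")

    # -- structure queries --------------------------------------------------
    @property
    def indicators(self) -> list[str]:
        out, seen = [], set()
        for _, inds in self.factors:
            for i in inds:
                if i not in seen:
                    seen.add(i)
                    out.append(i)
        return out

    @property
    def factor_names(self) -> list[str]:
        names = [f for f, _ in self.factors]
        if self.bifactor:
            names.append(GENERAL_FACTOR)
        return names

    def primary_factor(self, indicator: str) -> str:
        for fname, inds in self.factors:
            if indicator in inds:
                return fname
        raise KeyError(indicator)

    @property
    def cross_loadings(self) -> list[tuple[str, str]]:
        out, seen = [], set()
        for fname, inds in self.factors:
            for i in inds:
                if i in seen:
                    out.append((i, fname))
                else:
                    seen.add(i)
        return out

    @property
    def loading_entries(self) -> list[tuple[str, str]]:
        """Free loading cells as (indicator, factor), pattern order."""
        entries = [(i, f) for f, inds in self.factors for i in inds]
        if self.bifactor:
            entries.extend((i, GENERAL_FACTOR) for i in self.indicators)
        return entries

    @property
    def n_free(self) -> int:
        k = len(self.factors)
        n_phi = 0 if self.bifactor else k * (k - 1) // 2
        return len(self.loading_entries) + n_phi + len(self.residual_pairs)

    @property
    def df(self) -> int:
        d = len(self.indicators)
        return d * (d - 1) // 2 - self.n_free

    # -- construction helpers ----------------------------------------------
    def drop_indicator(self, indicator: str) -> "ModelSpec":
        factors = tuple(
            (f, tuple(i for i in inds if i != indicator))
            for f, inds in self.factors
        )
        factors = tuple((f, inds) for f, inds in factors if inds)
        pairs = tuple(p for p in self.residual_pairs if indicator not in p)
        return ModelSpec(factors=factors, residual_pairs=pairs,
                         bifactor=self.bifactor)

    def with_residual(self, a: str, b: str) -> "ModelSpec":
        return replace(self, residual_pairs=self.residual_pairs + ((a, b),))

    def with_cross_loading(self, indicator: str, factor: str) -> "ModelSpec":
        factors = tuple(
            (f, inds + (indicator,)) if f == factor else (f, inds)
            for f, inds in self.factors
        )
        return replace(self, factors=factors)

    def to_text(self) -> str:
        lines = [f"{f} =~ " + " + ".join(inds) for f, inds in self.factors]
        lines += [f"{a} ~~ {b}" for a, b in self.residual_pairs]
        if self.bifactor:
            lines.append("general: on")
        return "\n".join(lines) + "\n"


_FACTOR_RE = re.compile(r"^(?P<name>[^=~]+?)\s*=~\s*(?P<inds>.+)$")
_RESID_RE = re.compile(r"^(?P<a>.+?)\s*~~\s*(?P<b>.+)$")
_GENERAL_RE = re.compile(r"^general\s*:\s*(?P<val>on|off)$", re.IGNORECASE)


def parse_model(text: str) -> ModelSpec:
    """Parse the model mini-language into a ModelSpec.

    Malformed lines raise with their line number; structural violations
    (duplicate residual pairs, duplicate factors, negative df) also raise.
    """
    factors: list[tuple[str, tuple[str, ...]]] = []
    pairs: list[tuple[str, str]] = []
    bifactor = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _GENERAL_RE.match(line)
        if m:
            bifactor = m.group("val").lower() == "on"
            continue
        m = _FACTOR_RE.match(line)
        if m and "~~" not in line:
            name = m.group("name").strip()
            inds = tuple(s.strip() for s in m.group("inds").split("+"))
            if not name or any(not i for i in inds):
                raise ValueError(f"line {lineno}: malformed factor line {raw!r}")
            factors.append((name, inds))
            continue
        m = _RESID_RE.match(line)
        if m:
            a, b = m.group("a").strip(), m.group("b").strip()
            if not a or not b:
                raise ValueError(f"line {lineno}: malformed residual line {raw!r}")
            pairs.append((a, b))
            continue
        raise ValueError(f"line {lineno}: cannot parse {raw!r}")
    if not factors:
        raise ValueError("model defines no factors")
    spec = ModelSpec(factors=tuple(factors), residual_pairs=tuple(pairs),
                     bifactor=bifactor)
    if spec.df < 0:
        raise ValueError(
            f"model has negative degrees of freedom ({spec.df}): "
            f"{spec.n_free} free parameters for {len(spec.indicators)} indicators")
    return spec


# ---------------------------------------------------------------------------
# Parameter layout and implied matrix
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    spec: ModelSpec
    indicators: list[str]
    factor_names: list[str]
    load_cells: list[tuple[int, int]]        # (row, col) in Lambda
    phi_cells: list[tuple[int, int]]         # (p, q) p < q in Phi
    resid_cells: list[tuple[int, int]]       # (i, j) i < j in Theta

    @classmethod
    def build(cls, spec: ModelSpec) -> "_Layout":
        indicators = spec.indicators
        iidx = {v: i for i, v in enumerate(indicators)}
        fnames = spec.factor_names
        fidx = {v: i for i, v in enumerate(fnames)}
        load_cells = [(iidx[i], fidx[f]) for i, f in spec.loading_entries]
        k = len(spec.factors)
        phi_cells = ([] if spec.bifactor else
                     [(p, q) for p in range(k) for q in range(p + 1, k)])
        resid_cells = []
        for a, b in spec.residual_pairs:
            if a not in iidx or b not in iidx:
                raise KeyError(f"residual pair ({a!r}, {b!r}) references an "
                               "indicator absent from the model")
            i, j = sorted((iidx[a], iidx[b]))
            resid_cells.append((i, j))
        return cls(spec=spec, indicators=indicators, factor_names=fnames,
                   load_cells=load_cells, phi_cells=phi_cells,
                   resid_cells=resid_cells)

    @property
    def n_par(self) -> int:
        return len(self.load_cells) + len(self.phi_cells) + len(self.resid_cells)

    def split(self, x: np.ndarray):
        nl, np_ = len(self.load_cells), len(self.phi_cells)
        return x[:nl], x[nl:nl + np_], x[nl + np_:]

    def matrices(self, x: np.ndarray):
        lam, phi, th = self.split(x)
        d, K = len(self.indicators), len(self.factor_names)
        L = np.zeros((d, K))
        for val, (i, m) in zip(lam, self.load_cells):
            L[i, m] = val
        P = np.eye(K)
        for val, (p, q) in zip(phi, self.phi_cells):
            P[p, q] = P[q, p] = val
        T = np.zeros((d, d))
        for val, (i, j) in zip(th, self.resid_cells):
            T[i, j] = T[j, i] = val
        return L, P, T


def implied_matrix(spec: ModelSpec, loadings: np.ndarray,
                   factor_corr: np.ndarray | None = None,
                   residuals: dict[tuple[str, str], float] | None = None
                   ) -> np.ndarray:
    """Model-implied correlation matrix Sigma = Lambda Phi Lambda' + Theta.

    ``loadings`` is d x K in the spec's indicator/factor order (general
    factor last for bifactor specs).  Theta's diagonal is chosen so that
    diag(Sigma) is exactly 1; off-diagonal cells hold the given residual
    correlations.
    """
    L = np.asarray(loadings, dtype=float)
    K = len(spec.factor_names)
    P = np.eye(K) if factor_corr is None else np.asarray(factor_corr, float)
    S = L @ P @ L.T
    if residuals:
        iidx = {v: i for i, v in enumerate(spec.indicators)}
        for (a, b), val in residuals.items():
            i, j = iidx[a], iidx[b]
            S[i, j] += val
            S[j, i] += val
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


@dataclass
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    degenerate_null: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"CFI": self.cfi, "TLI": self.tli,
                "RMSEA": self.rmsea, "SRMR": self.srmr}


def fit_indices(T: float, df: int, T_null: float, df_null: int, n: int,
                residuals: np.ndarray) -> FitIndices:
    """Comparative fit indices from pseudo-chi-squares and residuals.

    ``residuals`` holds r_ij - sigma_ij over the unique off-diagonal cells
    (used for SRMR).  CFI/TLI compare against the independence null (all
    off-diagonal correlations zero).  These are comparative, not calibrated.
    """
    if df <= 0 or df_null <= 0 or n <= 1:
        raise ValueError("need df > 0, df_null > 0 and n > 1")
    residuals = np.asarray(residuals, dtype=float)
    degenerate = T_null <= df_null
    num = max(T - df, 0.0)
    den = max(T_null - df_null, T - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    cfi = float(np.clip(cfi, 0.0, 1.0))
    null_ratio = T_null / df_null
    if null_ratio > 1.0:
        tli = (null_ratio - T / df) / (null_ratio - 1.0)
        tli = float(np.clip(tli, 0.0, 1.0))
    else:
        tli = float("nan")
        degenerate = True
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    srmr = float(np.sqrt(np.mean(residuals ** 2))) if residuals.size else 0.0
    return FitIndices(cfi=cfi, tli=tli, rmsea=rmsea, srmr=srmr,
                      degenerate_null=degenerate)


@dataclass
class FitResult:
    """Standardized CFA solution with fit and convergence diagnostics."""

    spec: ModelSpec
    loadings: pd.DataFrame            # d x K standardized loadings
    factor_corr: pd.DataFrame         # K x K
    residual_corrs: dict[tuple[str, str], float]
    uniquenesses: pd.Series
    discrepancy: float                # F-hat
    T: float                          # (n - 1) * F-hat, pseudo-chi-square
    df: int
    n: int
    indices: FitIndices
    converged: bool
    heywood: list[str]
    estimator: str
    sample_corr: pd.DataFrame
    n_free: int
    start_index: int
    loading_se: pd.DataFrame | None = None

    @property
    def implied(self) -> pd.DataFrame:
        S = implied_matrix(self.spec, self.loadings.to_numpy(),
                           self.factor_corr.to_numpy(), self.residual_corrs)
        return pd.DataFrame(S, index=self.loadings.index,
                            columns=self.loadings.index)

    def primary_loadings(self) -> pd.Series:
        """Each indicator's loading on its primary (first-listed) factor."""
        vals = {ind: self.loadings.at[ind, self.spec.primary_factor(ind)]
                for ind in self.spec.indicators}
        return pd.Series(vals, name="loading")

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for ind, fac in self.spec.loading_entries:
            se = (self.loading_se.at[ind, fac]
                  if self.loading_se is not None else np.nan)
            rows.append(("loading", ind, fac,
                         self.loadings.at[ind, fac], se))
        for (p, q) in [(p, q) for p in range(len(self.spec.factors))
                       for q in range(p + 1, len(self.spec.factors))]:
            if self.spec.bifactor:
                break
            fp, fq = self.spec.factors[p][0], self.spec.factors[q][0]
            rows.append(("factor_corr", fp, fq,
                         self.factor_corr.at[fp, fq], np.nan))
        for (a, b), v in self.residual_corrs.items():
            rows.append(("residual_corr", a, b, v, np.nan))
        return pd.DataFrame(rows, columns=["kind", "lhs", "rhs", "estimate", "se"])


def _extract_corr(R, labels: list[str]) -> pd.DataFrame:
    if not isinstance(R, (pd.DataFrame, np.ndarray)) and hasattr(R, "corr"):
        R = R.corr                  # TetrachoricResult
    if isinstance(R, pd.DataFrame):
        missing = [lab for lab in labels if lab not in R.columns]
        if missing:
            raise KeyError(f"indicators absent from correlation matrix: {missing}")
        return R.loc[labels, labels]
    R = np.asarray(R, dtype=float)
    if R.shape != (len(labels), len(labels)):
        raise ValueError("unlabeled matrix shape does not match model indicators")
    return pd.DataFrame(R, index=labels, columns=labels)


def _residual_and_jac(x, layout, r_obs, sqrt_w, ii, jj, want_jac):
    L, P, Th = layout.matrices(x)
    S = L @ P @ L.T
    sig = S[ii, jj] + Th[ii, jj]
    res = sqrt_w * (r_obs - sig)
    if not want_jac:
        return res, None
    M = L @ P                                  # d x K
    J = np.zeros((len(ii), layout.n_par))
    col = 0
    for (a, m) in layout.load_cells:
        dcol = np.where(ii == a, M[jj, m], 0.0) + np.where(jj == a, M[ii, m], 0.0)
        J[:, col] = -sqrt_w * dcol
        col += 1
    for (p, q) in layout.phi_cells:
        dcol = L[ii, p] * L[jj, q] + L[ii, q] * L[jj, p]
        J[:, col] = -sqrt_w * dcol
        col += 1
    for (i, j) in layout.resid_cells:
        dcol = ((ii == i) & (jj == j)) | ((ii == j) & (jj == i))
        J[:, col] = -sqrt_w * dcol.astype(float)
        col += 1
    return res, J


def fit(R, n: int, spec: ModelSpec, estimator: str = "uls",
        weights: np.ndarray | None = None,
        extra_starts: list[np.ndarray] | None = None) -> FitResult:
    """Fit a factor model to a (smoothed) correlation matrix.

    Multi-start weighted least squares with analytic Jacobian; the best of
    five deterministic starts (plus any ``extra_starts`` in layout order)
    wins, ties broken by the first start.  The standardized solution fixes
    factor variances at 1; sign indeterminacy is resolved by making every
    factor's loading sum non-negative.
    """
    layout = _Layout.build(spec)
    labels = layout.indicators
    d = len(labels)
    if spec.df < 0:
        raise ValueError(f"model df must be non-negative (df = {spec.df})")
    Rm = _extract_corr(R, labels).to_numpy()
    ii, jj = np.triu_indices(d, k=1)
    r_obs = Rm[ii, jj]

    if estimator == "uls":
        w = np.ones_like(r_obs)
    elif estimator == "dwls":
        if weights is None:
            raise ValueError("dwls requires a pairwise weight matrix "
                             "(see pairwise_variance_jackknife)")
        W = _extract_corr(pd.DataFrame(weights.to_numpy()
                                       if isinstance(weights, pd.DataFrame)
                                       else np.asarray(weights),
                                       index=labels if not isinstance(weights, pd.DataFrame) else weights.index,
                                       columns=labels if not isinstance(weights, pd.DataFrame) else weights.columns),
                          labels).to_numpy()
        w = W[ii, jj]
        if np.any(w <= 0):
            raise ValueError("DWLS weights must be positive")
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    sqrt_w = np.sqrt(w)

    nl, npq, nr = (len(layout.load_cells), len(layout.phi_cells),
                   len(layout.resid_cells))
    lb = np.concatenate([np.full(nl, -1.2), np.full(npq, -0.999),
                         np.full(nr, -0.999)])
    ub = -lb

    starts = []
    for s in START_LOADINGS:
        x0 = np.concatenate([np.full(nl, s), np.full(npq, 0.3), np.zeros(nr)])
        starts.append(x0)
    if extra_starts:
        starts.extend(np.clip(x, lb + 1e-9, ub - 1e-9) for x in extra_starts)

    best = None
    best_idx = -1
    for sidx, x0 in enumerate(starts):
        sol = least_squares(
            lambda x: _residual_and_jac(x, layout, r_obs, sqrt_w, ii, jj, False)[0],
            x0,
            jac=lambda x: _residual_and_jac(x, layout, r_obs, sqrt_w, ii, jj, True)[1],
            bounds=(lb, ub), method="trf",
            ftol=1e-15, xtol=1e-15, gtol=1e-12, max_nfev=2000,
        )
        F = float(np.sum(sol.fun ** 2))
        if best is None or F < best_F - 1e-12:
            best, best_F, best_idx = sol, F, sidx
    sol = best
    converged = sol.status > 0

    L, P, Th = layout.matrices(sol.x)
    # sign convention: every factor's loading column sums non-negative
    for m in range(len(layout.factor_names)):
        if L[:, m].sum() < 0:
            L[:, m] = -L[:, m]
            P[m, :] = -P[m, :]
            P[:, m] = -P[:, m]
            P[m, m] = 1.0

    S = implied_matrix(spec, L, P,
                       {pair: Th[sorted((labels.index(pair[0]),
                                         labels.index(pair[1])))[0],
                                 sorted((labels.index(pair[0]),
                                         labels.index(pair[1])))[1]]
                        for pair in spec.residual_pairs})
    resid = r_obs - S[ii, jj]
    F_hat = float(np.sum(w * resid ** 2))
    communality = np.einsum("jk,kl,jl->j", L, P, L)
    uniq = 1.0 - communality
    heywood = [labels[j] for j in range(d)
               if uniq[j] < HEYWOOD_UNIQUENESS or np.any(np.abs(L[j]) > 1.0)]

    T = (n - 1) * F_hat
    F_null = float(np.sum(w * r_obs ** 2))
    T_null = (n - 1) * F_null
    df_null = d * (d - 1) // 2
    if spec.df > 0:
        idx = fit_indices(T, spec.df, T_null, df_null, n, resid)
    else:   # just-identified: incremental indices undefined
        srmr = float(np.sqrt(np.mean(resid ** 2)))
        idx = FitIndices(cfi=float("nan"), tli=float("nan"),
                         rmsea=float("nan"), srmr=srmr, degenerate_null=True)

    resid_dict = {}
    for (a, b) in spec.residual_pairs:
        i, j = sorted((labels.index(a), labels.index(b)))
        resid_dict[(a, b)] = float(Th[i, j])

    return FitResult(
        spec=spec,
        loadings=pd.DataFrame(L, index=labels, columns=layout.factor_names),
        factor_corr=pd.DataFrame(P, index=layout.factor_names,
                                 columns=layout.factor_names),
        residual_corrs=resid_dict,
        uniquenesses=pd.Series(uniq, index=labels, name="uniqueness"),
        discrepancy=F_hat, T=T, df=spec.df, n=n, indices=idx,
        converged=converged, heywood=heywood, estimator=estimator,
        sample_corr=pd.DataFrame(Rm, index=labels, columns=labels),
        n_free=spec.n_free, start_index=best_idx,
    )


def warm_start_vector(spec_new: ModelSpec, fit_base: FitResult) -> np.ndarray:
    """Start vector for ``spec_new`` seeded from a fitted nested model.

    Parameters shared with the base fit take the fitted values; parameters
    new in ``spec_new`` start at 0 (0.3 for factor correlations).
    """
    layout = _Layout.build(spec_new)
    x = np.zeros(layout.n_par)
    pos = 0
    base_factors = set(fit_base.loadings.columns)
    for (ind, fac) in spec_new.loading_entries:
        if fac in base_factors and ind in fit_base.loadings.index:
            x[pos] = fit_base.loadings.at[ind, fac]
        pos += 1
    fnames = [f for f, _ in spec_new.factors]
    for (p, q) in layout.phi_cells:
        fp, fq = fnames[p], fnames[q]
        if fp in base_factors and fq in base_factors:
            x[pos] = fit_base.factor_corr.at[fp, fq]
        else:
            x[pos] = 0.3
        pos += 1
    base_pairs = {frozenset(p): v for p, v in fit_base.residual_corrs.items()}
    for (a, b) in spec_new.residual_pairs:
        x[pos] = base_pairs.get(frozenset((a, b)), 0.0)
        pos += 1
    return x


def pairwise_variance_jackknife(m: BinaryDiagnosisMatrix, n_batches: int = 20,
                                seed: int = 0) -> pd.DataFrame:
    """Sampling variances of the pairwise tetrachorics by a jackknife of
    person batches; reciprocal values serve as DWLS weights."""
    from .tetra import correlation_matrix

    rng = np.random.default_rng(seed)
    n = m.n_persons
    if n_batches < 2 or n_batches > n:
        raise ValueError("need 2 <= n_batches <= n_persons")
    batch = rng.permutation(n) % n_batches
    mats = []
    for g in range(n_batches):
        sub = m.subset_persons(np.flatnonzero(batch != g))
        mats.append(correlation_matrix(sub, smooth=False).corr.to_numpy())
    arr = np.stack(mats)
    mean = arr.mean(axis=0)
    var = (n_batches - 1) / n_batches * np.sum((arr - mean) ** 2, axis=0)
    var = np.maximum(var, 1e-10)
    labels = list(m.labels)
    return pd.DataFrame(1.0 / var, index=labels, columns=labels)


@dataclass
class BootstrapResult:
    loading_se: pd.DataFrame
    factor_corr_se: pd.DataFrame
    residual_se: dict[tuple[str, str], float]
    n_converged: int
    n_failed: int
    replicates: np.ndarray            # (B_ok, n_loadings) aligned estimates


def bootstrap_se(m: BinaryDiagnosisMatrix, spec: ModelSpec, B: int = 100,
                 seed: int = 0, estimator: str = "uls",
                 index_sampler=None, max_fail: float = 0.2,
                 allow_high_failure: bool = False) -> BootstrapResult:
    """Nonparametric person-level bootstrap standard errors.

    Each resample reruns the full pipeline (tetrachoric -> smooth -> fit);
    the SE is the SD across converged resamples after aligning factor signs
    with the full-sample reference fit.  ``index_sampler(rng, n)`` may
    override resampling (tests use a degenerate stub).
    """
    from .tetra import correlation_matrix

    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    ref = fit(correlation_matrix(m), m.n_persons, spec, estimator=estimator)
    cells = spec.loading_entries
    pairs = list(spec.residual_pairs)
    fnames = [f for f, _ in spec.factors]
    phi_pairs = ([] if spec.bifactor else
                 [(fnames[p], fnames[q]) for p in range(len(fnames))
                  for q in range(p + 1, len(fnames))])

    rows_load, rows_phi, rows_res = [], [], []
    failed = 0
    for _ in range(B):
        idx = (index_sampler(rng, m.n_persons) if index_sampler is not None
               else rng.integers(0, m.n_persons, m.n_persons))
        sub = m.subset_persons(np.asarray(idx))
        try:
            Rb = correlation_matrix(sub)
            if Rb.excluded:
                raise ValueError("degenerate diagnosis in resample")
            fb = fit(Rb, sub.n_persons, spec, estimator=estimator)
            if not fb.converged:
                raise ValueError("non-convergence")
        except Exception:
            failed += 1
            continue
        flips = {}
        for fac in fb.loadings.columns:
            dot = float(fb.loadings[fac] @ ref.loadings[fac])
            flips[fac] = -1.0 if dot < 0 else 1.0
        rows_load.append([flips[f] * fb.loadings.at[i, f] for i, f in cells])
        rows_phi.append([flips[a] * flips[b] * fb.factor_corr.at[a, b]
                         for a, b in phi_pairs])
        rows_res.append([fb.residual_corrs[p] for p in pairs])

    n_ok = len(rows_load)
    if B and failed / B > max_fail and not allow_high_failure:
        raise RuntimeError(
            f"{failed}/{B} bootstrap resamples failed to converge "
            f"(> {max_fail:.0%}); pass allow_high_failure=True to override")
    if n_ok < 2:
        raise RuntimeError("fewer than 2 converged bootstrap resamples")

    arr_load = np.asarray(rows_load)
    se_load = arr_load.std(axis=0, ddof=1)
    loading_se = pd.DataFrame(0.0, index=ref.loadings.index,
                              columns=ref.loadings.columns)
    for (i, f), se in zip(cells, se_load):
        loading_se.at[i, f] = se
    phi_se = pd.DataFrame(0.0, index=ref.factor_corr.index,
                          columns=ref.factor_corr.columns)
    if phi_pairs:
        arr_phi = np.asarray(rows_phi)
        for (a, b), se in zip(phi_pairs, arr_phi.std(axis=0, ddof=1)):
            phi_se.at[a, b] = phi_se.at[b, a] = se
    res_se = {}
    if pairs:
        arr_res = np.asarray(rows_res)
        for p, se in zip(pairs, arr_res.std(axis=0, ddof=1)):
            res_se[p] = float(se)
    return BootstrapResult(loading_se=loading_se, factor_corr_se=phi_se,
                           residual_se=res_se, n_converged=n_ok,
                           n_failed=failed, replicates=arr_load)
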