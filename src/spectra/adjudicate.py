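"""Model adjudication: alternative indices, comparison tables, permutation
nulls, split-half replication, leave-one-out sensitivity, and a refit-based
candidate-parameter scan.

Conventional fit indices often fail to separate competing structures, so
each fitted model is also summarized by three "alternative indices" over its
factor loadings: magnitude (median absolute loading), consistency (SD of
loadings within a factor) and precision (mean bootstrap SE).  The preferred
structure is stress-tested by refitting under random diagnosis-to-factor
assignments, in random sample halves, and with each diagnosis removed in
turn; candidate cross-loadings / correlated residuals are ranked by the
discrepancy drop of a one-parameter refit (a refit-based stand-in for
analytic modification indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfa import FitResult, ModelSpec, bootstrap_se, fit, warm_start_vector
from .ehr_prep import BinaryDiagnosisMatrix
from .tetra import correlation_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "AltIndices",
    "split_indices",
    "alt_indices",
    "compare_models",
    "random_assignment_null",
    "split_half",
    "icc_absolute",
    "loo_scan",
    "candidate_scan",
]

INDEX_DIRECTION = {  # +1: higher is better, -1: lower is better
    "CFI": 1, "TLI": 1, "RMSEA": -1, "SRMR": -1,
    "FL": 1, "SD": -1, "SE": -1, "SD_within": -1,
}


@dataclass
class AltIndices:
    """Per-factor and pooled magnitude / consistency / precision."""

    per_factor: pd.DataFrame        # rows: factors; cols: FL, SD, SE, n_indicators
    pooled: dict[str, float]        # over all loadings
    pooled_by_factor: dict[str, float]  # mean of per-factor statistics
    flags: list[str] = field(default_factory=list)


def _loading_lists(fit_result: FitResult):
    """Loadings grouped by factor: cross-loadings count toward every factor
    they load on; the bifactor general factor is included."""
    spec = fit_result.spec
    by_factor: dict[str, list[float]] = {f: [] for f in fit_result.loadings.columns}
    se_by_factor: dict[str, list[float]] = {f: [] for f in fit_result.loadings.columns}
    for ind, fac in spec.loading_entries:
        by_factor[fac].append(float(fit_result.loadings.at[ind, fac]))
        if fit_result.loading_se is not None:
            se_by_factor[fac].append(float(fit_result.loading_se.at[ind, fac]))
    return by_factor, se_by_factor


def alt_indices(fit_result: FitResult) -> AltIndices:
    """Alternative adjudication indices of a converged fit.

    FL = median absolute loading (magnitude), SD = sample standard deviation
    of the loadings (consistency), SE = mean standard error (precision,
    omitted with a flag when no SEs are attached).
    """
    if not fit_result.converged:
        raise ValueError("alternative indices require a converged fit")
    by_factor, se_by_factor = _loading_lists(fit_result)
    flags = []
    rows = {}
    for fac, lams in by_factor.items():
        lams = np.asarray(lams, dtype=float)
        fl = float(np.median(np.abs(lams)))
        if lams.size >= 2:
            sd = float(np.std(lams, ddof=1))
        else:
            sd = float("nan")
            flags.append(f"factor {fac!r} has < 2 indicators; SD undefined")
        ses = se_by_factor[fac]
        se = float(np.mean(ses)) if ses else float("nan")
        rows[fac] = {"FL": fl, "SD": sd, "SE": se, "n_indicators": lams.size}
    if fit_result.loading_se is None:
        flags.append("no standard errors attached; precision omitted")
    per_factor = pd.DataFrame(rows).T

    all_lams = np.concatenate([np.asarray(v, float) for v in by_factor.values()])
    all_ses = np.concatenate(
        [np.asarray(v, float) for v in se_by_factor.values()]
    ) if fit_result.loading_se is not None else np.array([])
    pooled = {
        "FL": float(np.median(np.abs(all_lams))),
        "SD": float(np.std(all_lams, ddof=1)) if all_lams.size >= 2 else float("nan"),
        "SE": float(np.mean(all_ses)) if all_ses.size else float("nan"),
    }
    pooled_by_factor = {
        "FL": float(per_factor["FL"].mean()),
        "SD": float(per_factor["SD"].mean()),
        "SE": float(per_factor["SE"].mean()),
    }
    return AltIndices(per_factor=per_factor, pooled=pooled,
                      pooled_by_factor=pooled_by_factor, flags=flags)


def compare_models(fits: list[FitResult], names: list[str] | None = None
                   ) -> pd.DataFrame:
    """One row per model: fit indices, pooled alternative indices, ranks.

    All fits must be on the same correlation matrix and sample size; no
    single winner is declared (adjudication is multi-criterion).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        same = (f.n == ref.n
                and f.sample_corr.shape == ref.sample_corr.shape
                and list(f.sample_corr.columns) == list(ref.sample_corr.columns)
                and np.allclose(f.sample_corr.to_numpy(),
                                ref.sample_corr.to_numpy(), atol=1e-12))
        if not same:
            raise ValueError("fits were produced on different correlation "
                             "matrices; comparison is not meaningful")
    if names is None:
        names = [f"model_{i + 1}" for i in range(len(fits))]
    rows = []
    for name, f in zip(names, fits):
        alt = alt_indices(f)
        rows.append({
            "model": name, "df": f.df,
            "CFI": f.indices.cfi, "TLI": f.indices.tli,
            "RMSEA": f.indices.rmsea, "SRMR": f.indices.srmr,
            "FL": alt.pooled["FL"], "SD": alt.pooled["SD"],
            "SE": alt.pooled["SE"],
        })
    table = pd.DataFrame(rows).set_index("model")
    for col, direction in INDEX_DIRECTION.items():
        if col in table.columns and table[col].notna().any():
            table[f"rank_{col}"] = table[col].rank(
                ascending=direction < 0, method="min")
    return table


def fit_matrix(m: BinaryDiagnosisMatrix, spec: ModelSpec,
               estimator: str = "uls", R=None) -> FitResult:
    """Convenience: tetrachoric -> smooth -> fit from a binary matrix."""
    if R is None:
        R = correlation_matrix(m)
    return fit(R, m.n_persons, spec, estimator=estimator)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNullResult:
    observed: pd.Series
    null_distributions: pd.DataFrame      # one row per converged null model
    percentile: pd.Series                 # % of nulls the observed model beats
    n_requested: int
    n_converged: int
    n_failed: int
    null_specs: list = field(default_factory=list)


def random_assignment_null(m: BinaryDiagnosisMatrix, spec: ModelSpec,
                           K: int, seed: int = 0,
                           preserve_sizes: bool = True,
                           R=None) -> PermutationNullResult:
    """Fit K models with diagnoses randomly reassigned to factors.

    Null specs keep the observed factor-size multiset by default (an
    unconstrained multinomial assignment is available); cross-loadings and
    residual pairs are dropped.  Null fits that fail to converge are
    excluded and counted.  Percentiles are direction-aware: the share of
    null models the observed model beats on each index.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    rng = np.random.default_rng(seed)
    if R is None:
        R = correlation_matrix(m)
    obs_fit = fit_matrix(m, spec, R=R)
    obs_alt = alt_indices(obs_fit)
    observed = pd.Series({
        "CFI": obs_fit.indices.cfi, "TLI": obs_fit.indices.tli,
        "RMSEA": obs_fit.indices.rmsea, "SRMR": obs_fit.indices.srmr,
        "FL": obs_alt.pooled["FL"], "SD": obs_alt.pooled["SD"],
        "SD_within": obs_alt.pooled_by_factor["SD"],
    })

    indicators = spec.indicators
    fnames = [f for f, _ in spec.factors]
    sizes = [sum(1 for i in indicators if spec.primary_factor(i) == f)
             for f in fnames]
    rows = []
    null_specs = []
    failed = 0
    for _ in range(K):
        perm = rng.permutation(indicators)
        if preserve_sizes:
            cuts = np.cumsum(sizes)[:-1]
            groups = np.split(perm, cuts)
        else:
            assign = rng.integers(0, len(fnames), len(indicators))
            groups = [perm[assign == g] for g in range(len(fnames))]
            if any(len(g) == 0 for g in groups):
                failed += 1
                continue
        null_spec = ModelSpec(
            factors=tuple((f, tuple(g)) for f, g in zip(fnames, groups)),
            bifactor=spec.bifactor)
        null_specs.append(null_spec)
        try:
            nf = fit(R, m.n_persons, null_spec)
            if not nf.converged:
                raise RuntimeError("non-convergence")
        except Exception:
            failed += 1
            continue
        nalt = alt_indices(nf)
        rows.append({
            "CFI": nf.indices.cfi, "TLI": nf.indices.tli,
            "RMSEA": nf.indices.rmsea, "SRMR": nf.indices.srmr,
            "FL": nalt.pooled["FL"], "SD": nalt.pooled["SD"],
            "SD_within": nalt.pooled_by_factor["SD"],
            "heywood": len(nf.heywood) > 0,
        })
    nulls = pd.DataFrame(rows)
    pct = {}
    for col in observed.index:
        if len(nulls) == 0:
            pct[col] = float("nan")
        elif INDEX_DIRECTION[col] > 0:
            pct[col] = 100.0 * float((observed[col] > nulls[col]).mean())
        else:
            pct[col] = 100.0 * float((observed[col] < nulls[col]).mean())
    return PermutationNullResult(
        observed=observed, null_distributions=nulls,
        percentile=pd.Series(pct), n_requested=K,
        n_converged=len(nulls), n_failed=failed, null_specs=null_specs)


# ---------------------------------------------------------------------------
# Split-half replication
# ---------------------------------------------------------------------------

def split_indices(n: int, seed: int) -> tuple:
    """Random partition of range(n) into two disjoint halves (sizes differ
    by at most 1), sorted within each half."""
    import numpy as _np
    rng = _np.random.default_rng(seed)
    perm = rng.permutation(n)
    return _np.sort(perm[: n // 2]), _np.sort(perm[n // 2:])


def icc_absolute(x, y) -> float:
    """Two-way absolute-agreement single-measure intraclass correlation,
    ICC(A,1), between two measurement vectors.

    Computed from the mean squares of the two-way (subject x rater) layout;
    systematic offsets between the vectors are penalized.  Returns NaN when
    both vectors are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


@dataclass
class SplitHalfResult:
    per_model: pd.DataFrame       # index diffs + loading ICC per spec
    index_icc: pd.Series          # per-index ICC across models (>= 2 specs)
    half_sizes: tuple[int, int]
    dropped: list[str]


def split_half(m: BinaryDiagnosisMatrix, specs: dict[str, ModelSpec],
               seed: int = 0, estimator: str = "uls",
               partition: tuple[np.ndarray, np.ndarray] | None = None
               ) -> SplitHalfResult:
    """Replicate model fits in two random disjoint halves of the cohort.

    For each model: the absolute difference of every fit index between
    halves and the ICC(A,1) of the loading vectors.  With >= 2 models, each
    index additionally gets an ICC across models.  Diagnoses degenerate in
    either half are dropped from both (reported).  ``partition`` overrides
    the random split (tests use identical halves).
    """
    n = m.n_persons
    if n < 4:
        raise ValueError("need at least 4 persons to split")
    if partition is None:
        idx1, idx2 = split_indices(n, seed)
    else:
        idx1, idx2 = (np.asarray(p) for p in partition)
    h1, h2 = m.subset_persons(idx1), m.subset_persons(idx2)

    prev1, prev2 = h1.prevalence, h2.prevalence
    bad = [lab for lab in m.labels
           if prev1[lab] in (0.0, 1.0) or prev2[lab] in (0.0, 1.0)]
    if bad:
        logger.warning("dropping diagnoses degenerate in a half: %s", bad)
        keep = [lab for lab in m.labels if lab not in bad]
        h1, h2 = h1.subset_diagnoses(keep), h2.subset_diagnoses(keep)
    R1, R2 = correlation_matrix(h1), correlation_matrix(h2)

    rows = []
    index_vals: dict[str, list[tuple[float, float]]] = {
        "CFI": [], "TLI": [], "RMSEA": [], "SRMR": []}
    for name, spec in specs.items():
        use_spec = spec
        for lab in bad:
            if lab in spec.indicators:
                use_spec = use_spec.drop_indicator(lab)
        f1 = fit(R1, h1.n_persons, use_spec, estimator=estimator)
        f2 = fit(R2, h2.n_persons, use_spec, estimator=estimator)
        lam1 = np.array([f1.loadings.at[i, f] for i, f in use_spec.loading_entries])
        lam2 = np.array([f2.loadings.at[i, f] for i, f in use_spec.loading_entries])
        row = {"model": name,
               "loading_icc": icc_absolute(lam1, lam2)}
        for idx_name in index_vals:
            v1 = getattr(f1.indices, idx_name.lower())
            v2 = getattr(f2.indices, idx_name.lower())
            row[f"d{idx_name}"] = abs(v1 - v2)
            index_vals[idx_name].append((v1, v2))
        rows.append(row)
    per_model = pd.DataFrame(rows).set_index("model")

    index_icc = {}
    for idx_name, pairs in index_vals.items():
        if len(pairs) >= 2:
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            index_icc[idx_name] = icc_absolute(a, b)
        else:
            index_icc[idx_name] = float("nan")
    return SplitHalfResult(per_model=per_model,
                           index_icc=pd.Series(index_icc),
                           half_sizes=(h1.n_persons, h2.n_persons),
                           dropped=bad)


# ---------------------------------------------------------------------------
# Leave-one-out sensitivity
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    delta: pd.DataFrame           # (j, k): change in j's primary loading when k removed
    summary: pd.Series            # signed mean/median/sd/min/max over defined cells
    skipped: list[str]
    failed: list[str]


def loo_scan(m: BinaryDiagnosisMatrix | None, spec: ModelSpec,
             R=None, n: int | None = None) -> LooResult:
    """Refit with each diagnosis removed in turn; track loading changes.

    Cell (j, k) holds the signed change in diagnosis j's primary-factor
    loading when diagnosis k is removed; the diagonal is undefined.
    Removals that would leave a factor with < 2 indicators are skipped
    (flagged); non-converged reduced fits flag their column.
    """
    if R is None:
        if m is None:
            raise ValueError("need a matrix or a precomputed correlation matrix")
        R = correlation_matrix(m)
    if n is None:
        n = m.n_persons
    base = fit(R, n, spec)
    base_lam = base.primary_loadings()
    labels = spec.indicators
    delta = pd.DataFrame(np.nan, index=labels, columns=labels)
    skipped, failed = [], []
    for k_lab in labels:
        reduced = spec.drop_indicator(k_lab)
        sizes_ok = (len(reduced.factors) == len(spec.factors)
                    and all(len(inds) >= 2 for _, inds in reduced.factors))
        if not sizes_ok:
            skipped.append(k_lab)
            continue
        try:
            fr = fit(R, n, reduced)
            if not fr.converged:
                raise RuntimeError("non-convergence")
        except Exception:
            failed.append(k_lab)
            continue
        lam_r = fr.primary_loadings()
        for j_lab in reduced.indicators:
            delta.at[j_lab, k_lab] = lam_r[j_lab] - base_lam[j_lab]
    vals = delta.to_numpy()
    defined = vals[~np.isnan(vals)]
    summary = pd.Series({
        "mean": float(np.mean(defined)) if defined.size else float("nan"),
        "median": float(np.median(defined)) if defined.size else float("nan"),
        "sd": float(np.std(defined, ddof=1)) if defined.size > 1 else float("nan"),
        "min": float(np.min(defined)) if defined.size else float("nan"),
        "max": float(np.max(defined)) if defined.size else float("nan"),
    })
    return LooResult(delta=delta, summary=summary, skipped=skipped,
                     failed=failed)


# ---------------------------------------------------------------------------
# Candidate-parameter scan (refit-based modification search)
# ---------------------------------------------------------------------------

def candidate_scan(m: BinaryDiagnosisMatrix, spec: ModelSpec,
                   candidates: list[tuple[str, tuple[str, str]]],
                   R=None) -> pd.DataFrame:
    """Rank candidate one-parameter refinements by discrepancy drop.

    Candidates are ('residual', (a, b)) or ('cross', (indicator, factor)).
    Each is freed alone and the model refitted (warm-started from the base
    solution, so the drop is never negative); results are ranked by delta-F.
    Nothing is auto-accepted.
    """
    if R is None:
        R = correlation_matrix(m)
    base = fit(R, m.n_persons, spec)
    existing_pairs = {frozenset(p) for p in spec.residual_pairs}
    existing_loads = set(spec.loading_entries)
    rows = []
    for kind, target in candidates:
        label = f"{kind}:{target[0]}~{target[1]}"
        if kind == "residual":
            redundant = frozenset(target) in existing_pairs
            new_spec = None if redundant else spec.with_residual(*target)
        elif kind == "cross":
            redundant = (target[0], target[1]) in existing_loads
            new_spec = None if redundant else spec.with_cross_loading(*target)
        else:
            raise ValueError(f"unknown candidate kind {kind!r}")
        if redundant:
            rows.append({"candidate": label, "kind": kind, "delta_F": 0.0,
                         "estimate": float("nan"), "dCFI": 0.0, "dRMSEA": 0.0,
                         "dSRMR": 0.0, "status": "redundant"})
            continue
        if new_spec.df < 0:
            rows.append({"candidate": label, "kind": kind,
                         "delta_F": float("nan"), "estimate": float("nan"),
                         "dCFI": float("nan"), "dRMSEA": float("nan"),
                         "dSRMR": float("nan"), "status": "skipped: df < 0"})
            continue
        warm = warm_start_vector(new_spec, base)
        fr = fit(R, m.n_persons, new_spec, extra_starts=[warm])
        if kind == "residual":
            est = fr.residual_corrs.get(target,
                                        fr.residual_corrs.get((target[1], target[0]),
                                                              float("nan")))
        else:
            est = float(fr.loadings.at[target[0], target[1]])
        rows.append({
            "candidate": label, "kind": kind,
            "delta_F": max(base.discrepancy - fr.discrepancy, 0.0),
            "estimate": est,
            "dCFI": fr.indices.cfi - base.indices.cfi,
            "dRMSEA": fr.indices.rmsea - base.indices.rmsea,
            "dSRMR": fr.indices.srmr - base.indices.srmr,
            "status": "ok" if fr.converged else "non-converged",
        })
    table = pd.DataFrame(rows).sort_values("delta_F", ascending=False,
                                           kind="mergesort")
    return table.reset_index(drop=True)
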