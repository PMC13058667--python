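"""Liability-threshold generator for EHR-like psychiatric comorbidity data.

Each person has k latent factor scores eta ~ MVN(0, Phi).  Diagnosis j's
liability is lambda_j' eta + e_j, where the unique parts e are jointly normal
with covariance Theta = diag(uniqueness) + residual increments; uniqueness is
solved so every liability has unit variance, keeping loadings on the
standardized scale.  Diagnosis j is present iff liability exceeds
tau_j = probit(1 - prevalence_j).  The implied tetrachoric correlation matrix
is therefore Lambda Phi Lambda' + residual increments (off-diagonal), which
the truth object records as the recovery oracle.

Presence is additionally emitted as 1-4 raw diagnosis codes with event dates
(to exercise code clustering), and external correlates are generated from
linear models on the factor scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .ehr_prep import BinaryDiagnosisMatrix, ClusterMap

__all__ = [
    "CorrelateSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "six_factor_preset",
    "FACTOR_NAMES",
]

FACTOR_NAMES = ["Fear", "Distress", "Externalizing", "SubstanceUse",
                "ThoughtProblems", "Neurodevelopmental"]


@dataclass(frozen=True)
class CorrelateSpec:
    """External correlate generated from the latent factor scores.

    ``weights`` are regression coefficients of the correlate's latent part on
    the k factors; ``noise_sd`` scales an independent normal disturbance.
    Types: 'continuous' (identity), 'binary' (probit link on the linear
    predictor), 'ordinal' (continuous latent cut at ``cutpoints``).
    """

    name: str
    kind: str
    weights: tuple[float, ...]
    noise_sd: float = 1.0
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown correlate kind {self.kind!r}")
        if self.kind == "ordinal" and not self.cutpoints:
            raise ValueError(f"ordinal correlate {self.name!r} needs cutpoints")


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_persons: int
    labels: list[str]
    factor_names: list[str]
    factor_corr: np.ndarray          # k x k, unit diagonal, PSD
    loadings: np.ndarray             # d x k, standardized scale
    prevalences: np.ndarray          # d, in (0, 1)
    residual_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    correlates: list[CorrelateSpec] = field(default_factory=list)
    seed: int = 0
    codes_per_diagnosis: int = 4
    date_window: tuple[str, str] = ("2018-05-06", "2022-06-06")

    def __post_init__(self) -> None:
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        d, k = self.loadings.shape
        if len(self.labels) != d:
            raise ConfigurationError("labels do not match loadings rows")
        if len(self.factor_names) != k or self.factor_corr.shape != (k, k):
            raise ConfigurationError("factor names/corr do not match loadings cols")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise ConfigurationError("factor_corr must have unit diagonal")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ConfigurationError("factor_corr must be symmetric")
        eigs = np.linalg.eigvalsh(self.factor_corr)
        if eigs[0] < -1e-10:
            raise ConfigurationError(
                f"factor_corr is not PSD: smallest eigenvalue {eigs[0]:.3e}")
        if np.any(self.prevalences <= 0.0) or np.any(self.prevalences >= 1.0):
            raise ConfigurationError("prevalences must lie strictly inside (0,1)")
        u = self.uniqueness
        for j, (lab, uj) in enumerate(zip(self.labels, u)):
            if uj < 0:
                raise ConfigurationError(
                    f"negative uniqueness {uj:.4f} for diagnosis {lab!r} "
                    f"(row {j}): communality exceeds 1")
        for (a, b), val in self.residual_corr.items():
            if a not in self.labels or b not in self.labels or a == b:
                raise ConfigurationError(f"bad residual pair ({a!r}, {b!r})")
        theta = self.unique_cov
        teigs = np.linalg.eigvalsh(theta)
        if teigs[0] < -1e-10:
            raise ConfigurationError(
                f"unique-part covariance not PSD (min eig {teigs[0]:.3e}); "
                "residual increments too large for the uniquenesses")
        for cs in self.correlates:
            if len(cs.weights) != k:
                raise ConfigurationError(
                    f"correlate {cs.name!r} has {len(cs.weights)} weights, "
                    f"expected {k}")

    # -- derived quantities -------------------------------------------------
    @property
    def communality(self) -> np.ndarray:
        L, P = self.loadings, self.factor_corr
        return np.einsum("jk,kl,jl->j", L, P, L)

    @property
    def uniqueness(self) -> np.ndarray:
        return 1.0 - self.communality

    @property
    def unique_cov(self) -> np.ndarray:
        """Covariance of the unique parts: diag(u) + residual increments."""
        d = len(self.labels)
        theta = np.diag(self.uniqueness)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        for (a, b), val in self.residual_corr.items():
            i, j = idx[a], idx[b]
            theta[i, j] = theta[j, i] = val
        return theta

    @property
    def thresholds(self) -> np.ndarray:
        return ndtri(1.0 - self.prevalences)

    def implied_corr(self) -> np.ndarray:
        """Model-implied tetrachoric matrix Lambda Phi Lambda' + Theta_off."""
        L, P = self.loadings, self.factor_corr
        S = L @ P @ L.T + self.unique_cov
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        return S

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_persons": int(self.n_persons),
            "labels": list(self.labels),
            "factor_names": list(self.factor_names),
            "factor_corr": self.factor_corr.tolist(),
            "loadings": self.loadings.tolist(),
            "prevalences": self.prevalences.tolist(),
            "residual_corr": [[a, b, float(v)]
                              for (a, b), v in self.residual_corr.items()],
            "correlates": [
                {"name": c.name, "kind": c.kind, "weights": list(c.weights),
                 "noise_sd": c.noise_sd, "cutpoints": list(c.cutpoints)}
                for c in self.correlates
            ],
            "seed": int(self.seed),
            "codes_per_diagnosis": int(self.codes_per_diagnosis),
            "date_window": list(self.date_window),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        return cls(
            n_persons=data["n_persons"],
            labels=list(data["labels"]),
            factor_names=list(data["factor_names"]),
            factor_corr=np.asarray(data["factor_corr"], dtype=float),
            loadings=np.asarray(data["loadings"], dtype=float),
            prevalences=np.asarray(data["prevalences"], dtype=float),
            residual_corr={(a, b): float(v)
                           for a, b, v in data.get("residual_corr", [])},
            correlates=[
                CorrelateSpec(name=c["name"], kind=c["kind"],
                              weights=tuple(c["weights"]),
                              noise_sd=c.get("noise_sd", 1.0),
                              cutpoints=tuple(c.get("cutpoints", ())))
                for c in data.get("correlates", [])
            ],
            seed=data.get("seed", 0),
            codes_per_diagnosis=data.get("codes_per_diagnosis", 4),
            date_window=tuple(data.get("date_window",
                                       ("2018-05-06", "2022-06-06"))),
        )

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Generating parameters kept alongside simulated data for recovery tests."""

    config: GeneratorConfig
    tau: np.ndarray
    implied_corr: np.ndarray
    factor_scores: np.ndarray | None = None   # n x k latent draws

    def __post_init__(self) -> None:
        S = self.implied_corr
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("implied matrix must have unit diagonal")
        if np.any(np.abs(S) > 1.0 + 1e-10):
            raise ValueError("implied correlations must lie in [-1, 1]")


def _code_variants(label: str, n: int) -> list[str]:
    if label == "autism spectrum disorder":
        return ["autism spectrum disorder", "autism", "autistic disorder",
                "Asperger's syndrome"][:n]
    variants = [label, f"{label}, unspecified", f"{label} NOS",
                f"history of {label}"]
    return variants[:n]


def build_cluster_map(config: GeneratorConfig) -> ClusterMap:
    raw_to_label: dict[str, str] = {}
    for lab in config.labels:
        for code in _code_variants(lab, config.codes_per_diagnosis):
            raw_to_label[code] = lab
    return ClusterMap(raw_to_label=raw_to_label, labels=list(config.labels))


def simulate_dataset(config: GeneratorConfig):
    """Draw one synthetic cohort from the liability-threshold model.

    Returns ``(matrix, events, cluster_map, correlates, truth)``.  Persons
    with all-zero diagnosis rows are retained; the downstream cohort filter
    removes them.  All randomness derives from ``config.seed`` through
    per-component child streams, so identical seeds give identical output.
    """
    config.validate()
    d = len(config.labels)
    k = len(config.factor_names)
    n = config.n_persons
    ss = np.random.SeedSequence(config.seed)
    rng_liab, rng_codes, rng_dates, rng_corr = (
        np.random.default_rng(child) for child in ss.spawn(4))

    chol_phi = np.linalg.cholesky(
        config.factor_corr + 1e-12 * np.eye(k))
    eta = rng_liab.standard_normal((n, k)) @ chol_phi.T

    theta = config.unique_cov
    w, v = np.linalg.eigh(theta)
    chol_theta = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    unique = rng_liab.standard_normal((n, d)) @ chol_theta.T

    liab = eta @ config.loadings.T + unique
    tau = config.thresholds
    values = (liab > tau[None, :]).astype(np.int8)

    width = max(6, len(str(n)))
    person_ids = np.array([f"P{i:0{width}d}" for i in range(n)])
    matrix = BinaryDiagnosisMatrix(person_ids=person_ids,
                                   labels=list(config.labels), values=values)

    cmap = build_cluster_map(config)
    events = _emit_events(config, matrix, cmap, rng_codes, rng_dates)
    correlates = _emit_correlates(config, eta, person_ids, rng_corr)
    truth = SyntheticTruth(config=config, tau=tau,
                           implied_corr=config.implied_corr(),
                           factor_scores=eta)
    return matrix, events, cmap, correlates, truth


def _emit_events(config, matrix, cmap, rng_codes, rng_dates) -> pd.DataFrame:
    rows_p, rows_d = np.nonzero(matrix.values)
    n_pos = len(rows_p)
    counts = rng_codes.integers(1, 5, size=n_pos)          # 1..4 codes each
    rep_p = np.repeat(rows_p, counts)
    rep_d = np.repeat(rows_d, counts)
    variant = rng_codes.integers(0, config.codes_per_diagnosis,
                                 size=len(rep_p))
    variants_by_dx = [_code_variants(lab, config.codes_per_diagnosis)
                      for lab in config.labels]
    codes = np.array([variants_by_dx[dj][vj]
                      for dj, vj in zip(rep_d, variant)], dtype=object)

    start = np.datetime64(config.date_window[0])
    stop = np.datetime64(config.date_window[1])
    span = int((stop - start) / np.timedelta64(1, "D"))
    offsets = rng_dates.integers(0, span + 1, size=len(rep_p))
    dates = (start + offsets.astype("timedelta64[D]")).astype(str)

    return pd.DataFrame({
        "person_id": matrix.person_ids[rep_p],
        "raw_code": codes,
        "event_date": dates,
    })


def _emit_correlates(config, eta, person_ids, rng) -> pd.DataFrame:
    frames = []
    for cs in config.correlates:
        linpred = eta @ np.asarray(cs.weights, dtype=float)
        if cs.kind == "binary":
            p = ndtr(linpred)
            value = (rng.random(len(p)) < p).astype(float)
        else:
            latent = linpred + cs.noise_sd * rng.standard_normal(len(linpred))
            if cs.kind == "continuous":
                value = latent
            else:
                value = np.searchsorted(np.asarray(cs.cutpoints), latent).astype(float)
        frames.append(pd.DataFrame({
            "person_id": person_ids, "correlate": cs.name,
            "value": value, "type": cs.kind,
        }))
    if not frames:
        return pd.DataFrame(columns=["person_id", "correlate", "value", "type"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Six-factor preset: 39 diagnoses across Fear, Distress, Externalizing,
# Substance Use, Thought Problems, Neurodevelopmental Disorders.
# ---------------------------------------------------------------------------

# (label, factor, loading, prevalence); loadings on the Fear and Distress
# factors are deliberately lower (~.43-.55) than on the other four (~.6-.8),
# and within-cohort prevalences are compressed into [0.10, 0.40] so that all
# pairwise tables stay well populated at simulation scale.
_PRESET_ROSTER = [
    # Fear (7)
    ("agoraphobia",                    "Fear", 0.52, 0.10),
    ("panic disorder",                 "Fear", 0.50, 0.20),
    ("social anxiety disorder",        "Fear", 0.48, 0.18),
    ("specific phobia",                "Fear", 0.45, 0.12),
    ("obsessive-compulsive disorder",  "Fear", 0.43, 0.12),
    ("obsessive-compulsive personality disorder", "Fear", 0.43, 0.10),
    ("separation anxiety disorder",    "Fear", 0.47, 0.10),
    # Distress (8)
    ("major depressive disorder",      "Distress", 0.55, 0.40),
    ("dysthymia",                      "Distress", 0.52, 0.15),
    ("generalized anxiety disorder",   "Distress", 0.54, 0.32),
    ("post-traumatic stress disorder", "Distress", 0.50, 0.22),
    ("adjustment disorder",            "Distress", 0.48, 0.25),
    ("anorexia nervosa",               "Distress", 0.43, 0.10),
    ("bulimia nervosa",                "Distress", 0.44, 0.10),
    ("borderline personality disorder", "Distress", 0.45, 0.12),
    # Externalizing (5)
    ("conduct disorder",               "Externalizing", 0.75, 0.12),
    ("oppositional defiant disorder",  "Externalizing", 0.72, 0.12),
    ("ADHD hyperactive-impulsive",     "Externalizing", 0.65, 0.10),
    ("intermittent explosive disorder", "Externalizing", 0.68, 0.10),
    ("impulse-control disorder",       "Externalizing", 0.70, 0.12),
    # Substance Use (8)
    ("alcohol use disorder",           "SubstanceUse", 0.75, 0.30),
    ("nicotine dependence",            "SubstanceUse", 0.62, 0.35),
    ("cannabis use disorder",          "SubstanceUse", 0.72, 0.20),
    ("opioid use disorder",            "SubstanceUse", 0.70, 0.14),
    ("cocaine use disorder",           "SubstanceUse", 0.74, 0.12),
    ("stimulant use disorder",         "SubstanceUse", 0.71, 0.10),
    ("sedative use disorder",          "SubstanceUse", 0.65, 0.10),
    ("antisocial personality disorder", "SubstanceUse", 0.60, 0.10),
    # Thought Problems (6)
    ("schizophrenia",                  "ThoughtProblems", 0.74, 0.10),
    ("schizoaffective disorder",       "ThoughtProblems", 0.76, 0.10),
    ("delusional disorder",            "ThoughtProblems", 0.68, 0.10),
    ("psychotic disorder NOS",         "ThoughtProblems", 0.72, 0.12),
    ("bipolar I disorder",             "ThoughtProblems", 0.60, 0.15),
    ("schizotypal personality disorder", "ThoughtProblems", 0.62, 0.10),
    # Neurodevelopmental (5)
    ("autism spectrum disorder",       "Neurodevelopmental", 0.65, 0.10),
    ("ADHD combined",                  "Neurodevelopmental", 0.72, 0.15),
    ("ADHD inattentive",               "Neurodevelopmental", 0.70, 0.13),
    ("tic disorder",                   "Neurodevelopmental", 0.66, 0.10),
    ("Tourette's syndrome",            "Neurodevelopmental", 0.68, 0.10),
]

#: borderline PD additionally loads on Thought Problems (theory-driven
#: cross-loading retained in the preferred model).
_PRESET_CROSS = [("borderline personality disorder", "ThoughtProblems", 0.25)]

#: correlated residuals: closely related diagnosis pairs sharing variance
#: beyond their factors, on the implied-correlation increment scale.
_PRESET_RESIDUALS = {
    ("major depressive disorder", "dysthymia"): 0.15,
    ("schizophrenia", "schizoaffective disorder"): 0.15,
    ("obsessive-compulsive disorder",
     "obsessive-compulsive personality disorder"): 0.15,
    ("ADHD combined", "ADHD hyperactive-impulsive"): 0.10,
    ("ADHD combined", "ADHD inattentive"): 0.10,
    ("ADHD hyperactive-impulsive", "ADHD inattentive"): 0.10,
}

# Factor correlations (order: Fear, Distress, Ext, SU, Thought, Neuro).
# Fear-Distress is set to .898; the rest are moderate.
_PRESET_PHI = np.array([
    [1.000, 0.898, 0.350, 0.300, 0.400, 0.380],
    [0.898, 1.000, 0.420, 0.380, 0.450, 0.400],
    [0.350, 0.420, 1.000, 0.600, 0.420, 0.520],
    [0.300, 0.380, 0.600, 1.000, 0.380, 0.320],
    [0.400, 0.450, 0.420, 0.380, 1.000, 0.400],
    [0.380, 0.400, 0.520, 0.320, 0.400, 1.000],
])

# External correlates: weights on (F, D, E, SU, T, N).  Male sex loads
# positively on Substance Use / Externalizing and negatively on Fear /
# Distress; sleep disturbance loads most strongly on Distress; income and
# education load negatively on Substance Use.
_PRESET_CORRELATES = [
    CorrelateSpec("male_sex", "binary",
                  (-0.25, -0.30, 0.30, 0.40, 0.05, 0.10)),
    CorrelateSpec("sleep_disturbance", "continuous",
                  (0.20, 0.45, 0.15, -0.10, 0.10, 0.05), noise_sd=1.0),
    CorrelateSpec("income", "ordinal",
                  (-0.05, -0.10, -0.20, -0.35, -0.15, -0.10), noise_sd=1.0,
                  cutpoints=(-1.2, -0.4, 0.4, 1.2)),
    CorrelateSpec("education", "ordinal",
                  (-0.05, -0.08, -0.25, -0.30, -0.15, -0.20), noise_sd=1.0,
                  cutpoints=(-1.2, -0.4, 0.4, 1.2)),
]


def six_factor_preset(n_persons: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Default 39-diagnosis, six-factor generating configuration.

    Factor sizes are 7/8/5/8/6/5 (every size in 5..8 represented); named
    diagnoses cover the conditions discussed in the six-dimension structure,
    with correlated residuals among closely related pairs and one
    cross-loading.
    """
    labels = [row[0] for row in _PRESET_ROSTER]
    d, k = len(labels), len(FACTOR_NAMES)
    loadings = np.zeros((d, k))
    prev = np.zeros(d)
    fidx = {f: i for i, f in enumerate(FACTOR_NAMES)}
    for j, (lab, fac, lam, p) in enumerate(_PRESET_ROSTER):
        loadings[j, fidx[fac]] = lam
        prev[j] = p
    for lab, fac, lam in _PRESET_CROSS:
        loadings[labels.index(lab), fidx[fac]] = lam
    return GeneratorConfig(
        n_persons=n_persons,
        labels=labels,
        factor_names=list(FACTOR_NAMES),
        factor_corr=_PRESET_PHI.copy(),
        loadings=loadings,
        prevalences=prev,
        residual_corr=dict(_PRESET_RESIDUALS),
        correlates=list(_PRESET_CORRELATES),
        seed=seed,
    )


def preset_with(config: GeneratorConfig = None, **overrides) -> GeneratorConfig:
    """Copy of the preset (or given config) with fields replaced."""
    base = config if config is not None else six_factor_preset()
    return replace(base, **overrides)
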