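"""End-to-end orchestration: simulate/ingest -> prep -> correlate -> fit
ladder -> adjudicate -> external validation, driven by one config, with a
reproducibility manifest recording digests and seeds for every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjudicate, external, models, synth
from .cfa import bootstrap_se, fit, parse_model
from .ehr_prep import BinaryDiagnosisMatrix, ClusterMap, collapse_codes, filter_cohort
from .tetra import correlation_matrix, heatmap_order, plot_heatmap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run", "make_fixtures"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str
    seed: int = 0
    input_mode: str = "synthetic"            # 'synthetic' | 'matrix'
    n_persons: int = 20_000
    generator_config: str | None = None      # YAML path; preset if None
    matrix_path: str | None = None           # for input_mode == 'matrix'
    model_files: list[str] = field(default_factory=list)
    preferred_model: str | None = None       # name (stem) of preferred model
    estimator: str = "uls"
    bootstrap_B: int = 0                     # 0 disables SEs
    permutation_K: int = 0
    split_half: bool = False
    loo: bool = False
    external_B: int = 200
    heatmap: bool = False

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "matrix"):
            raise PipelineError(f"unknown input mode {self.input_mode!r}")
        if not self.model_files:
            raise PipelineError("model ladder is empty")
        for p in self.model_files:
            if not Path(p).exists():
                raise PipelineError(f"missing model file: {p}")
        if self.input_mode == "matrix" and (
                self.matrix_path is None or not Path(self.matrix_path).exists()):
            raise PipelineError(f"missing input matrix: {self.matrix_path}")
        if (self.generator_config is not None
                and not Path(self.generator_config).exists()):
            raise PipelineError(f"missing generator config: {self.generator_config}")

    @classmethod
    def read_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run(config: RunConfig) -> dict:
    """Execute the full analysis; return (and write) the run manifest.

    Every artifact is tab-separated text under ``config.out_dir``; the
    manifest lists per-stage status, seeds and SHA-256 digests, so a rerun
    with the same config and seed reproduces all numeric outputs exactly.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "estimator": config.estimator,
        "stages": {},
        "artifacts": {},
        "timestamps": {"start": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
                manifest["stages"][name] = {
                    "status": "ok", "seconds": round(time.time() - t0, 2)}
            except Exception as exc:
                manifest["stages"][name] = {"status": f"error: {exc}"}
                _finalize(manifest, artifacts, out)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    state: dict = {}

    @stage("ingest")
    def _ingest():
        if config.input_mode == "synthetic":
            if config.generator_config:
                gcfg = synth.GeneratorConfig.read_yaml(config.generator_config)
            else:
                gcfg = synth.six_factor_preset(n_persons=config.n_persons,
                                               seed=config.seed)
            gcfg = synth.preset_with(gcfg, seed=config.seed,
                                     n_persons=config.n_persons)
            matrix, events, cmap, correlates, truth = synth.simulate_dataset(gcfg)
            events.to_csv(out / "events.tsv", sep="\t", index=False)
            cmap.write_tsv(out / "cluster_map.tsv")
            correlates.to_csv(out / "correlates.tsv", sep="\t", index=False)
            gcfg.write_yaml(out / "generator_truth.yaml")
            artifacts.update({"events": out / "events.tsv",
                              "cluster_map": out / "cluster_map.tsv",
                              "correlates": out / "correlates.tsv",
                              "generator_truth": out / "generator_truth.yaml"})
            # rebuild the matrix from events through the cluster map, so the
            # prep stage is exercised end to end
            state["matrix_raw"] = collapse_codes(events, cmap)
            state["correlates"] = correlates
        else:
            state["matrix_raw"] = BinaryDiagnosisMatrix.read_tsv(config.matrix_path)
            state["correlates"] = None
        manifest["n_persons_raw"] = state["matrix_raw"].n_persons

    @stage("prep")
    def _prep():
        m = filter_cohort(state["matrix_raw"])
        state["matrix"] = m
        m.write_tsv(out / "matrix.tsv")
        artifacts["matrix"] = out / "matrix.tsv"
        manifest["n_persons_analytic"] = m.n_persons
        manifest["removed_no_diagnosis"] = m.meta.get("removed_no_diagnosis", 0)

    @stage("correlate")
    def _correlate():
        R = correlation_matrix(state["matrix"])
        state["R"] = R
        _write_table(R.corr, out / "tetrachoric.tsv")
        _write_table(R.tau.to_frame(), out / "thresholds.tsv")
        artifacts["tetrachoric"] = out / "tetrachoric.tsv"
        artifacts["thresholds"] = out / "thresholds.tsv"
        manifest["smoothed"] = R.smoothed
        manifest["min_eig_before_smoothing"] = R.min_eig_before
        manifest["excluded_degenerate"] = R.excluded

    @stage("fit_ladder")
    def _fit_ladder():
        fits, names = [], []
        n = state["matrix"].n_persons
        for path in config.model_files:
            name = Path(path).stem
            spec = parse_model(Path(path).read_text())
            f = fit(state["R"], n, spec, estimator=config.estimator)
            if config.bootstrap_B >= 2:
                bs = bootstrap_se(state["matrix"], spec, B=config.bootstrap_B,
                                  seed=config.seed, estimator=config.estimator)
                f.loading_se = bs.loading_se
            fits.append(f)
            names.append(name)
            _write_table(f.parameter_table(), out / f"fit_{name}.tsv",
                         index=False)
            artifacts[f"fit_{name}"] = out / f"fit_{name}.tsv"
        state["fits"] = dict(zip(names, fits))
        if len(fits) >= 2:
            table = adjudicate.compare_models(fits, names)
        else:
            alt = adjudicate.alt_indices(fits[0])
            f = fits[0]
            table = pd.DataFrame([{
                "model": names[0], "df": f.df, "CFI": f.indices.cfi,
                "TLI": f.indices.tli, "RMSEA": f.indices.rmsea,
                "SRMR": f.indices.srmr, "FL": alt.pooled["FL"],
                "SD": alt.pooled["SD"], "SE": alt.pooled["SE"],
            }]).set_index("model")
        _write_table(table, out / "model_comparison.tsv")
        artifacts["model_comparison"] = out / "model_comparison.tsv"
        manifest["ladder_models"] = names
        pref = config.preferred_model or names[-1]
        if pref not in state["fits"]:
            raise PipelineError(f"preferred model {pref!r} not in ladder")
        state["preferred"] = pref

    @stage("heatmap")
    def _heatmap():
        if not config.heatmap:
            return
        pref_fit = state["fits"][state["preferred"]]
        order, bounds = heatmap_order(state["R"].corr, pref_fit.spec)
        plot_heatmap(state["R"].corr, order, bounds, str(out / "heatmap.png"))

    @stage("adjudicate")
    def _adjudicate():
        pref_fit = state["fits"][state["preferred"]]
        spec = pref_fit.spec
        m = state["matrix"]
        if config.permutation_K > 0:
            null = adjudicate.random_assignment_null(
                m, spec, K=config.permutation_K, seed=config.seed,
                R=state["R"])
            _write_table(null.null_distributions, out / "permutation_null.tsv",
                         index=False)
            _write_table(null.percentile.to_frame("percentile"),
                         out / "permutation_percentiles.tsv")
            artifacts["permutation_null"] = out / "permutation_null.tsv"
            artifacts["permutation_percentiles"] = out / "permutation_percentiles.tsv"
        if config.split_half:
            specs = {name: f.spec for name, f in state["fits"].items()}
            sh = adjudicate.split_half(m, specs, seed=config.seed,
                                       estimator=config.estimator)
            _write_table(sh.per_model, out / "split_half.tsv")
            _write_table(sh.index_icc.to_frame("icc"),
                         out / "split_half_index_icc.tsv")
            artifacts["split_half"] = out / "split_half.tsv"
        if config.loo:
            loo = adjudicate.loo_scan(m, spec, R=state["R"])
            _write_table(loo.delta, out / "loo_delta.tsv")
            _write_table(loo.summary.to_frame("value"), out / "loo_summary.tsv")
            artifacts["loo_delta"] = out / "loo_delta.tsv"
            artifacts["loo_summary"] = out / "loo_summary.tsv"

    @stage("external")
    def _external():
        corr_tab = state.get("correlates")
        if corr_tab is None or corr_tab.empty:
            return
        pref_fit = state["fits"][state["preferred"]]
        scores = external.factor_scores(pref_fit, state["matrix"],
                                        state["R"].tau)
        reg = external.regress_correlates(scores, corr_tab,
                                          B=config.external_B,
                                          seed=config.seed)
        tests = external.profile_difference_test(reg)
        _write_table(reg.table, out / "correlate_regressions.tsv", index=False)
        _write_table(tests, out / "profile_tests.tsv", index=False)
        artifacts["correlate_regressions"] = out / "correlate_regressions.tsv"
        artifacts["profile_tests"] = out / "profile_tests.tsv"

    _finalize(manifest, artifacts, out)
    return manifest


def _finalize(manifest: dict, artifacts: dict[str, Path], out: Path) -> None:
    manifest["timestamps"]["end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["artifacts"] = {
        name: {"path": str(p.relative_to(out)), "sha256": _digest(p)}
        for name, p in artifacts.items() if p.exists()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir, seed: int = 0) -> dict[str, str]:
    """Write a small deterministic fixture family for the test suite.

    Preset data at n = 2,000, a bank of toy 2x2 tables (including the
    balanced independence table), and toy model files.  Regenerating with
    the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synth.six_factor_preset(n_persons=2000, seed=seed)
    matrix, events, cmap, correlates, truth = synth.simulate_dataset(cfg)
    matrix.write_tsv(out / "matrix_2000.tsv")
    events.to_csv(out / "events_2000.tsv", sep="\t", index=False)
    cmap.write_tsv(out / "cluster_map.tsv")
    correlates.to_csv(out / "correlates_2000.tsv", sep="\t", index=False)
    cfg.write_yaml(out / "generator_config.yaml")

    tables = {
        "independence_balanced": [[25, 25], [25, 25]],
        "positive_association": [[40, 10], [10, 40]],
        "perfect_agreement": [[50, 0], [0, 50]],
        "rare_margin": [[900, 40], [50, 10]],
        "negative_association": [[10, 40], [40, 10]],
    }
    with open(out / "toy_tables.json", "w") as fh:
        json.dump(tables, fh, indent=2, sort_keys=True)

    model_dir = out / "models"
    models.write_ladder(cfg, model_dir)
    (model_dir / "toy_one_factor.model").write_text(
        "F1 =~ a + b + c + d\n")
    (model_dir / "toy_two_factor.model").write_text(
        "F1 =~ a + b + c\nF2 =~ d + e + f\na ~~ d\n")
    paths = {p.stem: str(p) for p in sorted(out.rglob("*")) if p.is_file()}
    return paths
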