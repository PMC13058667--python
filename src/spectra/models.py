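"""Model ladder construction for the six-dimension comorbidity analysis.

Builds the ordered sequence of competing structural models fitted to the
tetrachoric matrix: from a single general factor, through progressively
differentiated correlated-factors models, to the preferred refined
six-factor model and its bifactor counterpart.
"""

from __future__ import annotations

import numpy as np

from .cfa import ModelSpec
from .synth import GeneratorConfig

__all__ = ["truth_model", "primary_assignment", "model_ladder", "write_ladder"]


def primary_assignment(config: GeneratorConfig) -> dict[str, list[str]]:
    """Factor -> primary indicators map from a generating configuration.

    An indicator's primary factor is the factor of its first nonzero
    loading (generation places the primary loading first).
    """
    out: dict[str, list[str]] = {f: [] for f in config.factor_names}
    for j, lab in enumerate(config.labels):
        nz = np.flatnonzero(config.loadings[j] != 0)
        if nz.size == 0:
            raise ValueError(f"diagnosis {lab!r} loads on no factor")
        out[config.factor_names[int(nz[0])]].append(lab)
    return out


def truth_model(config: GeneratorConfig) -> ModelSpec:
    """ModelSpec matching the generating structure (loading pattern,
    cross-loadings and correlated residuals) of a configuration."""
    assign = primary_assignment(config)
    factors = tuple((f, tuple(inds)) for f, inds in assign.items() if inds)
    spec = ModelSpec(factors=factors,
                     residual_pairs=tuple(config.residual_corr))
    for j, lab in enumerate(config.labels):
        nz = np.flatnonzero(config.loadings[j] != 0)
        for ki in nz[1:]:
            spec = spec.with_cross_loading(lab, config.factor_names[int(ki)])
    return spec


def _merge(assign: dict[str, list[str]], groups: dict[str, list[str]]
           ) -> tuple[tuple[str, tuple[str, ...]], ...]:
    factors = []
    for new_name, members in groups.items():
        inds: list[str] = []
        for mem in members:
            inds.extend(assign[mem])
        factors.append((new_name, tuple(inds)))
    return tuple(factors)


def model_ladder(config: GeneratorConfig) -> dict[str, ModelSpec]:
    """Ordered model-comparison ladder over the preset's six domains.

    Keys are model names; values ModelSpecs.  The ladder moves from one
    general dimension to the refined six-factor model (cross-loading and
    correlated residuals included) and a bifactor variant.
    """
    assign = primary_assignment(config)
    F, D, E, S, T, N = ("Fear", "Distress", "Externalizing", "SubstanceUse",
                        "ThoughtProblems", "Neurodevelopmental")
    ladder: dict[str, ModelSpec] = {}
    ladder["m1_general"] = ModelSpec(
        factors=_merge(assign, {"General": [F, D, E, S, T, N]}))
    ladder["m2_int_ext_thought_neuro"] = ModelSpec(
        factors=_merge(assign, {"Internalizing": [F, D],
                                "Externalizing": [E, S],
                                "ThoughtProblems": [T],
                                "Neurodevelopmental": [N]}))
    ladder["m5_int_ext_su_thought_neuro"] = ModelSpec(
        factors=_merge(assign, {"Internalizing": [F, D],
                                "Externalizing": [E],
                                "SubstanceUse": [S],
                                "ThoughtProblems": [T],
                                "Neurodevelopmental": [N]}))
    ladder["m8_fear_distress_ext_thought_neuro"] = ModelSpec(
        factors=_merge(assign, {"Fear": [F], "Distress": [D],
                                "Externalizing": [E, S],
                                "ThoughtProblems": [T],
                                "Neurodevelopmental": [N]}))
    ladder["m9_six_factor"] = ModelSpec(
        factors=_merge(assign, {F: [F], D: [D], E: [E], S: [S],
                                T: [T], N: [N]}))
    ladder["m9_5_six_factor_refined"] = truth_model(config)
    ladder["m10_bifactor"] = ModelSpec(
        factors=_merge(assign, {F: [F], D: [D], E: [E], S: [S],
                                T: [T], N: [N]}),
        bifactor=True)
    return ladder


def write_ladder(config: GeneratorConfig, out_dir) -> dict[str, str]:
    """Write each ladder model as a mini-language text file; return paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, spec in model_ladder(config).items():
        p = out / f"{name}.model"
        p.write_text(spec.to_text())
        paths[name] = str(p)
    return paths
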