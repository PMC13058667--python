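import numpy as np
import pandas as pd
import pytest

from conftest import loading_errors
from spectra.cfa import (FitIndices, ModelSpec, bootstrap_se, fit,
                         fit_indices, implied_matrix, parse_model,
                         pairwise_variance_jackknife, warm_start_vector)
from spectra.synth import GeneratorConfig, simulate_dataset


def _labelled(S, labels):
    return pd.DataFrame(S, index=labels, columns=labels)


class TestParseModel:
    def test_single_factor(self):
        spec = parse_model("F1 =~ a + b + c")
        assert spec.factors == (("F1", ("a", "b", "c")),)
        assert spec.residual_pairs == ()
        assert not spec.bifactor

    def test_free_parameter_count(self):
        spec = parse_model("F1 =~ a + b\nF2 =~ c + d\na ~~ c")
        assert len(spec.factors) == 2
        assert spec.residual_pairs == (("a", "c"),)
        assert spec.n_free == 6       # 4 loadings + 1 factor corr + 1 residual

    def test_duplicate_residual_rejected(self):
        with pytest.raises(ValueError, match="duplicate residual"):
            parse_model("F1 =~ a + b + c + d\na ~~ c\na ~~ c")

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_model("F1 =~ a + b\nwhat is this")

    def test_general_directive(self):
        spec = parse_model("F1 =~ a + b + c\nF2 =~ d + e + f\ngeneral: on")
        assert spec.bifactor
        assert spec.factor_names == ["F1", "F2", "G"]
        # 6 specific + 6 general loadings, orthogonal factors
        assert spec.n_free == 12

    def test_cross_loading_detected(self):
        spec = parse_model("F1 =~ a + b + c\nF2 =~ c + d + e")
        assert spec.cross_loadings == [("c", "F2")]
        assert spec.primary_factor("c") == "F1"

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            parse_model("F1 =~ a + b\nF2 =~ a + b")

    def test_comments_and_round_trip(self):
        text = "F1 =~ a + b + c  # loadings\nF2 =~ d + e + f\na ~~ d\n"
        spec = parse_model(text)
        assert parse_model(spec.to_text()) == spec


class TestImpliedMatrix:
    def test_one_factor_products(self):
        spec = parse_model("F =~ a + b + c")
        S = implied_matrix(spec, np.array([[0.6], [0.7], [0.8]]))
        assert S[0, 1] == pytest.approx(0.42)
        assert S[0, 2] == pytest.approx(0.48)
        assert S[1, 2] == pytest.approx(0.56)

    def test_residual_is_additive_cell(self):
        spec = parse_model("F =~ a + b + c + d\na ~~ b")
        S = implied_matrix(spec, np.array([[0.6], [0.7], [0.8], [0.5]]),
                           residuals={("a", "b"): 0.1})
        assert S[0, 1] == pytest.approx(0.52)
        assert S[0, 2] == pytest.approx(0.48)
        assert S[1, 2] == pytest.approx(0.56)

    def test_unit_diagonal_by_construction(self):
        rng = np.random.default_rng(4)
        spec = parse_model("F1 =~ a + b + c\nF2 =~ d + e + f")
        for _ in range(5):
            L = np.zeros((6, 2))
            L[:3, 0] = rng.uniform(0.2, 0.8, 3)
            L[3:, 1] = rng.uniform(0.2, 0.8, 3)
            phi = np.array([[1.0, 0.4], [0.4, 1.0]])
            S = implied_matrix(spec, L, phi)
            assert np.allclose(np.diag(S), 1.0)


class TestFit:
    def test_zero_residual_recovery(self):
        spec = parse_model("F =~ a + b + c")
        lam = np.array([[0.6], [0.7], [0.8]])
        R = _labelled(implied_matrix(spec, lam), ["a", "b", "c"])
        res = fit(R, 5000, spec)
        assert res.discrepancy < 1e-10
        assert np.allclose(res.loadings.to_numpy(), lam, atol=1e-6)

    def test_two_factor_phi_recovery(self):
        spec = parse_model("F1 =~ a + b + c\nF2 =~ d + e + f")
        L = np.zeros((6, 2))
        L[:3, 0] = 0.7
        L[3:, 1] = 0.7
        R = _labelled(implied_matrix(spec, L, np.array([[1, .5], [.5, 1]])),
                      list("abcdef"))
        res = fit(R, 5000, spec)
        assert res.factor_corr.at["F1", "F2"] == pytest.approx(0.5, abs=1e-4)

    def test_bifactor_exact_recovery(self):
        # three specific groups: the minimal identified bifactor layout
        spec = parse_model(
            "F1 =~ a + b + c\nF2 =~ d + e + f\nF3 =~ g + h + i\ngeneral: on")
        L = np.zeros((9, 4))
        L[:3, 0] = (0.5, 0.4, 0.45)
        L[3:6, 1] = (0.55, 0.5, 0.6)
        L[6:, 2] = (0.35, 0.45, 0.5)
        L[:, 3] = (0.5, 0.55, 0.6, 0.45, 0.5, 0.4, 0.55, 0.6, 0.5)
        R = _labelled(implied_matrix(spec, L), list("abcdefghi"))
        res = fit(R, 5000, spec)
        assert res.discrepancy < 1e-10
        assert np.allclose(res.loadings.to_numpy(), L, atol=1e-5)

    def test_residual_pair_exact_recovery(self):
        spec = parse_model("F =~ a + b + c + d\na ~~ b")
        lam = np.array([[0.6], [0.7], [0.8], [0.5]])
        R = _labelled(
            implied_matrix(spec, lam, residuals={("a", "b"): 0.12}),
            list("abcd"))
        res = fit(R, 5000, spec)
        assert res.residual_corrs[("a", "b")] == pytest.approx(0.12, abs=1e-6)

    def test_indicator_order_invariance(self, preset_R_20k, truth_spec,
                                        preset_fit_20k):
        """Permuting factors/indicators in the spec leaves estimates
        unchanged (up to the permutation)."""
        reordered = ModelSpec(
            factors=tuple(reversed([(f, tuple(reversed(inds)))
                                    for f, inds in truth_spec.factors])),
            residual_pairs=truth_spec.residual_pairs,
            bifactor=truth_spec.bifactor)
        res2 = fit(preset_R_20k, preset_fit_20k.n, reordered)
        for ind, fac in truth_spec.loading_entries:
            assert res2.loadings.at[ind, fac] == pytest.approx(
                preset_fit_20k.loadings.at[ind, fac], abs=1e-5)

    def test_sign_convention(self):
        """Each factor's loading sum is non-negative even when the data are
        generated with negated indicators."""
        spec = parse_model("F =~ a + b + c + d")
        lam = np.array([[-0.6], [-0.7], [-0.8], [-0.5]])
        R = _labelled(implied_matrix(spec, lam), list("abcd"))
        res = fit(R, 5000, spec)
        assert res.loadings["F"].sum() >= 0

    def test_nested_models_never_worsen(self, preset_R_20k, truth_spec):
        base = fit(preset_R_20k, 20_000, truth_spec)
        richer_spec = truth_spec.with_residual("alcohol use disorder",
                                               "cannabis use disorder")
        warm = warm_start_vector(richer_spec, base)
        richer = fit(preset_R_20k, 20_000, richer_spec, extra_starts=[warm])
        assert richer.discrepancy <= base.discrepancy + 1e-12

    def test_unknown_indicator_fails_at_fit_time(self):
        spec = parse_model("F =~ a + b + c + z")
        R = _labelled(np.eye(3), ["a", "b", "c"])
        with pytest.raises(KeyError, match="z"):
            fit(R, 100, spec)

    def test_preset_recovery(self, preset_R_20k, preset_fit_20k,
                             preset_cfg_20k):
        errs = loading_errors(preset_fit_20k, preset_cfg_20k)
        assert np.max(np.abs(errs)) < 0.1
        assert np.sqrt(np.mean(errs ** 2)) < 0.05
        phi_err = np.abs(
            preset_fit_20k.factor_corr.to_numpy() - preset_cfg_20k.factor_corr)
        assert phi_err.max() < 0.1
        assert preset_fit_20k.converged
        assert not preset_fit_20k.heywood


class TestFitIndices:
    def test_saturated_fit(self):
        idx = fit_indices(50.0, 50, 500.0, 60, 1000, np.zeros(10))
        assert idx.cfi == 1.0
        assert idx.rmsea == 0.0

    def test_worked_arithmetic(self):
        idx = fit_indices(100.0, 50, 1000.0, 60, 1001, np.full(3, 0.01))
        assert idx.rmsea == pytest.approx(np.sqrt(50 / 50_000))
        assert idx.cfi == pytest.approx(1 - 50 / 940)
        assert idx.srmr == pytest.approx(0.01)

    def test_zero_residuals_srmr(self):
        idx = fit_indices(10.0, 5, 100.0, 10, 500, np.zeros(10))
        assert idx.srmr == 0.0

    def test_degenerate_null_flagged(self):
        idx = fit_indices(10.0, 5, 8.0, 10, 500, np.zeros(10))
        assert idx.degenerate_null


def _one_factor_config(n, seed, d=5, lam=0.7):
    return GeneratorConfig(
        n_persons=n, labels=[f"v{j}" for j in range(d)],
        factor_names=["F"], factor_corr=np.eye(1),
        loadings=np.full((d, 1), lam),
        prevalences=np.full(d, 0.3), seed=seed)


class TestBootstrapSe:
    def test_degenerate_resampler_gives_zero_se(self):
        cfg = _one_factor_config(800, 21)
        m, *_ = simulate_dataset(cfg)
        spec = parse_model("F =~ " + " + ".join(cfg.labels))
        bs = bootstrap_se(m, spec, B=2,
                          index_sampler=lambda rng, n: np.arange(n))
        assert np.allclose(bs.loading_se.to_numpy(), 0.0)

    def test_matches_monte_carlo_sampling_distribution(self):
        """Bootstrap SEs track the SD of estimates across independent
        datasets within 50%."""
        spec_text = "F =~ v0 + v1 + v2 + v3 + v4"
        spec = parse_model(spec_text)
        n = 2000
        ests = []
        for rep in range(100):
            cfg = _one_factor_config(n, 1000 + rep)
            m, *_ = simulate_dataset(cfg)
            from spectra.tetra import correlation_matrix

            f = fit(correlation_matrix(m), n, spec)
            ests.append(f.loadings["F"].to_numpy())
        mc_sd = np.std(np.asarray(ests), axis=0, ddof=1)

        cfg = _one_factor_config(n, 555)
        m, *_ = simulate_dataset(cfg)
        bs = bootstrap_se(m, spec, B=100, seed=3)
        ratio = bs.loading_se["F"].to_numpy() / mc_sd
        assert np.all(ratio > 0.5) and np.all(ratio < 1.5)

    def test_se_shrinks_with_n(self):
        spec = parse_model("F =~ v0 + v1 + v2 + v3 + v4")
        ses = {}
        for n in (500, 4000):
            cfg = _one_factor_config(n, 77)
            m, *_ = simulate_dataset(cfg)
            bs = bootstrap_se(m, spec, B=30, seed=5)
            ses[n] = bs.loading_se["F"].to_numpy()
        assert np.all(ses[4000] < ses[500])

    def test_b_below_two_rejected(self):
        cfg = _one_factor_config(200, 1)
        m, *_ = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_se(m, parse_model("F =~ v0 + v1 + v2 + v3 + v4"), B=1)


class TestDwls:
    def test_dwls_recovers_like_uls(self):
        cfg = _one_factor_config(3000, 31)
        m, *_ = simulate_dataset(cfg)
        from spectra.tetra import correlation_matrix

        spec = parse_model("F =~ v0 + v1 + v2 + v3 + v4")
        W = pairwise_variance_jackknife(m, n_batches=10, seed=2)
        R = correlation_matrix(m)
        res = fit(R, 3000, spec, estimator="dwls", weights=W)
        assert res.converged
        assert np.all(np.abs(res.loadings["F"].to_numpy() - 0.7) < 0.1)
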