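import numpy as np
import pandas as pd
import pytest

from oracles import icc_a1_mean_squares
from spectra import adjudicate
from spectra.adjudicate import (alt_indices, candidate_scan, compare_models,
                                icc_absolute, loo_scan,
                                random_assignment_null, split_half,
                                split_indices)
from spectra.cfa import ModelSpec, fit, implied_matrix, parse_model
from spectra.synth import preset_with, simulate_dataset, six_factor_preset


def _fake_fit(loadings_by_factor, ses=None):
    """Minimal FitResult carrying only what alt_indices reads."""
    from spectra.cfa import FitIndices, FitResult

    factors = tuple((f, tuple(f"{f}_{i}" for i in range(len(lams))))
                    for f, lams in loadings_by_factor.items())
    spec = ModelSpec(factors=factors)
    inds = spec.indicators
    cols = [f for f, _ in factors]
    L = pd.DataFrame(0.0, index=inds, columns=cols)
    SE = pd.DataFrame(0.0, index=inds, columns=cols) if ses else None
    for f, lams in loadings_by_factor.items():
        for i, lam in enumerate(lams):
            L.at[f"{f}_{i}", f] = lam
            if ses:
                SE.at[f"{f}_{i}", f] = ses[f][i]
    d = len(inds)
    return FitResult(
        spec=spec, loadings=L,
        factor_corr=pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols),
        residual_corrs={}, uniquenesses=pd.Series(0.5, index=inds),
        discrepancy=0.0, T=0.0, df=1, n=100,
        indices=FitIndices(1.0, 1.0, 0.0, 0.0), converged=True, heywood=[],
        estimator="uls",
        sample_corr=pd.DataFrame(np.eye(d), index=inds, columns=inds),
        n_free=spec.n_free, start_index=0, loading_se=SE)


class TestAltIndices:
    def test_direct_computation(self):
        alt = alt_indices(_fake_fit({"F": [0.5, 0.6, 0.7]}))
        assert alt.per_factor.at["F", "FL"] == pytest.approx(0.6)
        assert alt.per_factor.at["F", "SD"] == pytest.approx(0.1)

    def test_equal_loadings_zero_sd(self):
        alt = alt_indices(_fake_fit({"F": [0.6, 0.6, 0.6, 0.6]}))
        assert alt.per_factor.at["F", "SD"] == 0.0

    def test_formula_oracle_with_ses(self):
        lams = [0.43, 0.52, 0.61, 0.70]
        ses = [0.01, 0.02, 0.02, 0.03]
        alt = alt_indices(_fake_fit({"F": lams}, ses={"F": ses}))
        assert alt.per_factor.at["F", "FL"] == pytest.approx(0.565)
        assert alt.per_factor.at["F", "SE"] == pytest.approx(0.02)
        assert alt.per_factor.at["F", "SD"] == pytest.approx(
            np.std(lams, ddof=1), abs=1e-12)

    def test_single_indicator_factor_flagged(self):
        alt = alt_indices(_fake_fit({"F": [0.5, 0.6], "Gx": [0.4]}))
        assert np.isnan(alt.per_factor.at["Gx", "SD"])
        assert any("Gx" in f for f in alt.flags)


class TestCompareModels:
    def test_same_model_twice_identical_rows(self, preset_R_20k, truth_spec):
        f1 = fit(preset_R_20k, 20_000, truth_spec)
        f2 = fit(preset_R_20k, 20_000, truth_spec)
        table = compare_models([f1, f2], ["a", "b"])
        cols = ["CFI", "TLI", "RMSEA", "SRMR", "FL", "SD"]
        assert np.allclose(table.loc["a", cols].to_numpy(dtype=float),
                           table.loc["b", cols].to_numpy(dtype=float))

    def test_rank_invariant_to_input_order(self, preset_R_20k, truth_spec,
                                           preset_cfg_20k):
        from spectra.models import model_ladder

        ladder = model_ladder(preset_cfg_20k)
        f_six = fit(preset_R_20k, 20_000, truth_spec)
        f_gen = fit(preset_R_20k, 20_000, ladder["m1_general"])
        t1 = compare_models([f_six, f_gen], ["six", "general"])
        t2 = compare_models([f_gen, f_six], ["general", "six"])
        for col in ["rank_CFI", "rank_RMSEA", "rank_FL"]:
            assert t1.loc["six", col] == t2.loc["six", col]
            assert t1.loc["general", col] == t2.loc["general", col]

    def test_different_matrices_rejected(self, preset_R_20k, truth_spec):
        f1 = fit(preset_R_20k, 20_000, truth_spec)
        cfg = six_factor_preset(n_persons=1500, seed=99)
        m, *_ = simulate_dataset(cfg)
        from spectra.tetra import correlation_matrix

        f2 = fit(correlation_matrix(m), 1500, truth_spec)
        with pytest.raises(ValueError, match="different"):
            compare_models([f1, f2])


class TestRandomAssignmentNull:
    def test_k_zero_flagged(self, small_data_4k, truth_spec):
        from spectra.tetra import correlation_matrix

        m = small_data_4k[0]
        res = random_assignment_null(m, truth_spec, K=0, seed=1)
        assert res.null_distributions.empty
        assert res.percentile.isna().all()

    def test_null_specs_preserve_size_multiset(self, small_data_4k,
                                               truth_spec):
        m = small_data_4k[0]
        res = random_assignment_null(m, truth_spec, K=5, seed=2)
        base_sizes = sorted(
            sum(1 for i in truth_spec.indicators
                if truth_spec.primary_factor(i) == f)
            for f, _ in truth_spec.factors)
        for ns in res.null_specs:
            assert sorted(len(inds) for _, inds in ns.factors) == base_sizes
            assert ns.residual_pairs == ()
            assert sorted(ns.indicators) == sorted(truth_spec.indicators)

    def test_reproducible_under_seed(self, small_data_4k, truth_spec):
        m = small_data_4k[0]
        r1 = random_assignment_null(m, truth_spec, K=3, seed=5)
        r2 = random_assignment_null(m, truth_spec, K=3, seed=5)
        pd.testing.assert_frame_equal(r1.null_distributions,
                                      r2.null_distributions)


class TestIcc:
    def test_identity(self):
        assert icc_absolute([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_offset_penalized_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0
        val = icc_absolute(x, y)
        assert val == pytest.approx(icc_a1_mean_squares(x, y), abs=1e-12)
        assert val < 0.2          # absolute agreement punishes the offset

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")

        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.3, size=12) + 0.1
        df = pd.DataFrame({
            "targets": np.r_[np.arange(12), np.arange(12)],
            "raters": ["a"] * 12 + ["b"] * 12,
            "scores": np.r_[x, y]})
        ref = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="scores")
        ref_val = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_absolute(x, y) == pytest.approx(ref_val, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 1000))
        assert abs(icc_absolute(x, y)) < 0.1

    def test_double_constant_undefined(self):
        assert np.isnan(icc_absolute([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))


class TestSplitHalf:
    def test_partition_invariants(self):
        idx1, idx2 = split_indices(1001, seed=4)
        assert len(idx1) == 500 and len(idx2) == 501
        assert np.intersect1d(idx1, idx2).size == 0
        assert np.array_equal(np.sort(np.r_[idx1, idx2]), np.arange(1001))

    def test_identical_halves_give_perfect_agreement(self, small_data_4k,
                                                     truth_spec):
        m = small_data_4k[0]
        idx = np.arange(m.n_persons)
        res = split_half(m, {"six": truth_spec}, partition=(idx, idx))
        row = res.per_model.loc["six"]
        assert row["loading_icc"] == pytest.approx(1.0)
        for col in ("dCFI", "dTLI", "dRMSEA", "dSRMR"):
            assert row[col] == 0.0

    def test_swapped_halves_symmetric(self, small_data_4k, truth_spec):
        m = small_data_4k[0]
        idx1, idx2 = split_indices(m.n_persons, seed=6)
        r1 = split_half(m, {"six": truth_spec}, partition=(idx1, idx2))
        r2 = split_half(m, {"six": truth_spec}, partition=(idx2, idx1))
        a, b = r1.per_model.loc["six"], r2.per_model.loc["six"]
        assert a["loading_icc"] == pytest.approx(b["loading_icc"], abs=1e-12)
        for col in ("dCFI", "dRMSEA", "dSRMR"):
            assert a[col] == pytest.approx(b[col], abs=1e-12)


class TestLooScan:
    def test_orthogonal_blocks_are_separable(self):
        """With Phi = 0 and an exact input matrix, removing a block-A
        indicator cannot move block-B loadings."""
        spec = parse_model("A =~ a1 + a2 + a3 + a4\nB =~ b1 + b2 + b3 + b4")
        L = np.zeros((8, 2))
        L[:4, 0] = (0.5, 0.6, 0.7, 0.55)
        L[4:, 1] = (0.65, 0.5, 0.6, 0.7)
        labels = spec.indicators
        S = implied_matrix(spec, L, np.eye(2))
        R = pd.DataFrame(S, index=labels, columns=labels)
        res = loo_scan(None, spec, R=R, n=5000)
        for k in ("a1", "a2", "a3", "a4"):
            for j in ("b1", "b2", "b3", "b4"):
                assert abs(res.delta.at[j, k]) < 1e-8

    def test_shape_and_diagonal(self, small_data_4k, truth_spec):
        m = small_data_4k[0]
        res = loo_scan(m, truth_spec)
        d = len(truth_spec.indicators)
        assert res.delta.shape == (d, d)
        assert res.delta.to_numpy()[np.diag_indices(d)].tolist() == \
            [pytest.approx(np.nan, nan_ok=True)] * d
        assert {"mean", "median", "sd", "min", "max"} <= set(res.summary.index)

    def test_small_factor_removal_skipped(self):
        spec = parse_model("A =~ a1 + a2\nB =~ b1 + b2 + b3 + b4")
        L = np.zeros((6, 2))
        L[:2, 0] = 0.7
        L[2:, 1] = 0.6
        labels = spec.indicators
        R = pd.DataFrame(implied_matrix(spec, L, np.eye(2) + 0.3 - 0.3 * np.eye(2)),
                         index=labels, columns=labels)
        res = loo_scan(None, spec, R=R, n=1000)
        assert "a1" in res.skipped and "a2" in res.skipped


class TestCandidateScan:
    def test_redundant_candidate_flagged(self, small_data_4k, truth_spec):
        m = small_data_4k[0]
        pair = truth_spec.residual_pairs[0]
        table = candidate_scan(m, truth_spec, [("residual", pair)])
        assert table.loc[0, "status"] == "redundant"
        assert table.loc[0, "delta_F"] == 0.0

    def test_delta_f_nonnegative(self, preset_R_20k, preset_matrix_20k,
                                 truth_spec):
        cands = [("residual", ("alcohol use disorder", "panic disorder")),
                 ("cross", ("schizophrenia", "Distress")),
                 ("residual", ("tic disorder", "dysthymia"))]
        table = candidate_scan(preset_matrix_20k, truth_spec, cands,
                               R=preset_R_20k)
        ok = table[table["status"] == "ok"]
        assert (ok["delta_F"] >= 0).all()

    def test_true_residual_ranks_first_among_decoys(self, preset_R_20k,
                                                    preset_matrix_20k,
                                                    truth_spec):
        """Dropping the generating MDD-dysthymia residual and scanning it
        against decoys recovers it as the top candidate."""
        target = ("major depressive disorder", "dysthymia")
        reduced = ModelSpec(
            factors=truth_spec.factors,
            residual_pairs=tuple(p for p in truth_spec.residual_pairs
                                 if set(p) != set(target)),
            bifactor=truth_spec.bifactor)
        rng = np.random.default_rng(10)
        labels = list(truth_spec.indicators)
        decoys = []
        existing = {frozenset(p) for p in truth_spec.residual_pairs}
        while len(decoys) < 10:
            a, b = rng.choice(labels, 2, replace=False)
            if frozenset((a, b)) not in existing | {frozenset((a, b)) for _, (a2, b2) in decoys for a, b in [(a2, b2)]}:
                decoys.append(("residual", (str(a), str(b))))
        table = candidate_scan(preset_matrix_20k, reduced,
                               [("residual", target)] + decoys,
                               R=preset_R_20k)
        assert table.loc[0, "candidate"] == "residual:" + "~".join(target)
        assert table.loc[0, "estimate"] == pytest.approx(0.15, abs=0.05)
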