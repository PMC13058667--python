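import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (bvn_cdf_genz, dichotomized_bvn_sample,
                     nearest_corr_clip_iteration, tetrachoric_grid)
from spectra.ehr_prep import BinaryDiagnosisMatrix
from spectra.synth import preset_with, six_factor_preset, simulate_dataset
from spectra.tetra import (PairTable, bvn_cdf, correlation_matrix,
                           heatmap_order, nearest_pd, tetrachoric_mle)


class TestBvnCdf:
    def test_matches_genz_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            h, k = rng.normal(scale=2.0, size=2)
            rho = rng.uniform(-0.98, 0.98)
            assert bvn_cdf(h, k, rho) == pytest.approx(
                bvn_cdf_genz(h, k, rho), abs=5e-7)

    @pytest.mark.parametrize("h,k,rho,expected", [
        (0.0, 0.0, 0.0, 0.25),
        (0.0, 0.0, 0.5, 0.25 + np.arcsin(0.5) / (2 * np.pi)),
        (np.inf, 1.3, 0.4, None),          # reduces to univariate
        (1.0, 1.0, 1.0, None),             # comonotone
    ])
    def test_special_points(self, h, k, rho, expected):
        from scipy.special import ndtr

        val = bvn_cdf(h, k, rho)
        if expected is None:
            expected = ndtr(min(h, k))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_axis_cases_match_genz(self):
        # one argument at zero exercises the infinite Owen's T branch
        for h, k, rho in [(0.0, 1.2, 0.6), (0.0, -1.2, 0.6), (-0.7, 0.0, -0.4)]:
            assert bvn_cdf(h, k, rho) == pytest.approx(
                bvn_cdf_genz(h, k, rho), abs=5e-7)


class TestTetrachoricMle:
    def test_balanced_independence(self):
        est = tetrachoric_mle(PairTable(25, 25, 25, 25))
        assert est.rho == pytest.approx(0.0, abs=1e-5)
        assert est.tau_row == 0.0
        assert est.tau_col == 0.0
        assert est.converged

    def test_matches_grid_oracle(self):
        est = tetrachoric_mle(PairTable(40, 10, 10, 40))
        oracle = tetrachoric_grid(40, 10, 10, 40)
        assert est.rho == pytest.approx(oracle, abs=1e-3)
        assert est.rho > 0.5

    def test_zero_cells_corrected(self):
        est = tetrachoric_mle(PairTable(50, 0, 0, 50))
        assert est.corrected
        assert est.rho >= 0.95
        assert est.rho == pytest.approx(tetrachoric_grid(50, 0, 0, 50), abs=1e-3)

    def test_degenerate_margin_flagged(self):
        est = tetrachoric_mle(PairTable(60, 40, 0, 0))
        assert not est.converged
        assert np.isnan(est.rho)
        assert "degenerate" in est.message

    @given(st.tuples(st.integers(0, 80), st.integers(0, 80),
                     st.integers(0, 80), st.integers(0, 80)))
    @settings(max_examples=40, deadline=None)
    def test_recoding_antisymmetry(self, cells):
        """Flipping one variable's 0/1 coding flips rho's sign exactly."""
        n00, n01, n10, n11 = cells
        if n00 + n01 + n10 + n11 == 0:
            return
        if (n10 + n11 == 0 or n00 + n01 == 0
                or n01 + n11 == 0 or n00 + n10 == 0):
            return
        a = tetrachoric_mle(PairTable(n00, n01, n10, n11))
        b = tetrachoric_mle(PairTable(n01, n00, n11, n10))  # recode y
        assert a.rho == -b.rho

    def test_calibration_small(self):
        """Mean estimate near the generating rho on dichotomized normals."""
        rng = np.random.default_rng(42)
        est = []
        for _ in range(30):
            x, y = dichotomized_bvn_sample(0.5, 2000, rng)
            est.append(tetrachoric_mle(PairTable.from_binary(x, y)).rho)
        assert np.mean(est) == pytest.approx(0.5, abs=0.03)


def _matrix_from_values(values):
    n, d = values.shape
    return BinaryDiagnosisMatrix(
        person_ids=np.array([f"p{i}" for i in range(n)]),
        labels=[f"dx{j}" for j in range(d)], values=values)


class TestCorrelationMatrix:
    def test_independence_case(self):
        # n chosen so the max over all 741 estimates sits inside the bound
        cfg = six_factor_preset(n_persons=20_000, seed=3)
        cfg = preset_with(cfg, loadings=np.zeros_like(cfg.loadings),
                          residual_corr={},
                          prevalences=np.full(len(cfg.labels), 0.5))
        m, *_ = simulate_dataset(cfg)
        res = correlation_matrix(m)
        off = res.corr.to_numpy()[~np.eye(len(res.labels), dtype=bool)]
        assert np.max(np.abs(off)) < 0.06

    def test_converges_to_implied_matrix(self):
        # n chosen so the extreme order statistic over all 741 pairs sits
        # well inside the tolerance
        cfg = six_factor_preset(n_persons=200_000, seed=0)
        m, *_, truth = simulate_dataset(cfg)
        res = correlation_matrix(m)
        err = np.abs(res.corr.to_numpy() - truth.implied_corr)
        assert err.max() < 0.03

    def test_row_duplication_invariance(self, small_data_4k):
        """The 2x2 tables are sufficient: stacking the data twice changes
        nothing."""
        m = small_data_4k[0]
        doubled = BinaryDiagnosisMatrix(
            person_ids=np.concatenate([m.person_ids, m.person_ids]),
            labels=list(m.labels),
            values=np.vstack([m.values, m.values]))
        r1 = correlation_matrix(m).corr.to_numpy()
        r2 = correlation_matrix(doubled).corr.to_numpy()
        assert np.allclose(r1, r2, atol=1e-9)

    def test_column_permutation_equivariance(self, small_data_4k):
        m = small_data_4k[0]
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(m.labels))
        mp = m.subset_diagnoses([m.labels[i] for i in perm])
        r1 = correlation_matrix(m).corr
        r2 = correlation_matrix(mp).corr
        assert np.allclose(r1.loc[mp.labels, mp.labels].to_numpy(),
                           r2.to_numpy(), atol=1e-12)

    def test_degenerate_column_excluded(self):
        values = np.array([[1, 0, 1], [0, 0, 1], [1, 0, 0], [0, 0, 1]],
                          dtype=np.int8)
        res = correlation_matrix(_matrix_from_values(values))
        assert res.excluded == ["dx1"]
        assert res.labels == ["dx0", "dx2"]


class TestNearestPd:
    def test_pd_input_unchanged(self):
        R = np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.1], [0.2, 0.1, 1.0]])
        assert np.allclose(nearest_pd(R), R, atol=1e-10)

    def test_identity_fixed_point(self):
        assert np.allclose(nearest_pd(np.eye(4)), np.eye(4))

    def test_indefinite_matches_clip_iteration_oracle(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        out = nearest_pd(R, tol=1e-10, max_iter=2000)
        assert np.linalg.eigvalsh(out)[0] >= -1e-8
        assert np.allclose(np.diag(out), 1.0)
        oracle = nearest_corr_clip_iteration(R)
        assert np.max(np.abs(out - oracle)) < 1e-6

    def test_rejects_asymmetric_input(self):
        R = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nearest_pd(R)


class TestHeatmapOrder:
    def test_two_block_rule(self):
        from spectra.cfa import parse_model

        spec = parse_model("A =~ a + b\nB =~ c + d")
        R = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        order, bounds = heatmap_order(R, spec)
        assert set(order[:2]) == {"a", "b"}
        assert set(order[2:]) == {"c", "d"}
        assert bounds == [2, 4]

    def test_permutation_is_bijection(self, preset_R_20k, truth_spec):
        order, _ = heatmap_order(preset_R_20k.corr, truth_spec)
        assert sorted(order) == sorted(preset_R_20k.labels)

    def test_preset_block_sizes(self, preset_R_20k, truth_spec):
        _, bounds = heatmap_order(preset_R_20k.corr, truth_spec)
        sizes = np.diff([0] + bounds).tolist()
        # blocks are primary assignments: a cross-loading stays in the block
        # of its first-listed factor
        expected = []
        seen = set()
        for _, inds in truth_spec.factors:
            block = [i for i in inds if i not in seen]
            seen.update(block)
            expected.append(len(block))
        assert sizes == expected

    def test_missing_diagnosis_errors(self):
        from spectra.cfa import parse_model

        spec = parse_model("A =~ a + b + c")
        R = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(ValueError, match="d"):
            heatmap_order(R, spec)
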