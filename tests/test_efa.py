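"""EFA tests: minres extraction, oblimin rotation, parallel analysis, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogvar.efa import (
    ExploratoryFactorAnalysis,
    _quartimin_value,
    extract_factors,
    factor_scores,
    loop_parallel,
    oblimin_rotate,
    parallel_analysis,
    tucker_congruence,
)
from tests.conftest import make_factor_scores


class TestExtractFactors:
    def test_identity_gives_null_loadings(self):
        lam, uniq = extract_factors(np.eye(7), 1)
        assert np.all(np.abs(lam) < 0.05)
        assert np.all(uniq > 0.9)

    def test_exact_one_factor_structure(self):
        lam0 = np.full(6, 0.8)
        R = np.outer(lam0, lam0) + np.diag(1 - lam0**2)
        lam, uniq = extract_factors(R, 1)
        np.testing.assert_allclose(lam[:, 0], 0.8, atol=1e-3)
        np.testing.assert_allclose(uniq, 0.36, atol=1e-3)

    def test_three_factor_recovery_congruence(self):
        Ltrue = np.zeros((11, 3))
        Ltrue[:5, 0] = 0.78
        Ltrue[5:9, 1] = 0.72
        Ltrue[9:, 2] = 0.68
        scores, _ = make_factor_scores(5000, Ltrue, seed=0)
        R = scores.corr().to_numpy()
        lam, _ = extract_factors(R, 3)
        rot = oblimin_rotate(lam)
        cong = np.abs(tucker_congruence(rot.loadings, Ltrue))
        # each generating factor matched by some rotated factor
        assert np.all(cong.max(axis=0) >= 0.95)

    def test_non_psd_repair_warns(self):
        R = np.array([[1.0, 0.95, -0.5], [0.95, 1.0, 0.6], [-0.5, 0.6, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        with pytest.warns(UserWarning, match="repair"):
            lam, _ = extract_factors(R, 1)
        assert np.all(np.isfinite(lam))

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            extract_factors(np.eye(4), 4)


class TestOblimin:
    def test_single_factor_identity(self):
        lam = np.linspace(0.3, 0.8, 6)[:, None]
        res = oblimin_rotate(lam)
        np.testing.assert_allclose(res.loadings, lam)
        np.testing.assert_allclose(res.Phi, np.eye(1))

    def test_model_implied_matrix_invariant(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(-0.3, 0.9, size=(10, 3))
        res = oblimin_rotate(A)
        before = A @ A.T
        after = res.loadings @ res.Phi @ res.loadings.T
        np.testing.assert_allclose(before, after, atol=1e-8)

    def test_two_factor_grid_search_oracle(self):
        # exhaustive grid over oblique transformations T with unit columns:
        # the gradient-projection optimum must not be beaten by the grid
        A = np.array([[0.8, 0.1], [0.75, 0.15], [0.65, 0.05],
                      [0.1, 0.7], [0.05, 0.75], [0.2, 0.6]])
        res = oblimin_rotate(A)
        best = np.inf
        for th1 in np.linspace(0, np.pi, 181):
            for th2 in np.linspace(0, np.pi, 181):
                T = np.array([[np.cos(th1), np.cos(th2)],
                              [np.sin(th1), np.sin(th2)]])
                if abs(np.linalg.det(T)) < 1e-3:
                    continue
                L = A @ np.linalg.inv(T.T)
                val = _quartimin_value(L)
                if val < best:
                    best = val
        assert res.criterion <= best + 1e-4

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(-0.5, 0.9, size=(8, 2))
        res = oblimin_rotate(A)
        np.testing.assert_allclose(
            A @ A.T, res.loadings @ res.Phi @ res.loadings.T, atol=1e-7
        )
        np.testing.assert_allclose(np.diag(res.Phi), 1.0, atol=1e-8)


class TestParallelAnalysis:
    def test_deterministic_given_seed(self):
        scores, _ = make_factor_scores(300, np.full((6, 1), 0.7), seed=2)
        a = parallel_analysis(scores, seed=5)
        b = parallel_analysis(scores, seed=5)
        assert a.suggested == b.suggested
        np.testing.assert_array_equal(a.reference, b.reference)

    def test_pure_noise_quantile_reference_suggests_at_most_one(self):
        # with the 95% quantile reference, pure noise triggers a factor in
        # at most ~5% of datasets
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(15):
            X = pd.DataFrame(rng.standard_normal((500, 11)))
            if parallel_analysis(X, seed=s, quantile=0.95).suggested <= 1:
                hits += 1
        assert hits >= 14

    def test_pure_noise_mean_reference_never_inflates_far(self):
        # the mean reference sits at the null's center, so it can flag one
        # or two spurious factors but never a rich structure
        rng = np.random.default_rng(1)
        for s in range(10):
            X = pd.DataFrame(rng.standard_normal((500, 11)))
            assert parallel_analysis(X, seed=s).suggested <= 3

    def test_three_factor_data_suggests_three(self):
        Ltrue = np.zeros((11, 3))
        Ltrue[:5, 0] = 0.78
        Ltrue[5:9, 1] = 0.72
        Ltrue[9:, 2] = 0.68
        scores, _ = make_factor_scores(800, Ltrue, seed=3)
        assert parallel_analysis(scores, seed=0).suggested == 3

    def test_loop_single_seed_equals_single_run(self):
        scores, _ = make_factor_scores(200, np.full((5, 1), 0.7), seed=4)
        single = parallel_analysis(scores, seed=17)
        tally = loop_parallel(scores, seeds=[17])
        assert tally["tally"] == {single.suggested: 1}

    def test_loop_concentrates_away_from_boundary(self):
        scores, _ = make_factor_scores(1000, np.full((8, 1), 0.8), seed=5)
        tally = loop_parallel(scores, seeds=range(10))
        assert tally["tally"] == {1: 10}

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            parallel_analysis(pd.DataFrame(np.ones((5, 3))), seed=0)


class TestFactorScores:
    def test_equal_loadings_proportional_to_row_means(self):
        scores, _ = make_factor_scores(400, np.full((6, 1), 0.7), seed=6)
        model = ExploratoryFactorAnalysis(1).fit(scores)
        fs = model.transform(scores)
        Z = (scores - scores.mean()) / scores.std(ddof=1)
        rowmeans = Z.mean(axis=1)
        r = np.corrcoef(fs["F1"], rowmeans)[0, 1]
        assert abs(r) > 0.999

    def test_recovery_of_true_factor(self):
        # loadings of .8 put the factor determinacy (the ceiling on the
        # score-truth correlation) near .92 for each factor
        Ltrue = np.zeros((11, 3))
        Ltrue[:4, 0] = 0.8
        Ltrue[4:8, 1] = 0.8
        Ltrue[8:, 2] = 0.8
        scores, f = make_factor_scores(1000, Ltrue, seed=7)
        model = ExploratoryFactorAnalysis(3).fit(scores)
        fs = model.transform(scores).to_numpy()
        # each true factor is recovered by some estimated score column
        cors = np.abs(np.corrcoef(fs.T, f.T)[:3, 3:])
        assert np.all(cors.max(axis=0) >= 0.9)

    def test_subject_permutation_permutes_scores(self):
        scores, _ = make_factor_scores(200, np.full((5, 1), 0.7), seed=8)
        model = ExploratoryFactorAnalysis(1).fit(scores)
        fs = model.transform(scores)
        perm = np.random.default_rng(0).permutation(200)
        fs_perm = model.transform(scores.iloc[perm])
        np.testing.assert_allclose(
            fs.iloc[perm].to_numpy(), fs_perm.to_numpy(), atol=1e-10
        )

    def test_transform_before_fit_errors(self):
        with pytest.raises(RuntimeError):
            ExploratoryFactorAnalysis(2).transform(pd.DataFrame(np.eye(3)))


class TestVarianceShares:
    def test_shares_sum_below_one_and_ordered(self):
        Ltrue = np.zeros((11, 3))
        Ltrue[:5, 0] = 0.8
        Ltrue[5:9, 1] = 0.7
        Ltrue[9:, 2] = 0.6
        scores, _ = make_factor_scores(2000, Ltrue, seed=9)
        model = ExploratoryFactorAnalysis(3).fit(scores)
        shares = model.variance_shares_
        assert shares.sum() <= 1.0
        assert np.all(np.diff(shares) <= 1e-9)

    def test_orthogonal_shares_equal_column_ss(self):
        lam0 = np.full(6, 0.75)
        R = np.outer(lam0, lam0) + np.diag(1 - lam0**2)
        lam, _ = extract_factors(R, 1)
        res = oblimin_rotate(lam)
        expected = np.sum(lam**2) / 6
        assert res.variance_shares[0] == pytest.approx(expected, abs=1e-6)
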