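"""Friedman / Nemenyi statistics and cross-validation orchestration."""

import numpy as np
import pytest
from scipy import stats

from osteoformer.config import Hyperparams, preset
from osteoformer.modelstats import (
    ScoreMatrix,
    compare_methods,
    friedman_test,
    kfold_indices,
    nemenyi_test,
    run_cross_validation,
)


def concordant(n_folds, k=5, seed=0):
    """Scores whose per-fold method ordering is identical in every fold."""
    rng = np.random.default_rng(seed)
    base = np.linspace(0.5, 0.9, k)
    scores = base + rng.uniform(0, 0.01, size=(n_folds, k))
    return ScoreMatrix(scores=scores, method_names=[f"m{i}" for i in range(k)],
                       fold_ids=[f"f{i}" for i in range(n_folds)])


class TestKFold:
    def test_singleton_folds(self):
        folds = kfold_indices(10, 10, seed=1)
        assert sorted(len(f) for f in folds) == [1] * 10
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))

    def test_balanced_sizes_23_by_10(self):
        folds = kfold_indices(23, 10, seed=2)
        assert sorted((len(f) for f in folds), reverse=True) == \
            [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_deterministic(self):
        a = kfold_indices(17, 4, seed=9)
        b = kfold_indices(17, 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_errors(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6)
        with pytest.raises(ValueError):
            kfold_indices(5, 1)


class TestFriedman:
    def test_concordant_10_folds_attains_maximum(self):
        res = friedman_test(concordant(10))
        assert res.statistic == pytest.approx(40.0, abs=1e-10)
        assert res.df == 4
        assert res.p_value < 0.001

    def test_concordant_2_folds(self):
        res = friedman_test(concordant(2))
        assert res.statistic == pytest.approx(8.0, abs=1e-10)
        assert res.df == 4

    def test_identical_columns_give_zero(self):
        scores = np.tile(np.random.default_rng(0).random((6, 1)), (1, 4))
        m = ScoreMatrix(scores=scores, method_names=list("abcd"),
                        fold_ids=[str(i) for i in range(6)])
        res = friedman_test(m)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_mean_ranks_sum_to_k_choose_identity(self):
        res = friedman_test(concordant(7, k=4))
        assert res.mean_ranks.sum() == pytest.approx(4 * 5 / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oracle_on_random_matrices(self, seed):
        scores = np.random.default_rng(seed).random((4, 3))
        m = ScoreMatrix(scores=scores, method_names=list("abc"),
                        fold_ids=[str(i) for i in range(4)])
        res = friedman_test(m)
        ref = stats.friedmanchisquare(*scores.T)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        m = concordant(6, seed=3)
        transformed = ScoreMatrix(scores=np.exp(5 * m.scores),
                                  method_names=m.method_names, fold_ids=m.fold_ids)
        assert friedman_test(m).statistic == pytest.approx(
            friedman_test(transformed).statistic, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ScoreMatrix(scores=np.array([[1.0, np.nan], [0.5, 0.2]]),
                        method_names=["a", "b"], fold_ids=["0", "1"])


class TestNemenyi:
    def test_concordant_pairwise_values(self):
        """Frozen p-values for rank differences 1..4 at k=5, N=10.

        Computed independently from the studentized-range tail:
        sf(diff / sqrt(k(k+1)/(12 N)), k, inf).
        """
        res = nemenyi_test(concordant(10))
        # columns are ordered worst..best; best method is index 4
        assert res.p_matrix[4, 3] == pytest.approx(0.6184, abs=2e-4)   # diff 1
        assert res.p_matrix[4, 2] == pytest.approx(0.0377, abs=2e-4)   # diff 2
        assert res.p_matrix[4, 1] == pytest.approx(2.142e-4, rel=1e-2)  # diff 3
        assert res.p_matrix[4, 0] == pytest.approx(1.538e-7, rel=1e-2)  # diff 4

    def test_symmetry_and_unit_diagonal(self):
        res = nemenyi_test(concordant(10))
        assert np.array_equal(res.p_matrix, res.p_matrix.T)
        np.testing.assert_allclose(np.diag(res.p_matrix), 1.0)
        assert ((res.p_matrix >= 0) & (res.p_matrix <= 1)).all()

    def test_monotone_in_rank_difference(self):
        res = nemenyi_test(concordant(10))
        ps = [res.p_matrix[4, j] for j in (3, 2, 1, 0)]  # diffs 1, 2, 3, 4
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_identical_columns_give_unit_pvalues(self):
        scores = np.tile(np.random.default_rng(1).random((5, 1)), (1, 3))
        m = ScoreMatrix(scores=scores, method_names=list("abc"),
                        fold_ids=[str(i) for i in range(5)])
        np.testing.assert_allclose(nemenyi_test(m).p_matrix, 1.0)


class TestCompare:
    def test_significant_includes_pairwise(self):
        out = compare_methods(concordant(10), alpha=0.05)
        assert out["p_value"] < 0.05 and "pairwise_p" in out
        assert len(out["pairwise_p"]) == 5 * 4 // 2

    def test_insignificant_skips_pairwise(self):
        scores = np.tile(np.random.default_rng(1).random((4, 1)), (1, 3))
        m = ScoreMatrix(scores=scores, method_names=list("abc"),
                        fold_ids=[str(i) for i in range(4)])
        out = compare_methods(m, alpha=0.05)
        assert "pairwise_p" not in out

    def test_csv_roundtrip(self, tmp_path):
        m = concordant(4)
        m.to_csv(tmp_path / "scores.csv")
        back = ScoreMatrix.from_csv(tmp_path / "scores.csv")
        np.testing.assert_allclose(back.scores, m.scores)
        assert back.method_names == m.method_names


class TestRunCrossValidation:
    def test_oracle_method_scores_one(self, phantoms32, quick_hp):
        def oracle(train_set, test_set, hp):
            from osteoformer.metrics import evaluate_set
            return evaluate_set([s.mask for s in test_set],
                                [s.mask for s in test_set]).mean_iou

        def constant(train_set, test_set, hp):
            return 0.25

        cfgs = [preset("tiny_baseline"), preset("tiny_baseline")]
        matrix = run_cross_validation(phantoms32, cfgs, K=3, train_settings=quick_hp,
                                      seed=0, method_names=["oracle", "const"],
                                      trainers=[oracle, constant])
        np.testing.assert_allclose(matrix.scores[:, 0], 1.0)
        np.testing.assert_allclose(matrix.scores[:, 1], 0.25)

    def test_real_training_shape_range_determinism(self, phantoms32):
        hp = Hyperparams(epochs=1, seed=5)
        cfgs = [preset("tiny_baseline"),
                preset("tiny_baseline", decoder_kind="fpn", decoder_attention=False)]
        kw = dict(K=2, train_settings=hp, seed=4, method_names=["a", "b"])
        m1 = run_cross_validation(phantoms32[:8], cfgs, **kw)
        assert m1.scores.shape == (2, 2)
        assert ((m1.scores >= 0) & (m1.scores <= 1)).all()
        m2 = run_cross_validation(phantoms32[:8], cfgs, **kw)
        np.testing.assert_array_equal(m1.scores, m2.scores)

    def test_failures_annotate_fold_and_method(self, phantoms32, quick_hp):
        def broken(train_set, test_set, hp):
            raise RuntimeError("boom")

        cfgs = [preset("tiny_baseline")]
        with pytest.raises(RuntimeError, match=r"fold 0, method 0"):
            run_cross_validation(phantoms32, cfgs, K=2, train_settings=quick_hp,
                                 seed=0, trainers=[broken])
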