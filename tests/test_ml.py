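import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from flimpheno.features import DECAY_FEATURES
from flimpheno.ml import (
    FEATURE_SETS,
    compare_feature_sets,
    embed_2d,
    group_ttests,
    make_folds,
    run_comparison_suite,
    train_rft_pairwise,
)
from flimpheno.synthetic import gaussian_feature_table as make_gaussian_table


class TestGroupTtests:
    def _table(self, a, b):
        return pd.DataFrame(
            {"group": ["a"] * len(a) + ["b"] * len(b), "x": np.concatenate([a, b])}
        )

    def test_identical_groups_null(self):
        x = np.random.default_rng(0).normal(size=30)
        res = group_ttests(self._table(x, x), "x")
        assert res.t_statistic.iloc[0] == 0.0
        assert res.p_value.iloc[0] == 1.0
        assert not res.significant.iloc[0]

    def test_huge_effect_detected(self):
        rng = np.random.default_rng(1)
        res = group_ttests(
            self._table(rng.normal(0, 1, 100), rng.normal(5, 1, 100)), "x"
        )
        assert res.p_value.iloc[0] < 1e-10
        assert res.significant.iloc[0]

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = group_ttests(
                self._table(rng.normal(size=25), rng.normal(size=25)), "x"
            )
            rejections += int(res.significant.iloc[0])
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_degenerate_group_named_in_error(self):
        table = self._table(np.zeros(5), np.random.default_rng(0).normal(size=5))
        with pytest.raises(ValueError, match="'a'"):
            group_ttests(table, "x")
        with pytest.raises(ValueError, match="'b'"):
            group_ttests(self._table(np.random.default_rng(0).normal(size=5), [1.0]), "x")

    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"group": np.repeat(["a", "b", "c"], 20), "x": rng.normal(size=60)}
        )
        assert len(group_ttests(table, "x")) == 3


class TestFolds:
    def test_partition_and_balance(self):
        table = make_gaussian_table(100, seed=0)
        y = (table.group == "case").to_numpy().astype(int)
        folds = make_folds(y, seed=1)
        assert set(folds) == {0, 1, 2, 3, 4}
        sizes = np.bincount(folds)
        assert sizes.sum() == len(y)
        assert np.all(np.abs(sizes - len(y) / 5) <= 1)

    def test_blocked_folds_keep_fields_together(self):
        y = np.tile([0, 1], 50)
        blocks = np.repeat(np.arange(20), 5)
        folds = make_folds(y, seed=0, blocks=blocks)
        for b in np.unique(blocks):
            assert len(set(folds[blocks == b])) == 1


class TestRandomForestPairwise:
    def test_chance_on_identical_distributions(self):
        table = make_gaussian_table(200, seed=4)
        report = train_rft_pairwise(table, "ctrl", "case", "combined12", seed=4,
                                    n_estimators=200)
        assert 0.40 <= report.mean_accuracy <= 0.60
        assert 0.40 <= report.mean_auc <= 0.60

    def test_separable_pair_near_perfect(self):
        table = make_gaussian_table(100, shift_features=("nadph_tau_m",), delta_sd=6.0,
                                    seed=5)
        report = train_rft_pairwise(table, "ctrl", "case", "combined12", seed=5,
                                    n_estimators=200)
        assert report.mean_accuracy >= 0.98
        assert report.mean_auc >= 0.99

    def test_signal_feature_ranks_first_in_gini(self):
        table = make_gaussian_table(150, shift_features=("fad_s",), delta_sd=3.0, seed=6)
        report = train_rft_pairwise(table, "ctrl", "case", "combined12", seed=6,
                                    n_estimators=200)
        assert max(report.importances, key=report.importances.get) == "fad_s"

    def test_small_class_rejected(self):
        table = make_gaussian_table(10, seed=7)
        with pytest.raises(ValueError, match="cells"):
            train_rft_pairwise(table, "ctrl", "case", "decay8", seed=7)

    def test_seeded_reproducibility(self):
        table = make_gaussian_table(60, shift_features=("nadph_g",), delta_sd=2.0, seed=8)
        a = train_rft_pairwise(table, "ctrl", "case", "decay8", seed=8, n_estimators=100)
        b = train_rft_pairwise(table, "ctrl", "case", "decay8", seed=8, n_estimators=100)
        assert a.to_dict() == b.to_dict()

    def test_permutation_chance_calibration(self):
        """Label-permuted features stay at chance across repeats."""
        rng = np.random.default_rng(9)
        table = make_gaussian_table(200, shift_features=DECAY_FEATURES, delta_sd=2.0,
                                    seed=9)
        accs = []
        for rep in range(5):
            permuted = table.copy()
            permuted["group"] = rng.permutation(permuted["group"].to_numpy())
            report = train_rft_pairwise(permuted, "ctrl", "case", "decay8",
                                        seed=rep, n_estimators=100)
            accs.append(report.mean_accuracy)
        assert 0.40 <= np.mean(accs) <= 0.60


class TestCompareFeatureSets:
    def test_self_comparison_null(self):
        table = make_gaussian_table(50, seed=10)
        rep = train_rft_pairwise(table, "ctrl", "case", "decay8", seed=10, n_estimators=50)
        res = compare_feature_sets(rep, rep, "accuracy")
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and not res.significant

    def test_fold_mismatch_rejected(self):
        table = make_gaussian_table(50, seed=11)
        a = train_rft_pairwise(table, "ctrl", "case", "decay8", seed=1, n_estimators=50)
        b = train_rft_pairwise(table, "ctrl", "case", "phasor4", seed=2, n_estimators=50)
        with pytest.raises(ValueError, match="fold"):
            compare_feature_sets(a, b, "accuracy")

    def test_planted_decay_signal_detected(self):
        """Signal in fit features only: decay8 beats phasor4 with matched folds."""
        table = make_gaussian_table(
            150, shift_features=("nadph_tau1", "nadph_tau2", "fad_tau1", "fad_tau2"),
            delta_sd=2.0, seed=12,
        )
        y = (table.group == "case").to_numpy().astype(int)
        folds = make_folds(y, seed=12)
        a = train_rft_pairwise(table, "ctrl", "case", "decay8", seed=12,
                               n_estimators=200, fold_assignment=folds)
        b = train_rft_pairwise(table, "ctrl", "case", "phasor4", seed=12,
                               n_estimators=200, fold_assignment=folds)
        res = compare_feature_sets(a, b, "accuracy")
        assert a.mean_accuracy > b.mean_accuracy
        assert res.p_value < 0.05 and res.significant


class TestComparisonSuite:
    def test_three_groups_nine_reports(self):
        table = pd.concat(
            [
                make_gaussian_table(40, seed=13, groups=("a", "b")),
                make_gaussian_table(40, seed=14, groups=("c", "d")).query("group == 'c'"),
            ],
            ignore_index=True,
        )
        suite = run_comparison_suite(table, seed=13, n_estimators=50)
        assert len(suite.reports) == 3
        assert sum(len(p) for p in suite.reports.values()) == 9
        assert len(suite.comparisons) == 3 * 6
        assert len(suite.summary_frame()) == 9

    def test_seeded_rerun_identical(self):
        table = make_gaussian_table(40, shift_features=("fad_g",), delta_sd=1.0, seed=15)
        a = run_comparison_suite(table, seed=15, n_estimators=50)
        b = run_comparison_suite(table, seed=15, n_estimators=50)
        assert a.to_dict() == b.to_dict()


class TestEmbedding:
    def test_separated_classes_and_determinism(self):
        table = make_gaussian_table(40, shift_features=tuple(DECAY_FEATURES),
                                    delta_sd=6.0, seed=16)
        coords_a = embed_2d(table, "combined12", seed=16)
        coords_b = embed_2d(table, "combined12", seed=16)
        assert np.allclose(coords_a[["umap1", "umap2"]], coords_b[["umap1", "umap2"]])
        score = silhouette_score(
            coords_a[["umap1", "umap2"]].to_numpy(), coords_a["group"].to_numpy()
        )
        assert score > 0.5

    def test_too_few_rows_rejected(self):
        table = make_gaussian_table(4, seed=17)
        with pytest.raises(ValueError, match="10"):
            embed_2d(table.head(8), "phasor4", seed=0)
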