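import math

import numpy as np
import pytest

from fmskit import (
    FmsConfig,
    MergeModel,
    delete_features,
    feature_importance,
    fisher_statistic,
    fit,
    fit_merging,
    merge_direction,
    merging_value,
    refit_combination_weights,
    select_degree_by_cv,
    select_degree_by_penalty,
    transform,
    SyntheticSpec,
    generate,
)
from fmskit.fms import CurvePoint, LearningCurve, combination_report
from fmskit.lda import pairwise_merge_stats
from fmskit.stats_core import pearson_correlation


def curve(entries):
    return LearningCurve([CurvePoint(*e) for e in entries])


class TestMergingValue:
    def test_direct_formula(self):
        assert merging_value(2.0, 8.0, 6.0, 0.5) == pytest.approx(0.75)

    def test_normalization_point(self):
        assert merging_value(2.0, 8.0, 4.0, -1.0) == pytest.approx(1.0)

    def test_uncorrelated_pair_scores_zero(self):
        assert merging_value(3.0, 5.0, 100.0, 0.0) == 0.0

    def test_signed_mode_keeps_sign(self):
        assert merging_value(2.0, 8.0, 4.0, -1.0, pearson_abs=False) == pytest.approx(-1.0)

    def test_zero_fisher_degenerate_ranks_low_but_finite(self):
        v = merging_value(0.0, 8.0, 5.0, 0.9)
        assert 0 < v < 1e-9

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            merging_value(1.0, 1.0, 1.0, 1.5)


class TestMergeOnce:
    def test_picks_exhaustive_argmax_pair(self):
        # duplicated informative pair + one noise column; the selected pair
        # must be the brute-force argmax of the merging value over all pairs
        rng = np.random.default_rng(2)
        labels = np.repeat(["A", "B"], 20)
        x = rng.normal(size=40) + 0.9 * (labels == "B")
        X = np.column_stack([x, x, rng.normal(size=40)])
        st = fit_merging(X, labels, 1, FmsConfig())

        fishers = [fisher_statistic(X[:, j], labels) for j in range(3)]
        best_pair, best_v = None, -np.inf
        for i in range(3):
            for j in range(i + 1, 3):
                _, _, f_new = merge_direction(X[:, i], X[:, j], labels)
                r = pearson_correlation(X[:, i], X[:, j])
                v = merging_value(fishers[i], fishers[j], f_new, r)
                if v > best_v:
                    best_pair, best_v = [i, j], v
        rec = st.merge_log[0]
        assert sorted(rec.left_members + rec.right_members) == best_pair
        assert rec.merging_value == pytest.approx(best_v, rel=1e-8)
        # with this seed the redundant duplicated pair is the winner
        assert best_pair == [0, 1]

    def test_weight_propagation_is_direction_times_parent_weights(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(["A", "B"], 20)
        x = rng.normal(size=40) + (labels == "B")
        X = np.column_stack([x, x + 0.05 * rng.normal(size=40), rng.normal(size=40)])
        st = fit_merging(X, labels, 1, FmsConfig())
        rec = st.merge_log[0]
        merged = next(c for c in st.combos if len(c.member_indices) == 2)
        expect = np.array([rec.a, rec.b])
        expect /= np.linalg.norm(expect)
        np.testing.assert_allclose(merged.weights, expect, atol=1e-12)

    def test_deterministic(self):
        table, _ = generate(SyntheticSpec(seed=5))
        a = fit_merging(table.values, table.labels, 10, FmsConfig())
        b = fit_merging(table.values, table.labels, 10, FmsConfig())
        for ra, rb in zip(a.merge_log, b.merge_log):
            assert ra.left_members == rb.left_members
            assert ra.right_members == rb.right_members
            assert ra.a == rb.a and ra.b == rb.b

    def test_redundant_pair_beats_independent_equally_informative(self):
        # merging-value bias toward correlated pairs, in the regime where all
        # candidates are comparably informative
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            labels = np.repeat(["A", "B"], 30)
            shared = rng.normal(size=60) + 0.8 * (labels == "B")
            indep = rng.normal(size=60) + 0.8 * (labels == "B")
            X = np.column_stack(
                [shared, shared + 0.1 * rng.normal(size=60), indep]
            )
            st = fit_merging(X, labels, 1, FmsConfig())
            rec = st.merge_log[0]
            wins += sorted(rec.left_members + rec.right_members) == [0, 1]
        assert wins >= 18


class TestFitMerging:
    def test_zero_merges_is_identity_model(self, two_class_table):
        table, _ = two_class_table
        st = fit_merging(table.values, table.labels, 0, FmsConfig())
        assert all(len(c.member_indices) == 1 for c in st.combos)
        assert all(c.weights.tolist() == [1.0] for c in st.combos)

    def test_full_merge_leaves_single_combination(self):
        table, _ = generate(
            SyntheticSpec(n_per_class=(15, 15), n_features=8, n_informative=4,
                          redundancy_groups=((2, 0.9),), sparsity=0.3, seed=1)
        )
        d = table.n_features
        st = fit_merging(table.values, table.labels, d - 1, FmsConfig())
        assert len(st.combos) == 1
        assert sorted(st.combos[0].member_indices) == sorted(range(d))
        assert len(st.merge_log) == d - 1

    def test_out_of_range_rejected(self, two_class_table):
        table, _ = two_class_table
        with pytest.raises(ValueError, match="out of range"):
            fit_merging(table.values, table.labels, table.n_features + 5, FmsConfig())


class TestRefit:
    def test_singleton_combination_untouched(self, two_class_table):
        table, _ = two_class_table
        st = fit_merging(table.values, table.labels, 0, FmsConfig())
        before = [c.weights.copy() for c in st.combos]
        refit_combination_weights(st)
        for w0, c in zip(before, st.combos):
            np.testing.assert_array_equal(w0, c.weights)

    def test_two_member_refit_equals_merge_direction(self):
        rng = np.random.default_rng(8)
        labels = np.repeat(["A", "B"], 25)
        x = rng.normal(size=50) + (labels == "B")
        X = np.column_stack([x, x + 0.2 * rng.normal(size=50), rng.normal(size=50)])
        st = fit_merging(X, labels, 1, FmsConfig())
        refit_combination_weights(st)
        combo = next(c for c in st.combos if len(c.member_indices) == 2)
        i, j = combo.member_indices
        a, b, f_new = merge_direction(X[:, i], X[:, j], labels)
        np.testing.assert_allclose(np.abs(combo.weights), np.abs([a, b]), atol=1e-9)
        assert combo.fisher == pytest.approx(f_new, rel=1e-9)

    def test_refit_never_lowers_fisher(self):
        for s in range(10):
            table, _ = generate(SyntheticSpec(seed=300 + s, n_per_class=(40, 40)))
            st = fit_merging(table.values, table.labels, 15, FmsConfig())
            before = {tuple(sorted(c.member_indices)): c.fisher for c in st.combos}
            refit_combination_weights(st)
            for c in st.combos:
                key = tuple(sorted(c.member_indices))
                assert c.fisher >= before[key] - 1e-9


class TestImportanceAndDeletion:
    def make_state(self):
        rng = np.random.default_rng(13)
        labels = np.repeat(["A", "B"], 25)
        x = rng.normal(size=50) + 1.2 * (labels == "B")
        X = np.column_stack(
            [x, x + 0.1 * rng.normal(size=50), rng.normal(size=50),
             rng.normal(size=50)]
        )
        return X, labels

    def test_score_is_weight_times_combination_fisher(self):
        X, labels = self.make_state()
        st = fit_merging(X, labels, 1, FmsConfig())
        scores = feature_importance(st)
        for c in st.combos:
            for f, w in zip(c.member_indices, c.weights):
                assert scores[f] == pytest.approx(abs(w) * c.fisher)

    def test_near_zero_weight_feature_deleted_first(self):
        rng = np.random.default_rng(14)
        labels = np.repeat(["A", "B"], 30)
        x = rng.normal(size=60) + 2 * (labels == "B")
        X = np.column_stack([x, x + 0.01 * rng.normal(size=60),
                             rng.normal(size=60)])
        st = fit_merging(X, labels, 2, FmsConfig())  # everything merged
        refit_combination_weights(st)
        order = st.importance_order(noisy=False)
        assert order[0] == 2  # the noise feature carries ~zero weight

    def test_zero_deletions_is_noop(self):
        X, labels = self.make_state()
        st = fit_merging(X, labels, 1, FmsConfig())
        before = [c.member_indices[:] for c in st.combos]
        delete_features(st, 0)
        assert [c.member_indices for c in st.combos] == before

    def test_singleton_deletion_reduces_dimension(self):
        X, labels = self.make_state()
        st = fit_merging(X, labels, 0, FmsConfig())  # all singletons
        dim_before = len(st.combos)
        delete_features(st, 1)
        assert len(st.combos) == dim_before - 1
        assert sum(len(c.member_indices) for c in st.combos) == dim_before - 1

    def test_deleting_from_multimember_combination_keeps_dimension(self):
        rng = np.random.default_rng(15)
        labels = np.repeat(["A", "B"], 30)
        x = rng.normal(size=60) + 1.5 * (labels == "B")
        X = np.column_stack(
            [x + 0.1 * rng.normal(size=60) for _ in range(3)]
        )
        st = fit_merging(X, labels, 2, FmsConfig())  # one 3-member combination
        assert len(st.combos) == 1
        delete_features(st, 1)
        assert len(st.combos) == 1  # dimension unchanged
        assert sum(len(c.member_indices) for c in st.combos) == 2  # one fewer feature

    def test_out_of_range_rejected(self):
        X, labels = self.make_state()
        st = fit_merging(X, labels, 0, FmsConfig())
        with pytest.raises(ValueError, match="out of range"):
            delete_features(st, 4)


class TestDegreeSelection:
    def test_cv_merge_tie_goes_to_largest_degree(self):
        c = curve([(0, 0.3, 10, 10), (1, 0.2, 9, 10), (2, 0.2, 8, 10), (3, 0.4, 7, 10)])
        assert select_degree_by_cv(c, "merge") == 2

    def test_cv_strictly_decreasing_takes_last(self):
        c = curve([(0, 0.3, 3, 3), (1, 0.2, 2, 3), (2, 0.1, 1, 3)])
        assert select_degree_by_cv(c, "merge") == 2

    def test_cv_single_entry(self):
        assert select_degree_by_cv(curve([(0, 0.5, 4, 4)]), "merge") == 0

    def test_cv_delete_tie_prefers_fewer_dimensions_then_features(self):
        c = curve([(0, 0.2, 5, 9), (1, 0.2, 5, 8), (2, 0.2, 4, 7), (3, 0.3, 3, 6)])
        assert select_degree_by_cv(c, "delete") == 2

    def test_penalty_hand_example(self):
        # two candidates (error, dim) = (0.10, 20) and (0.12, 5):
        # lam = 0.02/15, criteria tie at ~0.1267 -> lower dimension wins
        c = curve([(0, 0.10, 20, 20), (1, 0.12, 5, 20)])
        assert select_degree_by_penalty(c, N_original=4) == 1

    def test_penalty_equal_errors_prefer_lowest_dimension(self):
        c = curve([(0, 0.2, 12, 12), (1, 0.2, 8, 12), (2, 0.2, 5, 12)])
        assert select_degree_by_penalty(c, N_original=8) == 2

    def test_penalty_m_clamped_to_curve_length(self):
        c = curve([(0, 0.5, 3, 3), (1, 0.1, 2, 3)])
        # m = ceil(log2(1024)) = 10 >> 2 entries
        assert select_degree_by_penalty(c, N_original=1024) == 1


class TestFitAndTransform:
    def test_forced_identity_transform(self, two_class_table):
        table, _ = two_class_table
        cfg = FmsConfig(n_merges=0, n_deletions=0)
        model = fit(table, config=cfg)
        Z = model.transform(table.values)
        keep = [c.member_indices[0] for c in model.combinations]
        np.testing.assert_allclose(Z, table.values[:, keep], atol=1e-12)

    def test_training_columns_reproduced_exactly(self, two_class_table):
        table, _ = two_class_table
        cfg = FmsConfig(n_merges=5, n_deletions=2, classifier="knn")
        model = fit(table, config=cfg)
        Z1 = model.transform(table.values)
        Z2 = model.transform(table.values)
        np.testing.assert_array_equal(Z1, Z2)
        assert Z1.shape[1] == model.dimension

    def test_known_dot_product(self):
        model = MergeModel(
            combinations=[
                __import__("fmskit").fms.FeatureCombination([0, 1], np.array([0.6, 0.8]), 1.0)
            ],
            merge_log=[], deleted_features=[], n_merges_selected=1,
            n_deletions_selected=0, zero_variance_removed=[], n_features_in=2,
            noisy_branch=False,
        )
        out = transform(model, np.array([[1.0, 2.0]]))
        assert out[0, 0] == pytest.approx(2.2)

    def test_zero_row_maps_to_zero(self, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=4, n_deletions=0))
        Z = model.transform(np.zeros((1, table.n_features)))
        np.testing.assert_array_equal(Z, 0.0)

    def test_transform_linearity(self, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=6, n_deletions=1,
                                            classifier="knn"))
        rng = np.random.default_rng(0)
        X1 = rng.random((5, table.n_features))
        X2 = rng.random((5, table.n_features))
        lhs = model.transform(2.0 * X1 + 3.0 * X2)
        rhs = 2.0 * model.transform(X1) + 3.0 * model.transform(X2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_feature_count_mismatch_rejected(self, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=0, n_deletions=0))
        with pytest.raises(ValueError, match="expected"):
            model.transform(np.ones((2, table.n_features + 1)))

    def test_fit_deterministic_given_seed(self):
        table, _ = generate(SyntheticSpec(seed=21, n_per_class=(25, 25),
                                          n_features=24, n_informative=6,
                                          redundancy_groups=((3, 0.95),),
                                          sparsity=0.5))
        cfg = FmsConfig(classifier="knn", seed=3)
        m1 = fit(table, config=cfg)
        m2 = fit(table, config=cfg)
        assert m1.to_dict() == m2.to_dict()

    def test_noise_features_dominate_deletions(self):
        # dataset with informative block + many independent noise features
        hits, total = 0, 0
        for s in (0, 1):
            table, truth = generate(SyntheticSpec(seed=s))
            model = fit(table, config=FmsConfig(classifier="svm", seed=s))
            noise = set(truth.noise_indices)
            hits += sum(f in noise for f in model.deleted_features)
            total += len(model.deleted_features)
        assert total > 0
        assert hits / total >= 0.8

    def test_pure_signal_fixture_keeps_discriminative_coverage(self):
        # with no noise features, everything deleted is redundant-but-
        # informative (equal-error ties prefer fewer features), so the right
        # check is that what survives still spans the redundancy groups and
        # classifies well — not that deletion is rare
        table, truth = generate(
            SyntheticSpec(n_per_class=(40, 40), n_features=12, n_informative=12,
                          redundancy_groups=((4, 0.95),) * 3, sparsity=0.0,
                          effect_size=1.5, seed=9)
        )
        model = fit(table, config=FmsConfig(classifier="svm", seed=9))
        surviving = {f for c in model.combinations for f in c.member_indices}
        groups_covered = {truth.group_of_feature[f] for f in surviving}
        assert len(groups_covered) >= 2
        assert model.cv_error_selected <= 0.25


class TestModelInvariants:
    @pytest.mark.parametrize("n_merges,n_del", [(0, 0), (8, 3), (15, 6)])
    def test_disjointness_and_bookkeeping(self, n_merges, n_del):
        table, _ = generate(SyntheticSpec(seed=31))
        cfg = FmsConfig(n_merges=n_merges, n_deletions=n_del)
        model = fit(table, config=cfg)
        seen = set()
        for c in model.combinations:
            assert not (seen & set(c.member_indices))  # no overlap
            seen |= set(c.member_indices)
            assert np.linalg.norm(c.weights) == pytest.approx(1.0, abs=1e-9)
        d_after = table.n_features - len(model.zero_variance_removed)
        dropped = (d_after - n_merges) - model.dimension
        assert model.dimension + n_merges + dropped == d_after
        assert model.n_features_surviving == d_after - n_del

    def test_serialization_roundtrip(self, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=5, n_deletions=2))
        back = MergeModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(
            back.transform(table.values), model.transform(table.values)
        )
        assert back.to_dict() == model.to_dict()

    def test_save_load_file(self, tmp_path, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=3, n_deletions=1))
        path = tmp_path / "model.json"
        model.save(str(path))
        back = MergeModel.load(str(path))
        np.testing.assert_array_equal(
            back.transform(table.values), model.transform(table.values)
        )

    def test_combination_report_sorted_by_fisher(self, two_class_table):
        table, _ = two_class_table
        model = fit(table, config=FmsConfig(n_merges=5, n_deletions=0))
        rows = combination_report(model)
        fishers = [r["fisher"] for r in rows]
        assert fishers == sorted(fishers, reverse=True)
        assert all(r["combination"].startswith("FMS_comb_") for r in rows)
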