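"""Clustering, radar coordinates and Fisher/canonical discriminant analysis."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from qamskit.chemometrics import (
    FisherDiscriminantAnalysis,
    RescaledHierarchicalClustering,
    classify_fisher,
    cross_validate,
    cut_clusters,
    fit_discriminant,
    hierarchical_cluster,
    polygon_area,
    radar_coordinates,
)
from qamskit.fixtures import ELUTION_ORDER, fixture_fisher_model
from qamskit.types import ClassificationModel, ValidationError


def _brute_force_average_linkage(X):
    """Independent UPGMA oracle on squared Euclidean distances."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean(
                    [np.sum((X[i] - X[j]) ** 2) for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestHierarchicalClustering:
    def test_identical_samples_merge_at_zero(self):
        dendro = hierarchical_cluster(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dendro.merge_steps[0][2] == 0.0

    def test_toy_merge_order_matches_brute_force_oracle(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        dendro = hierarchical_cluster(X)
        oracle = _brute_force_average_linkage(X)
        # pairs {0,1} and {10,11} merge (heights 1) before the final join
        assert oracle[0][0] == [0, 1] and oracle[1][0] == [2, 3]
        assert [h for _, _, h in dendro.merge_steps] == pytest.approx(
            [h for _, h in oracle]
        )

    def test_rescaled_axis_tops_at_25(self, qams_matrix):
        dendro = hierarchical_cluster(qams_matrix)
        assert max(dendro.rescaled_heights) == pytest.approx(25.0)
        assert all(
            b >= a for a, b in zip(dendro.rescaled_heights, dendro.rescaled_heights[1:])
        )

    def test_cut_extremes(self, qams_matrix):
        dendro = hierarchical_cluster(qams_matrix)
        assert len(set(cut_clusters(dendro, 25.0).values())) == 1
        eps = min(h for h in dendro.rescaled_heights if h > 0) / 2
        assert len(set(cut_clusters(dendro, eps).values())) == 23
        with pytest.raises(ValidationError):
            cut_clusters(dendro, 0.0)

    def test_estimator_fit_predict_and_group_label_order(self):
        X = np.array([[0.0], [0.2], [10.0], [10.1]])
        est = RescaledHierarchicalClustering(cut_rescaled=9.0)
        labels = est.fit_predict(X)
        # labels follow first-appearance order
        assert list(labels) == ["G1", "G1", "G2", "G2"]

    def test_four_group_cut_on_study_panel(self, qams_matrix, group_labels):
        cut = RescaledHierarchicalClustering().fit(qams_matrix).cut(9.0)
        blocks = {}
        for s, g in cut.items():
            blocks.setdefault(g, set()).add(s)
        expected = {}
        for s, g in group_labels.items():
            expected.setdefault(g, set()).add(s)
        assert set(map(frozenset, blocks.values())) == set(map(frozenset, expected.values()))


class TestRadar:
    def test_regular_polygon_for_constant_vector(self):
        coords = radar_coordinates(np.array([[2.0, 2.0, 2.0, 2.0]]))
        verts = coords["0"]
        assert len(verts) == 5 and verts[0] == verts[-1]
        assert {r for _, r in verts} == {2.0}

    def test_per_compound_max_normalization_bounds(self, qams_matrix):
        coords = radar_coordinates(qams_matrix, normalization="per_compound_max")
        radii = np.array([[r for _, r in verts[:-1]] for verts in coords.values()])
        assert radii.min() >= 0.0 and radii.max() == pytest.approx(1.0)
        assert np.allclose(radii.max(axis=0), 1.0)

    def test_needs_three_variables(self):
        with pytest.raises(ValidationError):
            radar_coordinates(np.ones((2, 2)))

    def test_high_quality_group_has_larger_polygon(self, qams_matrix, group_labels):
        frame = qams_matrix.to_frame()
        means = {
            g: frame.loc[[s for s, gg in group_labels.items() if gg == g]].mean().to_numpy()
            for g in ("G1", "G4")
        }
        areas = {
            g: polygon_area(radar_coordinates(v[None, :])["0"]) for g, v in means.items()
        }
        assert areas["G1"] > areas["G4"]


class TestFisherDiscriminant:
    def test_separable_1d_groups_classify_perfectly(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        est = FisherDiscriminantAnalysis().fit(X, y)
        assert (est.predict(X) == y).all()
        assert est.variance_shares_pct_ == pytest.approx([100.0])

    def test_variance_shares_match_sklearn_eigen_solver(self, qams_matrix, group_labels):
        y = np.array([group_labels[s] for s in qams_matrix.sample_ids])
        est = FisherDiscriminantAnalysis().fit(qams_matrix.values, y)
        oracle = LinearDiscriminantAnalysis(solver="eigen").fit(qams_matrix.values, y)
        np.testing.assert_allclose(
            est.variance_shares_pct_ / 100.0,
            oracle.explained_variance_ratio_[: len(est.variance_shares_pct_)],
            atol=1e-6,
        )
        assert sum(est.variance_shares_pct_) == pytest.approx(100.0, abs=0.1)

    def test_number_of_canonical_functions(self, qams_matrix, group_labels):
        y = [group_labels[s] for s in qams_matrix.sample_ids]
        est = FisherDiscriminantAnalysis().fit(qams_matrix.values, y)
        assert len(est.eigenvalues_) == 3  # min(groups - 1, variables)

    def test_singular_covariance_triggers_ridge_warning(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [5.0, 10.0], [6.0, 12.0]])  # collinear
        y = ["a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="ridge"):
            FisherDiscriminantAnalysis().fit(X, y)
        with pytest.raises(np.linalg.LinAlgError):
            FisherDiscriminantAnalysis(ridge=0).fit(X, y)

    def test_groups_need_two_samples(self):
        with pytest.raises(ValidationError):
            FisherDiscriminantAnalysis().fit(np.eye(3), ["a", "a", "b"])

    def test_recovered_model_classifies_group_means(self):
        from qamskit.simulate import default_group_profiles, simulate_batches

        profiles = default_group_profiles(cv=0.05)
        _, truth, labels = simulate_batches(profiles, 6, seed=5)
        model = fit_discriminant(truth, labels)
        for prof in profiles:
            x = [prof.mean_vector[c] for c in truth.compound_ids]
            group, _ = classify_fisher(model, x)
            assert group == prof.label


class TestClassifyFisher:
    @pytest.mark.parametrize("sample,expected", [("S18", "G4"), ("S14", "G3")])
    def test_published_functions_on_panel_rows(self, qams_matrix, sample, expected):
        model = fixture_fisher_model()
        x = qams_matrix.reorder(ELUTION_ORDER).row(sample)
        group, scores = classify_fisher(model, x)
        assert group == expected
        assert len(scores) == 4

    def test_constant_dominance_and_tie_warning(self):
        model = ClassificationModel(
            group_labels=["a", "b"],
            fisher_coefficients=np.zeros((2, 2)),
            fisher_constants=np.array([0.0, 1.0]),
            variable_order=["x", "y"],
        )
        assert classify_fisher(model, [3.0, 4.0])[0] == "b"
        tied = ClassificationModel(
            group_labels=["a", "b"],
            fisher_coefficients=np.zeros((2, 2)),
            fisher_constants=np.zeros(2),
            variable_order=["x", "y"],
        )
        with pytest.warns(UserWarning, match="tie"):
            assert classify_fisher(tied, [1.0, 1.0])[0] == "a"

    def test_common_constant_shift_leaves_assignment_unchanged(self, qams_matrix):
        model = fixture_fisher_model()
        shifted = ClassificationModel(
            group_labels=model.group_labels,
            fisher_coefficients=model.fisher_coefficients,
            fisher_constants=model.fisher_constants + 123.45,
            variable_order=model.variable_order,
        )
        x = qams_matrix.reorder(ELUTION_ORDER).row("S6")
        assert classify_fisher(model, x)[0] == classify_fisher(shifted, x)[0]


class TestCrossValidation:
    def test_perfectly_separated_groups_are_fully_recovered(self):
        X = np.vstack([np.random.default_rng(0).normal(c, 0.01, (4, 2)) for c in (0, 10, 20)])
        y = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        conf, pct = cross_validate(X, y)
        assert pct == 100.0
        assert np.trace(conf.to_numpy()) == 12

    def test_confusion_row_sums_equal_group_sizes(self, qams_matrix, group_labels):
        conf, pct = cross_validate(qams_matrix, group_labels)
        assert conf.sum(axis=1).tolist() == [4, 9, 5, 5]
        assert pct == 100.0

    def test_small_group_folds_are_skipped_with_warning(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [5.2]])
        y = ["a", "a", "b", "b", "b"]
        with pytest.warns(UserWarning, match="skipped"):
            conf, _ = cross_validate(X, y)
        assert conf.to_numpy().sum() == 3  # only the b-folds are scored
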