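"""Nearest-centroid machinery: candidate filtering, t-ranking, centroid
fitting, prediction (against a brute-force oracle), CV training, and the
subtype classifier."""

import numpy as np
import pandas as pd
import pytest

from immunocentroid import (
    CandidateFilterParams,
    CentroidModel,
    ExpressionMatrix,
    NearestCentroidResponse,
    SubtypeCentroid,
    fit_centroids,
    gene_t_statistics,
    predict,
    select_candidates,
    train_response_classifier,
    train_subtype_classifier,
)
from immunocentroid.centroid import select_top_genes
from oracles import brute_force_nearest_centroid, pooled_t


def _norm(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, layer="log_normalized")


class TestSelectCandidates:
    def test_zero_percentiles_pass_all_genes(self, small_norm):
        got = select_candidates(small_norm, CandidateFilterParams(0.0, 0.0))
        assert got == small_norm.gene_ids

    def test_matches_double_threshold_scan(self):
        rng = np.random.default_rng(4)
        m = _norm(rng.normal(size=(10, 8)))
        params = CandidateFilterParams(0.25, 0.70)
        got = select_candidates(m, params)
        med = np.median(m.values, axis=1)
        var = np.var(m.values, axis=1, ddof=1)
        expected = [
            g for i, g in enumerate(m.gene_ids)
            if med[i] >= np.quantile(med, 0.25) and var[i] >= np.quantile(var, 0.70)
        ]
        assert got == expected

    def test_selected_fraction_under_independence(self):
        """With independent median and variance ranks the double filter
        keeps about (1-0.25)(1-0.70) = 22.5% of genes."""
        rng = np.random.default_rng(9)
        # heteroskedastic genes: variance rank independent of median rank
        base = rng.normal(0, 1, size=(4000, 1))
        scale = rng.lognormal(0, 0.5, size=(4000, 1))
        m = _norm(base + scale * rng.normal(size=(4000, 40)))
        frac = len(select_candidates(m)) / m.n_genes
        assert frac == pytest.approx(0.225, abs=0.03)

    def test_label_free(self, small_norm):
        # no labels argument exists; selection depends only on the matrix
        a = select_candidates(small_norm)
        b = select_candidates(small_norm)
        assert a == b

    def test_rejects_single_sample(self):
        m = _norm([[1.0], [2.0]])
        with pytest.raises(ValueError):
            select_candidates(m)


class TestGeneTStatistics:
    def test_identical_classes_give_zero(self):
        m = _norm([[1.0, 2.0, 1.0, 2.0]])
        t = gene_t_statistics(m, np.array([True, True, False, False]))
        assert t.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_arithmetic(self):
        """Class values {1,3} vs {-1,1}: t from a direct second evaluation."""
        m = _norm([[1.0, 3.0, -1.0, 1.0]])
        t = gene_t_statistics(m, np.array([True, True, False, False]))
        assert t.iloc[0] == pytest.approx(pooled_t([1, 3], [-1, 1]), abs=1e-12)

    def test_s0_offset_shrinks_t(self):
        m = _norm([[1.0, 3.0, -1.0, 1.0]])
        labels = np.array([True, True, False, False])
        t0 = gene_t_statistics(m, labels).iloc[0]
        t1 = gene_t_statistics(m, labels, s0=1.0).iloc[0]
        assert 0 < t1 < t0

    def test_permuted_labels_symmetric_about_zero(self, norm_cohort):
        norm, _, _ = norm_cohort
        rng = np.random.default_rng(0)
        means = []
        for _ in range(20):
            labels = np.zeros(norm.n_samples, dtype=bool)
            labels[rng.choice(norm.n_samples, 13, replace=False)] = True
            means.append(gene_t_statistics(norm, labels).mean())
        assert abs(np.mean(means)) < 0.1

    def test_small_class_rejected(self):
        m = _norm([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            gene_t_statistics(m, np.array([True, False, False]))


class TestSelectTopGenes:
    def test_balanced_takes_both_tails_with_deterministic_ties(self):
        t = pd.Series([3.0, 2.0, 2.0, -1.0, -5.0, 0.5],
                      index=["gB", "gC", "gA", "gD", "gE", "gF"])
        got = select_top_genes(t, 4)
        # up tail: gB (3.0) then tie 2.0 resolved lexicographically -> gA
        # down tail: gE (-5) then gD (-1)
        assert got == ["gB", "gA", "gE", "gD"]

    def test_unbalanced_takes_top_abs_t(self):
        t = pd.Series([3.0, -4.0, 1.0], index=["a", "b", "c"])
        assert select_top_genes(t, 2, balanced=False) == ["b", "a"]

    def test_odd_m_rejected_in_balanced_mode(self):
        t = pd.Series([1.0, -1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            select_top_genes(t, 3)


class TestFitCentroids:
    def test_one_sample_per_class_centroids_equal_samples(self):
        m = _norm([[1.0, 5.0], [2.0, 8.0]])
        model = fit_centroids(m, ["A", "B"], ["g0", "g1"])
        np.testing.assert_allclose(model.centroids, [[1, 2], [5, 8]])

    def test_centroids_equal_class_means(self):
        m = _norm([[1.0, 3.0, 10.0, 20.0], [0.0, 2.0, 5.0, 7.0]])
        model = fit_centroids(m, ["A", "A", "B", "B"], ["g0", "g1"])
        np.testing.assert_allclose(model.centroids, [[2, 1], [15, 6]])
        # pooled within-class SD by hand: g0 ss = 2+50, g1 ss = 2+2; df = 2
        np.testing.assert_allclose(model.pooled_sd, [np.sqrt(26), np.sqrt(2)])

    def test_class_swap_swaps_centroid_rows(self):
        m = _norm([[1.0, 3.0, 10.0, 20.0]])
        a = fit_centroids(m, ["A", "A", "B", "B"], ["g0"], class_labels=["A", "B"])
        b = fit_centroids(m, ["A", "A", "B", "B"], ["g0"], class_labels=["B", "A"])
        np.testing.assert_allclose(a.centroids, b.centroids[::-1])

    def test_empty_class_rejected(self):
        m = _norm([[1.0, 2.0]])
        with pytest.raises(ValueError):
            fit_centroids(m, ["A", "A"], ["g0"], class_labels=["A", "B"])

    def test_zero_variance_genes_get_positive_s0(self):
        m = _norm([[1.0, 1.0, 5.0, 5.0], [0.0, 2.0, 4.0, 6.0]])
        model = fit_centroids(m, ["A", "A", "B", "B"], ["g0", "g1"])
        assert model.pooled_sd[0] == 0.0
        assert model.s0 > 0  # fallback keeps distances finite
        pred = predict(model, m)
        assert np.isfinite(pred.filter(like="distance").to_numpy()).all()


class TestPredict:
    def test_sample_at_centroid_predicted_with_zero_distance(self):
        m = _norm([[1.0, 5.0, 1.0], [2.0, 8.0, 2.0]])
        model = fit_centroids(
            m.subset_samples(["s0", "s1"]), ["A", "B"], ["g0", "g1"]
        )
        pred = predict(model, m.subset_samples(["s2"]))
        assert pred["predicted_class"].iloc[0] == "A"
        assert pred["distance_A"].iloc[0] == pytest.approx(0.0)

    def test_equidistant_sample_goes_to_first_class(self):
        model = CentroidModel(
            selected_genes=["g0"], class_labels=["B", "A"],
            centroids=np.array([[1.0], [3.0]]), pooled_sd=np.array([1.0]),
        )
        m = _norm([[2.0]], genes=["g0"], samples=["s0"])
        assert predict(model, m)["predicted_class"].iloc[0] == "B"

    @pytest.mark.parametrize("distance_kind", ["standardized", "euclidean"])
    def test_matches_brute_force_oracle(self, distance_kind):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(2, 4))
            g = int(rng.integers(1, 6))
            centroids = rng.normal(size=(k, g))
            sd = rng.uniform(0.2, 2.0, size=g)
            model = CentroidModel(
                selected_genes=[f"g{i}" for i in range(g)],
                class_labels=[f"C{j}" for j in range(k)],
                centroids=centroids, pooled_sd=sd, s0=0.1,
                distance_kind=distance_kind,
            )
            x = rng.normal(size=g)
            m = _norm(x[:, None], genes=model.selected_genes, samples=["s"])
            pred = predict(model, m)
            scale = sd + 0.1 if distance_kind == "standardized" else np.ones(g)
            label, dists = brute_force_nearest_centroid(
                x, centroids, scale, model.class_labels
            )
            assert pred["predicted_class"].iloc[0] == label
            got = [pred[f"distance_C{j}"].iloc[0] for j in range(k)]
            np.testing.assert_allclose(got, dists, rtol=1e-9)

    def test_missing_genes_rejected_with_list(self):
        model = CentroidModel(
            selected_genes=["g0", "missing"], class_labels=["A", "B"],
            centroids=np.zeros((2, 2)), pooled_sd=np.ones(2),
        )
        m = _norm([[0.0]], genes=["g0"], samples=["s0"])
        with pytest.raises(KeyError, match="missing"):
            predict(model, m)

    def test_json_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(3)
        m = _norm(rng.normal(size=(6, 10)))
        labels = ["A"] * 5 + ["B"] * 5
        model = fit_centroids(m, labels, m.gene_ids)
        model.cv_trace = [(4, 0.8), (6, 0.9)]
        model.to_json(tmp_path / "model.json")
        back = CentroidModel.from_json(tmp_path / "model.json")
        pd.testing.assert_frame_equal(predict(model, m), predict(back, m))
        assert back.cv_trace == model.cv_trace


class TestTrainResponseClassifier:
    def test_separated_cohort_perfect_cv_and_gene_recovery(self, recovery_cohort):
        from immunocentroid import filter_min_expression, normalize

        counts, clinical, truth = recovery_cohort
        filtered, _ = filter_min_expression(counts)
        norm = normalize(filtered)
        model = train_response_classifier(
            norm, clinical.responder_labels(), gene_grid=[40]
        )
        cv = dict(model.cv_trace)
        assert cv[40] >= 0.9
        planted = set(truth.program_genes["response_up"]) | set(
            truth.program_genes["response_down"]
        )
        recovered = len(planted & set(model.selected_genes)) / len(planted)
        assert recovered >= 0.8

    def test_singleton_grid_equals_direct_fit(self, norm_cohort):
        norm, clinical, _ = norm_cohort
        labels = clinical.responder_labels()
        model = train_response_classifier(norm, labels, gene_grid=[20])
        assert model.chosen_n_genes == 20
        # grid machinery is transparent: final selection equals direct
        # selection at m=20 from full-data t statistics
        candidates = select_candidates(norm)
        t = gene_t_statistics(norm.subset_genes(candidates), labels)
        assert model.selected_genes == select_top_genes(t, 20)
        direct = fit_centroids(
            norm, np.where(labels == "CR/PR", "CR/PR", "SD/PD"),
            model.selected_genes, class_labels=["CR/PR", "SD/PD"],
        )
        np.testing.assert_allclose(model.centroids, direct.centroids)

    def test_cv_trace_covers_grid_and_stays_in_unit_interval(self, norm_cohort):
        norm, clinical, _ = norm_cohort
        grid = [4, 8, 12]
        model = train_response_classifier(
            norm, clinical.responder_labels(), gene_grid=grid
        )
        assert [m for m, _ in model.cv_trace] == grid
        assert all(0.0 <= a <= 1.0 for _, a in model.cv_trace)

    def test_fold_selection_uses_training_data_only(self, norm_cohort):
        """Perturbing one training label changes the fold's gene ranking:
        selection is recomputed inside folds, not inherited globally."""
        norm, clinical, _ = norm_cohort
        labels = (clinical.responder_labels() == "CR/PR").reindex(
            norm.sample_ids
        ).to_numpy()
        sub = norm.subset_samples(norm.sample_ids[:20])
        t_a = gene_t_statistics(sub, labels[:20])
        flipped = labels[:20].copy()
        flipped[0] = ~flipped[0]
        t_b = gene_t_statistics(sub, flipped)
        assert select_top_genes(t_a, 10) != select_top_genes(t_b, 10)

    def test_oversized_grid_truncated_with_warning(self, norm_cohort):
        norm, clinical, _ = norm_cohort
        small = norm.subset_genes(norm.gene_ids[:40])
        with pytest.warns(UserWarning, match="truncated"):
            model = train_response_classifier(
                small, clinical.responder_labels(),
                params=CandidateFilterParams(0.0, 0.0),
                gene_grid=[4, 500],
            )
        assert model.chosen_n_genes == 4

    def test_empty_grid_rejected(self, norm_cohort):
        norm, clinical, _ = norm_cohort
        with pytest.raises(ValueError):
            train_response_classifier(norm, clinical.responder_labels(), gene_grid=[])

    def test_tiny_class_rejected(self):
        m = _norm(np.random.default_rng(0).normal(size=(20, 6)))
        labels = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError, match="at least 3"):
            train_response_classifier(m, labels)

    def test_fast_cv_path_equals_naive_refit(self, norm_cohort):
        """The prefix-sum LOOCV shortcut reproduces the per-(fold, m)
        naive refit exactly (an s0 of 1e-12 forces the naive path without
        changing any distance materially)."""
        from immunocentroid.centroid import _loocv_accuracy

        norm, clinical, _ = norm_cohort
        labels = (clinical.responder_labels() == "CR/PR").reindex(
            norm.sample_ids
        ).to_numpy()
        cands = select_candidates(norm)[:60]
        t_full = gene_t_statistics(norm.subset_genes(cands), labels)
        grid = [4, 10, 20]
        args = (norm, labels, ["CR/PR", "SD/PD"], cands, grid,
                "standardized")
        fast = _loocv_accuracy(*args, 0.0, True, True, t_full)
        naive = _loocv_accuracy(*args, 1e-12, True, True, t_full)
        assert fast == naive

    def test_model_results_facade(self, norm_cohort):
        norm, clinical, _ = norm_cohort
        res = NearestCentroidResponse.from_clinical(
            norm, clinical, gene_grid=[10, 20]
        ).fit()
        assert res.model.chosen_n_genes in (10, 20)
        assert set(res.cv_trace["n_genes"]) == {10, 20}
        text = res.summary()
        assert "Nearest-centroid classifier" in text
        assert "LOOCV" in text
        preds = res.predict(norm)
        assert set(preds["predicted_class"]) <= {"CR/PR", "SD/PD"}


def _subtype_cohort(seed=0, n=120, sep=3.0):
    """Two-subtype toy data with strong separation on a 34-gene panel."""
    rng = np.random.default_rng(seed)
    genes = [f"sg{i}" for i in range(34)] + [f"bg{i}" for i in range(66)]
    labels = np.array(["ccA"] * (n // 2) + ["ccB"] * (n - n // 2))
    values = rng.normal(size=(100, n))
    values[:34, labels == "ccB"] += sep * rng.choice([-1, 1], size=(34, 1))
    m = ExpressionMatrix(genes, [f"s{i}" for i in range(n)], values,
                         layer="log_normalized")
    return m, pd.Series(labels, index=m.sample_ids), genes[:34]


class TestTrainSubtypeClassifier:
    def test_deterministic_given_seed(self):
        m, labels, panel = _subtype_cohort()
        m1, a1 = train_subtype_classifier(m, labels, panel, seed=5)
        m2, a2 = train_subtype_classifier(m, labels, panel, seed=5)
        assert a1 == a2
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_separated_subtypes_high_accuracy(self):
        m, labels, panel = _subtype_cohort(seed=1)
        model, accuracy = train_subtype_classifier(m, labels, panel, seed=0)
        assert accuracy >= 0.95
        assert model.selected_genes == panel
        assert model.center_offsets is not None

    def test_missing_panel_gene_rejected_by_name(self):
        m, labels, panel = _subtype_cohort()
        with pytest.raises(KeyError, match="absent_gene"):
            train_subtype_classifier(m, labels, panel + ["absent_gene"], seed=0)

    def test_facade_summary_reports_test_accuracy(self):
        m, labels, panel = _subtype_cohort(seed=2)
        res = SubtypeCentroid(m, labels, panel).fit(seed=3)
        assert "test accuracy" in res.summary()
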