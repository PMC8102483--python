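import numpy as np
import pandas as pd
import pytest

from scskin.classifier import (IdentityScores, TrainConfig, build_panel,
                               cross_validate, radar_coordinates,
                               randomized_control, score, train)
from scskin.simulate import rename_species

from conftest import make_cm


def tiny_markers(rows):
    df = pd.DataFrame(rows, columns=["gene", "cluster", "enrichment_score",
                                     "log2_fold_change", "fpr"])
    df["is_significant"] = df["fpr"] < 0.1
    return df


class TestBuildPanel:
    def test_cluster_with_few_markers_contributes_all(self):
        mk = tiny_markers([(f"g{i}", "A", 5.0, 2.0, 0.01) for i in range(5)])
        panel = build_panel(mk, k_per_cluster=30)
        assert sorted(panel.genes) == [f"g{i}" for i in range(5)]

    def test_shared_top_gene_appears_once(self):
        mk = tiny_markers([("gX", "A", 5.0, 3.0, 0.01),
                           ("gX", "B", 4.0, 2.5, 0.01),
                           ("gY", "B", 3.0, 2.0, 0.01)])
        panel = build_panel(mk, k_per_cluster=30)
        assert panel.genes.count("gX") == 1
        assert panel.source["A"] == ["gX"]
        assert "gX" not in panel.source["B"]

    def test_insignificant_cluster_contributes_none(self):
        mk = tiny_markers([("gX", "A", 5.0, 3.0, 0.01),
                           ("gY", "B", 1.0, 0.1, 0.8)])
        with pytest.warns(UserWarning, match="no significant markers"):
            panel = build_panel(mk, k_per_cluster=30)
        assert panel.source["B"] == []

    def test_panel_contains_planted_markers(self, atlas, marker_table):
        _, _, truth = atlas
        m = len(truth.planted_markers["type0"])
        panel = build_panel(marker_table, k_per_cluster=m)
        planted = {g for gl in truth.planted_markers.values() for g in gl}
        assert len(planted & set(panel.genes)) / len(planted) >= 0.9


class TestTrainAndScore:
    def test_training_accuracy_on_separated_types(self, atlas, trained):
        cm, _, truth = atlas
        _, model = trained
        sc = score(model, cm)
        acc = (sc.assigned_label.to_numpy()
               == truth.true_type.astype(object)).mean()
        assert acc > 0.95

    def test_same_seed_identical_scores(self, atlas, trained):
        cm, _, truth = atlas
        panel, model = trained
        model2 = train(cm, truth.true_type, panel, TrainConfig(seed=1))
        p1 = score(model, cm).probabilities.to_numpy()
        p2 = score(model2, cm).probabilities.to_numpy()
        np.testing.assert_array_equal(p1, p2)

    def test_rows_sum_to_one(self, atlas, trained):
        cm, _, _ = atlas
        _, model = trained
        p = score(model, cm).probabilities.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all() and (p <= 1).all()

    def test_all_zero_cell_near_uniform(self, atlas, trained):
        cm, _, _ = atlas
        _, model = trained
        zero = make_cm(np.zeros((cm.n_genes, 1), dtype=int),
                       genes=list(cm.gene_ids), barcodes=["z"])
        p = score(model, zero).probabilities.to_numpy().ravel()
        assert p.max() <= 2 / len(model.class_labels)

    def test_renamed_species_scores_identical(self, atlas, trained):
        cm, _, _ = atlas
        _, model = trained
        p1 = score(model, cm).probabilities.to_numpy()
        p2 = score(model, rename_species(cm)).probabilities.to_numpy()
        np.testing.assert_array_equal(p1, p2)

    def test_undersized_class_is_error(self, atlas, trained):
        cm, _, truth = atlas
        panel, _ = trained
        labels = truth.true_type.copy().astype(object)
        labels[:4] = "rare"
        labels[4:] = "common"
        with pytest.raises(ValueError, match="rare"):
            train(cm.subset_cells(np.arange(len(labels))), labels, panel)

    def test_insufficient_gene_overlap_is_error(self, atlas, trained):
        cm, _, _ = atlas
        _, model = trained
        n_keep = len(model.panel.genes) // 3  # 67% of panel missing
        query = cm.subset_genes(model.panel.genes[:n_keep])
        with pytest.raises(ValueError, match="overlap"):
            score(model, query)


class TestCrossValidate:
    def test_accuracy_at_least_80pct_on_synthetic_atlas(self, atlas, trained):
        cm, _, truth = atlas
        panel, _ = trained
        cv = cross_validate(cm, truth.true_type, panel, folds=5,
                            cfg=TrainConfig(seed=1))
        assert cv["overall_accuracy"] >= 0.80
        assert set(cv["per_class_recall"]) == set(np.unique(truth.true_type))

    def test_shuffled_labels_give_chance_accuracy(self, atlas, trained):
        cm, _, truth = atlas
        panel, _ = trained
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(truth.true_type)
        cv = cross_validate(cm, shuffled, panel, folds=3, cfg=TrainConfig(seed=1))
        k = len(np.unique(truth.true_type))
        assert cv["overall_accuracy"] < 1 / k + 0.1

    def test_two_and_five_folds_both_pass(self, atlas, trained):
        cm, _, truth = atlas
        panel, _ = trained
        cv2 = cross_validate(cm, truth.true_type, panel, folds=2,
                             cfg=TrainConfig(seed=1))
        assert cv2["overall_accuracy"] >= 0.8


class TestRandomizedControl:
    def test_fraction_near_zero_at_half_threshold(self, atlas, trained):
        cm, _, truth = atlas
        _, model = trained
        frac = randomized_control(cm, truth.true_type, model,
                                  assign_threshold=0.5, seed=1)
        assert frac <= 0.01

    def test_unrandomized_input_matches_resubstitution(self, atlas, trained):
        cm, _, truth = atlas
        _, model = trained
        sc = score(model, cm)
        resub_conf = ((sc.assigned_prob.to_numpy() >= 0.5)
                      & (sc.assigned_label.to_numpy()
                         == truth.true_type.astype(object))).mean()
        assert resub_conf > 0.9  # informative model is confident on real data

    def test_threshold_bounds_enforced(self, atlas, trained):
        cm, _, truth = atlas
        _, model = trained
        with pytest.raises(ValueError):
            randomized_control(cm, truth.true_type, model, assign_threshold=0.05)

    def test_fraction_decreases_as_threshold_rises(self, atlas, trained):
        cm, _, truth = atlas
        _, model = trained
        lo = randomized_control(cm, truth.true_type, model, 0.2, seed=2)
        hi = randomized_control(cm, truth.true_type, model, 0.9, seed=2)
        assert hi <= lo


class TestRadarCoordinates:
    def scores_from(self, p, classes):
        return IdentityScores(pd.DataFrame(
            p, index=[f"c{i}" for i in range(len(p))], columns=classes))

    def test_one_hot_lands_on_anchor(self):
        sc = self.scores_from([[1.0, 0.0, 0.0, 0.0]], list("ABCD"))
        xy = radar_coordinates(sc, list("ABCD")).iloc[0]
        np.testing.assert_allclose([xy.x, xy.y], [1.0, 0.0], atol=1e-12)

    def test_uniform_score_at_origin(self):
        sc = self.scores_from([[0.25] * 4], list("ABCD"))
        xy = radar_coordinates(sc, list("ABCD")).iloc[0]
        np.testing.assert_allclose([xy.x, xy.y], [0.0, 0.0], atol=1e-12)

    def test_half_half_adjacent_is_midpoint(self):
        sc = self.scores_from([[0.5, 0.5, 0.0, 0.0]], list("ABCD"))
        xy = radar_coordinates(sc, list("ABCD")).iloc[0]
        np.testing.assert_allclose([xy.x, xy.y], [0.5, 0.5], atol=1e-12)

    def test_class_order_must_be_permutation(self):
        sc = self.scores_from([[0.5, 0.5]], list("AB"))
        with pytest.raises(ValueError):
            radar_coordinates(sc, ["A", "C"])


class TestAgainstReferenceClassifier:
    def test_matches_sklearn_mlp_on_same_features(self, atlas, trained):
        """Independent route: sklearn's MLP on identical panel features
        reaches the same accuracy regime as the in-package network."""
        from sklearn.metrics import accuracy_score
        from sklearn.model_selection import train_test_split
        from sklearn.neural_network import MLPClassifier
        from scskin.classifier import _panel_features

        cm, _, truth = atlas
        panel, model = trained
        x, _ = _panel_features(cm, panel)
        xtr, xte, ytr, yte, _, ite = train_test_split(
            x, truth.true_type, np.arange(cm.n_cells),
            test_size=0.3, stratify=truth.true_type, random_state=0)
        ref = MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                            random_state=0).fit(xtr, ytr)
        ref_acc = accuracy_score(yte, ref.predict(xte))
        ours = score(model, cm.subset_cells(ite)).assigned_label.to_numpy()
        our_acc = (ours == np.asarray(yte, dtype=object)).mean()
        assert ref_acc >= 0.9 and our_acc >= 0.9
        assert abs(ref_acc - our_acc) <= 0.05


class TestEffectSizeMonotonicity:
    def test_cv_accuracy_non_decreasing_in_marker_effect(self):
        from scskin.markers import enrichment_scores, marker_fpr
        from scskin.simulate import SimConfig, simulate_atlas
        accs = []
        for lfc in (0.5, 1.5, 3.0):
            cfg = SimConfig(n_types=4, genes=800, marker_genes_per_type=20,
                            de_genes_per_type=5, marker_log2fc=lfc,
                            cells_per_type_per_donor={"control": 13, "disease": 13},
                            seed=21)
            cm, _, truth = simulate_atlas(cfg)
            mk = marker_fpr(cm, truth.true_type, n_perm=100, seed=1)
            panel = build_panel(mk, 20)
            cv = cross_validate(cm, truth.true_type, panel, folds=3,
                                cfg=TrainConfig(seed=1, epochs=60))
            accs.append(cv["overall_accuracy"])
        assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
        assert accs[2] >= 0.9
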