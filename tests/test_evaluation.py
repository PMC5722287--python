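import numpy as np
import pytest

import entrofuse as ef
from entrofuse.evaluation import CVSpec, ClassifierSpec, cv_accuracy
from entrofuse.features import FeatureMatrix, NormalizationSpec
from entrofuse.preprocessing import EpochSet
from oracle_utils import roc_auc_rank_stat, roc_auc_threshold_enum


def gaussian_clouds(n_per_class, n_features=4, sep=6.0, seed=0, subjects=("s1",)):
    """Two well-separated Gaussian clouds labeled normal/fatigue."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features)) + sep
    values = np.vstack([a, b])
    labels = np.array(["normal"] * n_per_class + ["fatigue"] * n_per_class)
    sids = np.resize(np.asarray(subjects), 2 * n_per_class)
    index = [(f"c{i}", "SE") for i in range(n_features)]
    return FeatureMatrix(values, index, labels, sids)


class TestConfusionMetrics:
    def test_all_correct(self):
        y = np.array(["fatigue", "normal", "fatigue"])
        assert ef.confusion_metrics(y, y) == (100.0, 100.0, 100.0)

    def test_hand_computed_example(self):
        actual = ["fatigue"] * 4 + ["normal"] * 4
        pred = ["fatigue"] * 3 + ["normal"] + ["fatigue"] * 2 + ["normal"] * 2
        acc, sn, sp = ef.confusion_metrics(pred, actual)
        assert (acc, sn, sp) == (62.5, 75.0, 50.0)

    def test_all_positive_predictions(self):
        actual = ["fatigue", "normal", "fatigue", "normal"]
        pred = ["fatigue"] * 4
        acc, sn, sp = ef.confusion_metrics(pred, actual)
        assert sn == 100.0 and sp == 0.0

    def test_flipping_positive_label_swaps_sn_sp(self, rng):
        actual = rng.choice(["normal", "fatigue"], 50)
        pred = rng.choice(["normal", "fatigue"], 50)
        _, sn1, sp1 = ef.confusion_metrics(pred, actual, positive="fatigue")
        _, sn2, sp2 = ef.confusion_metrics(pred, actual, positive="normal")
        assert sn1 == sp2 and sp1 == sn2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ef.confusion_metrics([], [])


class TestRocPrCurves:
    def test_perfect_separation_gives_auc_one(self):
        out = ef.roc_pr_curves([0.9, 0.8, 0.1, 0.2], ["fatigue", "fatigue", "normal", "normal"])
        assert out["roc"]["auc"] == pytest.approx(1.0)

    def test_matches_threshold_enumeration_oracle(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        labels = ["fatigue", "normal", "fatigue", "normal"]
        out = ef.roc_pr_curves(scores, labels)
        assert out["roc"]["auc"] == pytest.approx(
            roc_auc_threshold_enum(scores, labels, "fatigue"), abs=1e-12
        )

    def test_matches_rank_statistic_on_random_scores(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            labels = np.where(rng.random(n) < 0.5, "fatigue", "normal")
            if len(set(labels)) < 2:
                continue
            auc = ef.roc_pr_curves(scores, labels)["roc"]["auc"]
            assert auc == pytest.approx(roc_auc_rank_stat(scores, labels, "fatigue"), abs=1e-10)

    def test_null_scores_give_chance_auc(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scores = rng.standard_normal(500)
            labels = np.where(rng.random(500) < 0.5, "fatigue", "normal")
            aucs.append(ef.roc_pr_curves(scores, labels)["roc"]["auc"])
        assert 0.45 < np.mean(aucs) < 0.55

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ef.roc_pr_curves([0.1, 0.2], ["fatigue", "fatigue"])


class TestSplitTrainTest:
    def test_equal_stratified_split(self):
        fm = gaussian_clouds(100)
        train, test = ef.split_train_test(fm, CVSpec(scheme="holdout", seed=1))
        assert train.n_epochs == test.n_epochs == 100
        for part in (train, test):
            _, counts = np.unique(part.labels, return_counts=True)
            assert list(counts) == [50, 50]

    def test_reproducible_and_seed_sensitive(self):
        fm = gaussian_clouds(50)
        a1, _ = ef.split_train_test(fm, CVSpec(scheme="holdout", seed=5))
        a2, _ = ef.split_train_test(fm, CVSpec(scheme="holdout", seed=5))
        b1, _ = ef.split_train_test(fm, CVSpec(scheme="holdout", seed=6))
        assert np.array_equal(a1.values, a2.values)
        assert not np.array_equal(a1.values, b1.values)

    def test_missing_class_raises(self):
        fm = gaussian_clouds(10)
        single = fm.select_rows(fm.labels == "normal")
        with pytest.raises(ValueError):
            ef.split_train_test(single)


class TestLooCrossValidate:
    def test_separable_clouds_reach_full_accuracy(self):
        fm = gaussian_clouds(20)
        rep = ef.loo_cross_validate(fm, ClassifierSpec(kind="nearest_neighbor"))
        assert rep.acc == 100.0
        assert rep.tp + rep.tn + rep.fp + rep.fn == fm.n_epochs

    def test_one_heldout_prediction_per_unit(self):
        fm = gaussian_clouds(15)
        rep = ef.loo_cross_validate(fm, ClassifierSpec(kind="nearest_neighbor"))
        assert rep.provenance["n_units"] == fm.n_epochs

    def test_label_independent_features_score_near_chance(self):
        """iid random labels: majority-vote collapse lands near 50%."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.standard_normal((200, 6))
            labels = np.where(rng.random(200) < 0.5, "fatigue", "normal")
            fm = FeatureMatrix(values, [(f"c{i}", "SE") for i in range(6)],
                               labels, np.repeat("s1", 200))
            rep = ef.loo_cross_validate(fm, ClassifierSpec(kind="rbf_svm"))
            accs.append(rep.acc)
        assert 40.0 < np.mean(accs) < 60.0

    def test_subject_unit_holds_out_whole_subjects(self):
        fm = gaussian_clouds(10, subjects=("s1", "s2", "s1", "s2"))
        rep = ef.loo_cross_validate(
            fm, ClassifierSpec(kind="nearest_neighbor"), unit="subject"
        )
        assert rep.provenance["n_units"] == fm.n_epochs
        assert rep.acc == 100.0

    def test_determinism_of_report(self):
        fm = gaussian_clouds(15, sep=1.0)
        kw = dict(normalization=NormalizationSpec())
        r1 = ef.loo_cross_validate(fm, ClassifierSpec(kind="rbf_svm"), **kw)
        r2 = ef.loo_cross_validate(fm, ClassifierSpec(kind="rbf_svm"), **kw)
        assert r1.to_json() == r2.to_json()


class TestGridSearchSvm:
    def test_best_accuracy_is_surface_maximum(self):
        fm = gaussian_clouds(15)
        (c, g), surface = ef.grid_search_svm(
            fm, c_exponents=[-1, 3], g_exponents=[-5, -1],
            cv=CVSpec(scheme="holdout", seed=0),
        )
        assert surface["accuracy_pct"].between(0, 100).all()
        best_rows = surface[np.isclose(surface["accuracy_pct"], surface["accuracy_pct"].max())]
        assert (c, g) in set(zip(best_rows["c"], best_rows["g"]))

    def test_tie_breaks_to_smallest_c_then_g(self):
        fm = gaussian_clouds(15)  # separable: every lattice point scores 100
        (c, g), _ = ef.grid_search_svm(
            fm, c_exponents=[1, -1], g_exponents=[-3, -5],
            cv=CVSpec(scheme="holdout", seed=0),
        )
        assert (c, g) == (2.0 ** -1, 2.0 ** -5)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            ef.grid_search_svm(gaussian_clouds(5), c_exponents=[], g_exponents=[1])


def ar_epochs(n_per_class, length=128, seed=0):
    """Two classes driven by different AR(2) processes."""
    rng = np.random.default_rng(seed)
    chunks, labels = [], []
    # classes differ only at lag 2, so an order-1 fit cannot separate them
    for coefs, state in (((0.0, 0.5), "normal"), ((0.0, -0.5), "fatigue")):
        for _ in range(n_per_class):
            x = np.zeros(length + 50)
            e = rng.standard_normal(length + 50)
            for t in range(2, length + 50):
                x[t] = coefs[0] * x[t - 1] + coefs[1] * x[t - 2] + e[t]
            chunks.append(x[50:][None, :])
            labels.append(state)
    return EpochSet(
        epochs=np.stack(chunks),
        fs=128.0,
        epoch_length_s=1.0,
        labels=np.array(labels),
        subject_ids=np.repeat("s1", 2 * n_per_class),
        channel_names=("Cz",),
    )


class TestSelectArOrder:
    def test_single_candidate_is_returned(self):
        best, accs = ef.select_ar_order(
            ar_epochs(6), [3], cv=CVSpec(scheme="holdout", seed=0)
        )
        assert best == 3 and list(accs) == [3]

    def test_order_two_beats_order_one_on_ar2_classes(self):
        diffs = []
        for seed in range(20):
            best, accs = ef.select_ar_order(
                ar_epochs(12, seed=seed), [1, 2],
                cv=CVSpec(scheme="holdout", seed=seed),
            )
            diffs.append(accs[2] - accs[1])
        assert np.mean(diffs) > 0

    def test_accuracy_reported_per_candidate(self):
        _, accs = ef.select_ar_order(
            ar_epochs(6), [1, 2, 4], cv=CVSpec(scheme="holdout", seed=0)
        )
        assert sorted(accs) == [1, 2, 4]


class TestEntropyCombinationStudy:
    def test_all_fifteen_subsets_reported(self, desk_epochs_high):
        df = ef.entropy_combination_study(
            desk_epochs_high, cv=CVSpec(scheme="holdout", seed=0)
        )
        assert len(df) == 15
        assert set(df["measures"]) >= {"PE", "FE", "PE+AE+SE+FE"}

    def test_single_measure_row_matches_direct_evaluation(self, desk_epochs_high):
        df = ef.entropy_combination_study(
            desk_epochs_high, cv=CVSpec(scheme="holdout", seed=0)
        )
        fm = ef.extract_feature_matrix(
            desk_epochs_high, mode="entropy_subset", measures=["FE"]
        )
        direct = 100.0 * cv_accuracy(
            fm, ClassifierSpec(), CVSpec(scheme="holdout", seed=0), NormalizationSpec()
        )
        row = df[df["measures"] == "FE"].iloc[0]
        assert row["accuracy_pct"] == pytest.approx(direct, abs=1e-9)

    def test_fusion_does_not_degrade_below_best_single(self):
        fusion_minus_best = []
        for seed in range(20):
            spec = ef.desk_spec(seed=seed, effect_size=0.6, n_subjects=1,
                                n_channels=5, duration_s=10.0)
            epochs = ef.segment_recordings(ef.generate_cohort(spec))
            df = ef.entropy_combination_study(
                epochs, cv=CVSpec(scheme="holdout", seed=seed)
            ).set_index("measures")
            singles = df.loc[["PE", "AE", "SE", "FE"]]
            fusion = df.loc["PE+AE+SE+FE", "accuracy_pct"]
            fusion_minus_best.append(fusion - singles["accuracy_pct"].max())
        assert np.mean(fusion_minus_best) >= -2.0
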