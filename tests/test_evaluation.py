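"""Monte Carlo splits, ROC/AUC, averaged ROC, DeLong test, and the split
training path on plain synthetic feature tables."""
from __future__ import annotations

import numpy as np
import pytest

from optomics.evaluation import (
    average_roc,
    delong_test,
    make_mc_splits,
    roc_and_auc,
    run_experiment,
    train_eval_split,
    ROCCurve,
)

from conftest import SMALL_RF, synthetic_feature_table
from oracles import naive_auc, paired_permutation_auc_pvalue


class TestSplits:
    def test_ten_patients_fraction_03_gives_three_test_patients(self):
        patients = np.repeat([f"P{i}" for i in range(10)], 3)
        labels = np.tile([True, False, True], 10)
        splits = make_mc_splits(patients, labels, n_splits=5,
                                test_fraction=0.3, seed=0)
        assert all(len(s.test_patients) == 3 for s in splits)

    def test_same_seed_identical_split_list(self):
        patients = np.repeat([f"P{i}" for i in range(8)], 2)
        labels = np.tile([True, False], 8)
        a = make_mc_splits(patients, labels, n_splits=10, seed=4)
        b = make_mc_splits(patients, labels, n_splits=10, seed=4)
        assert [(s.train_patients, s.test_patients) for s in a] == \
               [(s.train_patients, s.test_patients) for s in b]

    def test_no_patient_on_both_sides_and_classes_present(self):
        rng = np.random.default_rng(0)
        patients = np.repeat([f"P{i}" for i in range(12)], 4)
        labels = rng.random(48) < 0.4
        labels[:4] = True  # ensure some structure
        splits = make_mc_splits(patients, labels, n_splits=50, seed=1)
        for s in splits:
            assert not set(s.train_patients) & set(s.test_patients)
            for side in (s.train_patients, s.test_patients):
                side_labels = labels[np.isin(patients, side)]
                assert side_labels.any() and not side_labels.all()

    def test_single_class_cohort_rejected(self):
        patients = np.repeat(["P0", "P1", "P2"], 2)
        with pytest.raises(ValueError):
            make_mc_splits(patients, np.ones(6, bool), n_splits=2, seed=0)


class TestROC:
    def test_perfect_and_inverted_separation(self):
        labels = np.array([1, 1, 0, 0], bool)
        assert roc_and_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels).auc == 1.0
        assert roc_and_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels).auc == 0.0

    def test_three_of_four_concordant_pairs(self):
        labels = np.array([1, 1, 0, 0], bool)
        scores = np.array([0.8, 0.4, 0.6, 0.2])
        assert roc_and_auc(scores, labels).auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, bool)
            labels[: max(1, n // 3)] = True
            rng.shuffle(labels)
            # discrete scores force ties, exercising the 1/2 convention
            scores = rng.integers(0, 5, n) / 4.0
            got = roc_and_auc(scores, labels).auc
            assert got == pytest.approx(naive_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc(np.array([0.1, 0.9]), np.array([True, True]))


class TestAverageROC:
    def test_identical_members_zero_sd(self):
        curve = ROCCurve(np.array([0, 0.5, 1.0]), np.array([0, 0.8, 1.0]),
                         0.9)
        avg = average_roc([curve] * 10)
        assert np.allclose(avg.sd_tpr, 0.0)
        assert avg.mean_auc == pytest.approx(0.9)

    def test_interpolated_mean_of_two_known_curves(self):
        """Diagonal and step-at-0 curves average to TPR 0.75 at FPR 0.5."""
        diag = ROCCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5)
        step = ROCCurve(np.array([0.0, 0.0, 1.0]),
                        np.array([0.0, 1.0, 1.0]), 1.0)
        avg = average_roc([diag, step])
        mid = np.argmin(np.abs(avg.fpr_grid - 0.5))
        assert avg.mean_tpr[mid] == pytest.approx(0.75)

    def test_band_contains_exactly_95_of_100_curves(self):
        rng = np.random.default_rng(2)
        curves = []
        for _ in range(100):
            fpr = np.linspace(0, 1, 20)
            tpr = np.clip(fpr + rng.normal(0, 0.05, 20), 0, 1)
            tpr = np.maximum.accumulate(tpr)
            curves.append(ROCCurve(fpr, tpr, float(np.trapezoid(tpr, fpr))))
        avg = average_roc(curves)
        assert avg.n_in_band == 95

    def test_mean_auc_close_to_grid_integral(self):
        rng = np.random.default_rng(3)
        curves = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            scores = np.concatenate([r.normal(1, 1, 20), r.normal(0, 1, 20)])
            labels = np.array([True] * 20 + [False] * 20)
            curves.append(roc_and_auc(scores, labels))
        avg = average_roc(curves)
        grid_auc = float(np.trapezoid(avg.mean_tpr, avg.fpr_grid))
        assert abs(grid_auc - avg.mean_auc) <= 0.01

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_roc([])


class TestDeLong:
    def test_identical_classifiers_z_zero_p_one(self):
        rng = np.random.default_rng(0)
        scores = rng.random(30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        res = delong_test(scores, scores, labels, paired=True)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_agrees_with_permutation_oracle_on_fixed_vectors(self):
        """n = 10 per class: asymptotic p within Monte-Carlo error of a
        10^4-draw sign-flip permutation p."""
        rng = np.random.default_rng(42)
        labels = np.array([True] * 10 + [False] * 10)
        base = np.where(labels, 0.8, 0.4) + rng.normal(0, 0.3, 20)
        scores_a = base + rng.normal(0, 0.15, 20)
        scores_b = base + rng.normal(0, 0.15, 20)
        res = delong_test(scores_a, scores_b, labels, paired=True)
        p_perm = paired_permutation_auc_pvalue(scores_a, scores_b, labels,
                                               n_perm=10_000, seed=0)
        assert res.p_value == pytest.approx(p_perm, abs=0.1)

    def test_type_one_error_calibrated_under_null(self):
        """Independent standard-normal score sets, shared labels: rejection
        rate at alpha = 0.05 stays within 0.05 +/- 0.02 over 1000 sims."""
        rng = np.random.default_rng(7)
        labels = np.array([True] * 50 + [False] * 50)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100)
            res = delong_test(a, b, labels, paired=False)
            rejections += res.p_value <= 0.05
        rate = rejections / n_sim
        assert 0.03 <= rate <= 0.07

    def test_zero_variance_with_unequal_aucs_rejected(self):
        labels = np.array([True, True, False, False])
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            delong_test(a, b, labels, paired=True)


class TestTrainEval:
    def test_perfectly_separable_feature_scores_perfectly(self):
        table = synthetic_feature_table(n_patients=12, samples_per_patient=3,
                                        n_features=4, signal=50.0,
                                        patient_sd=0.1, seed=0)
        splits = make_mc_splits(table.patient_id.to_numpy(),
                                table.malignant.to_numpy(), n_splits=3,
                                seed=1)
        res = train_eval_split(table, splits[0], mrmr_k=1,
                               rf_params=SMALL_RF)
        assert res.metrics["accuracy"] == 1.0
        assert res.metrics["auc"] == 1.0

    def test_deterministic_end_to_end(self, plain_table):
        splits = make_mc_splits(plain_table.patient_id.to_numpy(),
                                plain_table.malignant.to_numpy(),
                                n_splits=2, seed=5)
        a = train_eval_split(plain_table, splits[0], 3, rf_params=SMALL_RF)
        b = train_eval_split(plain_table, splits[0], 3, rf_params=SMALL_RF)
        assert np.array_equal(a.scores, b.scores)
        assert a.metrics == b.metrics

    def test_patient_level_splitting_defeats_patient_memorization(self):
        """With pure patient effects (no label signal), sample-level splits
        let the forest memorize patients and inflate AUC; the shipped
        patient-level splitter stays near chance."""
        table = synthetic_feature_table(n_patients=20, samples_per_patient=6,
                                        n_features=10, signal=0.0,
                                        patient_sd=2.0, seed=11)
        # patient-coherent but feature-independent labels
        feats = [c for c in table.columns if c.startswith("CT__")]
        y = table.malignant.to_numpy()

        splits = make_mc_splits(table.patient_id.to_numpy(), y, n_splits=10,
                                seed=2)
        patient_aucs = [train_eval_split(table, s, 3, feats, SMALL_RF)
                        .metrics["auc"] for s in splits]

        # deliberate bug: split at the sample level
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(3)
        sample_aucs = []
        x = table[feats].to_numpy()
        for _ in range(10):
            idx = rng.permutation(len(table))
            te, tr = idx[: len(idx) // 3], idx[len(idx) // 3 :]
            rf = RandomForestClassifier(random_state=0, **SMALL_RF)
            rf.fit(x[tr], y[tr])
            sc = rf.predict_proba(x[te])[:, list(rf.classes_).index(True)]
            sample_aucs.append(roc_and_auc(sc, y[te]).auc)
        assert np.mean(sample_aucs) > np.mean(patient_aucs) + 0.15
        assert abs(np.mean(patient_aucs) - 0.5) < 0.15

    def test_duplicated_modalities_give_equal_arm_aucs(self):
        """Arms built from identical information perform identically up to
        forest seeding noise."""
        table = synthetic_feature_table(n_patients=16, samples_per_patient=3,
                                        n_features=6, signal=1.2, seed=6)
        # mirror the CT columns into SFDI-tagged duplicates
        for j in range(6):
            table[f"w490_f0.00__firstorder__f{j}"] = \
                table[f"CT__firstorder__f{j}"]
        res = run_experiment(table, arms=("ct", "sfdi"), n_splits=15,
                             mrmr_k=3, rf_params=SMALL_RF, seed=9)
        auc_ct = res.summaries["ct"].mean_metrics["auc"]
        auc_sfdi = res.summaries["sfdi"].mean_metrics["auc"]
        assert auc_ct == pytest.approx(auc_sfdi, abs=0.03)
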