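"""Split logic, random forest runs, accuracy statistics and McNemar's test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from mdshape import (
    FeatureSetSpec,
    RFParams,
    accuracy_assessment,
    feature_sets,
    mcnemar_z,
    run_set,
    split_train_test,
)


def object_table(rng, n=120, n_features=3, names=None):
    names = names or [f"f{i}" for i in range(n_features)]
    data = {name: rng.normal(size=n) for name in names}
    return pd.DataFrame(data)


class TestFeatureSets:
    def test_table_structure(self):
        sets = {s.set_id: s for s in feature_sets()}
        assert len(sets[1].layers) == 21
        for sid, md_name in [(2, "MDIN"), (3, "MDRLR"), (4, "MDRRL"), (5, "MDI")]:
            assert len(sets[sid].layers) == 22
            extra = set(sets[sid].layers) - set(sets[1].layers)
            assert extra == {md_name}

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            FeatureSetSpec(1, ("a", "b"))


class TestSplit:
    def test_counts_single_class(self, rng):
        objects = object_table(rng, n=100)
        labels = np.ones(100, dtype=int)
        train, test = split_train_test(objects, labels, 0.3, seed=1)
        assert train.sum() == 30 and test.sum() == 70
        assert not np.any(train & test)

    def test_deterministic_under_seed(self, rng):
        objects = object_table(rng, n=50)
        labels = rng.integers(1, 4, size=50)
        labels[:6] = [1, 1, 2, 2, 3, 3]
        a = split_train_test(objects, labels, 0.3, seed=7)
        b = split_train_test(objects, labels, 0.3, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_per_class_rounded_counts(self, rng):
        objects = object_table(rng, n=200)
        labels = np.repeat([1, 2, 3, 4], [23, 57, 80, 40])
        train, _ = split_train_test(objects, labels, 0.3, seed=0)
        for cls, n_c in zip([1, 2, 3, 4], [23, 57, 80, 40]):
            assert train[labels == cls].sum() == round(0.3 * n_c)

    def test_exhaustive_over_labeled_and_excludes_unlabeled(self, rng):
        objects = object_table(rng, n=40)
        labels = np.array([0] * 10 + [1] * 15 + [2] * 15)
        train, test = split_train_test(objects, labels, 0.3, seed=0)
        assert np.all(~train[:10]) and np.all(~test[:10])
        assert np.all(train[10:] ^ test[10:])

    def test_small_class_error_names_class(self, rng):
        objects = object_table(rng, n=5)
        labels = np.array([1, 1, 1, 1, 2])
        with pytest.raises(ValueError, match="class 2"):
            split_train_test(objects, labels, 0.3, seed=0)


class TestRunSet:
    def make_spec(self, names):
        base = [f"x{i}" for i in range(21 - len(names))] + list(names)
        return FeatureSetSpec(1, tuple(base)), base

    def test_separable_classes_reach_full_accuracy(self, rng):
        n = 80
        labels = np.repeat([1, 2], n // 2)
        sep = np.where(labels == 1, 0.0, 10.0) + rng.normal(0, 0.1, n)
        cols = {f"x{i}": rng.normal(size=n) for i in range(5)}
        cols["sep"] = sep
        objects = pd.DataFrame(cols)
        train, test = split_train_test(objects, labels, 0.3, seed=0)
        pred, imp = run_set(objects, labels, tuple(cols), train, test,
                            RFParams(n_trees=100, n_permutations=3), seed=0)
        assert np.array_equal(pred, labels[test])
        assert imp.iloc[0]["layer"] == "sep"  # noise features rank below

    def test_same_seed_identical_outputs(self, rng):
        n = 60
        labels = rng.integers(1, 3, size=n)
        labels[:4] = [1, 1, 2, 2]
        cols = {f"x{i}": rng.normal(size=n) + labels for i in range(21)}
        objects = pd.DataFrame(cols)
        spec = FeatureSetSpec(1, tuple(cols))
        train, test = split_train_test(objects, labels, 0.3, seed=3)
        params = RFParams(n_trees=40, n_permutations=3)
        p1, i1 = run_set(objects, labels, spec, train, test, params, seed=5)
        p2, i2 = run_set(objects, labels, spec, train, test, params, seed=5)
        assert np.array_equal(p1, p2)
        pd.testing.assert_frame_equal(i1, i2)

    def test_missing_layer_named(self, rng):
        objects = pd.DataFrame({f"x{i}": rng.normal(size=10) for i in range(20)})
        spec = FeatureSetSpec(1, tuple(f"x{i}" for i in range(20)) + ("absent",))
        labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        train = np.zeros(10, bool); train[:4] = True
        with pytest.raises(ValueError, match="absent"):
            run_set(objects, labels, spec, train, ~train)


class TestAccuracy:
    def test_diagonal_matrix_perfect(self):
        truth = np.array([1, 1, 2, 2, 3])
        cm, rep = accuracy_assessment(truth, truth)
        assert rep.oa == 100.0
        assert rep.kappa == pytest.approx(1.0)
        assert all(v == 100.0 for v in rep.pa.values())
        assert all(v == 100.0 for v in rep.ua.values())

    def test_hand_computed_two_class_matrix(self):
        # confusion [[40, 10], [20, 30]]: p_o = 0.7, p_e = 0.5
        truth = np.repeat([1, 2], [50, 50])
        pred = np.concatenate([np.repeat([1, 2], [40, 10]), np.repeat([1, 2], [20, 30])])
        cm, rep = accuracy_assessment(truth, pred)
        assert np.array_equal(cm.to_numpy(), [[40, 10], [20, 30]])
        assert rep.oa == pytest.approx(70.0)
        assert rep.kappa == pytest.approx(0.4)
        assert rep.pa[1] == pytest.approx(80.0)
        assert rep.ua[1] == pytest.approx(100 * 40 / 60)

    def test_matches_counting_oracle_and_sklearn_kappa(self, rng):
        truth = rng.integers(1, 5, size=300)
        pred = rng.integers(1, 5, size=300)
        cm, rep = accuracy_assessment(truth, pred)
        assert rep.oa == pytest.approx(100.0 * np.mean(truth == pred))
        assert rep.kappa == pytest.approx(cohen_kappa_score(truth, pred))

    def test_chance_level_prediction_kappa_near_zero(self, rng):
        truth = rng.integers(1, 4, size=4000)
        pred = rng.permutation(truth)  # matched marginals, independent
        _, rep = accuracy_assessment(truth, pred)
        assert rep.kappa == pytest.approx(0.0, abs=0.05)

    def test_absent_predicted_class_gives_nan_ua(self):
        truth = np.array([1, 1, 2])
        pred = np.array([1, 1, 1])
        _, rep = accuracy_assessment(truth, pred)
        assert np.isnan(rep.ua[2])
        assert rep.pa[2] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            accuracy_assessment(np.array([]), np.array([]))


class TestMcNemar:
    def test_balanced_discordance_zero(self):
        truth = np.array([1, 1, 1, 1])
        a = np.array([1, 1, 2, 2])
        b = np.array([2, 2, 1, 1])
        z, sig = mcnemar_z(a, b, truth)
        assert z == 0.0 and not sig

    def test_closed_form_value(self):
        truth = np.ones(40, dtype=int)
        a = np.ones(40, dtype=int); a[30:] = 2   # A wrong on 10
        b = np.ones(40, dtype=int); b[10:30] = 2  # B wrong on 20
        z, sig = mcnemar_z(a, b, truth)  # f12 = 20, f21 = 10
        assert z == pytest.approx(10 / np.sqrt(30))
        assert not sig  # |Z| = 1.83 < 1.96

    def test_threshold_at_1_96(self):
        truth = np.ones(8, dtype=int)
        a = np.ones(8, dtype=int)
        b = np.ones(8, dtype=int); b[:4] = 2  # f12=4, f21=0 -> Z=2.0
        z, sig = mcnemar_z(a, b, truth)
        assert z == pytest.approx(2.0) and sig
        b2 = np.ones(8, dtype=int); b2[:3] = 2  # Z = sqrt(3) < 1.96
        z2, sig2 = mcnemar_z(a, b2, truth)
        assert z2 == pytest.approx(np.sqrt(3)) and not sig2

    def test_antisymmetric_under_swap(self, rng):
        truth = rng.integers(1, 3, size=100)
        a = rng.integers(1, 3, size=100)
        b = rng.integers(1, 3, size=100)
        z_ab, _ = mcnemar_z(a, b, truth)
        z_ba, _ = mcnemar_z(b, a, truth)
        assert z_ab == pytest.approx(-z_ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_z(np.ones(3), np.ones(4), np.ones(4))
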