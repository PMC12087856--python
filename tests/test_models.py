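import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from npskin.datamodel import (
    DEPTH_CLASSES,
    DatasetError,
    FeatureEncoder,
    depth_labels,
)
from npskin.models import (
    ClassifierSpec,
    ConfusionMatrix,
    VIPInputs,
    confusion_matrix_from_labels,
    evaluate,
    permutation_importance_table,
    train_classifier,
    vip_scores,
)
from npskin.synth import GeneratorConfig, PlantedRule, generate_frame


def kappa_bruteforce(counts):
    """Loop evaluation of the chance-corrected agreement formula."""
    counts = np.asarray(counts, float)
    n = counts.shape[0]
    N = counts.sum()
    diag = sum(counts[i, i] for i in range(n))
    gc = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(n))
    return (N * diag - gc) / (N * N - gc)


class TestKappa:
    @pytest.mark.parametrize("counts, expected", [
        ([[10, 0], [0, 10]], 1.0),
        ([[5, 5], [5, 5]], 0.0),
        # (50*35 - (25*30 + 25*20)) / (2500 - 1250)
        ([[20, 5], [10, 15]], 0.4),
    ])
    def test_known_matrices(self, counts, expected):
        cm = ConfusionMatrix(np.array(counts), labels=("a", "b"))
        assert cm.kappa() == pytest.approx(expected)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(1000):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 30, size=(k, k)).astype(float)
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, labels=tuple("abcde"[:k]))
            assert cm.kappa() == kappa_bruteforce(counts)

    def test_matches_sklearn_on_labels(self, rng):
        y_true = rng.choice(list(DEPTH_CLASSES), size=300)
        y_pred = rng.choice(list(DEPTH_CLASSES), size=300)
        cm = confusion_matrix_from_labels(y_true, y_pred)
        assert cm.kappa() == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    def test_invariant_under_class_relabelling(self, rng):
        counts = rng.integers(0, 20, size=(5, 5)).astype(float)
        perm = rng.permutation(5)
        cm = ConfusionMatrix(counts, labels=DEPTH_CLASSES)
        cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)], labels=DEPTH_CLASSES)
        assert cm.kappa() == pytest.approx(cm_p.kappa())
        assert cm.accuracy() == pytest.approx(cm_p.accuracy())


class TestVIP:
    def test_single_variable_is_one(self):
        assert vip_scores(VIPInputs(W=[[1.0, 0.5]], ssy=[2.0, 1.0])) == (
            pytest.approx([1.0])
        )

    def test_equal_weights_symmetric(self):
        out = vip_scores(VIPInputs(W=[[0.5]] * 4, ssy=[3.0]))
        np.testing.assert_allclose(out, 1.0)

    def test_hand_evaluated_two_component_case(self):
        W = np.array([[0.8, 0.1], [0.6, 0.3], [0.0, 0.9]])
        ssy = np.array([4.0, 1.0])
        Wn = W / np.sqrt((W**2).sum(axis=0))
        expected = np.sqrt(3 * (Wn**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip_scores(VIPInputs(W=W, ssy=ssy)), expected)

    def test_sum_of_squares_identity(self, rng):
        for _ in range(200):
            J, F = int(rng.integers(2, 15)), int(rng.integers(1, 6))
            W = rng.normal(size=(J, F))
            ssy = rng.uniform(0.1, 5.0, size=F)
            vip = vip_scores(VIPInputs(W=W, ssy=ssy))
            assert np.sum(vip**2) == pytest.approx(J, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(DatasetError):
            VIPInputs(W=[[1.0]], ssy=[0.0])


class TestTraining:
    def test_two_point_tree_is_perfect(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["Surface", "SC"])
        model = train_classifier(ClassifierSpec("decision_tree"), X, y)
        assert list(model.predict(X)) == list(y)

    def test_single_class_rejected(self):
        with pytest.raises(DatasetError, match="single class"):
            train_classifier(
                ClassifierSpec("knn"), np.zeros((5, 2)), ["SC"] * 5
            )

    def test_seeded_determinism(self, complete_fm, labels):
        spec = ClassifierSpec("random_forest", {"n_estimators": 50}, seed=3)
        a = train_classifier(spec, complete_fm.values, labels)
        b = train_classifier(spec, complete_fm.values, labels)
        np.testing.assert_array_equal(
            a.predict(complete_fm.values), b.predict(complete_fm.values)
        )

    def test_forest_interpolates_noiseless_rule(self):
        frame = generate_frame(GeneratorConfig(
            n_records=300, seed=5, missingness={},
            planted_rule=PlantedRule(noise_sd=0.0),
        ))
        fm = FeatureEncoder().fit(frame).transform(frame)
        y = depth_labels(frame)
        model = train_classifier(ClassifierSpec("random_forest"), fm.values, y)
        acc, kappa, _ = evaluate(model, fm.values, y)
        assert acc == 100.0 and kappa == pytest.approx(1.0)

    def test_every_family_beats_majority_baseline(self, complete_fm, labels):
        classes, counts = np.unique(labels, return_counts=True)
        majority = 100.0 * counts.max() / counts.sum()
        for family in ("decision_tree", "random_forest", "knn", "pls_da", "ksvm"):
            model = train_classifier(
                ClassifierSpec(family), complete_fm.values, labels
            )
            acc, _, _ = evaluate(model, complete_fm.values, labels)
            assert acc > majority, family


@pytest.fixture(scope="module")
def fitted():
    frame = generate_frame(GeneratorConfig(
        n_records=400, seed=6, missingness={},
        planted_rule=PlantedRule(noise_sd=0.0),
    ))
    fm = FeatureEncoder().fit(frame).transform(frame)
    y = depth_labels(frame)
    model = train_classifier(
        ClassifierSpec("random_forest", {"n_estimators": 200}),
        fm.values[:300], y[:300],
    )
    fm_val = fm.copy()
    fm_val.values = fm.values[300:]
    fm_val.missing_mask = fm.missing_mask[300:]
    fm_val.ids = []
    return model, fm_val, y[300:]


class TestPermutationImportance:
    def test_dominant_feature_ranks_first(self, fitted):
        model, fm_val, y_val = fitted
        table = permutation_importance_table(model, fm_val, y_val,
                                             n_repeats=10, seed=0)
        ranked = table.ranked()
        assert ranked.index[0] == "hf_diameter"
        assert ranked.iloc[0] == pytest.approx(100.0)

    def test_absent_feature_near_zero(self, fitted):
        model, fm_val, y_val = fitted
        table = permutation_importance_table(model, fm_val, y_val,
                                             n_repeats=10, seed=0)
        # contact time does not enter the planted rule at all
        assert table.scores.loc["contact_time", "overall"] < 10.0

    def test_shuffled_labels_kill_importance(self, fitted, rng):
        model, fm_val, y_val = fitted
        table = permutation_importance_table(
            model, fm_val, rng.permutation(y_val), n_repeats=5, seed=1
        )
        # with the label-feature link destroyed, accuracy drops are noise
        assert table.raw["overall"].abs().max() < 0.1
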