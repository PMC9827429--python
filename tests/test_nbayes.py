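"""Gaussian naive Bayes with prevalence priors and missing-feature handling."""

import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB

from sepsig import (
    CohortTable,
    fit_naive_bayes,
    lofo_cv_accuracy,
    lopo_cv_accuracy,
    predict,
    predict_table,
)
from sepsig.nbayes import FitError, NaiveBayesModel

from conftest import standardized_planted, two_phenotype_spec


def table_from(values, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"f{j}" for j in range(p)]
    return CohortTable(
        np.array([f"P{i}" for i in range(n)], dtype=object),
        np.array(names, dtype=object),
        values,
    )


def symmetric_model():
    return NaiveBayesModel(
        classes=np.array([1, 2]),
        priors=np.array([0.5, 0.5]),
        feature_names=np.array(["x"], dtype=object),
        means=np.array([[1.0], [-1.0]]),
        variances=np.array([[1.0], [1.0]]),
    )


def test_equal_classes_equal_priors():
    rng = np.random.default_rng(0)
    t = table_from(rng.standard_normal((20, 3)))
    model = fit_naive_bayes(t, np.array([1] * 10 + [2] * 10))
    assert model.priors.tolist() == [0.5, 0.5]


def test_development_cohort_prevalence_priors():
    # the development cohort split: 18 vs 139 of 157 patients
    rng = np.random.default_rng(1)
    t = table_from(rng.standard_normal((157, 2)))
    model = fit_naive_bayes(t, np.array([1] * 18 + [2] * 139))
    assert model.priors == pytest.approx([18 / 157, 139 / 157])
    assert model.priors == pytest.approx([0.1146, 0.8854], abs=1e-4)


def test_parameter_recovery_large_n():
    rng = np.random.default_rng(2)
    n = 10_000
    y = np.array([1] * (n // 2) + [2] * (n // 2))
    x = np.where(y[:, None] == 1, -1.0, 1.0) + rng.standard_normal((n, 1))
    model = fit_naive_bayes(table_from(x), y)
    se = 1 / np.sqrt(n / 2)
    assert model.means[:, 0] == pytest.approx([-1.0, 1.0], abs=3 * se)
    assert model.variances[:, 0] == pytest.approx([1.0, 1.0], abs=0.06)


def test_small_class_rejected():
    t = table_from(np.zeros((5, 2)) + np.arange(5)[:, None])
    with pytest.raises(FitError, match="fewer than 2"):
        fit_naive_bayes(t, np.array([1, 1, 1, 1, 2]))


def test_symmetric_input_gives_even_posterior():
    _, post = predict(symmetric_model(), np.array([0.0]))
    assert post == pytest.approx([0.5, 0.5])


def test_posterior_at_class_mean_hand_value():
    # likelihood ratio at x=+1 is e^2, so posterior = 1/(1+e^-2)
    label, post = predict(symmetric_model(), np.array([1.0]))
    assert label == 1
    assert post[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-10)
    assert post[0] == pytest.approx(0.8808, abs=1e-4)


def test_missing_feature_returns_priors():
    with pytest.warns(UserWarning, match="missing"):
        _, post = predict(symmetric_model(), np.array([np.nan]))
    assert post == pytest.approx([0.5, 0.5])


def test_posteriors_sum_to_one():
    rng = np.random.default_rng(3)
    spec = two_phenotype_spec(n=50, p=6, gap=2.0, seed=3)
    std, labels = standardized_planted(spec)
    model = fit_naive_bayes(std, labels + 1)
    for row in rng.permutation(std.values)[:20]:
        _, post = predict(model, row)
        assert abs(post.sum() - 1) < 1e-12


def test_monotone_evidence_toward_class_mean():
    model = symmetric_model()
    xs = np.linspace(-3, 3, 25)
    posts = [predict(model, np.array([x]))[1][0] for x in xs]
    assert np.all(np.diff(posts) >= 0)  # class-1 mean is at +1


def test_agrees_with_sklearn_on_complete_data():
    spec = two_phenotype_spec(n=120, p=8, gap=2.0, seed=4)
    std, labels = standardized_planted(spec)
    model = fit_naive_bayes(std, labels + 1)
    ours, _ = predict_table(model, std)
    sk = GaussianNB().fit(std.values, labels + 1)
    assert (ours == sk.predict(std.values)).mean() >= 0.99


def test_lofo_cv_perfect_on_separated_clusters():
    spec = two_phenotype_spec(n=100, p=20, gap=6.0, seed=5)
    std, labels = standardized_planted(spec)
    assert lofo_cv_accuracy(std, labels + 1) == 1.0


def test_lofo_cv_null_accuracy_near_half():
    rng = np.random.default_rng(6)
    t = table_from(rng.standard_normal((200, 6)))
    y = np.array([1, 2] * 100)
    rng.shuffle(y)
    acc = lofo_cv_accuracy(t, y)
    assert 0.3 < acc < 0.7


def test_lofo_cv_single_feature_rejected():
    t = table_from(np.arange(10, dtype=float)[:, None])
    with pytest.raises(FitError, match="at least 2"):
        lofo_cv_accuracy(t, np.array([1, 2] * 5))


def test_lopo_cv_variant_on_separated_clusters():
    spec = two_phenotype_spec(n=60, p=10, gap=6.0, seed=7)
    std, labels = standardized_planted(spec)
    assert lopo_cv_accuracy(std, labels + 1) == 1.0


def test_prediction_with_absent_panel_columns_warns():
    spec = two_phenotype_spec(n=60, p=6, gap=4.0, seed=8)
    std, labels = standardized_planted(spec)
    model = fit_naive_bayes(std, labels + 1)
    reduced = std.drop_feature(str(std.feature_names[0]))
    with pytest.warns(UserWarning, match="absent"):
        pred, post = predict_table(model, reduced)
    assert (pred == labels + 1).mean() >= 0.95


def test_model_json_round_trip(tmp_path):
    model = symmetric_model()
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = NaiveBayesModel.from_json(path)
    assert np.array_equal(loaded.means, model.means)
    assert np.array_equal(loaded.priors, model.priors)
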