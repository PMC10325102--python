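"""MCC, repeated stratified k-fold evaluation, and variant comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

import dyadsync as ds


def vectors_from_table(tp, tn, fp, fn):
    y_true = [True] * tp + [False] * tn + [False] * fp + [True] * fn
    y_pred = [True] * tp + [False] * tn + [True] * fp + [False] * fn
    return np.array(y_true), np.array(y_pred)


def test_mcc_perfect_and_anti_prediction():
    y = np.array([True, False, True, False, True])
    assert ds.mcc(y, y) == pytest.approx(1.0)
    assert ds.mcc(y, ~y) == pytest.approx(-1.0)


def test_mcc_matches_brute_force_enumeration():
    # every confusion matrix with total count <= 10, checked against the
    # Pearson correlation of the 0/1 vectors (an independent route) and
    # against scikit-learn
    for tp, tn, fp, fn in itertools.product(range(11), repeat=4):
        total = tp + tn + fp + fn
        if not 1 <= total <= 10:
            continue
        y_true, y_pred = vectors_from_table(tp, tn, fp, fn)
        got = ds.mcc(y_true, y_pred)
        if y_true.all() or not y_true.any() or y_pred.all() or not y_pred.any():
            assert got == 0.0
        else:
            expected = np.corrcoef(y_true, y_pred)[0, 1]
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9
            )


def test_mcc_specific_table():
    y_true, y_pred = vectors_from_table(tp=4, tn=3, fp=1, fn=2)
    expected = np.corrcoef(y_true, y_pred)[0, 1]
    assert ds.mcc(y_true, y_pred) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
def test_mcc_agrees_with_sklearn_on_arbitrary_vectors(pairs):
    y_true = np.array([p[0] for p in pairs])
    y_pred = np.array([p[1] for p in pairs])
    got = ds.mcc(y_true, y_pred)
    assert -1.0 <= got <= 1.0
    assert got == pytest.approx(
        matthews_corrcoef(y_true, y_pred), abs=1e-9
    )


def test_mcc_rejects_length_mismatch():
    with pytest.raises(ValueError):
        ds.mcc([True, False], [True])


def null_features(n=60, n_pos=12, n_feat=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_feat))
    y = np.zeros(n, dtype=bool)
    y[:n_pos] = True
    rng.shuffle(y)
    return X, y


def test_null_features_give_mcc_near_zero():
    # fresh label-independent cohort per repetition (null-simulation
    # oracle); a single fixed cohort would retain exploitable sampling
    # associations between its features and labels
    counter = [0]

    def source(rng):
        counter[0] += 1
        return null_features(seed=counter[0])

    dist = ds.repeated_kfold_eval(
        source, ds.EvalConfig(repetitions=15), np.random.default_rng(3)
    )
    assert abs(dist.mean_mcc) <= 2 * max(dist.se_mcc, 0.02)


def test_label_leak_feature_gives_mcc_near_one():
    X, y = null_features()
    X = np.column_stack([X, y.astype(float)])
    dist = ds.repeated_kfold_eval(
        (X, y), ds.EvalConfig(repetitions=5), np.random.default_rng(3)
    )
    assert dist.mean_mcc >= 0.95


def test_repetition_count_and_determinism():
    X, y = null_features()
    cfg = ds.EvalConfig(repetitions=50, rf_n_trees=10)
    d1 = ds.repeated_kfold_eval((X, y), cfg, np.random.default_rng(9))
    d2 = ds.repeated_kfold_eval((X, y), cfg, np.random.default_rng(9))
    assert d1.mcc_values.shape == (50,)
    np.testing.assert_array_equal(d1.mcc_values, d2.mcc_values)
    assert d1.se_mcc == pytest.approx(
        d1.mcc_values.std(ddof=1) / np.sqrt(50)
    )


def test_single_class_labels_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        ds.repeated_kfold_eval(
            (X, np.ones(10, bool)), ds.EvalConfig(repetitions=1)
        )


def test_regenerating_feature_source_called_per_repetition():
    calls = []

    def source(rng):
        calls.append(1)
        return null_features(seed=len(calls))

    ds.repeated_kfold_eval(
        source, ds.EvalConfig(repetitions=4, rf_n_trees=10),
        np.random.default_rng(0),
    )
    assert len(calls) == 4


def test_logistic_baseline_runs_on_separable_data():
    X, y = null_features()
    X = np.column_stack([X, y.astype(float) * 2 - 1])
    cfg = ds.EvalConfig(repetitions=3, model_kind="logistic_baseline")
    dist = ds.repeated_kfold_eval((X, y), cfg, np.random.default_rng(1))
    assert dist.mean_mcc >= 0.9


def test_baseline_features_correlation_term(rng):
    x = rng.uniform(-1, 1, 64)
    same = ds.baseline_features(ds.DyadSeries("c", "positive", x, x.copy()))
    assert same[4] == pytest.approx(1.0)
    flipped = ds.baseline_features(ds.DyadSeries("c", "positive", x, -x))
    assert flipped[4] == pytest.approx(-1.0)
    np.testing.assert_allclose(
        same[:4], [x.mean(), x.mean(), x.var(), x.var()], rtol=1e-12
    )


def test_baseline_features_against_direct_pearson(rng):
    cfg = ds.GeneratorConfig(series_length=100, seed=5)
    d = ds.generate_dyad(cfg, coupling=0.5, rng=rng)
    feats = ds.baseline_features(d)
    a, b = d.series_a, d.series_b
    r_direct = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
    assert feats[4] == pytest.approx(r_direct, abs=1e-12)


def test_baseline_features_zero_variance_warns(caplog):
    d = ds.DyadSeries("c", "positive", np.full(8, 0.1),
                      np.linspace(-1, 1, 8))
    with caplog.at_level("WARNING"):
        feats = ds.baseline_features(d)
    assert feats[4] == 0.0


def dist_of(values, variant="x", context="positive"):
    return ds.PerformanceDistribution(variant, context, np.asarray(values, float))


def test_compare_variants_interval_logic():
    d1 = dist_of(np.full(10, 0.10), "v1")
    d2 = dist_of(np.full(10, 0.02), "v2")
    d3 = dist_of(np.full(10, 0.10), "v3")
    cmp_ = ds.compare_variants([d1, d2, d3])
    pair = cmp_.pairwise.set_index(["variant_1", "variant_2"])
    assert pair.loc[("v1", "v2"), "significant"]
    assert not pair.loc[("v1", "v3"), "significant"]  # identical values
    zero = cmp_.vs_zero.set_index("variant")
    assert not zero.loc["v1", "indistinguishable_from_zero"]
    mixed = dist_of([0.01, -0.01] * 5, "v0")
    cmp0 = ds.compare_variants([mixed])
    assert cmp0.vs_zero.iloc[0]["indistinguishable_from_zero"]
    assert cmp0.pairwise.empty


def test_compare_variants_requires_shared_context():
    with pytest.raises(ValueError):
        ds.compare_variants(
            [dist_of([0.1]), dist_of([0.1], context="conflict")]
        )
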