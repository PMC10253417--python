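"""Classifier benchmark: AUC oracle, determinism, separability, integration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from aepkit.classify import (ModelSpec, benchmark, cross_validate,
                             integrate_features, trapezoidal_auc)
from aepkit.errors import DataError, ValidationError

FAST_GRID = {"model__estimator__C": [1.0]}


def _two_gaussians(rng, n=200, sep=2.0, p=5):
    y = np.array(["high" if v else "low" for v in rng.random(n) < 0.5])
    X = rng.normal(size=(n, p))
    X[y == "high", 0] += sep
    return pd.DataFrame(X, index=[f"i{k}" for k in range(n)]), pd.Series(
        y, index=[f"i{k}" for k in range(n)])


def test_trapezoidal_auc_equals_mann_whitney():
    """Trapezoid-rule AUC == U / (n+ * n-) to 1e-10 on random scores."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(20, 120))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() in (0, n):
            continue
        scores = rng.normal(size=n) + 0.8 * y
        u = mannwhitneyu(scores[y == 1], scores[y == 0],
                         alternative="two-sided").statistic
        oracle = u / (y.sum() * (n - y.sum()))
        assert trapezoidal_auc(y, scores) == pytest.approx(oracle, abs=1e-10)


def test_linearly_separable_svm_near_perfect():
    """Two Gaussians 6 sigma apart: linear SVM reaches AUC >= 0.99."""
    rng = np.random.default_rng(1)
    X, y = _two_gaussians(rng, n=400, sep=6.0)
    rep = cross_validate(X, y, ModelSpec("svm_linear", grid=FAST_GRID),
                         folds=10, seed=0)
    assert rep.auc >= 0.99
    assert rep.sensitivity >= 0.95 and rep.specificity >= 0.95


def test_confusion_counts_reproduce_rates():
    rng = np.random.default_rng(2)
    X, y = _two_gaussians(rng, n=200, sep=2.0)
    rep = cross_validate(X, y, ModelSpec("lda"), folds=5, seed=0)
    for (tp, fn, tn, fp), sens, spec in zip(rep.fold_confusion,
                                            rep.fold_sensitivity,
                                            rep.fold_specificity):
        assert sens == tp / (tp + fn)
        assert spec == tn / (tn + fp)
    assert rep.auc == pytest.approx(np.mean(rep.fold_auc))


def test_cross_validate_deterministic():
    rng = np.random.default_rng(3)
    X, y = _two_gaussians(rng, n=150, sep=1.0)
    a = cross_validate(X, y, ModelSpec("random_forest",
                                       grid={"model__n_estimators": [50]}),
                       folds=5, seed=4)
    b = cross_validate(X, y, ModelSpec("random_forest",
                                       grid={"model__n_estimators": [50]}),
                       folds=5, seed=4)
    assert a.fold_auc == b.fold_auc
    assert a.fold_confusion == b.fold_confusion
    pd.testing.assert_series_equal(a.fold_assignment, b.fold_assignment)


def test_grouped_folds_keep_patients_together():
    rng = np.random.default_rng(5)
    X, y = _two_gaussians(rng, n=120, sep=1.5)
    groups = np.repeat([f"p{i}" for i in range(60)], 2)
    # force both ears of a patient to share the label for stratification
    y = pd.Series(np.repeat(y.to_numpy()[::2], 2), index=y.index)
    rep = cross_validate(X, y, ModelSpec("lda"), folds=5, seed=0,
                         groups=groups)
    folds = rep.fold_assignment
    for i in range(60):
        pair = folds.iloc[2 * i:2 * i + 2]
        assert pair.iloc[0] == pair.iloc[1]


def test_nonfinite_features_rejected():
    X = pd.DataFrame([[1.0, np.nan], [2.0, 1.0]] * 10)
    y = pd.Series(["low", "high"] * 10)
    with pytest.raises(DataError, match="non-finite"):
        cross_validate(X, y, ModelSpec("lda"))


def test_unknown_model_kind_rejected():
    with pytest.raises(ValidationError, match="unknown model kind"):
        ModelSpec("boosted_trees")


def test_integrate_features_broadcasts_clinical_rows():
    scattering = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                              index=["p0-left", "p0-right",
                                     "p1-left", "p1-right"],
                              columns=[f"s{i}" for i in range(3)])
    clinical = pd.DataFrame({"Age": [50.0, 60.0], "GUF": [10.0, 20.0]},
                            index=["p0", "p1"])
    patient_of = pd.Series(["p0", "p0", "p1", "p1"], index=scattering.index)
    out = integrate_features(scattering, clinical, patient_of=patient_of)
    assert out.shape == (4, 5)
    # the two ears of one patient share the clinical block but not the
    # scattering block
    assert (out.loc["p0-left", ["Age", "GUF"]]
            == out.loc["p0-right", ["Age", "GUF"]]).all()
    assert not (out.loc["p0-left", ["s0", "s1", "s2"]]
                == out.loc["p0-right", ["s0", "s1", "s2"]]).all()


def test_integrate_features_column_arithmetic():
    """65 scattering + 15 clinical columns -> 80 integrated columns."""
    rng = np.random.default_rng(0)
    ears = [f"p{i}-{e}" for i in range(10) for e in ("left", "right")]
    scat = pd.DataFrame(rng.normal(size=(20, 65)), index=ears)
    scat.columns = [f"c{i}" for i in range(65)]
    clin = pd.DataFrame(rng.normal(size=(10, 15)),
                        index=[f"p{i}" for i in range(10)],
                        columns=[f"k{i}" for i in range(15)])
    patient_of = pd.Series([e.rsplit("-", 1)[0] for e in ears], index=ears)
    out = integrate_features(scat, clin, patient_of=patient_of)
    assert out.shape[1] == 80
    empty = integrate_features(scat, clin.iloc[:, :0], patient_of=patient_of)
    assert empty.shape[1] == 65


def test_integrate_features_orphan_ear_is_join_error():
    scat = pd.DataFrame([[1.0]], index=["px-left"])
    clin = pd.DataFrame({"Age": [50.0]}, index=["p0"])
    with pytest.raises(DataError, match="no clinical row"):
        integrate_features(scat, clin,
                           patient_of=pd.Series(["px"], index=["px-left"]))


def test_benchmark_row_count_and_best_flag():
    rng = np.random.default_rng(7)
    Xa, ya = _two_gaussians(rng, n=100, sep=2.0, p=4)
    Xb, yb = _two_gaussians(rng, n=100, sep=0.5, p=6)
    specs = [ModelSpec("lda"), ModelSpec("naive_bayes"),
             ModelSpec("svm_linear", grid=FAST_GRID)]
    table, reports = benchmark({"strong": (Xa, ya), "weak": (Xb, yb)},
                               specs, folds=5, seed=0)
    assert len(table) == 6  # cartesian product of sets and models
    assert table.groupby("feature_set")["best_in_set"].sum().eq(1).all()
    assert set(table["n_features"]) == {4, 6}
    one, _ = benchmark({"strong": (Xa, ya)}, [ModelSpec("lda")], folds=5,
                       seed=0)
    rep = reports[("strong", "lda")]
    assert one.iloc[0]["auc"] == pytest.approx(rep.auc)


@pytest.mark.parametrize("kind", ["lda", "svm_linear", "svm_radial",
                                  "svm_poly", "naive_bayes", "neural_net",
                                  "random_forest"])
def test_every_model_kind_trains_and_scores(kind):
    """All seven classifier kinds produce a coherent CVReport."""
    rng = np.random.default_rng(11)
    X, y = _two_gaussians(rng, n=80, sep=3.0, p=3)
    grid = {"random_forest": {"model__n_estimators": [30]},
            "neural_net": {"model__hidden_layer_sizes": [(3,)],
                           "model__alpha": [0.1]},
            }.get(kind, {"model__estimator__C": [1.0]}
            if kind.startswith("svm") else {})
    rep = cross_validate(X, y, ModelSpec(kind, grid=grid), folds=4, seed=0)
    assert 0.0 <= rep.auc <= 1.0
    assert rep.auc >= 0.8  # 3-sigma separation is easy for every family
    assert len(rep.fold_auc) == 4
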