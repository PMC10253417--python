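"""Cross-validated benchmark of seven classifiers on any feature set.

The classifier family covers linear discriminant analysis, linear / radial
/ polynomial support vector machines, Gaussian naive Bayes, a single
hidden-layer neural network, and a random forest.  Evaluation is
stratified 10-fold cross-validation reporting the mean over folds of the
trapezoidal ROC AUC, plus sensitivity and specificity at the 0.5 posterior
threshold (positive class = high distress).  Within each training fold,
features are standardized (fit on the training part only) and a small
hyperparameter grid is searched by inner-CV AUC.

When instances are ears, the two ears of one patient are kept in the same
fold (grouped stratification) so that the morphological similarity of a
patient's ears can never leak across the train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import (GridSearchCV, StratifiedGroupKFold,
                                     StratifiedKFold)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError, ValidationError

MODEL_KINDS = ("lda", "svm_linear", "svm_radial", "svm_poly",
               "naive_bayes", "neural_net", "random_forest")

_SVM_COST = [0.25, 0.5, 1.0, 2.0, 4.0]


@dataclass(frozen=True)
class ModelSpec:
    """One classifier kind with its hyperparameter grid.

    ``grid=None`` uses the default small grid for the kind (see
    :func:`default_grid`); an empty-or-singleton grid skips the inner
    search entirely.
    """

    kind: str
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValidationError(
                f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


def default_grid(kind: str, X: np.ndarray) -> dict:
    """Small, standard grids keeping runs desk-scale and reproducible."""
    p = X.shape[1]
    svm = "model__estimator__"
    if kind in ("svm_linear",):
        return {svm + "C": _SVM_COST}
    if kind == "svm_radial":
        gamma0 = _median_heuristic_gamma(X)
        return {svm + "C": _SVM_COST,
                svm + "gamma": [gamma0 / 2, gamma0, gamma0 * 2]}
    if kind == "svm_poly":
        return {svm + "C": _SVM_COST, svm + "degree": [2, 3]}
    if kind == "neural_net":
        return {"model__hidden_layer_sizes": [(3,), (5,), (7,)],
                "model__alpha": [0.01, 0.1]}
    if kind == "random_forest":
        base = max(1, round(np.sqrt(p)))
        cand = sorted({max(1, base - 1), base, min(p, base + 1)})
        return {"model__max_features": cand}
    return {}  # lda, naive_bayes


def _median_heuristic_gamma(X: np.ndarray, max_n: int = 200) -> float:
    """RBF bandwidth from the median pairwise squared distance."""
    sub = X[:max_n]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def build_estimator(spec: ModelSpec):
    k, seed = spec.kind, spec.seed
    if k == "lda":
        model = LinearDiscriminantAnalysis()
    elif k in ("svm_linear", "svm_radial", "svm_poly"):
        kernel = {"svm_linear": "linear", "svm_radial": "rbf",
                  "svm_poly": "poly"}[k]
        # posterior probabilities via Platt scaling on internal CV splits
        model = CalibratedClassifierCV(SVC(kernel=kernel, random_state=seed),
                                       ensemble=False)
    elif k == "naive_bayes":
        model = GaussianNB()
    elif k == "neural_net":
        model = MLPClassifier(hidden_layer_sizes=(5,), max_iter=2000,
                              random_state=seed)
    else:
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("model", model)])


@dataclass
class CVReport:
    """Cross-validation result for one model on one feature set."""

    kind: str
    n_features: int
    fold_auc: list
    fold_sensitivity: list
    fold_specificity: list
    fold_youden_threshold: list
    fold_confusion: list          # (tp, fn, tn, fp) per fold
    roc_points: np.ndarray        # pooled held-out (fpr, tpr) curve
    fold_assignment: pd.Series    # instance id -> fold
    auc: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = float(np.mean(self.fold_auc))
        self.sensitivity = float(np.mean(self.fold_sensitivity))
        self.specificity = float(np.mean(self.fold_specificity))


def trapezoidal_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def _as_binary(labels) -> np.ndarray:
    y = pd.Series(labels)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes, got {classes}")
    positive = "high" if "high" in classes else classes[1]
    return (y == positive).astype(int).to_numpy()


def cross_validate(features, labels, spec: ModelSpec, *, folds: int = 10,
                   seed: int = 0, groups=None, inner_folds: int = 3) -> CVReport:
    """Stratified (optionally patient-grouped) k-fold evaluation.

    Returns a :class:`CVReport` with per-fold and mean AUC, sensitivity
    and specificity; fully reproducible for identical inputs and seed.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("features contain non-finite values")
    y = _as_binary(labels)
    if isinstance(features, pd.DataFrame):
        ids = features.index
    else:
        ids = pd.RangeIndex(len(X))

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=seed)
        split = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split = splitter.split(X, y)

    grid = spec.grid if spec.grid is not None else default_grid(spec.kind, X)
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1

    fold_auc, fold_sens, fold_spec = [], [], []
    fold_youden, fold_conf = [], []
    assignment = pd.Series(index=ids, dtype=int, name="fold")
    pooled_true, pooled_score = [], []
    for fold_no, (tr, te) in enumerate(split):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise DataError(
                f"fold {fold_no}: a class is absent from the split; "
                f"use fewer folds or more data")
        est = build_estimator(spec)
        if n_combos > 1:
            inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                    random_state=seed + 1)
            est = GridSearchCV(est, grid, scoring="roc_auc", cv=inner,
                               n_jobs=1, refit=True)
        elif grid:  # singleton grid: set directly
            est.set_params(**{k: v[0] for k, v in grid.items()})
        est.fit(X[tr], y[tr])
        prob = est.predict_proba(X[te])[:, 1]
        fold_auc.append(trapezoidal_auc(y[te], prob))
        pred = (prob >= 0.5).astype(int)
        tp = int(((pred == 1) & (y[te] == 1)).sum())
        fn = int(((pred == 0) & (y[te] == 1)).sum())
        tn = int(((pred == 0) & (y[te] == 0)).sum())
        fp = int(((pred == 1) & (y[te] == 0)).sum())
        fold_conf.append((tp, fn, tn, fp))
        fold_sens.append(tp / (tp + fn))
        fold_spec.append(tn / (tn + fp))
        fpr, tpr, thr = roc_curve(y[te], prob)
        fold_youden.append(float(thr[np.argmax(tpr - fpr)]))
        assignment.iloc[te] = fold_no
        pooled_true.append(y[te])
        pooled_score.append(prob)

    fpr, tpr, _ = roc_curve(np.concatenate(pooled_true),
                            np.concatenate(pooled_score))
    return CVReport(kind=spec.kind, n_features=X.shape[1], fold_auc=fold_auc,
                    fold_sensitivity=fold_sens, fold_specificity=fold_spec,
                    fold_youden_threshold=fold_youden, fold_confusion=fold_conf,
                    roc_points=np.column_stack([fpr, tpr]),
                    fold_assignment=assignment)


def integrate_features(scattering: pd.DataFrame,
                       clinical_selected: pd.DataFrame, *,
                       patient_of: pd.Series | None = None,
                       exclude: tuple = ()) -> pd.DataFrame:
    """Ear-level matrix: scattering features + broadcast clinical features.

    ``scattering`` is indexed by ear/record id; ``patient_of`` maps that
    index to patient ids (default: index of the form ``<patient>-<ear>``
    split on the last dash... supplied explicitly in pipelines).  Clinical
    rows are repeated for both ears of a patient; ``exclude`` drops named
    clinical columns (e.g. audiological variables unrelated to the
    tinnitus-matched ears).  An ear whose patient has no clinical row is a
    join error.
    """
    if patient_of is None:
        raise ValidationError("integrate_features: patient_of mapping required")
    patient_of = patient_of.loc[scattering.index]
    missing = set(patient_of) - set(clinical_selected.index)
    if missing:
        raise DataError(
            f"integrate_features: no clinical row for patient(s) "
            f"{sorted(missing)[:5]}")
    clin = clinical_selected.drop(columns=[c for c in exclude
                                           if c in clinical_selected.columns])
    broadcast = clin.loc[patient_of].set_index(scattering.index)
    return pd.concat([scattering, broadcast], axis=1)


def benchmark(feature_sets: dict, specs, *, folds: int = 10,
              seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """All (feature set x model) cross-validations.

    ``feature_sets`` maps a set name to ``(features, labels)`` or
    ``(features, labels, groups)``.  Returns the results table (one row per
    combination, best model per set flagged by AUC) and the full
    :class:`CVReport` per combination.
    """
    rows, reports = [], {}
    for name, bundle in feature_sets.items():
        features, labels, *rest = bundle
        groups = rest[0] if rest else None
        for spec in specs:
            rep = cross_validate(features, labels, spec, folds=folds,
                                 seed=seed, groups=groups)
            reports[(name, spec.kind)] = rep
            rows.append({"feature_set": name, "classifier": spec.kind,
                         "n_features": rep.n_features, "auc": rep.auc,
                         "sensitivity": rep.sensitivity,
                         "specificity": rep.specificity})
    table = pd.DataFrame(rows)
    table["best_in_set"] = False
    for name, grp in table.groupby("feature_set"):
        table.loc[grp["auc"].idxmax(), "best_in_set"] = True
    return table, reports


def export_roc(report: CVReport, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1],
            label=f"{report.kind} (mean fold AUC {report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title or "Pooled held-out ROC")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
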