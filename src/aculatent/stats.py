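"""ANOVA on attractor axes and cross-validated condition classification.

The feature table has one row per trial: long and short semi-axis of that
trial's fitted latent attractor, plus condition, subject and trial labels.
Condition is predicted from the two axis features with four standard
classifiers (RBF-kernel SVM, k-nearest neighbours, linear discriminant
analysis, decision tree) under stratified 5-fold cross-validation repeated
10 times; features are standardized inside each training fold only, so no
information leaks from test folds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_NAMES = ("SVM", "KNN", "LDA", "DT")

FEATURE_COLUMNS = ("long_axis", "short_axis")


@dataclass
class CvResult:
    """Cross-validation outcome for one classifier."""

    model_name: str
    fold_accuracies: np.ndarray  # folds x repeats flattened
    mean_accuracy: float
    confusion: pd.DataFrame      # summed counts over all folds and repeats


def _make_model(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _validate_features(features: pd.DataFrame) -> pd.DataFrame:
    for col in (*FEATURE_COLUMNS, "condition"):
        if col not in features.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    if features[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table contains missing values")
    return features


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA -> (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if pooled.var() <= 0:
        raise ValueError("total variance is zero")
    if all(g.var() == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    f, p = sstats.f_oneway(*groups)
    return float(f), float(p)


def axis_anova(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Attractor-axis significance tables.

    ``within``: per condition, ANOVA of long- vs short-axis trial values
    (are the two axes distinguishable within a state?).  ``between``: per
    axis, ANOVA between each pair of conditions (does the axis separate
    states?); empty with a single condition.
    """
    _validate_features(features)
    conditions = list(dict.fromkeys(features["condition"]))

    within_rows = []
    for cond in conditions:
        sub = features[features["condition"] == cond]
        f, p = anova_oneway([sub["long_axis"].to_numpy(),
                             sub["short_axis"].to_numpy()])
        within_rows.append({"condition": cond, "F": f, "p": p})
    within = pd.DataFrame(within_rows).set_index("condition")

    between_rows = []
    for axis in FEATURE_COLUMNS:
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1:]:
                ga = features.loc[features["condition"] == ca, axis].to_numpy()
                gb = features.loc[features["condition"] == cb, axis].to_numpy()
                f, p = anova_oneway([ga, gb])
                between_rows.append({"axis": axis, "contrast": f"{ca} vs {cb}",
                                     "F": f, "p": p})
    between = pd.DataFrame(between_rows,
                           columns=["axis", "contrast", "F", "p"])
    return {"within": within, "between": between}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def cross_validate(
    features: pd.DataFrame,
    model: str = "SVM",
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation, repeated, for one classifier."""
    _validate_features(features)
    x = features[list(FEATURE_COLUMNS)].to_numpy()
    y = features["condition"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 conditions to classify")
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has {counts.min()} members < k={k}")

    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    accs = []
    conf = np.zeros((classes.size, classes.size), dtype=int)
    for train_idx, test_idx in cv.split(x, y):
        clf = make_pipeline(StandardScaler(), _make_model(model, seed))
        clf.fit(x[train_idx], y[train_idx])
        pred = clf.predict(x[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        conf += confusion_matrix(y[test_idx], pred, labels=classes)
    accs = np.array(accs)
    return CvResult(
        model_name=model, fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
    )


def compare_models(
    features: pd.DataFrame,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-validated accuracy for all four classifiers, shared seed."""
    rows = []
    for name in MODEL_NAMES:
        res = cross_validate(features, model=name, k=k, repeats=repeats, seed=seed)
        rows.append({"model": name, "mean_accuracy": res.mean_accuracy,
                     "sd_accuracy": float(res.fold_accuracies.std(ddof=1))})
    return pd.DataFrame(rows).set_index("model")
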