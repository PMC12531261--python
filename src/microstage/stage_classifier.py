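"""Three-class random-forest staging from ASV relative abundances.

The diagnostic question: can NC / NM / M status be read off the fecal (or
salivary) community? A random forest ranks ASVs by MeanDecreaseGini (total
impurity reduction) and MeanDecreaseAccuracy (out-of-bag accuracy drop under
per-feature permutation); only the top-k Gini features are kept as the
biomarker panel. Performance is estimated with stratified five-fold
cross-validation, with feature selection repeated inside each training fold
so no test information leaks into the panel. Metrics are computed on the
pooled out-of-fold class probabilities: accuracy, Cohen's kappa, log loss,
macro/micro F1, and one-vs-rest per-class, macro and micro AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize


@dataclass
class ClassifierReport:
    accuracy: float
    kappa: float
    log_loss: float
    macro_f1: float
    micro_f1: float
    per_class_auc: dict
    macro_auc: float
    micro_auc: float
    confusion: np.ndarray
    classes: list
    selected_features: list
    folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "log_loss": self.log_loss,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "selected_features": list(self.selected_features),
            "folds": self.folds,
            "seed": self.seed,
        }


def _as_array(x):
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    x = np.asarray(x, dtype=float)
    return x, [f"feature_{k}" for k in range(x.shape[1])]


def rank_features(
    x, y, n_trees: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Gini and OOB-permutation-accuracy importances with ranks.

    MeanDecreaseGini is the forest's mean impurity decrease per feature;
    MeanDecreaseAccuracy permutes one feature at a time within each tree's
    out-of-bag samples and records the accuracy drop, averaged over trees.
    """
    x_arr, names = _as_array(x)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, bootstrap=True, n_jobs=1
    ).fit(x_arr, y)
    gini = forest.feature_importances_

    n = x_arr.shape[0]
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    rng = np.random.default_rng(seed)
    drops = np.zeros((len(forest.estimators_), x_arr.shape[1]))
    class_index = {c: k for k, c in enumerate(forest.classes_)}
    y_idx = np.array([class_index[v] for v in y])
    for t, tree in enumerate(forest.estimators_):
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) == 0:
            continue
        x_oob = x_arr[oob]
        base = (tree.predict(x_oob).astype(int) == y_idx[oob]).mean()
        for j in range(x_arr.shape[1]):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(len(oob)), j]
            acc = (tree.predict(x_perm).astype(int) == y_idx[oob]).mean()
            drops[t, j] = base - acc
    mda = drops.mean(axis=0)

    table = pd.DataFrame({
        "asv_id": names,
        "mean_decrease_gini": gini,
        "mean_decrease_accuracy": mda,
    })
    table["rank_gini"] = (
        table["mean_decrease_gini"].rank(ascending=False, method="first").astype(int)
    )
    table["rank_accuracy"] = (
        table["mean_decrease_accuracy"].rank(ascending=False, method="first").astype(int)
    )
    return table.set_index("asv_id")


def ovr_roc(probabilities: np.ndarray, y, classes=None) -> dict:
    """One-vs-rest per-class AUC plus macro (unweighted mean over present
    classes) and micro (pooled flattened (sample, class) indicator pairs)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    classes = list(classes)
    if p.shape[1] != len(classes):
        raise ValueError("probability columns must match the class list")
    per_class = {}
    for k, c in enumerate(classes):
        mask = y == c
        if mask.all() or not mask.any():
            warnings.warn(f"class {c!r} absent from y; its AUC is undefined")
            per_class[str(c)] = np.nan
            continue
        per_class[str(c)] = float(roc_auc_score(mask.astype(int), p[:, k]))
    present = [v for v in per_class.values() if np.isfinite(v)]
    macro = float(np.mean(present)) if present else np.nan
    onehot = label_binarize(y, classes=classes)
    if onehot.shape[1] == 1:  # degenerate two-class binarization
        onehot = np.column_stack([1 - onehot, onehot])
    micro = float(roc_auc_score(onehot.ravel(), p.ravel()))
    return {"per_class_auc": per_class, "macro_auc": macro, "micro_auc": micro}


def kappa_f1(confusion: np.ndarray) -> dict:
    """Accuracy, Cohen's kappa and macro/micro F1 from a confusion matrix
    (rows = truth, columns = prediction)."""
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0 or (c < 0).any():
        raise ValueError("confusion matrix must be nonnegative with positive total")
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum() / total**2)
    degenerate = np.isclose(pe, 1.0)
    kappa = 0.0 if degenerate else (po - pe) / (1.0 - pe)
    f1s = []
    for k in range(c.shape[0]):
        tp = c[k, k]
        denom = 2 * tp + (c[k, :].sum() - tp) + (c[:, k].sum() - tp)
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return {
        "accuracy": float(po),
        "kappa": float(kappa),
        "kappa_degenerate": bool(degenerate),
        "macro_f1": float(np.mean(f1s)),
        "micro_f1": float(po),  # equals accuracy for single-label multiclass
    }


def evaluate_cv(
    x,
    y,
    top_k: int = 8,
    folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    select_in_fold: bool = True,
) -> ClassifierReport:
    """Stratified k-fold CV with leakage-safe in-fold top-k Gini selection.

    ``select_in_fold=False`` reproduces the optimistic full-data selection for
    comparison; it is not the default precisely because it leaks.
    """
    x_df = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < folds).any():
        small = classes[counts < folds].tolist()
        raise ValueError(
            f"classes {small} have fewer than {folds} samples; use fewer folds"
        )
    top_k = min(top_k, x_df.shape[1])
    if not select_in_fold:
        full_rank = rank_features(x_df, y, n_trees=n_trees, seed=seed)
        fixed = full_rank.sort_values("rank_gini").index[:top_k].tolist()

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = len(y)
    proba = np.zeros((n, len(classes)))
    pred = np.empty(n, dtype=object)
    panels = []
    for f, (tr, te) in enumerate(skf.split(x_df, y)):
        if select_in_fold:
            imp = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed + f, n_jobs=1
            ).fit(x_df.iloc[tr], y[tr]).feature_importances_
            order = np.argsort(-imp, kind="stable")
            panel = x_df.columns[order[:top_k]].tolist()
        else:
            panel = fixed
        panels.append(panel)
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + f, n_jobs=1
        ).fit(x_df.iloc[tr][panel], y[tr])
        p = clf.predict_proba(x_df.iloc[te][panel])
        for k, c in enumerate(clf.classes_):
            proba[te, np.searchsorted(classes, c)] = p[:, k]
        pred[te] = clf.predict(x_df.iloc[te][panel])

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    cindex = {c: k for k, c in enumerate(classes)}
    for truth, hat in zip(y, pred):
        confusion[cindex[truth], cindex[hat]] += 1
    base = kappa_f1(confusion)
    roc = ovr_roc(proba, y, classes=classes)
    ll = float(log_loss(y, proba, labels=classes))
    consensus = sorted(set().union(*panels)) if panels else []
    return ClassifierReport(
        accuracy=base["accuracy"], kappa=base["kappa"], log_loss=ll,
        macro_f1=base["macro_f1"], micro_f1=base["micro_f1"],
        per_class_auc=roc["per_class_auc"], macro_auc=roc["macro_auc"],
        micro_auc=roc["micro_auc"], confusion=confusion,
        classes=[str(c) for c in classes], selected_features=consensus,
        folds=folds, seed=seed,
    )
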