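"""Imbalance-aware nested cross-validated depression classification.

The protocol: stratified 10-fold outer cross-validation for unbiased
evaluation; within each outer training set, a stratified 3-fold inner grid
search selects hyperparameters by macro-averaged F1; class imbalance is
handled by SMOTE applied to training partitions only (synthetic minority
points interpolated between minority nearest neighbors); the selected model
is refit on the (oversampled) outer training set and scored on the untouched
outer test fold with accuracy, precision, recall, F1 (positive label =
depressed), ROC AUC, and Cohen kappa. Feature influence is measured by AUC
permutation importance on the outer test folds.

Two baselines bracket the classifiers: a random weighted classifier (RWC)
drawing predictions i.i.d. from the empirical class distribution, and a
decision tree restricted to the one-hot demographic columns.

Fold assignment is record-level by default (each pooled assessment is one
row, faithful to the emulated protocol); ``group_folds=True`` switches to
participant-grouped folds, which removes the repeated-measures leakage of
having one participant's rows in both partitions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .synthgen import TABLE_DEMOGRAPHIC_MARGINALS

__all__ = [
    "CvConfig",
    "DEFAULT_GRIDS",
    "one_hot_demographics",
    "stratified_folds",
    "smote",
    "cohen_kappa",
    "metric_set",
    "nested_cv",
    "rwc_baseline",
    "dt_baseline",
    "permutation_importance_auc",
]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "XGB": {
        "max_depth": [3, 6],
        "learning_rate": [0.1, 0.3],
        "n_estimators": [100, 300],
    },
    "KNN": {"n_neighbors": [3, 5, 11]},
    "LR": {"C": [0.01, 0.1, 1.0]},
    "DT": {"max_depth": [None, 3, 5]},
}

#: Distance/margin learners whose features are standardized with
#: training-fold statistics; tree learners are left unscaled.
SCALED_CLASSIFIERS = frozenset({"SVM", "KNN", "LR"})

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc", "kappa")


@dataclass
class CvConfig:
    """Nested cross-validation configuration."""

    outer_folds: int = 10
    inner_folds: int = 3
    classifiers: tuple[str, ...] = ("RF", "SVM", "XGB", "KNN", "LR")
    grids: dict[str, dict[str, list]] = field(
        default_factory=lambda: {k: {p: list(v) for p, v in g.items()} for k, g in DEFAULT_GRIDS.items()}
    )
    smote_k: int = 5
    smote_enabled: bool = True
    permutation_repeats: int = 5
    group_folds: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must both be >= 2")
        for name in self.classifiers:
            if name not in self.grids or not self.grids[name]:
                raise ValueError(f"no hyperparameter grid for classifier {name!r}")


def _make_estimator(name: str, params: dict, seed: int):
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "XGB":
        return XGBClassifier(
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}")


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def one_hot_demographics(
    samples: pd.DataFrame, profiles: pd.DataFrame, *, include: bool = True
) -> pd.DataFrame:
    """Append one-hot age-group (5) and gender (3) indicator columns.

    With ``include=False`` the table is returned unchanged (feature-only
    variant). Categories outside the study's label sets raise.
    """
    if not include:
        return samples.copy()
    demo = profiles.set_index("participant_id")[["age_group", "gender"]]
    out = samples.copy()
    for var in ("age_group", "gender"):
        cats = list(TABLE_DEMOGRAPHIC_MARGINALS[var].keys())
        values = demo.loc[out["participant_id"], var].to_numpy()
        unknown = set(values) - set(cats)
        if unknown:
            raise ValueError(f"unknown {var} categories: {sorted(unknown)}")
        for cat in cats:
            out[f"{var}__{cat}"] = (values == cat).astype(int)
    return out


def demographic_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(("age_group__", "gender__"))]


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: returns an array of fold ids in [0, k).

    Each fold's positive fraction is within one item of the global fraction.
    Raises when any class has fewer members than ``k`` (or k < 2).
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot make {k} stratified folds"
        )
    assign = np.empty(y.size, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((y.size, 1)), y)):
        assign[test_idx] = fold
    return assign


def smote(
    train_features,
    train_labels,
    *,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling by nearest-neighbor interpolation.

    For each needed synthetic point, a minority sample ``x`` and one of its
    ``k`` nearest minority neighbors ``x'`` (Euclidean) are picked, and
    ``x + u (x' - x)`` with ``u ~ U(0, 1)`` is emitted; the output has equal
    class counts. A singleton minority class falls back to duplication
    (with a warning). Must only ever see training partitions.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE expects exactly two classes in the training labels")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return x.copy(), y.copy()
    xm = x[y == minority]
    if len(xm) == 1:
        warnings.warn("singleton minority class; duplicating instead of interpolating")
        synth = np.repeat(xm, n_needed, axis=0)
    else:
        k_eff = min(k, len(xm) - 1)
        d2 = ((xm[:, None, :] - xm[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        neighbors = np.argsort(d2, axis=1)[:, :k_eff]
        base = rng.integers(0, len(xm), n_needed)
        nb = neighbors[base, rng.integers(0, k_eff, n_needed)]
        u = rng.random((n_needed, 1))
        synth = xm[base] + u * (xm[nb] - xm[base])
    return (
        np.vstack([x, synth]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``; defined as 0
    when expected agreement is 1."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.size != p.size:
        raise ValueError("label vectors must have equal length")
    n = t.size
    po = float(np.mean(t == p))
    classes = np.union1d(t, p)
    pe = float(
        sum((np.mean(t == c)) * (np.mean(p == c)) for c in classes)
    )
    if pe >= 1.0 - 1e-15:
        return 0.0
    return (po - pe) / (1.0 - pe)


def metric_set(y_true, y_pred, y_score=None) -> dict[str, float]:
    """The six-metric suite on one evaluation fold (positive label 1)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    tp = float(np.sum((p == 1) & (t == 1)))
    fp = float(np.sum((p == 1) & (t == 0)))
    fn = float(np.sum((p == 0) & (t == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    if y_score is None:
        y_score = p
    auc = (
        float(roc_auc_score(t, np.asarray(y_score, dtype=float)))
        if np.unique(t).size == 2
        else float("nan")
    )
    return {
        "accuracy": float(np.mean(t == p)),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": auc,
        "kappa": cohen_kappa(t, p),
    }


def _fold_seed(seed: int, fold: int, clf_idx: int) -> int:
    return int((seed * 1000003 + fold * 9973 + clf_idx * 101 + 17) % (2**31 - 1))


def _fit_eval(
    name: str,
    params: dict,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_te: np.ndarray,
    config: CvConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, object, object]:
    """Scale (if the learner needs it), oversample the training partition,
    fit, and return test predictions, test scores, the model and scaler."""
    scaler = None
    if name in SCALED_CLASSIFIERS:
        scaler = StandardScaler().fit(x_tr)
        x_tr = scaler.transform(x_tr)
        x_te = scaler.transform(x_te)
    if config.smote_enabled:
        x_tr, y_tr = smote(
            x_tr, y_tr, k=config.smote_k, seed=np.random.default_rng(seed)
        )
    model = _make_estimator(name, params, seed)
    model.fit(x_tr, y_tr)
    return model.predict(x_te), _scores(model, x_te), model, scaler


def _grid_combos(grid: dict[str, list]):
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def nested_cv(
    table: pd.DataFrame,
    config: CvConfig,
    *,
    feature_names: list[str],
    label_col: str = "label",
    group_col: str = "participant_id",
    collect_importance: bool = True,
) -> dict:
    """Run the full nested-CV evaluation over the configured classifiers.

    Parameters
    ----------
    table
        Pooled analysis table with the feature columns, the binary label,
        and the participant id (used only when ``config.group_folds``).
    config
        Protocol configuration (folds, grids, SMOTE, seeds).
    feature_names
        Columns used as predictors.
    collect_importance
        Also compute AUC permutation importance on each outer test fold.

    Returns
    -------
    dict with ``folds`` (per classifier × outer fold metric rows),
    ``summary`` (mean/SD per metric × 100), ``importance`` (mean AUC drop
    per feature per classifier), ``chosen_params`` and ``audit`` (per-fit
    row-index bookkeeping proving test rows never enter a fit).
    """
    config.validate()
    x_all = table[feature_names].to_numpy(dtype=float)
    y_all = table[label_col].to_numpy(dtype=int)
    groups = table[group_col].to_numpy() if group_col in table.columns else None
    if np.isnan(x_all).any():
        raise ValueError("predictor matrix contains missing values; impute first")

    if config.group_folds:
        outer = StratifiedGroupKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=config.seed
        )
        outer_splits = list(outer.split(x_all, y_all, groups=groups))
    else:
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=config.seed
        )
        outer_splits = list(outer.split(x_all, y_all))

    fold_rows, imp_rows, chosen, audit = [], [], [], []
    for fold, (train_idx, test_idx) in enumerate(outer_splits):
        assert np.intersect1d(train_idx, test_idx).size == 0, "fold leakage"
        x_tr_full, y_tr_full = x_all[train_idx], y_all[train_idx]
        x_te, y_te = x_all[test_idx], y_all[test_idx]
        for ci, name in enumerate(config.classifiers):
            seed = _fold_seed(config.seed, fold, ci)
            # inner grid search on the outer training set only
            if config.group_folds:
                inner = StratifiedGroupKFold(
                    n_splits=config.inner_folds, shuffle=True, random_state=seed
                )
                inner_splits = list(
                    inner.split(x_tr_full, y_tr_full, groups=groups[train_idx])
                )
            else:
                inner = StratifiedKFold(
                    n_splits=config.inner_folds, shuffle=True, random_state=seed
                )
                inner_splits = list(inner.split(x_tr_full, y_tr_full))
            best_params, best_score = None, -np.inf
            for params in _grid_combos(config.grids[name]):
                scores = []
                for tr_i, va_i in inner_splits:
                    pred, _, _, _ = _fit_eval(
                        name,
                        params,
                        x_tr_full[tr_i],
                        y_tr_full[tr_i],
                        x_tr_full[va_i],
                        config,
                        seed,
                    )
                    scores.append(f1_score(y_tr_full[va_i], pred, average="macro"))
                mean_score = float(np.mean(scores))
                if mean_score > best_score:
                    best_score, best_params = mean_score, params
            # refit on the outer training set, score the untouched test fold
            pred, score, model, scaler = _fit_eval(
                name, best_params, x_tr_full, y_tr_full, x_te, config, seed
            )
            metrics = metric_set(y_te, pred, score)
            fold_rows.append({"classifier": name, "fold": fold, **metrics})
            chosen.append({"classifier": name, "fold": fold, "params": best_params})
            audit.append(
                {
                    "classifier": name,
                    "fold": fold,
                    "train_rows": train_idx.copy(),
                    "test_rows": test_idx.copy(),
                    "fit_rows": train_idx.copy(),
                }
            )
            if collect_importance:
                x_te_model = scaler.transform(x_te) if scaler is not None else x_te
                imp = permutation_importance_auc(
                    model,
                    x_te_model,
                    y_te,
                    repeats=config.permutation_repeats,
                    seed=seed,
                )
                for f, v in zip(feature_names, imp):
                    imp_rows.append(
                        {"classifier": name, "fold": fold, "feature": f, "importance": v}
                    )

    folds_df = pd.DataFrame(fold_rows)
    summary = (
        folds_df.groupby("classifier")[list(METRIC_NAMES)]
        .agg(["mean", "std"])
        .mul(100.0)
    )
    importance = (
        pd.DataFrame(imp_rows)
        .groupby(["classifier", "feature"], sort=False)["importance"]
        .mean()
        .reset_index()
        if imp_rows
        else pd.DataFrame(columns=["classifier", "feature", "importance"])
    )
    return {
        "folds": folds_df,
        "summary": summary,
        "importance": importance,
        "chosen_params": chosen,
        "audit": audit,
    }


def permutation_importance_auc(
    model, x_test: np.ndarray, y_test: np.ndarray, *, repeats: int = 5, seed: int = 0
) -> np.ndarray:
    """AUC drop per feature when its test-fold column is shuffled.

    ``importance_f = AUC(original) - mean_r AUC(column f permuted)``;
    constant columns get importance 0 by construction.
    """
    rng = np.random.default_rng(seed)
    if np.unique(y_test).size < 2:
        return np.zeros(x_test.shape[1])
    base = roc_auc_score(y_test, _scores(model, x_test))
    out = np.empty(x_test.shape[1])
    for j in range(x_test.shape[1]):
        if np.all(x_test[:, j] == x_test[0, j]):
            out[j] = 0.0
            continue
        drops = []
        for _ in range(repeats):
            xp = x_test.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            drops.append(roc_auc_score(y_test, _scores(model, xp)))
        out[j] = base - float(np.mean(drops))
    return out


def rwc_baseline(labels, *, n_draws: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Random weighted classifier: predictions drawn i.i.d. from the
    empirical class distribution, metrics averaged over ``n_draws`` random
    prediction vectors (AUC from the hard 0/1 predictions, equivalent to
    the midrank convention).

    Returns a table with the mean and SD of each metric on the x100 scale.
    """
    y = np.asarray(labels, dtype=float)
    n = y.size
    pi = float(y.mean())
    if pi in (0.0, 1.0):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n1 = y.sum()
    n0 = n - n1
    tp = np.empty(n_draws)
    npos_pred = np.empty(n_draws)
    # draw in chunks to bound memory
    chunk = max(1, int(2e7 // n))
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        pred = (rng.random((hi - lo, n)) < pi).astype(np.float32)
        tp[lo:hi] = pred @ y
        npos_pred[lo:hi] = pred.sum(axis=1)
    fp = npos_pred - tp
    fn = n1 - tp
    tn = n0 - fp
    acc = (tp + tn) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(npos_pred > 0, tp / np.maximum(npos_pred, 1), 0.0)
        recall = tp / n1
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / np.maximum(precision + recall, 1e-300),
            0.0,
        )
    tpr = tp / n1
    fpr = fp / n0
    auc = 0.5 * (1.0 + tpr - fpr)
    pe = (npos_pred / n) * (n1 / n) + (1 - npos_pred / n) * (n0 / n)
    kappa = np.where(pe < 1.0, (acc - pe) / (1.0 - pe), 0.0)
    rows = {
        "accuracy": acc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": auc,
        "kappa": kappa,
    }
    return pd.DataFrame(
        {
            "metric": list(rows),
            "mean": [100.0 * float(v.mean()) for v in rows.values()],
            "sd": [100.0 * float(v.std(ddof=1)) for v in rows.values()],
        }
    )


def dt_baseline(table: pd.DataFrame, config: CvConfig, *, label_col: str = "label") -> dict:
    """Decision-tree baseline under the identical nested-CV protocol but
    restricted to the one-hot demographic columns."""
    demo_cols = demographic_columns(table)
    if not demo_cols:
        raise ValueError("no one-hot demographic columns present")
    from dataclasses import replace

    dt_config = replace(config, classifiers=("DT",))
    return nested_cv(
        table,
        dt_config,
        feature_names=demo_cols,
        label_col=label_col,
        collect_importance=False,
    )
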