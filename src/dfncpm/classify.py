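"""Subject classification from sequential-pattern features.

Each subject is encoded as a binary vector of pattern containment (one-hot
encoding of the mined patterns against the subject's dominant-state
sequence) or as real-valued percent dwell times.  Two models — random
forest and linear discriminant analysis — are tuned by grid search on a
stratified training split and evaluated with repeated stratified k-fold
cross-validation (default 100 iterations of 10-fold CV, 80/20 train/test
split), reporting accuracy, AUC, recall, precision and F1.  Feature
importances identify the most discriminative patterns: mean impurity
decrease for the forest, absolute standardized discriminant coefficients
for LDA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from ._errors import ValidationError
from .patterns import compress_runs, contains_pattern, pattern_name

__all__ = [
    "FeatureMatrix",
    "ClassificationProtocol",
    "ClassificationReport",
    "one_hot_encode",
    "dwell_feature_matrix",
    "evaluate_classifiers",
    "rank_feature_importance",
]

METRICS = ("accuracy", "auc", "recall", "precision", "f1")

RF_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 4, 8],
    "min_samples_leaf": [1, 3],
}
LDA_GRID = {"shrinkage": [None, "auto"]}


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features with group labels.

    ``values`` is binary for pattern presence or real for dwell features;
    row order follows ``subject_ids``.
    """

    values: np.ndarray
    feature_names: tuple
    subject_ids: tuple
    labels: tuple  # group label per subject

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.subject_ids),
                          columns=list(self.feature_names))
        df.insert(0, "group", list(self.labels))
        return df


@dataclass(frozen=True)
class ClassificationProtocol:
    """Evaluation protocol: 80/20 stratified split, grid-search tuning on
    the training split, then 100 iterations of 10-fold stratified CV.

    ``rf_grid``/``lda_grid`` override the default tuning grids (mostly
    useful to shrink them in quick exploratory runs)."""

    train_fraction: float = 0.8
    cv_repeats: int = 100
    cv_folds: int = 10
    tuning_folds: int = 5
    seed: int = 0
    rf_grid: dict | None = None
    lda_grid: dict | None = None

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.cv_repeats < 1 or self.cv_folds < 2:
            raise ValidationError("need cv_repeats >= 1 and cv_folds >= 2")


@dataclass(frozen=True)
class ClassificationReport:
    """Cross-validated metric distributions and ranked pattern importances."""

    cv_metrics: dict  # model -> metric -> (mean, sd)
    holdout_metrics: dict  # model -> metric -> value
    tuned_params: dict  # model -> best grid-search params
    importances: dict  # model -> ((feature, score), ...) top-10
    models: dict = field(repr=False, default_factory=dict)  # fitted on all data
    classes: tuple = ()
    protocol: ClassificationProtocol = ClassificationProtocol()

    def to_jsonable(self) -> dict:
        return {
            "classes": list(self.classes),
            "cv_metrics": {
                m: {k: {"mean": v[0], "sd": v[1]} for k, v in d.items()}
                for m, d in self.cv_metrics.items()
            },
            "holdout_metrics": self.holdout_metrics,
            "tuned_params": {
                m: {k: (v if not isinstance(v, np.generic) else v.item())
                    for k, v in p.items()}
                for m, p in self.tuned_params.items()
            },
            "importances": {
                m: [{"feature": f, "importance": s} for f, s in ranks]
                for m, ranks in self.importances.items()
            },
        }


def one_hot_encode(state_sequences, pattern_set, compress: bool | None = None,
                   n_states: int | None = None, groups: dict | None = None) -> FeatureMatrix:
    """Binary pattern-presence encoding.

    Entry (i, j) is 1 iff pattern j is a subsequence of subject i's
    (optionally run-compressed) dominant-state sequence.  The compression
    convention defaults to the one recorded in the pattern set's MiningSpec
    and must match the convention used at mining time.  When ``n_states``
    is given, sequence and pattern labels must lie in 1..n_states.
    """
    patterns = list(getattr(pattern_set, "patterns", pattern_set))
    if compress is None:
        spec = getattr(pattern_set, "spec", None)
        compress = spec.compress if spec is not None else True
    pattern_alphabet = {int(s) for p in patterns for s in p}
    if n_states is not None and pattern_alphabet and (
        min(pattern_alphabet) < 1 or max(pattern_alphabet) > n_states
    ):
        raise ValidationError("pattern alphabet does not match the state alphabet")
    sids, labels, rows = [], [], []
    for seq in state_sequences:
        lab = getattr(seq, "labels", seq)
        lab = np.asarray(lab)
        if n_states is not None and lab.size and (
            lab.min() < 1 or lab.max() > n_states
        ):
            raise ValidationError("sequence labels outside the state alphabet")
        if compress:
            lab = compress_runs(lab)
        rows.append([1 if contains_pattern(lab, p) else 0 for p in patterns])
        sid = getattr(seq, "subject_id", f"s{len(sids)}")
        sids.append(sid)
        labels.append(groups[sid] if groups is not None else getattr(seq, "group", ""))
    values = np.asarray(rows, dtype=np.int8).reshape(len(rows), len(patterns))
    names = tuple(pattern_name(p) for p in patterns)
    return FeatureMatrix(values, names, tuple(sids), tuple(labels))


def dwell_feature_matrix(dwell_stats_by_subject, labels_by_subject, k: int) -> FeatureMatrix:
    """Percent-dwell-time features: one column per state (fraction of
    windows spent in that state)."""
    sids = list(dwell_stats_by_subject)
    values = np.array([dwell_stats_by_subject[s].fraction_time for s in sids])
    names = tuple(f"pct_dwell_state_{s}" for s in range(1, k + 1))
    labels = tuple(labels_by_subject[s] for s in sids)
    return FeatureMatrix(values, names, tuple(sids), labels)


def _make_models(seed: int) -> dict:
    return {
        "rf": RandomForestClassifier(random_state=seed),
        "lda": LinearDiscriminantAnalysis(solver="lsqr"),
    }


def _grids(protocol: "ClassificationProtocol") -> dict:
    return {
        "rf": protocol.rf_grid or RF_GRID,
        "lda": protocol.lda_grid or LDA_GRID,
    }


def _scores(model, X, y, positive_index):
    pred = model.predict(X)
    proba = model.predict_proba(X)[:, positive_index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc = roc_auc_score(y, proba) if len(np.unique(y)) == 2 else np.nan
    return {
        "accuracy": accuracy_score(y, pred),
        "auc": auc,
        "recall": recall_score(y, pred, zero_division=0),
        "precision": precision_score(y, pred, zero_division=0),
        "f1": f1_score(y, pred, zero_division=0),
    }


def evaluate_classifiers(
    features: FeatureMatrix,
    protocol: ClassificationProtocol = ClassificationProtocol(),
) -> ClassificationReport:
    """Tune and evaluate RF and LDA on a binary classification task.

    Procedure: (1) seeded stratified train/test split at the protocol's
    train fraction; (2) grid-search tuning with inner stratified CV on the
    training split; (3) held-out metrics on the test split; (4) repeated
    stratified k-fold CV on the full cohort with the tuned
    hyperparameters — one metric value per repetition from the pooled
    out-of-fold predictions, summarized as mean and sd across repetitions.
    """
    protocol.validate()
    X = np.asarray(features.values, dtype=float)
    y_raw = np.asarray(features.labels)
    classes = tuple(sorted(set(y_raw.tolist())))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if len(classes) > 2:
        raise ValidationError("binary tasks only")
    if X.shape[1] == 0:
        raise ValidationError("no features to train on")
    y = (y_raw == classes[1]).astype(int)  # class 1 = second label, positive
    counts = np.bincount(y)
    folds = protocol.cv_folds
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} subjects; reducing CV folds "
            f"to {folds}"
        )
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=protocol.train_fraction, stratify=y,
        random_state=protocol.seed,
    )
    tuning_folds = max(2, min(protocol.tuning_folds, int(np.bincount(y_train).min())))
    cv_metrics: dict = {}
    holdout: dict = {}
    tuned_params: dict = {}
    fitted: dict = {}
    for name, base in _make_models(protocol.seed).items():
        search = GridSearchCV(
            base,
            _grids(protocol)[name],
            cv=StratifiedKFold(tuning_folds, shuffle=True,
                               random_state=protocol.seed),
            scoring="accuracy",
            n_jobs=None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X_train, y_train)
        tuned = search.best_estimator_
        tuned_params[name] = dict(search.best_params_)
        holdout[name] = _scores(tuned, X_test, y_test, positive_index=1)
        per_rep = {m: [] for m in METRICS}
        for rep in range(protocol.cv_repeats):
            skf = StratifiedKFold(folds, shuffle=True,
                                  random_state=protocol.seed + 1 + rep)
            pred = np.empty_like(y)
            proba = np.empty(len(y), dtype=float)
            for tr, te in skf.split(X, y):
                est = clone(tuned)
                if name == "rf":
                    est.set_params(random_state=protocol.seed + 1 + rep)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                pred[te] = est.predict(X[te])
                proba[te] = est.predict_proba(X[te])[:, 1]
            per_rep["accuracy"].append(accuracy_score(y, pred))
            per_rep["auc"].append(roc_auc_score(y, proba))
            per_rep["recall"].append(recall_score(y, pred, zero_division=0))
            per_rep["precision"].append(precision_score(y, pred, zero_division=0))
            per_rep["f1"].append(f1_score(y, pred, zero_division=0))
        cv_metrics[name] = {
            m: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for m, v in per_rep.items()
        }
        final = clone(tuned)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(X, y)
        fitted[name] = final
    importances = rank_feature_importance(fitted, features.feature_names, X)
    return ClassificationReport(
        cv_metrics=cv_metrics,
        holdout_metrics=holdout,
        tuned_params=tuned_params,
        importances=importances,
        models=fitted,
        classes=classes,
        protocol=protocol,
    )


def rank_feature_importance(models: dict, feature_names, X=None, top: int = 10) -> dict:
    """Rank features by importance for each fitted model.

    Random forest: mean impurity-decrease importance across trees.  LDA:
    absolute standardized discriminant coefficients (|coef| times the
    feature's standard deviation, which requires ``X``).  Scores are
    normalized to sum 1; the top ``top`` features are returned per model.
    """
    feature_names = list(feature_names)
    out: dict = {}
    for name, model in models.items():
        if isinstance(model, RandomForestClassifier):
            if not hasattr(model, "estimators_"):
                raise ValidationError("random forest is not fitted")
            raw = np.asarray(model.feature_importances_, dtype=float)
        elif isinstance(model, LinearDiscriminantAnalysis):
            if not hasattr(model, "coef_"):
                raise ValidationError("LDA model is not fitted")
            coef = np.abs(np.ravel(model.coef_))
            if X is not None:
                coef = coef * np.asarray(X, dtype=float).std(axis=0)
            raw = coef
        else:
            raise ValidationError(f"unsupported model type for {name!r}")
        total = raw.sum()
        norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
        order = np.argsort(-norm, kind="stable")[:top]
        out[name] = tuple((feature_names[i], float(norm[i])) for i in order)
    return out
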