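"""Single-sample machine-learning classifiers and their multi-label
adaptation (ML2CRIS).

Single-label models (SVMs with linear/polynomial/RBF kernels, random forest,
gradient boosting, one-hidden-layer neural net) are trained on the NTP
primary labels of a reference cohort, using CPM values of the signature
genes as features — no cohort Z-scoring, so a fitted model classifies any
single sample in isolation. The multi-label adaptation keeps the
single-label argmax as the primary class and adds as secondary every other
class whose continuous model score clears a class-specific threshold tau_k,
calibrated as the 5th percentile of that class's scores over training
samples carrying it as primary (the mirror of the nearest-template
secondary-threshold rule, applied to model scores).
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

from .types import (
    ExpressionMatrix,
    MultiLabelAssignment,
    NOT_CLASSIFIED,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = (
    "linear_svm",
    "poly_svm",
    "rbf_svm",
    "random_forest",
    "gradient_boosting",
    "neural_net_1hidden",
)

# Small fixed grids; regularization over log-spaced values.
DEFAULT_GRIDS: Dict[str, dict] = {
    "linear_svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "poly_svm": {"estimator__C": [0.1, 1.0, 10.0], "estimator__degree": [2, 3]},
    "rbf_svm": {"estimator__C": [0.1, 1.0, 10.0], "estimator__gamma": ["scale", 0.01]},
    "random_forest": {"max_features": ["sqrt", 0.5]},
    "gradient_boosting": {"n_estimators": [100, 200]},
    "neural_net_1hidden": {"hidden_layer_sizes": [(16,), (64,)]},
}


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter grid and seed."""

    kind: str
    grid: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        if self.grid is None:
            self.grid = dict(DEFAULT_GRIDS[self.kind])


def _build_estimator(spec: ModelSpec):
    seed = spec.seed
    if spec.kind == "linear_svm":
        return LinearSVC(random_state=seed, max_iter=100000)
    if spec.kind == "poly_svm":
        return OneVsRestClassifier(SVC(kernel="poly", random_state=seed))
    if spec.kind == "rbf_svm":
        return OneVsRestClassifier(SVC(kernel="rbf", random_state=seed))
    if spec.kind == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed)
    if spec.kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if spec.kind == "neural_net_1hidden":
        return MLPClassifier(max_iter=3000, random_state=seed)
    raise AssertionError(spec.kind)


@dataclass
class SplitPlan:
    """Deterministic stratified train/test split (train fraction default 0.7)."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int


def stratified_split(labels: Sequence[str], fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Split sample indices preserving per-class proportions within rounding."""
    labels = pd.Series(list(labels))
    counts = labels.value_counts()
    singles = counts[counts < 2].index.tolist()
    if singles:
        raise ValidationError(f"classes with a single member cannot be stratified: {singles}")
    idx = np.arange(len(labels))
    if fraction >= 1.0:
        return SplitPlan(idx, np.array([], dtype=int), fraction, seed)
    train, test = train_test_split(
        idx, train_size=fraction, stratify=labels, random_state=seed, shuffle=True
    )
    return SplitPlan(np.sort(train), np.sort(test), fraction, seed)


@dataclass
class TrainedClassifier:
    """A fitted single-sample classifier with everything prediction needs:
    feature gene list, class order, and (after calibration) the per-class
    secondary thresholds tau."""

    spec: ModelSpec
    estimator: object
    feature_genes: List[str]
    class_names: List[str]
    log1p: bool = True
    tau: Optional[Dict[str, float]] = None
    best_params: Optional[dict] = None
    best_cv_score: Optional[float] = None
    nc_min_score: Optional[float] = None

    def _design(self, matrix: ExpressionMatrix) -> np.ndarray:
        missing = [g for g in self.feature_genes if g not in matrix.data.index]
        if missing:
            raise ValidationError(f"matrix is missing model feature genes: {missing[:10]}")
        X = matrix.data.loc[self.feature_genes].to_numpy(dtype=float).T
        if self.log1p:
            X = np.log1p(X)
        return X

    def score_frame(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Per-class continuous scores (decision values or probabilities),
        samples x classes in signature class order. Classes unseen in
        training get -inf."""
        X = self._design(matrix)
        est = self.estimator
        if hasattr(est, "decision_function"):
            raw = np.asarray(est.decision_function(X))
            if raw.ndim == 1:  # binary: single margin for classes_[1]
                raw = np.column_stack([-raw, raw])
        else:
            raw = np.asarray(est.predict_proba(X))
        frame = pd.DataFrame(-np.inf, index=matrix.sample_ids, columns=self.class_names, dtype=float)
        for i, cls in enumerate(est.classes_):
            if cls not in frame.columns:
                raise ValidationError(f"model was trained on unknown class {cls!r}")
            frame[cls] = raw[:, i]
        return frame


def train_single_label(
    matrix: ExpressionMatrix,
    primary_labels: Mapping[str, str],
    spec: ModelSpec,
    plan: Optional[SplitPlan] = None,
    cv_folds: int = 10,
    log1p: bool = True,
    class_names: Optional[Sequence[str]] = None,
) -> TrainedClassifier:
    """Fit a single-label model on confident primary labels.

    Hyperparameters are selected by stratified cross-validation (default
    10-fold) on the training fraction, then the winning configuration is
    refit once on the entire training set. Features are the CPM values of
    the matrix's (signature) genes; ``primary_labels`` maps sample id to its
    reference primary class and must not contain NC.
    """
    if matrix.unit not in ("cpm", "raw_counts"):
        raise ValidationError("train on CPM (or raw count) features, not Z-scores")
    labels = pd.Series({s: primary_labels[s] for s in matrix.sample_ids if s in primary_labels})
    if (labels == NOT_CLASSIFIED).any():
        raise ValidationError("training labels must be confident calls (no NC)")
    sub = matrix.select_samples(list(labels.index))
    if labels.nunique() < 2:
        raise ValidationError("training labels are degenerate (single class)")
    if plan is not None:
        train_samples = [sub.sample_ids[i] for i in plan.train_indices]
    else:
        train_samples = sub.sample_ids
    y = labels.loc[train_samples].to_numpy()
    X = sub.select_samples(train_samples).data.to_numpy(dtype=float).T
    if log1p:
        X = np.log1p(X)
    min_class = pd.Series(y).value_counts().min()
    folds = min(cv_folds, int(min_class))
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class size)", cv_folds, folds)
    estimator = _build_estimator(spec)
    if folds >= 2:
        search = GridSearchCV(
            estimator,
            spec.grid,
            cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed),
            n_jobs=None,
        )
        search.fit(X, y)
        fitted = search.best_estimator_
        best = search.best_params_
        cv_score = float(search.best_score_)
    else:
        fitted = estimator.fit(X, y)
        best = {}
        cv_score = None
    return TrainedClassifier(
        spec=spec,
        estimator=fitted,
        feature_genes=list(sub.gene_ids),
        class_names=list(class_names) if class_names is not None else sorted(set(labels)),
        log1p=log1p,
        best_params=best,
        best_cv_score=cv_score,
    )


def predict_primary(model: TrainedClassifier, matrix: ExpressionMatrix) -> pd.Series:
    """Argmax of per-class scores, sample by sample; ties break to the first
    class in class order. No reference cohort is consulted."""
    scores = model.score_frame(matrix)
    values = scores.to_numpy()
    best = np.argmax(values, axis=1)
    return pd.Series(
        [model.class_names[i] for i in best], index=scores.index, name="primary"
    )


def calibrate_mla_thresholds(
    model: TrainedClassifier,
    matrix: ExpressionMatrix,
    multilabels: Sequence[MultiLabelAssignment],
    percentile: float = 5.0,
) -> Dict[str, float]:
    """tau_k = the given percentile of score_k over training samples whose
    (reference) primary class is k. Classes with no primary training samples
    get +inf (no secondary calls). The thresholds are stored on the model so
    prediction needs no cohort context."""
    scores = model.score_frame(matrix)
    primary = {a.sample_id: a.primary for a in multilabels}
    tau: Dict[str, float] = {}
    for k in model.class_names:
        members = [s for s in scores.index if primary.get(s) == k]
        if not members:
            logger.warning("class %s has no primary training samples; tau set to +inf", k)
            tau[k] = math.inf
        else:
            tau[k] = float(np.percentile(scores.loc[members, k].to_numpy(), percentile))
    model.tau = tau
    return tau


def predict_multilabel(
    model: TrainedClassifier,
    matrix: ExpressionMatrix,
    tau: Optional[Dict[str, float]] = None,
) -> List[MultiLabelAssignment]:
    """Multi-label single-sample prediction: the primary is inherited from
    the single-label argmax; every other class whose score clears tau_k is
    added as secondary. By default a primary is always produced (unlike
    NTP's NC outcome); an optional minimum top score (``model.nc_min_score``)
    can re-enable NC."""
    thresholds = tau if tau is not None else model.tau
    if thresholds is None:
        raise ValidationError("model has no calibrated thresholds; run calibrate_mla_thresholds")
    scores = model.score_frame(matrix)
    primary = predict_primary(model, matrix)
    out = []
    for sid in scores.index:
        row = scores.loc[sid]
        top = primary.loc[sid]
        if model.nc_min_score is not None and row[top] < model.nc_min_score:
            out.append(
                MultiLabelAssignment(sample_id=sid, primary=NOT_CLASSIFIED, scores=row.to_dict())
            )
            continue
        secondary = frozenset(
            k for k in model.class_names if k != top and row[k] >= thresholds.get(k, math.inf)
        )
        out.append(
            MultiLabelAssignment(
                sample_id=sid, primary=top, secondary=secondary, scores=row.to_dict()
            )
        )
    return out


def rank_features(model: TrainedClassifier) -> Dict[str, pd.DataFrame]:
    """Per-class feature importance for linear models: genes ordered by
    descending coefficient magnitude, signed direction reported."""
    est = model.estimator
    coef = getattr(est, "coef_", None)
    if coef is None:
        raise ValidationError("feature ranking is defined only for linear-kernel models")
    coef = np.asarray(coef)
    classes = list(est.classes_)
    if coef.shape[0] == 1 and len(classes) == 2:
        coef = np.vstack([-coef[0], coef[0]])
    out: Dict[str, pd.DataFrame] = {}
    for i, cls in enumerate(classes):
        w = coef[i]
        if not np.any(w):
            logger.warning("class %s: all-zero coefficients; empty ranking", cls)
            out[cls] = pd.DataFrame(columns=["gene", "coefficient"])
            continue
        order = np.argsort(-np.abs(w), kind="stable")
        out[cls] = pd.DataFrame(
            {"gene": [model.feature_genes[j] for j in order], "coefficient": w[order]}
        )
    return out


# ---------------------------------------------------------------------------
# persistence: JSON metadata + joblib weights sidecar


def save_model(model: TrainedClassifier, folder: str) -> None:
    os.makedirs(folder, exist_ok=True)
    meta = {
        "format_version": 1,
        "kind": model.spec.kind,
        "seed": model.spec.seed,
        "grid": {k: [str(v) for v in vs] for k, vs in (model.spec.grid or {}).items()},
        "feature_genes": model.feature_genes,
        "class_names": model.class_names,
        "log1p": model.log1p,
        "tau": model.tau,
        "best_params": {k: str(v) for k, v in (model.best_params or {}).items()},
        "nc_min_score": model.nc_min_score,
    }
    with open(os.path.join(folder, "model.json"), "wt", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    joblib.dump(model.estimator, os.path.join(folder, "weights.joblib"))


def load_model(folder: str) -> TrainedClassifier:
    with open(os.path.join(folder, "model.json"), "rt", encoding="utf-8") as fh:
        meta = json.load(fh)
    estimator = joblib.load(os.path.join(folder, "weights.joblib"))
    return TrainedClassifier(
        spec=ModelSpec(kind=meta["kind"], seed=meta["seed"]),
        estimator=estimator,
        feature_genes=meta["feature_genes"],
        class_names=meta["class_names"],
        log1p=meta["log1p"],
        tau=meta["tau"],
        nc_min_score=meta.get("nc_min_score"),
    )
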