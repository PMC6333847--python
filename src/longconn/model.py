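"""Progression classifier: stratified k-fold CV and model averaging.

Controls (label 0) and Parkinson's disease subjects (label 1) are split
into k stratified folds (default k = size of the PD class, the maximum
admissible, so test folds hold 2-3 subjects at the studied sample sizes).
Each subject's progression score is the predicted probability from the one
fold model that did not see it; an independent cohort — never part of any
training fold — is scored by averaging the predicted probabilities of all
k fold models.

Five linear/ensemble families are supported with fixed, untuned
hyperparameters.  The headline family is L1-regularized logistic
regression fit by coordinate descent (liblinear), whose sparse weight
vector is what the permutation-relevance analysis interrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

LINEAR_FAMILIES = ("logreg_l1", "logreg_l2", "elastic_net", "linear_svm")
FAMILIES = LINEAR_FAMILIES + ("random_forest",)


@dataclass(frozen=True)
class ModelSpec:
    """A model family with immutable default hyperparameters.

    ``scaling="trainfold_zscore"`` (the default) z-scores features with
    statistics estimated on the training fold only, so count-scale
    features do not dominate the regularization penalty over FA/MD-scale
    ones; ``scaling="none"`` reproduces a raw-feature run.
    """

    family: str = "logreg_l1"
    scaling: str = "trainfold_zscore"
    C: float = 1.0  # inverse regularization strength, never tuned
    l1_ratio: float = 0.5  # elastic net only
    n_estimators: int = 100  # random forest only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {FAMILIES}")
        if self.scaling not in ("none", "trainfold_zscore"):
            raise ValueError("scaling must be 'none' or 'trainfold_zscore'")

    def _estimator(self, seed: int):
        if self.family == "logreg_l1":
            # liblinear = coordinate descent; l1_ratio=1 is the pure L1 penalty
            return LogisticRegression(
                C=self.C, l1_ratio=1.0, solver="liblinear", max_iter=1000,
                random_state=seed,
            )
        if self.family == "logreg_l2":
            return LogisticRegression(
                C=self.C, l1_ratio=0.0, solver="liblinear", max_iter=1000,
                random_state=seed,
            )
        if self.family == "elastic_net":
            return LogisticRegression(
                C=self.C, l1_ratio=self.l1_ratio,
                solver="saga", max_iter=5000, random_state=seed,
            )
        if self.family == "linear_svm":
            return LinearSVC(C=self.C, random_state=seed)
        return RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed
        )


@dataclass
class TrainedModel:
    """One fitted fold model with its train-fold scaling statistics.

    ``weights`` are the linear coefficients (per-feature importances for
    the random forest, which has no signed weights).
    """

    family: str
    weights: np.ndarray
    intercept: float
    scale_mean: np.ndarray | None
    scale_sd: np.ndarray | None
    estimator: object = field(repr=False, default=None)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scale_mean is None:
            return X
        return (X - self.scale_mean) / self.scale_sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(PD-like progression) in [0, 1] for each row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"expected {self.weights.shape[0]} features, got shape {X.shape}"
            )
        Z = self._transform(X)
        if self.family == "linear_svm":
            # LinearSVC exposes no probabilities; squash the margin
            return expit(self.estimator.decision_function(Z))
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(Z)[:, pos]


@dataclass
class ModelEnsemble:
    """All k fold models plus the fold assignment of the training cohort."""

    fold_models: list[TrainedModel]
    fold_assignment: np.ndarray  # test-fold index per training subject
    subject_ids: list[str]
    spec: ModelSpec
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_models)


@dataclass
class ScoreTable:
    """Per-subject progression scores with provenance."""

    scores: pd.Series  # indexed by subject_id, values in [0, 1]
    provenance: str  # "out_of_fold" or "model_averaged"

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("progression scores must lie in [0, 1]")


def stratified_folds(
    labels: Sequence[int] | np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Partition subjects into k class-balanced folds.

    Each class is shuffled and dealt ``n_c // k`` members per fold, with
    the remainder going to the currently smallest folds, so per-fold class
    counts differ from perfect proportionality by at most one subject and
    no fold is empty (``k = n`` yields leave-one-out).  Unlike
    scikit-learn's StratifiedKFold this accepts k larger than the minority
    class.  Deterministic given seed.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects n={n}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to stratify")

    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        base, extra = divmod(len(idx), k)
        counts = np.full(k, base, dtype=int)
        if extra:
            # remainder goes to the smallest folds, random tie-break
            order = np.lexsort((rng.random(k), fold_sizes))
            counts[order[:extra]] += 1
        pos = 0
        for f in range(k):
            assignment[idx[pos : pos + counts[f]]] = f
            pos += counts[f]
        fold_sizes += counts
    return assignment


def train_fold(
    features: np.ndarray, labels: Sequence[int], spec: ModelSpec, seed: int = 0
) -> TrainedModel:
    """Fit one model on one training fold (scaling fitted on that fold only)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class")

    mean = sd = None
    if spec.scaling == "trainfold_zscore":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd < 1e-12, 1.0, sd)  # constant features carry no signal
        X = (X - mean) / sd

    est = spec._estimator(seed)
    est.fit(X, y)

    if spec.family == "random_forest":
        weights = est.feature_importances_.copy()
        intercept = 0.0
    else:
        weights = est.coef_.ravel().copy()
        intercept = float(np.ravel(est.intercept_)[0])
    return TrainedModel(
        family=spec.family,
        weights=weights,
        intercept=intercept,
        scale_mean=mean,
        scale_sd=sd,
        estimator=est,
    )


def cross_validated_scores(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int] | pd.Series,
    spec: ModelSpec = ModelSpec(),
    k: int | None = None,
    seed: int = 0,
) -> tuple[ScoreTable, ModelEnsemble]:
    """Out-of-fold progression scores for the training cohort.

    Every subject is scored exactly once, by the model whose test fold
    contains it.  ``k`` defaults to the positive-class size (the maximum
    number of stratified folds that keeps at least one positive per fold).
    Returns the score table and the ensemble of all k fold models.
    """
    if isinstance(features, pd.DataFrame):
        subject_ids = [str(s) for s in features.index]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        subject_ids = [str(i) for i in range(X.shape[0])]
    y = np.asarray(labels)
    if k is None:
        k = int((y == 1).sum())

    assignment = stratified_folds(y, k, seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                  np.random.SeedSequence(seed).spawn(k)]

    scores = np.empty(len(y), dtype=float)
    models: list[TrainedModel] = []
    for f in range(k):
        test = assignment == f
        model = train_fold(X[~test], y[~test], spec, seed=fold_seeds[f])
        models.append(model)
        if test.any():
            scores[test] = model.predict_proba(X[test])

    table = ScoreTable(
        scores=pd.Series(scores, index=pd.Index(subject_ids, name="subject_id")),
        provenance="out_of_fold",
    )
    ensemble = ModelEnsemble(
        fold_models=models,
        fold_assignment=assignment,
        subject_ids=subject_ids,
        spec=spec,
        seed=seed,
    )
    return table, ensemble


def ensemble_predict(
    ensemble: ModelEnsemble, features: pd.DataFrame | np.ndarray
) -> ScoreTable:
    """Model-averaged scores for an independent cohort.

    The score of each subject is the unweighted arithmetic mean of the
    predicted probabilities of all k fold models; the cohort must be
    disjoint from the training subjects (checked when ids are available).
    """
    if isinstance(features, pd.DataFrame):
        subject_ids = [str(s) for s in features.index]
        overlap = set(subject_ids) & set(ensemble.subject_ids)
        if overlap:
            raise ValueError(
                f"independent cohort overlaps training subjects: {sorted(overlap)}"
            )
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        subject_ids = [str(i) for i in range(X.shape[0])]
    per_model = np.vstack([m.predict_proba(X) for m in ensemble.fold_models])
    return ScoreTable(
        scores=pd.Series(
            per_model.mean(axis=0), index=pd.Index(subject_ids, name="subject_id")
        ),
        provenance="model_averaged",
    )
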