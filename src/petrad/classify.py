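"""Stratified k-fold multinomial classification, pairwise/multiclass AUC
(average of all pairwise two-class AUCs) and the label-shuffling sham null.

Per fold, every preprocessing artefact (scaler, redundancy filter, factor
model) is fitted on the training lesions only; test lesions are projected
with training parameters. Fold metrics are averaged, never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from petrad.dimred import DimredConfig, FactorModel, Scaler, apply_scaler, fit_dimred, fit_scaler, transform
from petrad.models import BIOCHEM_COLS, ModelSpec, imaging_columns, pet_columns

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "AucResult",
    "FoldResult",
    "CvResult",
    "ShamResult",
    "make_folds",
    "fit_multinomial",
    "auc_rank",
    "pairwise_auc",
    "multiclass_auc",
    "run_cv",
    "sham_experiment",
]

CLASSES = ("cluster1", "cluster2", "sporadic")
_RIDGE_LAMBDA = 1e-4  # tiny slope penalty; training folds can be separable


# ------------------------------------------------------------------ folds

def make_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment with fold sizes and per-class counts
    each differing by at most one across folds."""
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([0xF01D, int(seed)]))
    classes = sorted(set(labels.tolist()), key=lambda c: (-int(np.sum(labels == c)), str(c)))
    assign = np.full(n, -1, dtype=int)
    loads = np.zeros(k, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        order = np.argsort(loads, kind="stable")  # fill least-loaded folds first
        for t, i in enumerate(idx):
            f = int(order[t % k])
            assign[i] = f
            loads[f] += 1
    return assign


# ------------------------------------------------------------------ model

class _FrequencyModel:
    """Intercept-only multinomial model: predicts class frequencies."""

    def __init__(self, y: np.ndarray):
        self.classes_, counts = np.unique(y, return_counts=True)
        self._proba = counts / counts.sum()

    def predict_proba(self, X) -> np.ndarray:
        return np.tile(self._proba, (len(X), 1))


def fit_multinomial(X: np.ndarray, y: np.ndarray, ridge_lambda: float = _RIDGE_LAMBDA):
    """Softmax-linear model with a small ridge penalty on the slopes.

    With no predictor columns, returns the intercept-only frequency model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes in the training fold")
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] == 0:
        return _FrequencyModel(y)
    model = LogisticRegression(
        C=1.0 / ridge_lambda,
        solver="lbfgs",
        max_iter=10000,
        tol=1e-8,
    )
    model.fit(X, y)
    if int(np.max(model.n_iter_)) >= 10000:
        raise RuntimeError("multinomial fit did not converge within 10000 iterations")
    return model


# -------------------------------------------------------------------- AUC

def auc_rank(scores, is_positive) -> float:
    """Two-class AUC by the rank-sum formula with mid-ranks for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    s = float(ranks[pos].sum())
    return (s - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def pairwise_auc(proba: np.ndarray, y, class_i: str, class_j: str, classes=CLASSES) -> float:
    """A-hat(i, j) = [A(i|j) + A(j|i)] / 2 on the class-i and class-j scores."""
    y = np.asarray(y)
    classes = list(classes)
    sel = (y == class_i) | (y == class_j)
    if not (np.any(y[sel] == class_i) and np.any(y[sel] == class_j)):
        return float("nan")
    a_ij = auc_rank(proba[sel, classes.index(class_i)], y[sel] == class_i)
    a_ji = auc_rank(proba[sel, classes.index(class_j)], y[sel] == class_j)
    return 0.5 * (a_ij + a_ji)


def multiclass_auc(pairwise: dict[tuple[str, str], float]) -> float:
    """M = mean of the pairwise A-hat values (2/(c(c-1)) * sum over i<j)."""
    vals = list(pairwise.values())
    if any(np.isnan(v) for v in vals):
        return float("nan")
    return float(np.mean(vals))


@dataclass
class AucResult:
    pairwise: dict[tuple[str, str], float]
    multiclass: float

    @classmethod
    def from_proba(cls, proba: np.ndarray, y, classes=CLASSES) -> "AucResult":
        present = [c for c in classes if np.any(np.asarray(y) == c)]
        pw = {
            (ci, cj): pairwise_auc(proba, y, ci, cj, classes)
            for ci, cj in combinations(classes, 2)
        }
        if len(present) < len(classes):
            logger.warning("classes absent from split: %s", set(classes) - set(present))
        return cls(pw, multiclass_auc(pw))


# ----------------------------------------------------------- CV pipeline

@dataclass
class FoldResult:
    fold: int
    train: AucResult
    test: AucResult
    artifacts: dict = field(default_factory=dict)


@dataclass
class CvResult:
    folds: list[FoldResult]
    spec: ModelSpec

    def _mean(self, split: str) -> AucResult:
        pw_keys = self.folds[0].__getattribute__(split).pairwise.keys()
        pw = {
            k: float(np.nanmean([f.__getattribute__(split).pairwise[k] for f in self.folds]))
            for k in pw_keys
        }
        m = float(np.nanmean([f.__getattribute__(split).multiclass for f in self.folds]))
        return AucResult(pw, m)

    @property
    def mean_train(self) -> AucResult:
        return self._mean("train")

    @property
    def mean_test(self) -> AucResult:
        return self._mean("test")


def _build_predictors(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    dimred_config: DimredConfig,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fit fold-local preprocessing on `train` only; return (Xtr, Xte, artifacts)."""
    artifacts: dict = {}

    def _scaled_block(cols: list[str]) -> tuple[np.ndarray, np.ndarray, Scaler]:
        scaler = fit_scaler(train[cols])
        return (
            apply_scaler(scaler, train).to_numpy(),
            apply_scaler(scaler, test).to_numpy(),
            scaler,
        )

    if spec.base == "biochem":
        Xtr = train[BIOCHEM_COLS].to_numpy(dtype=np.float64)
        Xte = test[BIOCHEM_COLS].to_numpy(dtype=np.float64)
    elif spec.base == "suvmax":
        Xtr, Xte, scaler = _scaled_block(["PET_firstorder_Maximum"])
        artifacts["scaler"] = scaler
    elif spec.base in ("pet3factor", "petct3factor"):
        cols = pet_columns(train) if spec.base == "pet3factor" else imaging_columns(train)
        model: FactorModel = fit_dimred(train[cols], dimred_config)
        Xtr = transform(model, train).to_numpy()
        Xte = transform(model, test).to_numpy()
        artifacts["factor_model"] = model
    elif spec.base == "pet3feature":
        cols = pet_columns(train)
        model = fit_dimred(train[cols], dimred_config)
        feats = list(dict.fromkeys(model.factor_labels))  # dedupe, keep order
        Xtr, Xte, scaler = _scaled_block(feats)
        artifacts["factor_model"] = model
        artifacts["selected_features"] = feats
        artifacts["scaler"] = scaler
    else:  # pragma: no cover
        raise ValueError(spec.base)

    if spec.add_biochem:
        Xtr = np.column_stack([Xtr, train[BIOCHEM_COLS].to_numpy(dtype=np.float64)])
        Xte = np.column_stack([Xte, test[BIOCHEM_COLS].to_numpy(dtype=np.float64)])
    return Xtr, Xte, artifacts


def run_cv(
    features: pd.DataFrame,
    labels,
    spec: ModelSpec,
    dimred_config: DimredConfig | None = None,
    k: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation of one model spec.

    `features` holds the radiomic columns plus the biochemistry flags;
    `labels` the cluster labels. Returns per-fold and fold-mean AUCs for
    train and test splits.
    """
    labels = np.asarray(labels)
    dimred_config = dimred_config or DimredConfig()
    if folds is None:
        folds = make_folds(labels, k=k, seed=seed)
    folds = np.asarray(folds)
    results: list[FoldResult] = []
    for f in sorted(set(folds.tolist())):
        tr = folds != f
        te = folds == f
        try:
            Xtr, Xte, artifacts = _build_predictors(
                spec, features.loc[tr], features.loc[te], dimred_config
            )
            model = fit_multinomial(Xtr, labels[tr])
            artifacts["classifier"] = model
            proba_order = list(model.classes_)
            tr_auc = AucResult.from_proba(model.predict_proba(Xtr), labels[tr], proba_order)
            te_auc = AucResult.from_proba(model.predict_proba(Xte), labels[te], proba_order)
        except Exception as exc:
            raise RuntimeError(f"fold {f} failed for model {spec.name}: {exc}") from exc
        results.append(FoldResult(int(f), tr_auc, te_auc, artifacts))
    return CvResult(results, spec)


# ------------------------------------------------------------------- sham

@dataclass
class ShamResult:
    spec: ModelSpec
    per_iteration: list[float]   # test multiclass AUC per shuffle

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_iteration))


def sham_experiment(
    features: pd.DataFrame,
    labels,
    spec: ModelSpec,
    iterations: int = 100,
    seed: int = 0,
    k: int = 5,
    dimred_config: DimredConfig | None = None,
    permutations: list[np.ndarray] | None = None,
) -> ShamResult:
    """Label-shuffling null: re-runs the full per-fold pipeline per shuffle.

    Shuffling permutes the outcome labels uniformly (class counts are
    preserved), leaving feature distributions and multicollinearity
    untouched while uncoupling any feature-outcome relation. A failed
    iteration is re-drawn once, then aborts.
    """
    labels = np.asarray(labels)
    n = len(labels)
    aucs: list[float] = []
    for it in range(iterations):
        rng = np.random.default_rng(np.random.SeedSequence([0x5A4A, int(seed), it]))
        if permutations is not None:
            perm = np.asarray(permutations[it])
        else:
            perm = rng.permutation(n)
        y_sham = labels[perm]
        try:
            res = run_cv(features, y_sham, spec, dimred_config, k=k, seed=int(seed) + 7919 * it)
        except RuntimeError as exc:
            logger.warning("sham iteration %d failed (%s); re-drawing once", it, exc)
            perm = rng.permutation(n)
            res = run_cv(features, labels[perm], spec, dimred_config, k=k, seed=int(seed) + 31 + 7919 * it)
        aucs.append(res.mean_test.multiclass)
    return ShamResult(spec, aucs)
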