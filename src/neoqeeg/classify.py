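"""Outcome classification from quantitative EEG features.

The classifier mirrors the analysis it models: within each feature
family, the most discriminant features are selected by Fisher score
(absolute standardised two-sample mean difference), a linear
discriminant is fit from the class means and pooled within-class
covariance, and performance is assessed by stratified three-fold
testing — two thirds of subjects develop the model, one third tests
it — reporting the misclassification error E(%) and the area under the
ROC curve (AUC). Feature selection is repeated inside every training
fold; nothing from a test fold leaks into model development.

Both steps are sklearn-compatible estimators so they compose with
``sklearn.pipeline.Pipeline`` and model-selection utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_scores", "select_discriminant_features", "FisherScoreSelector",
    "PooledCovarianceLDA", "lda_fit", "lda_score", "roc_auc",
    "three_fold_evaluate", "CVResult", "family_report",
]


# --------------------------------------------------------------------------
# discriminant feature selection
# --------------------------------------------------------------------------

def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute standardised mean difference of each feature between classes.

    Score_j = |mean1_j - mean0_j| / s_pooled_j with the pooled
    within-class standard deviation. Zero-variance features score 0
    (never NaN).
    """
    X, y = check_X_y(X, y)
    classes = unique_labels(y)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    m0, m1 = (X[y == c].mean(axis=0) for c in classes)
    n0, n1 = (int((y == c).sum()) for c in classes)
    v0, v1 = (X[y == c].var(axis=0, ddof=1) if (y == c).sum() > 1
              else np.zeros(X.shape[1]) for c in classes)
    dof = max(n0 + n1 - 2, 1)
    sp = np.sqrt(((n0 - 1) * v0 + (n1 - 1) * v1) / dof)
    diff = np.abs(m1 - m0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = diff / sp
    # zero pooled spread: constant feature scores 0, a feature that still
    # separates the class means is perfectly discriminant
    return np.where(sp > 0, score, np.where(diff > 0, np.inf, 0.0))


def select_discriminant_features(X, y, k: int) -> np.ndarray:
    """Indices of the ``k`` highest-scoring features, ties to the lower index."""
    scores = fisher_scores(X, y)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the {scores.size} available features")
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


class FisherScoreSelector(BaseEstimator, TransformerMixin):
    """Select the top-``k`` features by Fisher score.

    Fitted attributes: ``scores_`` (per-feature Fisher score) and
    ``support_`` (boolean mask of retained features).
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.scores_ = fisher_scores(X, y)
        idx = select_discriminant_features(X, y, min(self.k, X.shape[1]))
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[idx] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_


# --------------------------------------------------------------------------
# linear discriminant analysis
# --------------------------------------------------------------------------

class PooledCovarianceLDA(BaseEstimator, ClassifierMixin):
    """Two-class LDA from class means and pooled within-class covariance.

    The discriminant weight vector is ``w = Σ⁻¹ (μ₁ − μ₀)``; the raw
    score of a sample is ``wᵀx`` and the decision threshold is placed
    where the posterior odds under the class priors equal one. A ridge
    term ``ridge · tr(Σ)/p`` is added to a singular or ill-conditioned
    pooled covariance (logged).

    Fitted attributes: ``classes_``, ``means_`` (2 x p), ``priors_``,
    ``covariance_``, ``coef_`` (w), ``threshold_``.
    """

    def __init__(self, ridge: float = 1e-6, priors=None):
        self.ridge = ridge
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if self.classes_.size != 2:
            raise ValueError("PooledCovarianceLDA requires exactly two classes")
        n, p = X.shape
        masks = [y == c for c in self.classes_]
        counts = np.array([m.sum() for m in masks])
        if counts.min() < 2:
            raise ValueError("each class needs at least two samples")
        self.means_ = np.vstack([X[m].mean(axis=0) for m in masks])
        if self.priors is None:
            self.priors_ = counts / n
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if self.priors_.sum() <= 0:
                raise ValueError("priors must sum to a positive value")
            self.priors_ = self.priors_ / self.priors_.sum()
        dev = np.vstack([X[m] - self.means_[i] for i, m in enumerate(masks)])
        cov = dev.T @ dev / max(n - 2, 1)
        # regularise when singular or ill-conditioned (always when p >= n)
        eig_min = np.linalg.eigvalsh(cov).min() if p else 0.0
        if p >= n or eig_min <= 1e-10 * max(np.trace(cov) / max(p, 1), 1e-30):
            lam = self.ridge * np.trace(cov) / max(p, 1)
            lam = max(lam, 1e-12)
            cov = cov + lam * np.eye(p)
            logger.info("pooled covariance regularised with ridge %.3e", lam)
        self.covariance_ = cov
        diff = self.means_[1] - self.means_[0]
        self.coef_ = np.linalg.solve(cov, diff)
        self.threshold_ = float(
            0.5 * self.coef_ @ (self.means_[0] + self.means_[1])
            - np.log(self.priors_[1] / self.priors_[0]))
        self.n_features_in_ = p
        return self

    def raw_score(self, X) -> np.ndarray:
        """Discriminant projection ``wᵀx`` (no threshold applied)."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_

    def decision_function(self, X) -> np.ndarray:
        return self.raw_score(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d > 0).astype(int)]

    def predict_proba(self, X) -> np.ndarray:
        d = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
        return np.column_stack([1.0 - p1, p1])


def lda_fit(X, y, ridge: float = 1e-6, priors=None) -> PooledCovarianceLDA:
    """Fit a two-class pooled-covariance LDA; thin wrapper over the estimator."""
    return PooledCovarianceLDA(ridge=ridge, priors=priors).fit(X, y)


def lda_score(model: PooledCovarianceLDA, X) -> np.ndarray:
    """Raw discriminant scores ``wᵀx`` of samples under a fitted model."""
    return model.raw_score(X)


# --------------------------------------------------------------------------
# ROC AUC (Mann-Whitney identity)
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    ``AUC = U₁ / (n₁ n₀)`` with midranks, so tied scores count one half;
    equals trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("both classes must be present to compute AUC")
    pos = labels == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u1 = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


# --------------------------------------------------------------------------
# three-fold testing
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Pooled cross-validated performance of the select-then-LDA model.

    ``E_pct`` is the misclassification error and ``auc_pct`` the ROC AUC,
    both in percent over the pooled test predictions; ``fold_ids`` maps
    every subject to the (repetition, fold) in which it was tested.
    """

    E_pct: float
    auc_pct: float
    predictions: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    fold_ids: np.ndarray = field(repr=False)
    seed: int = 0
    per_fold_auc_pct: list = field(default_factory=list, repr=False)


def three_fold_evaluate(X, y, k_features: int = 5, seed: int = 0,
                        n_folds: int = 3, repetitions: int = 1,
                        ridge: float = 1e-6) -> CVResult:
    """Stratified k-fold (default three-fold) testing of the LDA model.

    Per fold: Fisher-score feature selection and LDA fitting on the
    training two-thirds only, scoring of the held-out third. Pooled test
    predictions give E(%) and AUC(%). With ``repetitions > 1`` the
    partition is redrawn (seeds ``seed .. seed + repetitions - 1``) and
    the metrics averaged.
    """
    X, y = check_X_y(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    if X.shape[0] < 3 * n_folds:
        raise ValueError(f"need at least {3 * n_folds} subjects for "
                         f"{n_folds}-fold testing")
    if counts.min() < n_folds:
        raise ValueError(
            f"rarest class has {counts.min()} subjects, fewer than the "
            f"{n_folds} folds; use a larger cohort or fewer folds")
    e_list, auc_list = [], []
    predictions = scores = fold_ids = None
    per_fold_auc = []
    for rep in range(repetitions):
        rep_seed = seed + rep
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rep_seed)
        preds = np.empty_like(y)
        sc = np.empty(len(y), dtype=float)
        fids = np.empty(len(y), dtype=int)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            sel = FisherScoreSelector(k=min(k_features, X.shape[1]))
            Xtr = sel.fit(X[tr], y[tr]).transform(X[tr])
            lda = PooledCovarianceLDA(ridge=ridge).fit(Xtr, y[tr])
            Xte = sel.transform(X[te])
            preds[te] = lda.predict(Xte)
            sc[te] = lda.decision_function(Xte)
            fids[te] = f
            if np.unique(y[te]).size == 2:
                per_fold_auc.append(100.0 * roc_auc(sc[te], y[te]))
        e_list.append(100.0 * float(np.mean(preds != y)))
        auc_list.append(100.0 * roc_auc(sc, y))
        if rep == 0:
            predictions, scores, fold_ids = preds, sc, fids
    return CVResult(
        E_pct=float(np.mean(e_list)), auc_pct=float(np.mean(auc_list)),
        predictions=predictions, scores=scores, fold_ids=fold_ids,
        seed=seed, per_fold_auc_pct=per_fold_auc)


def family_report(features: pd.DataFrame, y, families=None,
                  k_features: int = 5, seed: int = 0,
                  repetitions: int = 1) -> pd.DataFrame:
    """Per-family classification report (rows: family; columns: E(%), AUC(%)).

    ``features`` is a subjects x features matrix whose column names carry
    the family prefixes (``bp_``, ``mse_``, ``reeg_asym_``, ``hurst``);
    NaN columns are dropped, NaN cells mean-imputed per column before
    evaluation.
    """
    from .features import FEATURE_FAMILIES

    families = families or FEATURE_FAMILIES
    y = np.asarray(y)
    rows = {}
    for fam, prefix in families.items():
        cols = [c for c in features.columns if c.startswith(prefix)]
        if not cols:
            continue
        sub = features[cols].astype(float)
        sub = sub.dropna(axis=1, how="all")
        sub = sub.fillna(sub.mean())
        res = three_fold_evaluate(sub.to_numpy(), y, k_features=k_features,
                                  seed=seed, repetitions=repetitions)
        rows[fam] = {"E_pct": res.E_pct, "auc_pct": res.auc_pct}
    return pd.DataFrame.from_dict(rows, orient="index")
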