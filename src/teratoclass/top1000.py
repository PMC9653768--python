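"""Leave-one-compound-out L1-regularized logistic classification.

For every non-cytotoxic compound, all of its replicate samples (both
concentration buckets) are removed from the training data; the 1000 probe
sets with the highest variance across the remaining samples are selected;
an L1-penalized logistic regression is fitted with the penalty tuned by
inner 10-fold cross-validation minimizing the mean cross-validated deviance
(lambda.min semantics); the left-out compound's replicates are scored and
averaged per bucket.  Cytotoxic conditions are assigned probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .core_io import ClassificationReport, Condition, ScoreRecord, ScoreSet
from . import sps_classifier


@dataclass
class FoldResult:
    left_out_compound: str
    selected_probe_sets: list[str]
    lambda_selected: float
    coefficients: np.ndarray
    intercept: float
    replicate_probabilities: dict[str, dict[str, list[float]]] = field(
        default_factory=dict
    )  # bucket -> {sample_id: prob}... stored flat per bucket


def select_top_variance(matrix: pd.DataFrame, k: int = 1000) -> list[str]:
    """The k probe sets (rows) with largest sample variance across the given
    samples (columns); ties broken by probe-set identifier order."""
    if matrix.shape[0] < k:
        raise ValueError(
            f"need at least {k} probe sets, got {matrix.shape[0]}"
        )
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a variance")
    variances = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda p: (-variances[p], p))
    return order[:k]


def _l1_logistic(C: float, seed: int) -> LogisticRegression:
    # liblinear shuffles internally; pin its stream for reproducibility
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=seed
    )


def _tune_l1(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cv_folds: int,
    seed: int,
    n_lambdas: int = 20,
    group_inner_folds: bool = True,
) -> tuple[LogisticRegression, float]:
    """Fit an L1 logistic regression, choosing the penalty that minimizes
    mean cross-validated deviance over a data-driven lambda path."""
    n = X.shape[0]
    p_bar = y.mean()
    # glmnet-style path: lambda_max is the smallest penalty with all-zero
    # coefficients; descend 3 decades from it.
    lambda_max = np.abs(X.T @ (y - p_bar)).max() / n
    lambda_max = max(lambda_max, 1e-6)
    lambdas = lambda_max * np.logspace(0, -3, n_lambdas)

    n_groups_minority = min(
        len(np.unique(groups[y == cls])) for cls in np.unique(y)
    )
    n_splits = int(min(cv_folds, n_groups_minority * 2, len(np.unique(groups))))
    n_splits = max(n_splits, 2)
    if group_inner_folds:
        splitter = StratifiedGroupKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        )
        split_iter = list(splitter.split(X, y, groups=groups))
    else:
        splitter = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        )
        split_iter = list(splitter.split(X, y))

    mean_deviance = np.full(len(lambdas), np.inf)
    for i, lam in enumerate(lambdas):
        C = 1.0 / (n * lam)
        losses = []
        for train_idx, test_idx in split_iter:
            if len(np.unique(y[train_idx])) < 2:
                continue
            model = _l1_logistic(C, seed)
            model.fit(X[train_idx], y[train_idx])
            prob = model.predict_proba(X[test_idx])[:, 1]
            losses.append(log_loss(y[test_idx], prob, labels=[0, 1]))
        if losses:
            mean_deviance[i] = float(np.mean(losses))
    best = int(np.argmin(mean_deviance))  # ties -> largest penalty
    lam = float(lambdas[best])
    final = _l1_logistic(1.0 / (n * lam), seed)
    final.fit(X, y)
    return final, lam


def loo_predict(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    conditions: list[Condition],
    k: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    group_inner_folds: bool = True,
) -> tuple[ScoreSet, list[FoldResult]]:
    """Mean per-condition teratogenicity probabilities via LOO.

    ``matrix`` holds normalized expression values (probe sets x samples);
    ``samples`` is indexed by sample id with columns compound_id and bucket.
    Condition truths provide the training labels, broadcast to replicates.
    """
    truth_by_key = {c.key: c.truth for c in conditions}
    cytotoxic_keys = {c.key for c in conditions if c.cytotoxic}
    test_system = conditions[0].test_system if conditions else ""

    sample_ids = list(matrix.columns)
    compounds = samples.loc[sample_ids, "compound_id"]
    buckets = samples.loc[sample_ids, "bucket"]
    y_all = np.array(
        [
            1.0
            if truth_by_key[(compounds[s], buckets[s])] == "teratogen"
            else 0.0
            for s in sample_ids
        ]
    )

    scores: dict[tuple[str, str], ScoreRecord] = {}
    folds: list[FoldResult] = []
    left_out_compounds = sorted(
        {
            c.compound_id
            for c in conditions
            if not c.cytotoxic and c.compound_id in set(compounds)
        }
    )
    for compound in left_out_compounds:
        test_mask = (compounds == compound).to_numpy()
        train_ids = [s for s, m in zip(sample_ids, test_mask) if not m]
        test_ids = [s for s, m in zip(sample_ids, test_mask) if m]
        y_train = y_all[~test_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold leaving out {compound!r} has single-class training data"
            )
        selected = select_top_variance(matrix[train_ids], k=min(k, matrix.shape[0]))
        X_train = matrix.loc[selected, train_ids].to_numpy().T
        X_test = matrix.loc[selected, test_ids].to_numpy().T
        if standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        groups = compounds[train_ids].to_numpy()
        model, lam = _tune_l1(
            X_train,
            y_train,
            groups,
            cv_folds=cv_folds,
            seed=seed,
            group_inner_folds=group_inner_folds,
        )
        probs = model.predict_proba(X_test)[:, 1]
        fold = FoldResult(
            left_out_compound=compound,
            selected_probe_sets=selected,
            lambda_selected=lam,
            coefficients=model.coef_.ravel().copy(),
            intercept=float(model.intercept_[0]),
        )
        per_bucket: dict[str, list[float]] = {}
        for sid, prob in zip(test_ids, probs):
            per_bucket.setdefault(buckets[sid], []).append(float(prob))
        fold.replicate_probabilities = {
            b: {sid: float(p) for sid, p in zip(test_ids, probs) if buckets[sid] == b}
            for b in per_bucket
        }
        folds.append(fold)
        for bucket, values in per_bucket.items():
            scores[(compound, bucket)] = ScoreRecord(
                score=float(np.mean(values))
            )

    for key in cytotoxic_keys:
        scores[key] = ScoreRecord(score=1.0, cytotox_assigned=True)

    score_set = ScoreSet(
        score_kind="probability", test_system=test_system, scores=scores
    )
    return score_set, folds


def classify_probabilities(
    scores: ScoreSet,
    truths: dict[tuple[str, str], str],
    threshold: float | None = None,
) -> ClassificationReport:
    """Delegate probability classification to the shared threshold
    machinery (fixed threshold, or exhaustive search when None)."""
    if scores.score_kind != "probability":
        raise ValueError("expected a probability ScoreSet")
    if threshold is None:
        return sps_classifier.search_threshold(scores, truths)
    return sps_classifier.report_at_threshold(scores, truths, threshold)
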