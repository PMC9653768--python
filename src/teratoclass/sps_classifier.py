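"""Threshold classification of per-condition scores.

Implements cytotoxic score assignment, the stand-in rule for untestable
high-concentration conditions, strict greater-than classification, confusion
metrics, tie-aware ROC/AUC and the exhaustive threshold search with
lexicographic (accuracy, sensitivity, specificity) tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.stats import rankdata

from .core_io import ClassificationReport, Condition, ScoreRecord, ScoreSet

MODES = ("cytotox_only", "gene_only", "combined")


def assign_scores(
    counts: dict[tuple[str, str], int | None],
    conditions: list[Condition],
    mode: str = "combined",
    cytotox_score: float | None = None,
) -> ScoreSet:
    """Build a ScoreSet from per-condition SPS counts.

    ``counts`` maps (compound_id, bucket) to an integer count, or None for
    cytotoxic conditions.  In ``combined`` mode cytotoxic conditions receive
    the test-system-wise maximum observed count plus five (overridable via
    ``cytotox_score``); in ``cytotox_only`` mode scores are the 0/1
    cytotoxicity indicator; in ``gene_only`` mode cytotoxic conditions carry
    a None sentinel (no expression data).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    system = conditions[0].test_system if conditions else ""
    for c in conditions:
        if not c.cytotoxic and counts.get(c.key) is None:
            raise ValueError(
                f"non-cytotoxic condition {c.key} has no SPS count"
            )
    observed = [counts[c.key] for c in conditions if not c.cytotoxic]
    if mode == "combined" and cytotox_score is None:
        if any(c.cytotoxic for c in conditions) and not observed:
            raise ValueError(
                "all conditions cytotoxic: maximum observed count undefined"
            )
        cytotox_score = (max(observed) + 5) if observed else None

    scores: dict[tuple[str, str], ScoreRecord] = {}
    for c in conditions:
        sub = c.substituted_from_1x
        if mode == "cytotox_only":
            rec = ScoreRecord(1.0 if c.cytotoxic else 0.0,
                              cytotox_assigned=c.cytotoxic,
                              substituted_from_1x=sub)
        elif mode == "gene_only":
            if c.cytotoxic:
                rec = ScoreRecord(None, cytotox_assigned=True,
                                  substituted_from_1x=sub)
            else:
                rec = ScoreRecord(float(counts[c.key]),
                                  substituted_from_1x=sub)
        else:  # combined
            if c.cytotoxic:
                rec = ScoreRecord(float(cytotox_score), cytotox_assigned=True,
                                  substituted_from_1x=sub)
            else:
                rec = ScoreRecord(float(counts[c.key]),
                                  substituted_from_1x=sub)
        scores[c.key] = rec
    return ScoreSet(score_kind="sps", test_system=system, scores=scores)


def substitute_20x(
    scores_1x: ScoreSet,
    scores_20x: ScoreSet,
    unavailable: set[str],
) -> ScoreSet:
    """Return a 20x-bucket ScoreSet where each compound in ``unavailable``
    carries its 1x score, flagged ``substituted_from_1x``."""
    out = dict(scores_20x.scores)
    for compound in sorted(unavailable):
        key_1x = (compound, "1x")
        if key_1x not in scores_1x.scores:
            raise KeyError(
                f"compound {compound!r} marked unavailable at 20x has no 1x score"
            )
        rec = scores_1x.scores[key_1x]
        out[(compound, "20x")] = replace(rec, substituted_from_1x=True)
    return ScoreSet(
        score_kind=scores_20x.score_kind,
        test_system=scores_20x.test_system,
        scores=out,
    )


def classify(scores: ScoreSet, threshold: float) -> dict[tuple[str, str], bool]:
    """Positive iff score is strictly greater than the threshold.  None
    scores (gene-only cytotoxic sentinel) classify negative."""
    predictions = {}
    for key, rec in scores.scores.items():
        if rec.score is not None and not math.isfinite(rec.score):
            raise ValueError(f"non-finite score for {key}")
        predictions[key] = rec.score is not None and rec.score > threshold
    return predictions


def confusion_metrics(
    predictions: dict[tuple[str, str], bool],
    truths: dict[tuple[str, str], str],
) -> dict:
    """TP/TN/FP/FN counts plus accuracy, sensitivity and specificity.

    Sensitivity/specificity are None when the corresponding truth class is
    empty.
    """
    if set(predictions) != set(truths):
        raise ValueError("predictions and truths cover different conditions")
    tp = tn = fp = fn = 0
    for key, positive in predictions.items():
        is_teratogen = truths[key] == "teratogen"
        if is_teratogen and positive:
            tp += 1
        elif is_teratogen:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    total = tp + tn + fp + fn
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": (tp + tn) / total if total else math.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }


def roc_auc(
    scores: ScoreSet,
    truths: dict[tuple[str, str], str],
    exclude_missing: bool = True,
) -> float:
    """Tie-aware AUC over all (teratogen, non-teratogen) score pairs.

    Equals the area under the empirical ROC curve obtained by sweeping every
    threshold.  Conditions with a None score are excluded (the gene-only
    convention) when ``exclude_missing``; otherwise they raise.
    """
    pos, neg = [], []
    for key, rec in scores.scores.items():
        if rec.score is None:
            if exclude_missing:
                continue
            raise ValueError(f"missing score for {key}")
        (pos if truths[key] == "teratogen" else neg).append(rec.score)
    if not pos or not neg:
        raise ValueError("AUC undefined: one truth class has no scored conditions")
    # Mann-Whitney via midranks: sum of positive ranks minus the minimum.
    values = np.asarray(pos + neg, dtype=float)
    ranks = rankdata(values)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _report_at(scores, truths, threshold, interval, auc):
    predictions = classify(scores, threshold)
    m = confusion_metrics(predictions, truths)
    return ClassificationReport(
        threshold=threshold,
        optimal_threshold_interval=interval,
        predictions=predictions,
        tp=m["tp"],
        tn=m["tn"],
        fp=m["fp"],
        fn=m["fn"],
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=auc,
    )


def report_at_threshold(
    scores: ScoreSet,
    truths: dict[tuple[str, str], str],
    threshold: float,
    auc: bool = True,
) -> ClassificationReport:
    """Classification report at a fixed threshold (no search)."""
    auc_val = roc_auc(scores, truths) if auc else None
    return _report_at(scores, truths, threshold, None, auc_val)


def search_threshold(
    scores: ScoreSet,
    truths: dict[tuple[str, str], str],
) -> ClassificationReport:
    """Exhaustive threshold search maximizing (accuracy, sensitivity,
    specificity) lexicographically.

    Candidates are the observed unique score values plus one value below the
    minimum (classification is strict '>', so any threshold between two
    consecutive observed values is equivalent).  The report carries the full
    closed-open interval of equivalent thresholds; its lower bound is the
    canonical representative.
    """
    observed = sorted(
        {rec.score for rec in scores.scores.values() if rec.score is not None}
    )
    if len(observed) < 2:
        raise ValueError("threshold search needs at least 2 distinct scores")
    candidates = [(-math.inf, observed[0])]
    for i, s in enumerate(observed):
        upper = observed[i + 1] if i + 1 < len(observed) else math.inf
        candidates.append((s, upper))
    best = None
    best_key = None
    for low, high in candidates:
        predictions = classify(scores, low)
        m = confusion_metrics(predictions, truths)
        key = (
            m["accuracy"],
            -1.0 if m["sensitivity"] is None else m["sensitivity"],
            -1.0 if m["specificity"] is None else m["specificity"],
            -low,  # prefer the lowest equivalent threshold interval
        )
        if best_key is None or key > best_key:
            best_key = key
            best = (low, high)
    auc_val = roc_auc(scores, truths)
    return _report_at(scores, truths, best[0], best, auc_val)
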