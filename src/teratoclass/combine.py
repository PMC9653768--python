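"""Condition-wise combination of two test systems' score sets."""

from __future__ import annotations

from .core_io import ScoreRecord, ScoreSet

METHODS = ("min", "max", "mean")


def combine_scores(a: ScoreSet, b: ScoreSet, method: str) -> ScoreSet:
    """Element-wise min/max/mean of two score sets over identical condition
    keys.  Cytotoxic conditions enter with their assigned numeric scores;
    the cytotox_assigned and substituted flags propagate as 'any'."""
    if method not in METHODS:
        raise ValueError(f"unknown combination method {method!r}")
    if a.score_kind != b.score_kind:
        raise ValueError(
            f"cannot combine score kinds {a.score_kind!r} and {b.score_kind!r}"
        )
    if set(a.scores) != set(b.scores):
        only_a = sorted(set(a.scores) - set(b.scores))
        only_b = sorted(set(b.scores) - set(a.scores))
        raise ValueError(
            f"condition keys differ: only-in-a={only_a}, only-in-b={only_b}"
        )
    combined = {}
    for key in a.scores:
        ra, rb = a.scores[key], b.scores[key]
        if ra.score is None or rb.score is None:
            raise ValueError(
                f"cannot combine missing score for {key}; apply "
                "gene_only_filter first"
            )
        if method == "min":
            value = min(ra.score, rb.score)
        elif method == "max":
            value = max(ra.score, rb.score)
        else:
            value = (ra.score + rb.score) / 2.0
        combined[key] = ScoreRecord(
            score=value,
            cytotox_assigned=ra.cytotox_assigned or rb.cytotox_assigned,
            substituted_from_1x=ra.substituted_from_1x or rb.substituted_from_1x,
        )
    return ScoreSet(
        score_kind=a.score_kind,
        test_system=f"{a.test_system}+{b.test_system}:{method}",
        scores=combined,
    )


def gene_only_filter(a: ScoreSet, b: ScoreSet) -> tuple[ScoreSet, ScoreSet]:
    """Drop every condition cytotoxic in at least one system (the
    gene-only 'mean'/'max' variant) before combination."""
    if set(a.scores) != set(b.scores):
        raise ValueError("condition keys differ between score sets")
    drop = {
        key
        for key in a.scores
        if a.scores[key].cytotox_assigned
        or b.scores[key].cytotox_assigned
        or a.scores[key].score is None
        or b.scores[key].score is None
    }
    keep_a = {k: r for k, r in a.scores.items() if k not in drop}
    keep_b = {k: r for k, r in b.scores.items() if k not in drop}
    return (
        ScoreSet(score_kind=a.score_kind, test_system=a.test_system, scores=keep_a),
        ScoreSet(score_kind=b.score_kind, test_system=b.test_system, scores=keep_b),
    )
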