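"""Control-matched normalization, moderated one-sample testing, FDR
adjustment and significant-probe-set selection.

The test is a one-sample empirical-Bayes moderated t on per-replicate
(treated - control) log2 differences: per-probe-set sample variances are
shrunk toward a prior estimated from the marginal distribution of
log-variances across the whole array (moment matching on the digamma /
trigamma scale), and the statistic is referred to a t distribution with
``d0 + (n - 1)`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import DiffExpTable, ExpressionStudy


@dataclass
class NormalizedDifferences:
    """Per-condition probe_set x replicate grids of (treated - control)
    log2 differences, keyed by (compound_id, concentration_label)."""

    by_condition: dict[tuple[str, str], pd.DataFrame]


@dataclass(frozen=True)
class EBayesParams:
    d0: float  # prior degrees of freedom, may be +inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("EBayes hyperparameters must be positive")


@dataclass
class SpsSelection:
    up: set[str]
    down: set[str]

    @property
    def count(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def normalize_to_controls(study: ExpressionStudy) -> NormalizedDifferences:
    """Subtract the matched-control mean (or, failing that, the batch-wise
    control mean) from every non-control sample, grouped by condition."""
    samples = study.samples
    controls = samples[samples["is_control"]]
    batch_means: dict = {}
    for batch, grp in controls.groupby("batch"):
        batch_means[batch] = study.matrix[list(grp.index)].mean(axis=1)

    diffs: dict[tuple[str, str], dict[str, pd.Series]] = {}
    treated = samples[~samples["is_control"]]
    for sid, row in treated.iterrows():
        matched = row["matched_controls"]
        if matched:
            reference = study.matrix[list(matched)].mean(axis=1)
        elif row["batch"] in batch_means:
            reference = batch_means[row["batch"]]
        else:
            raise ValueError(
                f"sample {sid} has neither matched controls nor batch controls"
            )
        key = (row["compound_id"], row["concentration_label"])
        diffs.setdefault(key, {})[sid] = study.matrix[sid] - reference

    by_condition = {
        key: pd.DataFrame(cols) for key, cols in sorted(diffs.items())
    }
    return NormalizedDifferences(by_condition=by_condition)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_ebayes_prior(variances: np.ndarray, df: int) -> EBayesParams:
    """Moment-match an inverse-chi-square prior to the observed sample
    variances: the log-variances have known digamma mean and trigamma
    variance offsets under the scaled-F marginal."""
    s2 = np.asarray(variances, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError(
            "empirical Bayes prior unidentifiable: fewer than two probe sets "
            "with positive variance"
        )
    e = np.log(positive) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        half_d0 = _trigamma_inverse(e_var)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(
            e_mean + special.digamma(half_d0) - math.log(half_d0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    diffs: pd.DataFrame,
    prior: EBayesParams | None = None,
) -> tuple[DiffExpTable, EBayesParams]:
    """Moderated one-sample t-test of per-replicate differences against 0.

    ``diffs`` is probe_set x replicate.  ``prior`` overrides hyperparameter
    estimation (the d0 -> 0 limit recovers the ordinary one-sample t).
    """
    if diffs.shape[1] < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    n = diffs.shape[1]
    dg = n - 1
    values = diffs.to_numpy(dtype=float)
    means = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)
    if prior is None:
        prior = fit_ebayes_prior(s2, dg)
    d0, s0_sq = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(s2_post / n)
    t = np.where(means == 0, 0.0, t)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p_raw)
    fc = np.sign(means) * np.exp2(np.abs(means))
    fc = np.where(means == 0, 1.0, fc)
    table = pd.DataFrame(
        {
            "log2_fc": means,
            "fc": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=diffs.index,
    )
    return DiffExpTable(table=table), prior


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment mapped back to input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    # guard against 1-ulp rounding in p*m/rank: adjusted >= raw by definition
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def select_sps(
    table: DiffExpTable, alpha: float = 0.05, fc_cut: float = 2.0
) -> SpsSelection:
    """Probe sets with FDR-adjusted p strictly below ``alpha`` AND absolute
    linear fold-change strictly above ``fc_cut``, split by direction."""
    df = table.table
    mask = (df["p_adj"] < alpha) & (df["fc"].abs() > fc_cut)
    up = set(df.index[mask & (df["log2_fc"] > 0)])
    down = set(df.index[mask & (df["log2_fc"] < 0)])
    return SpsSelection(up=up, down=down)


def sps_counts_for_study(
    study: ExpressionStudy,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], SpsSelection]]:
    """Convenience: normalize, test and count SPS per condition."""
    normalized = normalize_to_controls(study)
    counts: dict[tuple[str, str], int] = {}
    selections: dict[tuple[str, str], SpsSelection] = {}
    for key, diffs in normalized.by_condition.items():
        table, _ = moderated_t_test(diffs)
        sel = select_sps(table, alpha=alpha, fc_cut=fc_cut)
        counts[key] = sel.count
        selections[key] = sel
    return counts, selections
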