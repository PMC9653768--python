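"""Domain types and readers/writers shared by all pipeline stages.

The on-disk dialect is TSV throughout: expression matrices carry probe-set
identifiers row-wise and sample identifiers column-wise; sample metadata is
one row per sample.  Packaged study fixtures (condition tables, confusion
labels, operating points) are loaded from TSV files shipped inside the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

CONCENTRATION_LABELS = frozenset({"1x", "20x", "10x", "1.67x"})
BUCKETS = ("1x", "20x")
TRUTHS = ("teratogen", "non_teratogen")

#: compounds whose high-concentration condition could not be tested and is
#: stood in for by the low-concentration result
SUBSTITUTED_COMPOUNDS = frozenset({"LFL", "PHE", "TER", "VIS"})


class LoadError(ValueError):
    """Raised when an on-disk study fails validation."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, used when comparing metrics to published
    two-decimal values (banker's rounding would turn 0.875 into 0.88 too,
    but 0.845 into 0.84)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Condition:
    """One compound x concentration-bucket x test-system unit."""

    compound_id: str
    concentration_label: str
    bucket: str
    test_system: str
    truth: str
    cytotoxic: bool
    substituted_from_1x: bool = False

    def __post_init__(self) -> None:
        if self.concentration_label not in CONCENTRATION_LABELS:
            raise ValueError(
                f"unknown concentration label {self.concentration_label!r}"
            )
        if self.bucket not in BUCKETS:
            raise ValueError(f"unknown bucket {self.bucket!r}")
        if self.truth not in TRUTHS:
            raise ValueError(f"unknown truth label {self.truth!r}")
        if self.substituted_from_1x and self.bucket != "20x":
            raise ValueError("substituted_from_1x implies the 20x bucket")

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.bucket)


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus per-sample metadata.

    ``matrix`` is probe sets x samples; ``samples`` is indexed by sample id
    with columns compound_id, concentration_label, replicate, batch,
    is_control and matched_controls (a list, possibly empty).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mat_samples = set(self.matrix.columns)
        meta_samples = set(self.samples.index)
        if mat_samples != meta_samples:
            only_mat = sorted(mat_samples - meta_samples)
            only_meta = sorted(meta_samples - mat_samples)
            raise LoadError(
                "sample sets differ between matrix and metadata: "
                f"matrix-only={only_mat}, metadata-only={only_meta}"
            )
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise LoadError(f"duplicate probe-set identifiers: {dupes}")
        if self.matrix.isna().any().any():
            stacked = self.matrix.stack(future_stack=True)
            cells = stacked[stacked.isna()].index.tolist()[:10]
            raise LoadError(f"missing values in matrix at {cells}")
        controls_by_batch = (
            self.samples[self.samples["is_control"]].groupby("batch").size()
        )
        for sid, row in self.samples.iterrows():
            if row["is_control"]:
                continue
            if row["matched_controls"]:
                missing = [
                    c for c in row["matched_controls"] if c not in meta_samples
                ]
                if missing:
                    raise LoadError(
                        f"sample {sid} references unknown controls {missing}"
                    )
            elif controls_by_batch.get(row["batch"], 0) < 1:
                raise LoadError(
                    f"sample {sid} has no matched controls and batch "
                    f"{row['batch']!r} contains no control samples"
                )

    @property
    def probe_sets(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class DiffExpTable:
    """Per-probe-set differential expression estimates.

    ``table`` columns: log2_fc, fc, p_raw, p_adj.  The linear fold-change is
    signed: ``fc = sign(log2_fc) * 2**abs(log2_fc)`` (``1`` at log2_fc 0).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"log2_fc", "fc", "p_raw", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DiffExpTable missing columns {sorted(missing)}")


@dataclass(frozen=True)
class ScoreRecord:
    """Score for one condition.  ``score`` is None for the gene-only
    'no data' sentinel carried by cytotoxic conditions."""

    score: float | None
    cytotox_assigned: bool = False
    substituted_from_1x: bool = False


@dataclass
class ScoreSet:
    """Per-condition classifier scores keyed by (compound_id, bucket)."""

    score_kind: str  # {"sps", "probability"}
    test_system: str
    scores: dict[tuple[str, str], ScoreRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score_kind not in ("sps", "probability"):
            raise ValueError(f"unknown score kind {self.score_kind!r}")
        for key, rec in self.scores.items():
            if rec.score is None:
                continue
            if rec.score < 0:
                raise ValueError(f"negative score for {key}")
            if self.score_kind == "probability" and not 0 <= rec.score <= 1:
                raise ValueError(f"probability out of [0,1] for {key}")

    def __len__(self) -> int:
        return len(self.scores)

    def keys(self):
        return self.scores.keys()

    def __getitem__(self, key: tuple[str, str]) -> ScoreRecord:
        return self.scores[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": c,
                "bucket": b,
                "score": r.score,
                "cytotox_assigned": r.cytotox_assigned,
                "substituted_from_1x": r.substituted_from_1x,
            }
            for (c, b), r in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ClassificationReport:
    threshold: float
    optimal_threshold_interval: tuple[float, float] | None
    predictions: dict[tuple[str, str], bool]
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "optimal_threshold_interval": self.optimal_threshold_interval,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


# ---------------------------------------------------------------------------
# readers / writers


def _parse_matched(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return []
    return [tok for tok in text.split(",") if tok]


def read_expression_study(matrix_path, metadata_path) -> ExpressionStudy:
    """Read a TSV matrix + TSV metadata pair into a validated study."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {
        "sample_id",
        "compound_id",
        "concentration_label",
        "replicate",
        "batch",
        "is_control",
        "matched_controls",
    }
    missing = required - set(meta.columns)
    if missing:
        raise LoadError(f"metadata missing columns {sorted(missing)}")
    meta = meta.set_index("sample_id")
    meta["is_control"] = meta["is_control"].astype(bool)
    meta["matched_controls"] = meta["matched_controls"].map(_parse_matched)
    return ExpressionStudy(matrix=matrix, samples=meta)


def write_expression_study(study: ExpressionStudy, out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / "matrix.tsv"
    metadata_path = out_dir / "metadata.tsv"
    study.matrix.to_csv(matrix_path, sep="\t", index_label="probe_set")
    meta = study.samples.copy()
    meta["matched_controls"] = meta["matched_controls"].map(",".join)
    meta.to_csv(metadata_path, sep="\t", index_label="sample_id")
    return matrix_path, metadata_path


def write_diffexp_table(table: DiffExpTable, path, sps=None) -> None:
    """Write a per-condition differential-expression TSV; ``sps`` is an
    optional selection (up/down sets) used to fill is_sps/direction."""
    out = table.table.copy()
    if sps is not None:
        out["is_sps"] = out.index.isin(sps.up | sps.down)
        out["direction"] = [
            "up" if p in sps.up else ("down" if p in sps.down else "")
            for p in out.index
        ]
    out.to_csv(path, sep="\t", index_label="probe_set")


def read_score_set(path, score_kind: str, test_system: str) -> ScoreSet:
    df = pd.read_csv(path, sep="\t")
    scores = {}
    for _, row in df.iterrows():
        score = row["score"]
        score = None if pd.isna(score) else float(score)
        scores[(str(row["compound_id"]), str(row["bucket"]))] = ScoreRecord(
            score=score,
            cytotox_assigned=bool(row.get("cytotox_assigned", False)),
            substituted_from_1x=bool(row.get("substituted_from_1x", False)),
        )
    return ScoreSet(score_kind=score_kind, test_system=test_system, scores=scores)


def write_score_set(scores: ScoreSet, path) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged study fixtures


@dataclass
class FixtureBundle:
    """Transcribed study tables for the UKN1 assay.

    conditions: test_system -> bucket -> compound_id -> Condition
    counts:     test_system -> bucket -> compound_id -> SPS count (int) or
                None for cytotoxic conditions (20x substitution applied)
    labels:     confusion-label table, one row per (compound, truth), one
                column per procedure x combination x bucket
    thresholds: (procedure, system, bucket) -> published operating point
    cytotox_scores: test_system -> assigned cytotoxic score
    """

    conditions: dict
    counts: dict
    labels: pd.DataFrame
    thresholds: dict
    cytotox_scores: dict

    def condition_list(self, system: str, bucket: str) -> list[Condition]:
        return sorted(
            self.conditions[system][bucket].values(),
            key=lambda c: c.compound_id,
        )


def _fixture_path(name: str):
    return resources.files("teratoclass.fixtures").joinpath(name)


def load_paper_fixtures() -> FixtureBundle:
    """Load the packaged UKN1 condition, count and label tables."""
    with resources.as_file(_fixture_path("ukn1_conditions.tsv")) as p:
        raw = pd.read_csv(p, sep="\t")
    conditions: dict = {"UKN1": {"1x": {}, "20x": {}}}
    counts: dict = {"UKN1": {"1x": {}, "20x": {}}}
    by_key = {}
    for _, row in raw.iterrows():
        cond = Condition(
            compound_id=row["compound_id"],
            concentration_label=row["concentration_label"],
            bucket=row["bucket"],
            test_system="UKN1",
            truth=row["truth"],
            cytotoxic=bool(row["cytotoxic"]),
        )
        by_key[cond.key] = cond
        conditions["UKN1"][cond.bucket][cond.compound_id] = cond
        if cond.cytotoxic:
            counts["UKN1"][cond.bucket][cond.compound_id] = None
        else:
            counts["UKN1"][cond.bucket][cond.compound_id] = int(row["up"]) + int(
                row["down"]
            )
    # 20x-bucket stand-ins for the four untestable compounds: the 1x result
    # (count, cytotoxicity) is carried over, but the truth label is the one
    # that applies at the 20x bucket (same as 1x for all four).
    for compound in sorted(SUBSTITUTED_COMPOUNDS):
        base = by_key[(compound, "1x")]
        sub = replace(base, bucket="20x", substituted_from_1x=True)
        conditions["UKN1"]["20x"][compound] = sub
        counts["UKN1"]["20x"][compound] = counts["UKN1"]["1x"][compound]

    with resources.as_file(_fixture_path("confusion_labels.tsv")) as p:
        labels = pd.read_csv(p, sep="\t")

    with resources.as_file(_fixture_path("operating_points.tsv")) as p:
        op = pd.read_csv(p, sep="\t")
    thresholds = {
        (row["procedure"], row["system"], row["bucket"]): float(row["threshold"])
        for _, row in op.iterrows()
    }

    with resources.as_file(_fixture_path("cytotox_scores.tsv")) as p:
        cs = pd.read_csv(p, sep="\t")
    cytotox_scores = {row["system"]: float(row["score"]) for _, row in cs.iterrows()}

    return FixtureBundle(
        conditions=conditions,
        counts=counts,
        labels=labels,
        thresholds=thresholds,
        cytotox_scores=cytotox_scores,
    )
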