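"""Synthetic study generator.

Produces expression studies with the statistical structure the analysis
assumes: per-compound planted deregulation (many probe sets for teratogens,
none or few for non-teratogens), replicate-level Gaussian noise, additive
batch effects shared with matched controls (so control differencing cancels
them exactly), and cytotoxic conditions that contribute no expression
columns.  Random streams are split per compound, so adding a compound to a
configuration does not perturb the data of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Condition, ExpressionStudy


@dataclass(frozen=True)
class CompoundSpec:
    compound_id: str
    truth: str  # {teratogen, non_teratogen}
    bucket: str = "20x"
    n_deregulated: int = 0
    cytotoxic: bool = False
    n_replicates: int = 3


@dataclass
class SimulationConfig:
    compounds: list[CompoundSpec]
    n_probe_sets: int = 5000
    effect_size_range: tuple[float, float] = (1.2, 3.0)
    noise_sd: float = 0.25
    batch_sd: float = 0.5
    n_batches: int = 4
    n_control_replicates: int = 3
    #: when True the direction of a planted effect is a property of the
    #: probe set (co-regulation across compounds, linearly learnable); when
    #: False each compound draws directions independently
    consistent_signs: bool = True
    #: when True probe sets carry a global sensitivity order and a compound
    #: with n_deregulated=k hits the k most sensitive ones (potency model,
    #: planted sets nested across compounds); when False each compound
    #: samples its planted set uniformly
    nested_deregulation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        for spec in self.compounds:
            if spec.n_deregulated > self.n_probe_sets:
                raise ValueError(
                    f"{spec.compound_id}: n_deregulated "
                    f"{spec.n_deregulated} exceeds n_probe_sets"
                )


@dataclass
class TruthManifest:
    """Planted signed log2 fold-changes per (compound, bucket) condition."""

    planted: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compound_id": c, "bucket": b, "probe_set": p, "planted_log2fc": v}
            for (c, b), series in sorted(self.planted.items())
            for p, v in series.items()
        ]
        return pd.DataFrame(
            rows, columns=["compound_id", "bucket", "probe_set", "planted_log2fc"]
        )


def _compound_rng(seed: int, compound_id: str, bucket: str) -> np.random.Generator:
    # CRC32 gives a stable per-condition stream independent of list order.
    return np.random.default_rng(
        [seed, zlib.crc32(compound_id.encode()), zlib.crc32(bucket.encode())]
    )


def generate_study(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, TruthManifest, list[Condition]]:
    """Generate a study, its ground-truth manifest and its condition list.

    Model per sample: baseline + batch effect + planted effect (non-control
    only) + replicate noise.  Controls within a batch share the batch-effect
    vector with the treated samples matched to them, so the matched-control
    differencing performed downstream recovers planted effects exactly when
    noise is zero.
    """
    probe_ids = [f"PS{i:05d}_at" for i in range(1, config.n_probe_sets + 1)]
    global_rng = np.random.default_rng([config.seed, 0])
    baseline = global_rng.normal(8.0, 1.0, size=config.n_probe_sets)
    batch_effects = {
        b: global_rng.normal(0.0, config.batch_sd, size=config.n_probe_sets)
        for b in range(config.n_batches)
    }
    probe_signs = global_rng.choice([-1.0, 1.0], size=config.n_probe_sets)
    sensitivity_order = global_rng.permutation(config.n_probe_sets)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    manifest = TruthManifest()
    conditions: list[Condition] = []

    # one control replicate set per batch
    control_ids_by_batch: dict[int, list[str]] = {}
    control_rng = np.random.default_rng([config.seed, 1])
    for b in range(config.n_batches):
        ids = []
        for r in range(1, config.n_control_replicates + 1):
            sid = f"CTRL_b{b}_r{r}"
            noise = control_rng.normal(0.0, config.noise_sd, config.n_probe_sets)
            columns[sid] = baseline + batch_effects[b] + noise
            meta_rows.append(
                {
                    "sample_id": sid,
                    "compound_id": "CONTROL",
                    "concentration_label": "1x",
                    "replicate": r,
                    "batch": b,
                    "is_control": True,
                    "matched_controls": [],
                }
            )
            ids.append(sid)
        control_ids_by_batch[b] = ids

    tested_keys = [
        (s.compound_id, s.bucket) for s in config.compounds if not s.cytotoxic
    ]
    batch_of = {key: i % config.n_batches for i, key in enumerate(tested_keys)}
    for spec in config.compounds:
        conditions.append(
            Condition(
                compound_id=spec.compound_id,
                concentration_label=spec.bucket,
                bucket=spec.bucket,
                test_system="SYN",
                truth=spec.truth,
                cytotoxic=spec.cytotoxic,
            )
        )
        if spec.cytotoxic:
            continue
        rng = _compound_rng(config.seed, spec.compound_id, spec.bucket)
        if config.nested_deregulation:
            chosen = sensitivity_order[: spec.n_deregulated]
        else:
            chosen = rng.choice(
                config.n_probe_sets, size=spec.n_deregulated, replace=False
            )
        if config.consistent_signs:
            signs = probe_signs[chosen]
        else:
            signs = rng.choice([-1.0, 1.0], size=spec.n_deregulated)
        lo, hi = config.effect_size_range
        magnitudes = rng.uniform(lo, hi, size=spec.n_deregulated)
        effect = np.zeros(config.n_probe_sets)
        effect[chosen] = signs * magnitudes
        manifest.planted[(spec.compound_id, spec.bucket)] = pd.Series(
            effect[chosen], index=[probe_ids[i] for i in chosen]
        )
        batch = batch_of[(spec.compound_id, spec.bucket)]
        for r in range(1, spec.n_replicates + 1):
            sid = f"{spec.compound_id}_{spec.bucket}_r{r}"
            noise = rng.normal(0.0, config.noise_sd, config.n_probe_sets)
            columns[sid] = baseline + batch_effects[batch] + effect + noise
            meta_rows.append(
                {
                    "sample_id": sid,
                    "compound_id": spec.compound_id,
                    "concentration_label": spec.bucket,
                    "replicate": r,
                    "batch": batch,
                    "is_control": False,
                    "matched_controls": list(control_ids_by_batch[batch]),
                }
            )

    matrix = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_set"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    study = ExpressionStudy(matrix=matrix, samples=samples)
    return study, manifest, conditions


def generate_qpcr(
    genes: list[str],
    planted_ddct: dict[tuple[str, str], float],
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate ddCT values for a gene panel.

    ``planted_ddct`` maps (condition_id, gene) to the planted mean ddCT.
    Returns a long table (condition, gene, replicate, ddct).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    rows = []
    for (condition, gene), mean in sorted(planted_ddct.items()):
        if gene not in genes:
            raise KeyError(f"gene {gene!r} not in the configured panel")
        rng = np.random.default_rng(
            [seed, zlib.crc32(condition.encode()), zlib.crc32(gene.encode())]
        )
        values = mean + rng.normal(0.0, noise_sd, size=n_replicates)
        for r, v in enumerate(values, start=1):
            rows.append(
                {"condition": condition, "gene": gene, "replicate": r, "ddct": v}
            )
    return pd.DataFrame(rows)


def write_truth_manifest(manifest: TruthManifest, path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)
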