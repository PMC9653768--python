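"""Downstream interpretation: condition-mean PCA, Venn partitioning of
significant probe sets across systems, two-level top-gene ranking with
probe-set-to-gene collapse, and Fisher / elim overrepresentation.

Ontology and pathway annotations are user-supplied (term -> probe-set
tables, optional DAG edges); no live database access.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust


@dataclass
class GeneAnnotation:
    """Probe-set -> gene map plus term -> probe-set map and an optional
    acyclic child -> parent term DAG."""

    gene_map: dict[str, str] = field(default_factory=dict)
    term_map: dict[str, set[str]] = field(default_factory=dict)
    dag: nx.DiGraph | None = None  # edges child -> parent


# suffix filter for displayed top lists: _at, _a_at and _s_at only
_DISPLAY_SUFFIX = re.compile(r"(?:_[as])?_at$")
_OTHER_TAG = re.compile(r"_[b-z]_at$")


def keep_probe_for_display(probe_set: str) -> bool:
    if not probe_set.endswith("_at"):
        return False
    tag = re.search(r"_([a-z])_at$", probe_set)
    return tag is None or tag.group(1) in ("a", "s")


def condition_mean_pca(
    diffs_by_condition: dict[tuple[str, str], pd.DataFrame],
    top_k: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """PCA of per-condition replicate-mean expression profiles.

    Returns (explained-variance proportions, condition x component
    coordinates).  ``top_k`` restricts to the k probe sets with highest
    variance across the condition means (e.g. 100).
    """
    if len(diffs_by_condition) < 2:
        raise ValueError("PCA needs at least 2 conditions")
    means = pd.DataFrame(
        {key: df.mean(axis=1) for key, df in sorted(diffs_by_condition.items())}
    )
    if top_k is not None:
        variances = means.var(axis=1, ddof=1)
        keep = sorted(means.index, key=lambda p: (-variances[p], p))[:top_k]
        means = means.loc[keep]
    X = means.to_numpy().T  # conditions x probe sets
    X = X - X.mean(axis=0, keepdims=True)
    total_var = (X**2).sum()
    if total_var == 0:
        raise ValueError("total variance is zero; PCA undefined")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    explained = s**2 / (s**2).sum()
    coords = pd.DataFrame(
        u * s,
        index=pd.MultiIndex.from_tuples(means.columns),
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return explained, coords


def venn_partition(
    sps_by_compound_a: dict[str, set[str]],
    sps_by_compound_b: dict[str, set[str]],
    truths: dict[str, str],
) -> dict[str, set[str]]:
    """Partition teratogen-deregulated probe sets into overlap / A-only /
    B-only; probe sets deregulated exclusively by non-teratogens are
    discarded."""
    union_a: set[str] = set()
    union_b: set[str] = set()
    for compound, probes in sps_by_compound_a.items():
        if truths[compound] == "teratogen":
            union_a |= probes
    for compound, probes in sps_by_compound_b.items():
        if truths[compound] == "teratogen":
            union_b |= probes
    return {
        "overlap": union_a & union_b,
        "A_only": union_a - union_b,
        "B_only": union_b - union_a,
    }


def rank_top_genes(
    fold_changes_by_compound: dict[str, dict[str, float]],
    gene_map: dict[str, str],
    universe: set[str] | None = None,
    second_system: dict[str, dict[str, float]] | None = None,
    absolute_means: bool = True,
    filter_suffixes: bool = True,
) -> pd.DataFrame:
    """Two-level ranked gene list.

    ``fold_changes_by_compound`` maps compound -> {probe set deregulated by
    it -> log2 fold-change}.  Level 1 is the number of deregulating
    compounds (summed across both systems when ``second_system`` is given,
    the 'overlap' context); level 2 is the mean (absolute by default) log2
    fold-change over those compounds.  Only the highest-ranked probe set per
    gene is kept; probe sets absent from ``gene_map`` are retained under
    their own identifier and flagged.
    """
    counts: dict[str, int] = {}
    fcs: dict[str, list[float]] = {}
    systems = [fold_changes_by_compound]
    if second_system is not None:
        systems.append(second_system)
    for system in systems:
        for _, probe_fcs in system.items():
            for probe, fc in probe_fcs.items():
                if universe is not None and probe not in universe:
                    continue
                counts[probe] = counts.get(probe, 0) + 1
                fcs.setdefault(probe, []).append(float(fc))
    rows = []
    for probe, n in counts.items():
        if filter_suffixes and not keep_probe_for_display(probe):
            continue
        values = fcs[probe]
        mean_fc = (
            float(np.mean(np.abs(values)))
            if absolute_means
            else float(np.mean(values))
        )
        rows.append(
            {
                "probe_set": probe,
                "gene": gene_map.get(probe, probe),
                "unmapped": probe not in gene_map,
                "n_compounds": n,
                "mean_log2fc": mean_fc,
            }
        )
    ranked = pd.DataFrame(
        rows,
        columns=["probe_set", "gene", "unmapped", "n_compounds", "mean_log2fc"],
    )
    ranked = ranked.sort_values(
        by=["n_compounds", "mean_log2fc", "probe_set"],
        ascending=[False, False, True],
        kind="stable",
    )
    ranked = ranked.drop_duplicates(subset="gene", keep="first")
    return ranked.reset_index(drop=True)


def _fisher_p(k: int, big_n: int, big_k: int, n: int) -> float:
    """One-sided hypergeometric upper tail: P(X >= k)."""
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def fisher_overrepresentation(
    sps_set: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-term one-sided Fisher (hypergeometric tail) p-values with BH
    adjustment across terms."""
    if not sps_set <= universe:
        raise ValueError("sps_set must be a subset of the universe")
    rows = []
    for term, probes in sorted(term_map.items()):
        in_universe = probes & universe
        if not in_universe:
            warnings.warn(f"term {term!r} has no universe members; skipped")
            continue
        k = len(sps_set & in_universe)
        rows.append(
            {
                "term": term,
                "term_size": len(in_universe),
                "hits": k,
                "p_raw": _fisher_p(k, len(universe), len(in_universe), len(sps_set)),
            }
        )
    result = pd.DataFrame(rows, columns=["term", "term_size", "hits", "p_raw"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
    else:
        result["p_adj"] = []
    return result


def propagate_annotations(
    term_map: dict[str, set[str]], dag: nx.DiGraph
) -> dict[str, set[str]]:
    """Propagate probe-set annotations from each term to all ancestors
    (edges point child -> parent)."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term DAG contains a cycle")
    propagated = {t: set(p) for t, p in term_map.items()}
    for term in nx.topological_sort(dag):  # children before parents
        for parent in dag.successors(term):
            propagated.setdefault(parent, set()).update(
                propagated.get(term, set())
            )
    return propagated


def elim_overrepresentation(
    sps_set: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
    dag: nx.DiGraph | None = None,
    elim_cut: float = 0.01,
) -> pd.DataFrame:
    """Bottom-up ('elim') overrepresentation testing.

    Annotations are propagated to ancestors, then terms are processed most
    specific first; when a term's Fisher p falls strictly below
    ``elim_cut``, its currently-annotated probe sets are removed from all of
    its ancestors before those are tested.  With ``elim_cut`` 0 this reduces
    to plain Fisher testing on the propagated map.
    """
    if dag is None:
        dag = nx.DiGraph()
        dag.add_nodes_from(term_map)
    else:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("term DAG contains a cycle")
        dag = dag.copy()
        dag.add_nodes_from(term_map)
    current = propagate_annotations(term_map, dag)
    rows = []
    for term in nx.topological_sort(dag):  # most specific first
        probes = current.get(term, set()) & universe
        if not probes:
            warnings.warn(f"term {term!r} has no universe members; skipped")
            continue
        k = len(sps_set & probes)
        p = _fisher_p(k, len(universe), len(probes), len(sps_set))
        rows.append(
            {"term": term, "term_size": len(probes), "hits": k, "p_raw": p}
        )
        if p < elim_cut:
            for ancestor in nx.descendants(dag, term):
                if ancestor in current:
                    current[ancestor] -= current.get(term, set())
    result = pd.DataFrame(rows, columns=["term", "term_size", "hits", "p_raw"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
    else:
        result["p_adj"] = []
    return result


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, probe_set) -> term map."""
    df = pd.read_csv(path, sep="\t", header=0)
    term_col, probe_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row[term_col]), set()).add(str(row[probe_col]))
    return out


def read_dag(path) -> nx.DiGraph:
    """Two-column TSV (child, parent) -> child->parent DiGraph."""
    df = pd.read_csv(path, sep="\t", header=0)
    child_col, parent_col = df.columns[:2]
    dag = nx.DiGraph()
    for _, row in df.iterrows():
        dag.add_edge(str(row[child_col]), str(row[parent_col]))
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term DAG contains a cycle")
    return dag


def read_gmt(path) -> dict[str, set[str]]:
    """GMT import for flat gene sets (name, description, members...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out
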