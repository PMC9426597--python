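"""Sequence similarity networks and their connected-component clusters.

Proteins are nodes; an edge joins two proteins when the alignment score
``-log10(E)`` of their optimal local alignment reaches a threshold
(default 70, the value conventionally glossed as roughly 90% amino-acid
identity for proteins of this size).  Clusters are the connected
components, numbered by descending size with deterministic tie-breaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import SequenceRecord
from .orf_search import AlignmentResult, SearchParams, local_align

logger = logging.getLogger("baiminer")

SCORE_CLAMP = 300.0


@dataclass(frozen=True)
class SSNGraph:
    """Undirected similarity graph; edges stored with id_a < id_b."""

    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], float]
    threshold: float
    alignments: Mapping[tuple[str, str], AlignmentResult] | None = None

    def __post_init__(self) -> None:
        for (a, b), score in self.edges.items():
            if a >= b:
                raise ValueError(f"edge ({a}, {b}) not stored with id_a < id_b")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if score < self.threshold:
                raise ValueError(f"edge ({a}, {b}) below build threshold")


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: int
    members: frozenset[str]
    min_within_identity: float
    contains_query: bool

    def __post_init__(self) -> None:
        if self.cluster_id < 1 or not self.members:
            raise ValueError("cluster_id must be >= 1 and members non-empty")


def alignment_score(aln: AlignmentResult) -> float:
    """EFI-EST-style edge weight: ``-log10(E)``, clamped at 300."""
    if aln.e_value <= 0:
        raise ValueError("e_value must be positive")
    return min(-math.log10(aln.e_value), SCORE_CLAMP)


def all_vs_all(
    seqs: Sequence[SequenceRecord], params: SearchParams = SearchParams()
) -> dict[tuple[str, str], AlignmentResult]:
    """Every unordered pair aligned once; keys are (min_id, max_id).

    The E-value search space is the pairwise product of lengths
    (``db_size`` is ignored) so the graph does not depend on input order
    or batch composition.
    """
    from dataclasses import replace

    pair_params = replace(params, db_size=0)
    out: dict[tuple[str, str], AlignmentResult] = {}
    for a, b in combinations(sorted(seqs, key=lambda r: r.id), 2):
        out[(a.id, b.id)] = local_align(a, b, pair_params)
    return out


def build_ssn(
    seqs: Sequence[SequenceRecord],
    params: SearchParams = SearchParams(),
    threshold: float = 70.0,
    alignments: Mapping[tuple[str, str], AlignmentResult] | None = None,
) -> SSNGraph:
    """All-vs-all alignment, keeping edges with score >= ``threshold``."""
    if len(seqs) < 2:
        raise ValueError("build_ssn needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if alignments is None:
        alignments = all_vs_all(seqs, params)
    edges = {}
    for pair, aln in alignments.items():
        score = alignment_score(aln)
        if score >= threshold:
            edges[pair] = score
    logger.info(
        "build_ssn: %d nodes, %d edges at threshold %g", len(ids), len(edges), threshold
    )
    return SSNGraph(frozenset(ids), edges, threshold, alignments=alignments)


def components(
    graph: SSNGraph, query_ids: frozenset[str] = frozenset()
) -> list[ClusterAssignment]:
    """Connected components as clusters.

    Clusters are numbered 1..k by descending size, ties broken by the
    lexicographically smallest member id.  Singletons are retained.
    ``min_within_identity`` is the minimum pairwise percent identity over
    all member pairs (100 for singletons), taken from the build-time
    alignments when available.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    out = []
    for i, members in enumerate(comps, start=1):
        min_ident = 100.0
        if graph.alignments is not None and len(members) > 1:
            min_ident = min(
                graph.alignments[pair].pct_identity
                for pair in combinations(sorted(members), 2)
            )
        out.append(
            ClusterAssignment(
                cluster_id=i,
                members=members,
                min_within_identity=min_ident,
                contains_query=bool(members & query_ids),
            )
        )
    return out


def cluster_report(
    clusters: Sequence[ClusterAssignment],
    alignments: Mapping[tuple[str, str], AlignmentResult] | None = None,
) -> pd.DataFrame:
    """One row per cluster, sorted by size descending.

    The headline statistic (the global minimum within-cluster identity
    over non-singleton clusters) is attached as ``df.attrs`` entry
    ``min_within_identity``.
    """
    rows = []
    for c in clusters:
        min_ident = c.min_within_identity
        if alignments is not None and len(c.members) > 1:
            min_ident = min(
                alignments[pair].pct_identity
                for pair in combinations(sorted(c.members), 2)
            )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "size": len(c.members),
                "min_within_identity": round(min_ident, 2),
                "contains_query": c.contains_query,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["size", "cluster_id"], ascending=[False, True], ignore_index=True
    )
    multi = df[df["size"] > 1]
    df.attrs["min_within_identity"] = (
        float(multi["min_within_identity"].min()) if len(multi) else 100.0
    )
    return df


def write_edgelist(graph: SSNGraph, path: str | Path) -> None:
    rows = [
        {"id_a": a, "id_b": b, "alignment_score": round(s, 2)}
        for (a, b), s in sorted(graph.edges.items())
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "alignment_score"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: SSNGraph, path: str | Path) -> None:
    """GraphML export for external viewers (Cytoscape-style use)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    for (a, b), s in sorted(graph.edges.items()):
        g.add_edge(a, b, alignment_score=float(s))
    nx.write_graphml(g, str(path))
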