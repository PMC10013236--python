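"""A-B-C open discovery over the CUI knowledge graph.

Vertices are concept identifiers and a directed edge i -> j exists when at
least one triple has subject i and object j (predicates are ignored; edges
are untyped and binary).  With sparse adjacency matrix A, its square
A^2 = (s_ij) counts walks of length two, so any ordered pair (i, j) with
s_ij > 0 but a_ij = 0 is a one-step *candidate hidden knowledge pair*
(CHKP): A and C are unconnected but linked through at least one B.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .triples import Triple

__all__ = [
    "KnowledgeGraph",
    "CHKPSet",
    "build_graph",
    "square_adjacency",
    "extract_chkps",
    "linking_terms",
    "write_chkps",
]


class KnowledgeGraph:
    """Directed binary graph over CUIs with a stable vertex order.

    Vertices are kept in sorted order so adjacency-matrix indices are
    reproducible across runs and platforms.
    """

    def __init__(self, graph: nx.DiGraph):
        self._g = graph
        self.vertices: list[str] = sorted(graph.nodes)
        self._index = {v: i for i, v in enumerate(self.vertices)}

    @property
    def nx_graph(self) -> nx.DiGraph:
        return self._g

    def __len__(self) -> int:
        return len(self.vertices)

    def __contains__(self, cui: str) -> bool:
        return cui in self._index

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency in the stable vertex order (CSR, int64)."""
        A = nx.to_scipy_sparse_array(self._g, nodelist=self.vertices, dtype=np.int64,
                                     format="csr")
        A.data[:] = 1  # binary: duplicate relations already collapsed by DiGraph
        return sp.csr_matrix(A)

    def mean_in_degree(self) -> float:
        n = len(self)
        return self.n_edges / n if n else 0.0

    mean_out_degree = mean_in_degree  # sum of in-degrees = sum of out-degrees


@dataclass
class CHKPSet:
    """Ordered candidate pairs with their linking-term counts (s_ij)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    linking_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def sorted_pairs(self) -> list[tuple[str, str]]:
        """Descending linking count, then lexicographic."""
        return sorted(self.pairs, key=lambda p: (-self.linking_counts.get(p, 0), p))


def build_graph(triples: Iterable[Triple]) -> KnowledgeGraph:
    """Directed edge subject -> object per triple; duplicates collapse."""
    g = nx.DiGraph()
    for t in triples:
        g.add_edge(t.subject_cui, t.object_cui)
    return KnowledgeGraph(g)


def square_adjacency(graph: KnowledgeGraph) -> sp.csr_matrix:
    """Exact integer counts of length-two walks: A @ A on the sparse matrix."""
    A = graph.adjacency()
    return (A @ A).tocsr()


def extract_chkps(graph: KnowledgeGraph, symmetric_suppression: bool = False) -> CHKPSet:
    """All ordered pairs (i, j), i != j, with s_ij > 0 and a_ij = 0.

    Self-pairs are excluded (a mutual edge pair makes s_ii > 0 but a
    self-CHKP is meaningless).  With ``symmetric_suppression`` on, a known
    reverse edge j -> i also suppresses the pair; by default only the stated
    condition — a zero in the original adjacency matrix — applies.
    """
    if len(graph) == 0:
        return CHKPSet()
    A = graph.adjacency().tocoo()
    edges = set(zip(A.row.tolist(), A.col.tolist()))
    candidates = square_adjacency(graph).tocoo()
    out = CHKPSet()
    for i, j, count in zip(candidates.row.tolist(), candidates.col.tolist(),
                           candidates.data.tolist()):
        if count <= 0 or i == j:
            continue
        if (i, j) in edges:
            continue
        if symmetric_suppression and (j, i) in edges:
            continue
        pair = (graph.vertices[i], graph.vertices[j])
        out.pairs.add(pair)
        out.linking_counts[pair] = int(count)
    return out


def linking_terms(graph: KnowledgeGraph, source: str, target: str) -> set[str]:
    """All B with edges source -> B and B -> target (closed discovery)."""
    g = graph.nx_graph
    for v in (source, target):
        if v not in graph:
            raise KeyError(f"unknown vertex {v!r}")
    return set(g.successors(source)) & set(g.predecessors(target))


def write_chkps(chkps: CHKPSet, path: str | Path) -> None:
    """TSV export: source_cui, target_cui, linking_count; count-desc order."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source_cui", "target_cui", "linking_count"])
        for pair in chkps.sorted_pairs():
            writer.writerow([pair[0], pair[1], chkps.linking_counts.get(pair, 0)])
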