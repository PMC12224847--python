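"""Thresholded cosine-similarity graphs and the modularity-driven grid search.

Nodes are patients; an undirected edge joins two patients whenever the cosine
similarity of their standardized feature vectors reaches the threshold.  The
adjacency used for modularity is binary (threshold selection already encodes
the weight information); a weighted variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "SimilarityGraph",
    "GridSearchResult",
    "NoStructureError",
    "cosine_similarity",
    "build_graph",
    "grid_search",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.30, 0.70 + 1e-9, 0.05), 2))
DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.50, 1.50 + 1e-9, 0.05), 2))


class NoStructureError(RuntimeError):
    """Raised when every grid combination yields an edgeless graph."""


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Dot product over the product of Euclidean norms; symmetric, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be 1-D and of equal length >= 1")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SimilarityGraph:
    """Undirected graph: node ids plus {(i, j): similarity} with i < j."""

    node_ids: list[str]
    edges: dict[tuple[int, int], float]
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=float)
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def n_retained_nodes(self) -> int:
        """Number of non-isolated nodes."""
        seen: set[int] = set()
        for (i, j) in self.edges:
            seen.add(i)
            seen.add(j)
        return len(seen)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j) in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def neighbor_weights(self, weighted: bool = False) -> list[dict[int, float]]:
        nbrs: list[dict[int, float]] = [dict() for _ in range(self.n_nodes)]
        for (i, j), sim in self.edges.items():
            w = sim if weighted else 1.0
            nbrs[i][j] = w
            nbrs[j][i] = w
        return nbrs

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for (i, j), sim in self.edges.items():
            g.add_edge(self.node_ids[i], self.node_ids[j], similarity=float(sim))
        return g

    def export_edgelist(self, path: str | Path) -> None:
        rows = [
            (self.node_ids[i], self.node_ids[j], sim)
            for (i, j), sim in sorted(self.edges.items())
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "similarity"]).to_csv(
            path, sep="\t", index=False
        )

    def export_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


def build_graph(fm: FeatureMatrix | np.ndarray, threshold: float, node_ids: list[str] | None = None) -> SimilarityGraph:
    """Evaluate all unordered pairs; keep an edge iff similarity >= threshold.

    Zero-norm rows have undefined similarity and contribute no edges; isolated
    nodes stay in the node list.
    """
    if threshold < -1.0:
        # thresholds above 1 are allowed and trivially yield an edgeless graph
        raise ValueError(f"threshold must be >= -1, got {threshold}")
    if isinstance(fm, FeatureMatrix):
        values = fm.values
        ids = list(fm.row_ids)
    else:
        values = np.asarray(fm, dtype=float)
        ids = node_ids if node_ids is not None else [str(i) for i in range(len(values))]
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    norms = np.linalg.norm(values, axis=1)
    ok = norms > 0
    unit = np.zeros_like(values)
    unit[ok] = values[ok] / norms[ok, None]
    sims = unit @ unit.T
    np.clip(sims, -1.0, 1.0, out=sims)
    edges: dict[tuple[int, int], float] = {}
    iu, ju = np.triu_indices(n, k=1)
    mask = (sims[iu, ju] >= threshold) & ok[iu] & ok[ju]
    for i, j, s in zip(iu[mask], ju[mask], sims[iu[mask], ju[mask]]):
        edges[(int(i), int(j))] = float(s)
    return SimilarityGraph(node_ids=ids, edges=edges, threshold=float(threshold))


@dataclass
class GridSearchResult:
    """Argmax cell of the (threshold, resolution) grid plus the full table."""

    threshold: float
    resolution: float
    modularity: float          # Q of the detected partition, evaluated at gamma=1
    modularity_at_gamma: float  # same partition, evaluated at gamma=resolution
    n_retained_nodes: int
    table: pd.DataFrame = field(repr=False)
    partition: "object | None" = field(default=None, repr=False)
    graph: SimilarityGraph | None = field(default=None, repr=False)


def grid_search(
    fm: FeatureMatrix,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    resolutions: Iterable[float] = DEFAULT_RESOLUTIONS,
    seed: int = 0,
    weighted: bool = False,
) -> GridSearchResult:
    """Exhaustive sweep; Louvain at each cell; argmax of Q at gamma=1.

    Ties break by higher retained-node count, then lower threshold, then
    lower resolution.  Q for cross-cell comparison is always evaluated at
    gamma=1 on the detected partition; gamma only shapes the Louvain
    objective.
    """
    from .community import louvain, modularity

    thresholds = list(thresholds)
    resolutions = list(resolutions)
    if not thresholds or not resolutions:
        raise ValueError("grids must be non-empty")

    rows = []
    best = None  # (Q, retained, -threshold, -resolution) maximized
    best_cell = None
    for t in thresholds:
        graph = build_graph(fm, t)
        for r in resolutions:
            if graph.n_edges == 0:
                rows.append((t, r, np.nan, np.nan, 0, 0))
                continue
            part = louvain(graph, gamma=r, seed=seed, weighted=weighted)
            q1 = modularity(graph, part.assignment, gamma=1.0, weighted=weighted)
            qg = part.modularity
            rows.append((t, r, q1, qg, graph.n_retained_nodes, part.n_communities))
            key = (q1, graph.n_retained_nodes, -t, -r)
            if best is None or key > best:
                best = key
                best_cell = (t, r, q1, qg, graph, part)
    table = pd.DataFrame(
        rows,
        columns=["threshold", "resolution", "modularity", "modularity_at_gamma",
                 "n_retained_nodes", "n_communities"],
    )
    if best_cell is None:
        raise NoStructureError("every grid combination produced an edgeless graph")
    t, r, q1, qg, graph, part = best_cell
    return GridSearchResult(
        threshold=float(t),
        resolution=float(r),
        modularity=float(q1),
        modularity_at_gamma=float(qg),
        n_retained_nodes=graph.n_retained_nodes,
        table=table,
        partition=part,
        graph=graph,
    )
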