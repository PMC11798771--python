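"""Spatial adjacency graphs for areal (state-level) random effects.

An :class:`AdjacencyGraph` is a symmetric, weighted, self-loop-free
neighbourhood structure over areal units (states).  It backs the Besag
intrinsic CAR prior: the prior's rank deficiency equals the number of
connected components, so the graph tracks its components and exposes the
weighted Laplacian together with its generalized log-determinant (product
of the nonzero eigenvalues), which is constant per graph and cached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["AdjacencyGraph", "make_lattice_graph"]


@dataclass
class AdjacencyGraph:
    """Symmetric weighted neighbourhood structure over areal units.

    Parameters
    ----------
    labels : sequence of str
        Node labels in index order (index ``i`` of any spatial-effect
        vector refers to ``labels[i]``).
    edges : sequence of (int, int, float)
        Undirected edges as index pairs with positive weights.  Each
        unordered pair appears once; self-loops are rejected.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[int, int, float], ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        n = len(self.labels)
        if n == 0:
            raise ValueError("graph must have at least one node")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate node labels")
        seen: set[tuple[int, int]] = set()
        canon = []
        for a, b, w in self.edges:
            a, b, w = int(a), int(b), float(w)
            if a == b:
                raise ValueError(f"self-loop on node {self.labels[a]!r}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) out of range")
            if w < 0:
                raise ValueError("edge weights must be >= 0")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            canon.append((key[0], key[1], w))
        self.edges = tuple(sorted(canon))

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def components(self) -> list[np.ndarray]:
        """Connected components as sorted index arrays."""
        if "components" not in self._cache:
            comps = nx.connected_components(self.to_networkx())
            self._cache["components"] = [
                np.array(sorted(c), dtype=int) for c in sorted(comps, key=min)
            ]
        return self._cache["components"]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def component_index(self) -> np.ndarray:
        """Per-node component label (0-based)."""
        out = np.empty(self.n_nodes, dtype=int)
        for k, comp in enumerate(self.components):
            out[comp] = k
        return out

    @property
    def isolated_nodes(self) -> np.ndarray:
        """Nodes with no neighbours (allowed, but flagged by callers)."""
        deg = np.zeros(self.n_nodes)
        for a, b, w in self.edges:
            deg[a] += 1
            deg[b] += 1
        return np.flatnonzero(deg == 0)

    def neighbours(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    # ------------------------------------------------------------------
    def laplacian(self) -> np.ndarray:
        """Dense weighted graph Laplacian L = D - W."""
        if "laplacian" not in self._cache:
            n = self.n_nodes
            L = np.zeros((n, n))
            for a, b, w in self.edges:
                L[a, b] -= w
                L[b, a] -= w
                L[a, a] += w
                L[b, b] += w
            self._cache["laplacian"] = L
        return self._cache["laplacian"]

    def laplacian_eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of the Laplacian."""
        if "eig" not in self._cache:
            self._cache["eig"] = np.linalg.eigh(self.laplacian())
        return self._cache["eig"]

    def logdet_plus(self) -> float:
        """Generalized log-determinant: sum of log of nonzero eigenvalues.

        The Laplacian has rank ``n_nodes - n_components``; exactly
        ``n_components`` eigenvalues are (numerically) zero.
        """
        if "logdet" not in self._cache:
            vals, _ = self.laplacian_eig()
            nz = vals[self.n_components:]
            if np.any(nz <= 0):
                raise np.linalg.LinAlgError("Laplacian rank below n - c")
            self._cache["logdet"] = float(np.sum(np.log(nz)))
        return self._cache["logdet"]

    def quadratic_form(self, s: np.ndarray) -> float:
        """Pairwise-difference form sum_{i~j} w_ij (s_i - s_j)^2 = s'Ls."""
        s = np.asarray(s, dtype=float)
        if s.shape != (self.n_nodes,):
            raise ValueError("field length does not match graph")
        q = 0.0
        for a, b, w in self.edges:
            q += w * (s[a] - s[b]) ** 2
        return float(q)

    # ------------------------------------------------------------------
    # I/O: edge-list CSV (node_a,node_b,weight) and JSON adjacency.
    # Nodes are strings mapped to contiguous indices in sorted order.
    @classmethod
    def from_edge_frame(cls, frame: pd.DataFrame,
                        extra_nodes: Sequence[str] = ()) -> "AdjacencyGraph":
        cols = [c.strip() for c in frame.columns]
        frame = frame.set_axis(cols, axis=1)
        if not {"node_a", "node_b"}.issubset(cols):
            raise ValueError("edge list needs node_a,node_b[,weight] columns")
        if "weight" not in frame:
            frame = frame.assign(weight=1.0)
        names = sorted(set(frame["node_a"].astype(str))
                       | set(frame["node_b"].astype(str))
                       | {str(x) for x in extra_nodes})
        index = {name: i for i, name in enumerate(names)}
        edges = [(index[str(a)], index[str(b)], float(w))
                 for a, b, w in frame[["node_a", "node_b", "weight"]].itertuples(index=False)]
        return cls(tuple(names), tuple(edges))

    @classmethod
    def from_edge_csv(cls, path: str | Path) -> "AdjacencyGraph":
        return cls.from_edge_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "AdjacencyGraph":
        """JSON adjacency: {"node": [["neighbour", weight] | "neighbour", ...]}."""
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                source = json.load(fh)
        names = sorted({str(k) for k in source}
                       | {str(e[0] if isinstance(e, (list, tuple)) else e)
                          for v in source.values() for e in v})
        index = {name: i for i, name in enumerate(names)}
        pairs: dict[tuple[int, int], float] = {}
        for node, neigh in source.items():
            for entry in neigh:
                if isinstance(entry, (list, tuple)):
                    other, w = str(entry[0]), float(entry[1])
                else:
                    other, w = str(entry), 1.0
                a, b = index[str(node)], index[other]
                key = (min(a, b), max(a, b))
                if key in pairs and pairs[key] != w:
                    raise ValueError(f"conflicting weights for edge {key}")
                pairs[key] = w
        edges = tuple((a, b, w) for (a, b), w in pairs.items())
        return cls(tuple(names), edges)

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.labels[a], self.labels[b], w) for a, b, w in self.edges],
            columns=["node_a", "node_b", "weight"],
        )

    def to_edge_csv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, index=False)


def make_lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency ``rows x cols`` lattice with unit weights.

    A stand-in for a state contiguity map: connected (one component)
    for any positive dimensions.  Node labels are zero-padded ``"rIIIcJJJ"``
    strings and the index order is row-major.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    # zero-padded labels so sorted order (used by file round-trips) is row-major
    labels = [f"r{i:03d}c{j:03d}" for i in range(rows) for j in range(cols)]
    idx = lambda i, j: i * cols + j
    edges = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                edges.append((idx(i, j), idx(i, j + 1), 1.0))
            if i + 1 < rows:
                edges.append((idx(i, j), idx(i + 1, j), 1.0))
    return AdjacencyGraph(tuple(labels), tuple(edges))
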