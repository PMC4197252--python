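"""Area adjacency structures for intrinsic-CAR spatial priors.

Small-area survival models need to know which areas share a border: the
intrinsic conditional autoregressive (ICAR) prior penalises squared
differences between the random effects of adjacent areas.  This module
builds adjacency structures from regular lattices (the synthetic stand-in
for a real administrative map), reads and writes them as plain-text edge
lists or WinBUGS-style ``num``/``adj`` vectors, and exposes the graph
quantities the models need: binary weights, neighbour counts, connected
components and a graph colouring for blocked MCMC updates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["AdjacencyStructure", "lattice_adjacency", "read_adjacency", "write_adjacency"]


@dataclass
class AdjacencyStructure:
    """Symmetric binary adjacency over ``n_areas`` areas labelled 0..J-1.

    Parameters
    ----------
    n_areas : int
        Number of areas J.
    edges : ndarray of shape (E, 2)
        Unique undirected edges with ``edges[:, 0] < edges[:, 1]``.
    """

    n_areas: int
    edges: np.ndarray

    neighbor_counts: np.ndarray = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= self.n_areas):
            bad = edges[(edges < 0).any(axis=1) | (edges >= self.n_areas).any(axis=1)][0]
            raise ValueError(f"edge {tuple(bad)} references an area outside 0..{self.n_areas - 1}")
        if edges.size and (edges[:, 0] == edges[:, 1]).any():
            raise ValueError("self-loops are not allowed (omega_jj = 0)")
        # canonicalise: sort endpoints, drop duplicates
        edges = np.sort(edges, axis=1)
        edges = np.unique(edges, axis=0)
        self.edges = edges
        counts = np.zeros(self.n_areas, dtype=np.int64)
        np.add.at(counts, edges.ravel(), 1)
        self.neighbor_counts = counts
        g = self.to_networkx()
        labels = np.empty(self.n_areas, dtype=np.int64)
        for c, comp in enumerate(nx.connected_components(g)):
            labels[list(comp)] = c
        self.component_labels = labels

    # -- derived graph quantities -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbours (excluded from the ICAR form)."""
        return np.flatnonzero(self.neighbor_counts == 0)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 weight matrix omega."""
        w = np.zeros((self.n_areas, self.n_areas))
        if self.n_edges:
            w[self.edges[:, 0], self.edges[:, 1]] = 1.0
            w[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return w

    def icar_precision(self) -> np.ndarray:
        """Unscaled ICAR precision Q = D - W (singular by construction)."""
        return np.diag(self.neighbor_counts.astype(float)) - self.weight_matrix()

    def coloring(self) -> list[np.ndarray]:
        """Partition of areas into independent sets (no within-set edges).

        Areas in the same colour class are conditionally independent in the
        ICAR prior given the rest, so a blocked Metropolis sweep may update a
        whole class at once.
        """
        cols = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(cols.values()) + 1 if cols else 0
        return [np.array(sorted(j for j, c in cols.items() if c == col)) for col in range(k)]

    def connected_components(self) -> np.ndarray:
        """Component label per area (alias for :attr:`component_labels`)."""
        return self.component_labels

    # -- I/O ----------------------------------------------------------------------

    def to_winbugs(self) -> dict:
        """WinBUGS ``num``/``adj`` dialect: neighbour counts and concatenated
        1-based neighbour indices, ordered by area."""
        neigh: list[list[int]] = [[] for _ in range(self.n_areas)]
        for j, k in self.edges:
            neigh[j].append(int(k) + 1)
            neigh[k].append(int(j) + 1)
        adj = [i for lst in neigh for i in sorted(lst)]
        return {"num": [int(c) for c in self.neighbor_counts], "adj": adj}

    @classmethod
    def from_winbugs(cls, num: list[int], adj: list[int]) -> "AdjacencyStructure":
        if sum(num) != len(adj):
            raise ValueError(f"sum(num) = {sum(num)} but adj has {len(adj)} entries")
        edges = []
        pos = 0
        for j, nj in enumerate(num):
            for k1 in adj[pos : pos + nj]:
                k = k1 - 1
                if not 0 <= k < len(num):
                    raise ValueError(f"adjacency index {k1} out of range for {len(num)} areas")
                if j < k:
                    edges.append((j, k))
            pos += nj
        return cls(len(num), np.array(edges, dtype=np.int64).reshape(-1, 2))


def lattice_adjacency(rows: int, cols: int, rule: str = "rook") -> AdjacencyStructure:
    """Regular ``rows`` x ``cols`` lattice with rook (4-) or queen (8-)
    neighbourhoods; cell (r, c) is area ``r * cols + c``."""
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    edges = []
    for r in range(rows):
        for c in range(cols):
            j = r * cols + c
            if c + 1 < cols:
                edges.append((j, j + 1))
            if r + 1 < rows:
                edges.append((j, j + cols))
            if rule == "queen" and r + 1 < rows:
                if c + 1 < cols:
                    edges.append((j, j + cols + 1))
                if c - 1 >= 0:
                    edges.append((j, j + cols - 1))
    out = AdjacencyStructure(rows * cols, np.array(edges, dtype=np.int64).reshape(-1, 2))
    if out.n_edges == 0:
        warnings.warn("lattice has a single cell: the area is an island", stacklevel=2)
    return out


def read_adjacency(path: str, format: str = "edge_list", n_areas: int | None = None) -> AdjacencyStructure:
    """Read an adjacency structure from disk.

    ``edge_list``: two whitespace-separated integer columns (0-based area
    ids), ``#`` comments allowed.  Asymmetric listings are symmetrised with a
    warning.  ``winbugs_adj``: JSON object with ``num`` and ``adj`` vectors
    (1-based, as WinBUGS writes them).
    """
    if format == "edge_list":
        directed = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two integers, got {line!r}")
                directed.add((int(parts[0]), int(parts[1])))
        doubled = sum((k, j) in directed for j, k in directed)
        if 0 < doubled < len(directed):
            # file mixes one-directional and two-directional listings
            warnings.warn(f"{path}: edge list is not symmetric; symmetrising", stacklevel=2)
        pairs = sorted({(min(j, k), max(j, k)) for j, k in directed})
        arr = np.array(pairs, dtype=np.int64).reshape(-1, 2)
        n = n_areas if n_areas is not None else (int(arr.max()) + 1 if arr.size else 0)
        return AdjacencyStructure(n, arr)
    if format == "winbugs_adj":
        with open(path) as fh:
            obj = json.load(fh)
        return AdjacencyStructure.from_winbugs(obj["num"], obj["adj"])
    raise ValueError(f"unknown adjacency format {format!r}")


def write_adjacency(adj: AdjacencyStructure, path: str, format: str = "edge_list") -> None:
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write("# edge list, 0-based area ids\n")
            for j, k in adj.edges:
                fh.write(f"{j} {k}\n")
    elif format == "winbugs_adj":
        with open(path, "w") as fh:
            json.dump(adj.to_winbugs(), fh)
    else:
        raise ValueError(f"unknown adjacency format {format!r}")
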