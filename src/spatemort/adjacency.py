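"""District neighbourhood graphs for spatial smoothing.

The spatial prior borrows strength between neighbouring districts, so every
model needs a symmetric adjacency structure.  Real analyses derive it from
shared boundaries; synthetic studies use a rook-adjacency lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbourhood structure on ``n_units`` areal units.

    Edges are unordered pairs of 0-based unit indices with no self-loops.
    """

    n_units: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        seen = set()
        norm = []
        for i, j in self.edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop on unit {i}")
            if not (0 <= i < self.n_units and 0 <= j < self.n_units):
                raise ValueError(f"edge ({i},{j}) out of range for {self.n_units} units")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            norm.append(key)
        object.__setattr__(self, "edges", tuple(sorted(norm)))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_counts(self) -> np.ndarray:
        deg = np.zeros(self.n_units, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian D - A, the precision structure of the ICAR prior."""
        q = np.zeros((self.n_units, self.n_units))
        for i, j in self.edges:
            q[i, i] += 1.0
            q[j, j] += 1.0
            q[i, j] -= 1.0
            q[j, i] -= 1.0
        return q

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_units))
        g.add_edges_from(self.edges)
        return nx.is_connected(g)


def make_grid_adjacency(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-adjacency graph on an ``n_rows`` x ``n_cols`` lattice.

    Units are numbered row-major; each interior cell has four neighbours.
    The edge count is ``n_rows*(n_cols-1) + n_cols*(n_rows-1)``.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            u = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((u, u + 1))
            if r + 1 < n_rows:
                edges.append((u, u + n_cols))
    return AdjacencyGraph(n_rows * n_cols, tuple(edges))


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> None:
    """Write an edge list, one ``i j`` pair (0-based) per line."""
    path = Path(path)
    lines = [f"# n_units {graph.n_units}"]
    lines += [f"{i} {j}" for i, j in graph.edges]
    path.write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> AdjacencyGraph:
    """Read an edge-list file written by :func:`write_adjacency`.

    A leading ``# n_units N`` comment fixes the unit count; otherwise it is
    inferred as ``max index + 1``.
    """
    path = Path(path)
    n_units = None
    edges = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "n_units":
                n_units = int(parts[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'i j', got {line!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer unit index") from exc
        edges.append((i, j))
    if n_units is None:
        n_units = max((max(e) for e in edges), default=0) + 1
    return AdjacencyGraph(n_units, tuple(edges))
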