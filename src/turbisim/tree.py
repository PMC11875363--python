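"""Backbone tree and boundary containers, with SWC / JSON serialization.

The turbinate backbone is a one-dimensional elastic tree of nodes embedded
in the plane.  For speed the tree is stored as flat arrays (positions,
parent indices, birth times) with capacity doubling; a :mod:`networkx` view
is available for graph algorithms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["Node", "BackboneTree", "BoundaryState"]


@dataclass(frozen=True)
class Node:
    """A single backbone node: position, creation time and id."""

    id: int
    position: np.ndarray
    birth_time: int


class BackboneTree:
    """Rooted tree of nodes in the plane.

    Node 0 is the root, fixed to the boundary; every other node stores the
    index of its parent.  Chain neighbours of a node are its parent and its
    children.
    """

    def __init__(self, positions, parents, birth_times):
        positions = np.asarray(positions, dtype=np.float64)
        parents = np.asarray(parents, dtype=np.int64)
        birth_times = np.asarray(birth_times, dtype=np.int64)
        n = len(positions)
        if positions.shape != (n, 2):
            raise ValueError("positions must be (n, 2)")
        if len(parents) != n or len(birth_times) != n:
            raise ValueError("array length mismatch")
        if n == 0:
            raise ValueError("tree must contain at least the root")
        if parents[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if n > 1 and not np.all((parents[1:] >= 0) & (parents[1:] < np.arange(1, n))):
            raise ValueError("parents must reference previously created nodes")
        if not np.all(np.isfinite(positions)):
            raise ValueError("positions must be finite")
        if np.any(birth_times < 0):
            raise ValueError("birth times must be non-negative")
        cap = max(16, n)
        self._pos = np.empty((cap, 2), dtype=np.float64)
        self._parent = np.empty(cap, dtype=np.int64)
        self._birth = np.empty(cap, dtype=np.int64)
        self._degree = np.zeros(cap, dtype=np.int64)
        self._pos[:n] = positions
        self._parent[:n] = parents
        self._birth[:n] = birth_times
        self.n = n
        counts = np.bincount(parents[1:], minlength=n) if n > 1 else np.zeros(n, int)
        self._degree[:n] = counts
        self._degree[1:n] += 1  # each non-root has one parent edge

    # -- array views -------------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        return self._pos[: self.n]

    @property
    def parents(self) -> np.ndarray:
        return self._parent[: self.n]

    @property
    def birth_times(self) -> np.ndarray:
        return self._birth[: self.n]

    @property
    def degrees(self) -> np.ndarray:
        return self._degree[: self.n]

    @property
    def root_id(self) -> int:
        return 0

    def __len__(self) -> int:
        return self.n

    def node(self, i: int) -> Node:
        if not 0 <= i < self.n:
            raise KeyError(i)
        return Node(i, self._pos[i].copy(), int(self._birth[i]))

    def copy(self) -> "BackboneTree":
        return BackboneTree(
            self.positions.copy(), self.parents.copy(), self.birth_times.copy()
        )

    # -- growth ------------------------------------------------------------

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n + extra
        cap = len(self._parent)
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("_pos", "_parent", "_birth", "_degree"):
            old = getattr(self, name)
            shape = (cap,) + old.shape[1:]
            new = np.zeros(shape, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def add_node(self, parent: int, position, birth_time: int) -> int:
        if not 0 <= parent < self.n:
            raise KeyError(parent)
        self._ensure_capacity(1)
        i = self.n
        self._pos[i] = position
        self._parent[i] = parent
        self._birth[i] = birth_time
        self._degree[i] = 1
        self._degree[parent] += 1
        self.n += 1
        return i

    # -- structure queries -------------------------------------------------

    def tips(self) -> np.ndarray:
        """Indices of branch tips: degree-1 nodes other than the root."""
        idx = np.nonzero(self.degrees == 1)[0]
        return idx[idx != 0]

    def leaf_count(self) -> int:
        return len(self.tips())

    def chain_neighbors(self, i: int) -> list[int]:
        """Parent and children of node ``i``."""
        out = []
        if i != 0:
            out.append(int(self._parent[i]))
        out.extend(int(j) for j in np.nonzero(self.parents == i)[0])
        return out

    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Chain-neighbour adjacency in CSR form (indptr, indices)."""
        n = self.n
        deg = self.degrees
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.empty(indptr[-1], dtype=np.int64)
        fill = indptr[:-1].copy()
        par = self.parents
        for c in range(1, n):
            p = par[c]
            indices[fill[c]] = p
            fill[c] += 1
            indices[fill[p]] = c
            fill[p] += 1
        return indptr, indices

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of each parent edge (one per non-root node)."""
        if self.n < 2:
            return np.zeros(0)
        child = self.positions[1:]
        par = self.positions[self.parents[1:]]
        return np.hypot(*(child - par).T)

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        pos = self.positions
        for i in range(self.n):
            g.add_node(i, pos=tuple(pos[i]), birth_time=int(self._birth[i]))
        lengths = self.edge_lengths()
        for c in range(1, self.n):
            g.add_edge(int(self.parents[c]), c, length=float(lengths[c - 1]))
        return g

    # -- serialization -----------------------------------------------------

    def to_swc(self, path: str | Path, radius: float = 0.5) -> None:
        """Write the tree as SWC (id type x y z radius parent), 1-based ids."""
        lines = ["# SWC backbone tree; z = 0; radius = w/2"]
        for i in range(self.n):
            p = -1 if i == 0 else int(self.parents[i]) + 1
            x, y = self.positions[i]
            t = 1 if i == 0 else 0
            lines.append(f"{i + 1} {t} {x:.8g} {y:.8g} 0 {radius:.8g} {p}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_swc(cls, path: str | Path) -> "BackboneTree":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            rows.append((int(f[0]), float(f[2]), float(f[3]), int(f[6])))
        rows.sort()
        ids = {r[0]: k for k, r in enumerate(rows)}
        pos = np.array([[r[1], r[2]] for r in rows])
        parents = np.array([-1 if r[3] == -1 else ids[r[3]] for r in rows])
        return cls(pos, parents, np.zeros(len(rows), dtype=np.int64))

    def to_json(self, path: str | Path) -> None:
        """JSON dialect of SWC that additionally stores per-node birth times."""
        doc = {
            "format": "turbisim-tree-v1",
            "nodes": [
                {
                    "id": i,
                    "x": float(self.positions[i, 0]),
                    "y": float(self.positions[i, 1]),
                    "parent": int(self.parents[i]),
                    "birth_time": int(self.birth_times[i]),
                }
                for i in range(self.n)
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "BackboneTree":
        doc = json.loads(Path(path).read_text())
        nodes = sorted(doc["nodes"], key=lambda d: d["id"])
        pos = np.array([[d["x"], d["y"]] for d in nodes])
        parents = np.array([d["parent"] for d in nodes])
        births = np.array([d["birth_time"] for d in nodes])
        return cls(pos, parents, births)


@dataclass
class BoundaryState:
    """Circular boundary of radius ``b``, capped at ``b_max``; never shrinks."""

    b: float
    b_max: float

    def __post_init__(self) -> None:
        if not (0 < self.b <= self.b_max):
            raise ValueError("need 0 < b <= b_max")
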