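"""Random interaction graphs: Erdős–Rényi coupling matrices, perturbations,
and pair-level topology (shortest-path distances and multiplicities).

Couplings are uniform ferromagnetic 0/1 values on the edges of a Bernoulli
random graph: each unordered pair (i, j), i < j, carries an interaction with
probability ``lambda / n`` independently. The diagonal is always zero and the
matrix is symmetric; vertex indices are 0-based internally and 1-based in
human-readable output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphSpec",
    "CouplingMatrix",
    "GraphPerturbation",
    "PairTopology",
    "generate_er_couplings",
    "perturb_graph",
    "pair_topology",
    "distance_gt2_fraction",
    "shortest_path_table",
]


@dataclass(frozen=True)
class GraphSpec:
    """Parameters of the Bernoulli random-graph ensemble."""

    n: int
    mean_degree: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 vertices, got n={self.n}")
        if self.mean_degree < 0:
            raise ValueError(f"mean degree must be nonnegative, got {self.mean_degree}")
        if self.mean_degree / self.n > 1:
            raise ValueError(
                f"edge probability lambda/n = {self.mean_degree / self.n:.4g} exceeds 1"
            )

    @property
    def edge_probability(self) -> float:
        return self.mean_degree / self.n


class CouplingMatrix:
    """Symmetric binary interaction matrix with zero diagonal.

    Wraps an ``(n, n)`` int8 array; the upper triangle is the source of truth
    and the matrix is validated on construction.
    """

    __slots__ = ("entries", "meta")

    def __init__(self, entries: np.ndarray, meta: dict | None = None):
        entries = np.asarray(entries)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {entries.shape}")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("coupling entries must be 0 or 1")
        if np.any(np.diag(entries) != 0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(entries, entries.T):
            raise ValueError("coupling matrix must be symmetric")
        self.entries = entries.astype(np.int8)
        self.meta = dict(meta or {})

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def edge_count(self) -> int:
        return int(self.entries.sum()) // 2

    def edges(self) -> np.ndarray:
        """Edge list as an (m, 2) array of 0-based pairs with i < j."""
        i, j = np.triu_indices(self.n, k=1)
        mask = self.entries[i, j] == 1
        return np.column_stack([i[mask], j[mask]])

    def nonedges(self) -> np.ndarray:
        i, j = np.triu_indices(self.n, k=1)
        mask = self.entries[i, j] == 0
        return np.column_stack([i[mask], j[mask]])

    def degree(self) -> np.ndarray:
        return self.entries.sum(axis=1).astype(np.int64)

    def checksum(self) -> str:
        import hashlib

        return hashlib.sha256(self.entries.tobytes()).hexdigest()[:16]

    def __eq__(self, other) -> bool:
        return isinstance(other, CouplingMatrix) and np.array_equal(
            self.entries, other.entries
        )

    def __repr__(self) -> str:
        return f"CouplingMatrix(n={self.n}, edges={self.edge_count()})"

    # -- edge-list I/O ------------------------------------------------------

    def to_edgelist(self, path, header_fields: dict | None = None) -> None:
        """Write the tab-separated edge list (i < j, stored once)."""
        fields = {**self.meta, **(header_fields or {})}
        parts = [f"n={self.n}"]
        if "lambda" in fields:
            parts.append(f"lambda={fields['lambda']}")
        if "seed" in fields:
            parts.append(f"seed={fields['seed']}")
        with open(path, "w") as fh:
            fh.write("# " + " ".join(parts) + "\n")
            for i, j in self.edges():
                fh.write(f"{i}\t{j}\n")

    @classmethod
    def from_edgelist(cls, path) -> "CouplingMatrix":
        meta: dict = {}
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        if "=" in tok:
                            key, val = tok.split("=", 1)
                            meta[key] = val
                    continue
                i, j = map(int, line.split()[:2])
                pairs.append((i, j))
        if "n" not in meta:
            raise ValueError("edge-list header must record n")
        n = int(meta.pop("n"))
        entries = np.zeros((n, n), dtype=np.int8)
        for i, j in pairs:
            entries[i, j] = entries[j, i] = 1
        if "lambda" in meta:
            meta["lambda"] = float(meta["lambda"])
        if "seed" in meta:
            meta["seed"] = int(meta["seed"])
        return cls(entries, meta=meta)


@dataclass(frozen=True)
class GraphPerturbation:
    """Record of edges deleted from / added to a source graph."""

    deleted_edges: tuple
    added_edges: tuple
    l1_size: int = field(default=-1)

    def __post_init__(self):
        if self.l1_size == -1:
            object.__setattr__(
                self, "l1_size", len(self.deleted_edges) + len(self.added_edges)
            )
        if self.l1_size != len(self.deleted_edges) + len(self.added_edges):
            raise ValueError("l1_size must equal |deleted| + |added|")

    def inverse(self) -> "GraphPerturbation":
        return GraphPerturbation(self.added_edges, self.deleted_edges)

    def delta_matrix(self, n: int) -> np.ndarray:
        """Upper-triangular J' - J as a dense int array."""
        delta = np.zeros((n, n), dtype=np.int8)
        for i, j in self.deleted_edges:
            delta[min(i, j), max(i, j)] = -1
        for i, j in self.added_edges:
            delta[min(i, j), max(i, j)] = 1
        return delta


@dataclass(frozen=True)
class PairTopology:
    """Ground-truth topology of one unordered vertex pair."""

    pair: tuple
    label: bool  # True when the pair interacts (graph distance 1)
    graph_distance: float  # math.inf when disconnected
    num_shortest_paths: int


def generate_er_couplings(spec: GraphSpec) -> CouplingMatrix:
    """Draw a coupling matrix from the Bernoulli ensemble.

    Each unordered pair is set independently to 1 with probability
    ``mean_degree / n``; deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    entries = np.zeros((n, n), dtype=np.int8)
    iu, ju = np.triu_indices(n, k=1)
    draws = rng.random(iu.size) < spec.edge_probability
    entries[iu, ju] = draws
    entries[ju, iu] = draws
    return CouplingMatrix(
        entries, meta={"lambda": spec.mean_degree, "seed": spec.seed}
    )


def perturb_graph(
    J: CouplingMatrix, n_delete: int, n_add: int, seed: int
) -> tuple[CouplingMatrix, GraphPerturbation]:
    """Delete and add edges uniformly at random without replacement.

    The perturbed graph may have a different edge count than the source; the
    returned record fixes the L1 size ``n_delete + n_add`` of the change.
    """
    if n_delete < 0 or n_add < 0:
        raise ValueError("deletion and addition counts must be nonnegative")
    edges = J.edges()
    nonedges = J.nonedges()
    if n_delete > len(edges):
        raise ValueError(f"cannot delete {n_delete} of {len(edges)} edges")
    if n_add > len(nonedges):
        raise ValueError(f"cannot add {n_add} of {len(nonedges)} nonedges")
    rng = np.random.default_rng(seed)
    del_idx = rng.choice(len(edges), size=n_delete, replace=False) if n_delete else []
    add_idx = rng.choice(len(nonedges), size=n_add, replace=False) if n_add else []
    entries = J.entries.copy()
    deleted = []
    for k in del_idx:
        i, j = edges[k]
        entries[i, j] = entries[j, i] = 0
        deleted.append((int(i), int(j)))
    added = []
    for k in add_idx:
        i, j = nonedges[k]
        entries[i, j] = entries[j, i] = 1
        added.append((int(i), int(j)))
    pert = GraphPerturbation(tuple(deleted), tuple(added))
    return CouplingMatrix(entries, meta=J.meta), pert


def shortest_path_table(J: CouplingMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and path multiplicities.

    Returns ``(dist, counts)``: ``dist`` is an (n, n) float matrix with
    ``inf`` for disconnected pairs; ``counts[i, j]`` is the number of distinct
    shortest paths between i and j (0 when disconnected), computed by layered
    breadth-first accumulation. For distance-2 pairs the count equals the
    number of common neighbors.
    """
    A = J.entries.astype(np.float64)
    dist = shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)
    n = J.n
    counts = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(counts, 1)
    # layer-by-layer DP: paths to level l = paths to level l-1 pushed one hop
    frontier = np.eye(n)
    finite = dist[np.isfinite(dist)]
    max_d = int(finite.max()) if finite.size else 0
    for level in range(1, max_d + 1):
        frontier = (frontier * (dist == level - 1)) @ A
        sel = dist == level
        counts[sel] = frontier[sel].astype(np.int64)
    return dist, counts


def pair_topology(J: CouplingMatrix) -> list[PairTopology]:
    """Label, graph distance, and shortest-path count for every unordered pair."""
    dist, counts = shortest_path_table(J)
    out = []
    n = J.n
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            out.append(
                PairTopology(
                    pair=(i, j),
                    label=bool(J.entries[i, j]),
                    graph_distance=math.inf if np.isinf(d) else float(d),
                    num_shortest_paths=int(counts[i, j]),
                )
            )
    return out


def distance_gt2_fraction(J: CouplingMatrix) -> float:
    """Fraction of unordered pairs at graph distance > 2 (incl. disconnected).

    A pair is within distance 2 iff adjacent or sharing a neighbor, so this
    avoids a full shortest-path solve.
    """
    A = J.entries.astype(bool)
    within2 = A | ((A.astype(np.int64) @ A.astype(np.int64)) > 0)
    iu, ju = np.triu_indices(J.n, k=1)
    return float(1.0 - within2[iu, ju].mean())
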