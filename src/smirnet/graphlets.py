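"""Two-labelled graphlet isomer classes and graphlet-interaction counting.

A graphlet here is a small connected induced subgraph (2-4 nodes) of a
similarity network.  A graphlet *interaction isomer* is an equivalence
class of (connected graphlet, ordered pair of distinguished distinct
nodes) under isomorphisms that fix both distinguished nodes.  Exhaustive
enumeration yields exactly 28 such classes: 1 on two nodes, 4 more on
three, 23 more on four.  The interaction vector of a node pair (a, b) in a
network counts, for every vertex subset of size 2-4 containing both, the
class of its induced subgraph when that subgraph is connected, with a in
the source position and b in the target position.

Counting is implemented twice: a vectorised lookup-table version used by
the predictor, and a literal subset-enumeration version
(:func:`count_interactions_bruteforce`) kept as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Sequence

import networkx as nx
import numpy as np

from .similarity import SimilarityMatrix

#: Total number of isomer classes on graphlets of at most four nodes.
N_ISOMER_CLASSES = 28

CanonKey = tuple[int, tuple[tuple[int, int], ...]]


def _connected(k: int, edges: Sequence[tuple[int, int]]) -> bool:
    adj: dict[int, set[int]] = {i: set() for i in range(k)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == k


def canonical_key(k: int, edges: Sequence[tuple[int, int]]) -> CanonKey:
    """Canonical form of a graphlet on vertices 0..k-1 with the ordered
    distinguished pair fixed at (0, 1).

    Isomorphisms must fix both distinguished nodes, so only the remaining
    vertices are permuted; the key is the lexicographically smallest sorted
    edge tuple over those permutations.
    """
    best: tuple[tuple[int, int], ...] | None = None
    for perm in permutations(range(2, k)):
        m = {0: 0, 1: 1, **{old: new for old, new in zip(range(2, k), perm)}}
        key = tuple(sorted(tuple(sorted((m[u], m[v]))) for u, v in edges))
        if best is None or key < best:
            best = key
    return (k, best if best is not None else ())


@dataclass(frozen=True)
class IsomerCatalogue:
    """The ordered list of two-labelled graphlet classes on <=4 nodes."""

    classes: tuple[CanonKey, ...]

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def index(self) -> dict[CanonKey, int]:
        return {c: i for i, c in enumerate(self.classes)}

    def involution(self) -> np.ndarray:
        """Permutation mapping each class to its source<->target swap."""
        idx = self.index
        out = np.empty(len(self.classes), dtype=int)
        for i, (k, edges) in enumerate(self.classes):
            swap = {0: 1, 1: 0}
            swapped = [
                (swap.get(u, u), swap.get(v, v)) for u, v in edges
            ]
            out[i] = idx[canonical_key(k, swapped)]
        return out


def enumerate_isomers(max_nodes: int = 4) -> IsomerCatalogue:
    """Exhaustively enumerate the isomer classes on 2..max_nodes nodes.

    Ordering is deterministic: by node count, then canonical edge tuple.
    """
    if not 2 <= max_nodes <= 4:
        raise ValueError("max_nodes must be 2, 3 or 4")
    classes: set[CanonKey] = set()
    for k in range(2, max_nodes + 1):
        vertex_pairs = list(combinations(range(k), 2))
        for bits in product((0, 1), repeat=len(vertex_pairs)):
            edges = [p for p, b in zip(vertex_pairs, bits) if b]
            if _connected(k, edges):
                classes.add(canonical_key(k, edges))
    return IsomerCatalogue(classes=tuple(sorted(classes)))


@dataclass
class SimilarityNetwork:
    """Binary similarity network: symmetric adjacency, no self-loops."""

    ids: tuple[str, ...]
    adjacency: np.ndarray
    threshold_rule: dict

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.ids)
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be {(n, n)}, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.int8)

    def __len__(self) -> int:
        return len(self.ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacency[i, j]:
                    g.add_edge(self.ids[i], self.ids[j])
        return g


def binarize_similarity(
    matrix: SimilarityMatrix, retain_fraction: float = 0.05
) -> SimilarityNetwork:
    """Keep the top ``retain_fraction`` of off-diagonal similarities as edges.

    The edge threshold is the (1 - retain_fraction) quantile of the
    off-diagonal values; ties at the threshold are all included, so the
    realised density can slightly exceed the requested fraction.
    """
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must be in (0, 1]")
    v = matrix.values
    n = len(matrix)
    iu = np.triu_indices(n, k=1)
    off = v[iu]
    threshold = float(np.quantile(off, 1.0 - retain_fraction))
    adj = np.zeros((n, n), dtype=np.int8)
    keep = off >= threshold
    adj[iu[0][keep], iu[1][keep]] = 1
    adj = adj | adj.T
    return SimilarityNetwork(
        ids=matrix.ids,
        adjacency=adj,
        threshold_rule={
            "method": "top_quantile",
            "retain_fraction": retain_fraction,
            "threshold": threshold,
        },
    )


# --------------------------------------------------------------------------
# fast counting via lookup tables
#
# For a subset {a, b, c} the induced edges are encoded as the 3-bit mask
# (ab, ac, bc); for {a, b, c, d} as the 6-bit mask
# (ab, ac, ad, bc, bd, cd).  Each mask maps to an isomer class index, or -1
# when the induced subgraph is disconnected.  Masks related by swapping the
# two undistinguished nodes map to the same class, so unordered {c, d}
# enumeration is sufficient.

_PAIRS3 = ((0, 1), (0, 2), (1, 2))
_PAIRS4 = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def _build_tables(cat: IsomerCatalogue) -> tuple[np.ndarray, np.ndarray, int]:
    idx = cat.index
    t3 = np.full(8, -1, dtype=int)
    for mask in range(8):
        edges = [p for i, p in enumerate(_PAIRS3) if mask >> i & 1]
        if _connected(3, edges):
            t3[mask] = idx[canonical_key(3, edges)]
    t4 = np.full(64, -1, dtype=int)
    for mask in range(64):
        edges = [p for i, p in enumerate(_PAIRS4) if mask >> i & 1]
        if _connected(4, edges):
            t4[mask] = idx[canonical_key(4, edges)]
    edge_class = idx[(2, ((0, 1),))]
    return t3, t4, edge_class


class InteractionCounter:
    """Per-pair isomer interaction counts on one similarity network."""

    def __init__(
        self, network: SimilarityNetwork, catalogue: IsomerCatalogue | None = None
    ) -> None:
        self.network = network
        self.catalogue = catalogue if catalogue is not None else enumerate_isomers()
        self._t3, self._t4, self._edge_class = _build_tables(self.catalogue)
        self._id_pos = {v: i for i, v in enumerate(network.ids)}

    def count(self, a: str, b: str) -> np.ndarray:
        """Interaction vector of ordered pair (a, b): 28 subset counts."""
        if a == b:
            raise ValueError("the two nodes must be distinct")
        try:
            ia, ib = self._id_pos[a], self._id_pos[b]
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} not in network") from None
        return self._count_by_index(ia, ib)

    def _count_by_index(self, ia: int, ib: int) -> np.ndarray:
        A = self.network.adjacency
        n = len(self.network)
        counts = np.zeros(len(self.catalogue), dtype=np.int64)
        ab = int(A[ia, ib])
        if ab:
            counts[self._edge_class] += 1

        others = np.array([v for v in range(n) if v not in (ia, ib)], dtype=int)
        if others.size:
            mask3 = ab | (A[ia, others].astype(int) << 1) | (A[ib, others].astype(int) << 2)
            cls3 = self._t3[mask3]
            valid = cls3 >= 0
            if valid.any():
                counts += np.bincount(cls3[valid], minlength=len(self.catalogue))

        if others.size >= 2:
            ci, di = np.triu_indices(others.size, k=1)
            c = others[ci]
            d = others[di]
            mask4 = (
                ab
                | (A[ia, c].astype(int) << 1)
                | (A[ia, d].astype(int) << 2)
                | (A[ib, c].astype(int) << 3)
                | (A[ib, d].astype(int) << 4)
                | (A[c, d].astype(int) << 5)
            )
            cls4 = self._t4[mask4]
            valid = cls4 >= 0
            if valid.any():
                counts += np.bincount(cls4[valid], minlength=len(self.catalogue))
        return counts

    def weighted_matrix(self, weights: np.ndarray) -> np.ndarray:
        """n x n matrix W with W[i, j] = sum_k w_k * counts_k(i, j).

        Row index is the source position.  The diagonal is zero (a pair
        requires two distinct nodes).  Uses the catalogue involution to
        fill (j, i) from (i, j) without recounting.
        """
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(self.catalogue),):
            raise ValueError(
                f"need {len(self.catalogue)} weights, got {weights.shape}"
            )
        inv = self.catalogue.involution()
        n = len(self.network)
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                counts = self._count_by_index(i, j)
                W[i, j] = float(counts @ weights)
                W[j, i] = float(counts[inv] @ weights)
        return W


def count_interactions(
    network: SimilarityNetwork,
    a: str,
    b: str,
    catalogue: IsomerCatalogue | None = None,
) -> np.ndarray:
    """Interaction vector of (a, b); convenience wrapper over the counter."""
    return InteractionCounter(network, catalogue).count(a, b)


def count_interactions_bruteforce(
    network: SimilarityNetwork,
    a: str,
    b: str,
    catalogue: IsomerCatalogue | None = None,
) -> np.ndarray:
    """Literal subset-enumeration oracle for :func:`count_interactions`.

    Enumerates every vertex subset of size 2-4 containing both nodes,
    takes the induced subgraph via networkx, tests connectivity, and
    canonicalises with a in the source and b in the target position.
    Intended for small networks (n <= 15).
    """
    if a == b:
        raise ValueError("the two nodes must be distinct")
    if a not in network.ids or b not in network.ids:
        raise KeyError("node not in network")
    cat = catalogue if catalogue is not None else enumerate_isomers()
    idx = cat.index
    g = network.to_networkx()
    rest = [v for v in network.ids if v not in (a, b)]
    counts = np.zeros(len(cat), dtype=np.int64)
    for extra in range(0, 3):
        for comb in combinations(rest, extra):
            nodes = [a, b, *comb]
            sub = g.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            pos = {v: i for i, v in enumerate(nodes)}  # a -> 0, b -> 1
            edges = [(pos[u], pos[v]) for u, v in sub.edges()]
            counts[idx[canonical_key(len(nodes), edges)]] += 1
    return counts
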