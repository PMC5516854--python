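"""k-shortest loopless paths on an additive cost graph.

The cost graph is a :class:`networkx.DiGraph` whose edges carry a
non-negative ``cost`` attribute (``-log`` of an interaction probability for
real edges, 0 for the artificial source/sink edges added by
:func:`pathlinker.core.augment`). The engine provides:

* :func:`dijkstra` — single-source shortest path tree with a lexicographic
  predecessor tie-break;
* :func:`reverse_distances` — exact node-to-sink distances, used as an
  admissible and consistent A* heuristic;
* :func:`astar_shortest_path` — a least-cost path between two nodes under
  edge/node bans, returning the minimum under the total order
  ``(cost, lexicographic node sequence)``;
* :func:`yen_ksp` — Yen's algorithm for the k least-cost loopless paths,
  optionally accelerated by the A* heuristic. The heuristic prunes nodes that
  cannot reach the sink and focuses each spur search toward the sink; it
  never changes the result, because both search variants minimise the same
  ``(cost, sequence)`` order.

Determinism contract: every routine breaks cost ties by the lexicographic
order of the node sequence, so outputs are byte-reproducible across runs and
independent of hash seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from heapq import heappop, heappush
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "SOURCE",
    "SINK",
    "Path",
    "dijkstra",
    "reverse_distances",
    "astar_shortest_path",
    "yen_ksp",
]

#: Names of the artificial source and sink nodes in an augmented cost graph.
SOURCE = "__source__"
SINK = "__sink__"

_INF = math.inf


@dataclass(frozen=True)
class Path:
    """A loopless path with its additive cost and 1-based emission index.

    ``score`` is the product of the real-edge interaction probabilities,
    recovered as ``exp(-cost)`` (artificial edges cost 0, so they do not
    contribute).
    """

    nodes: tuple[str, ...]
    cost: float
    index: int

    @property
    def score(self) -> float:
        return math.exp(-self.cost)

    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes, self.nodes[1:]))

    def __len__(self) -> int:
        return len(self.nodes)


def dijkstra(
    cg: nx.DiGraph, source: str
) -> tuple[dict[str, float], dict[str, str | None]]:
    """Single-source least costs and a deterministic shortest-path tree.

    Among equal-cost alternatives the lexicographically smaller predecessor
    is recorded. Unreachable nodes are absent from both maps (treat their
    distance as +inf).
    """
    if source not in cg:
        raise KeyError(f"source {source!r} not in graph")
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    settled: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        d = dist[u]
        for v in cg.successors(u):
            if v in settled:
                continue
            nd = d + cg[u][v]["cost"]
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heappush(heap, (nd, v))
            elif nd == dist[v] and pred[v] is not None and u < pred[v]:
                pred[v] = u
    return dist, pred


def reverse_distances(cg: nx.DiGraph, target: str = SINK) -> dict[str, float]:
    """Exact least cost from every node to ``target`` (the A* heuristic).

    Computed by Dijkstra on the edge-reversed graph; nodes that cannot reach
    the target are absent (look up with a default of +inf). The table is
    consistent: ``h(u) <= cost(u, v) + h(v)`` for every edge.
    """
    dist, _ = dijkstra(cg.reverse(copy=False), target)
    return dist


def astar_shortest_path(
    cg: nx.DiGraph,
    source: str,
    target: str,
    h: Mapping[str, float] | None = None,
    banned_edges: Iterable[tuple[str, str]] = (),
    banned_nodes: Iterable[str] = (),
) -> tuple[float, tuple[str, ...]] | None:
    """Least-cost loopless ``source -> target`` path avoiding bans.

    ``h`` maps each node to an exact-or-underestimated remaining cost to
    ``target`` (see :func:`reverse_distances`); ``None`` means the zero
    heuristic, i.e. plain Dijkstra. Bans only remove edges/nodes, which can
    only increase true remaining costs, so a heuristic computed on the
    unbanned graph stays admissible.

    Returns ``(cost, node_sequence)`` for the path minimising
    ``(cost, lexicographic sequence)``, or ``None`` if target is unreachable.

    The search carries the partial node sequence in the heap key: along any
    path both the f-value (with a consistent heuristic) and the sequence are
    monotone under extension, so the first entry popped for ``target`` is the
    global minimum of the product order.
    """
    banned_edges = set(banned_edges)
    banned_nodes = set(banned_nodes)
    if source not in cg or target not in cg:
        return None
    if source in banned_nodes or target in banned_nodes:
        return None

    if h is None:
        h_get = lambda n: 0.0  # noqa: E731
    else:
        h_get = lambda n: h.get(n, _INF)  # noqa: E731
    h0 = h_get(source)
    if h0 == _INF:
        return None

    # Heap entries: (f, node_sequence, g). The sequence doubles as the
    # deterministic tie-break and the loopless-visit record.
    heap: list[tuple[float, tuple[str, ...], float]] = [(h0, (source,), 0.0)]
    settled: set[str] = set()
    while heap:
        _f, seq, g = heappop(heap)
        u = seq[-1]
        if u == target:
            return g, seq
        if u in settled:
            continue
        settled.add(u)
        for v in cg.successors(u):
            if v in settled or v in banned_nodes or (u, v) in banned_edges:
                continue
            hv = h_get(v)
            if hv == _INF:
                continue
            g2 = g + cg[u][v]["cost"]
            heappush(heap, (g2 + hv, seq + (v,), g2))
    return None


def _path_cost(cg: nx.DiGraph, seq: tuple[str, ...]) -> float:
    # Single left-to-right sum: keeps float association identical for a given
    # sequence no matter how the path was assembled (root + spur vs direct).
    c = 0.0
    for u, v in zip(seq, seq[1:]):
        c += cg[u][v]["cost"]
    return c


def yen_ksp(
    cg: nx.DiGraph,
    k: int,
    source: str = SOURCE,
    target: str = SINK,
    use_astar: bool = True,
) -> list[Path]:
    """The k least-cost loopless ``source -> target`` paths, in order.

    Yen's algorithm: each newly emitted path is scanned for spur nodes; at a
    spur node the next-edges of all previously emitted paths sharing the same
    root prefix are banned (together with the root's interior nodes) and a
    shortest deviation is computed. Candidates live in a min-heap keyed by
    ``(cost, node sequence)`` and are de-duplicated by full sequence, so the
    emission order is the global ``(cost, lexicographic)`` order over simple
    paths. If fewer than ``k`` simple paths exist, all of them are returned.

    With ``use_astar`` every spur search is guided by exact reverse distances
    to ``target``; this prunes dead-end nodes and terminates each search as
    soon as the target is popped, without changing any returned path.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if source not in cg:
        raise KeyError(f"source {source!r} not in graph")
    if target not in cg:
        raise KeyError(f"target {target!r} not in graph")

    h = reverse_distances(cg, target) if use_astar else None

    first = astar_shortest_path(cg, source, target, h)
    if first is None:
        return []
    emitted: list[tuple[float, tuple[str, ...]]] = [first]
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = {first[1]}

    while len(emitted) < k:
        _prev_cost, prev = emitted[-1]
        for i in range(len(prev) - 1):
            spur = prev[i]
            root = prev[: i + 1]
            banned_edges = {
                (p[i], p[i + 1])
                for _c, p in emitted
                if len(p) > i + 1 and p[: i + 1] == root
            }
            banned_nodes = set(root[:-1])
            res = astar_shortest_path(
                cg, spur, target, h, banned_edges, banned_nodes
            )
            if res is None:
                continue
            seq = root[:-1] + res[1]
            if seq in seen:
                continue
            seen.add(seq)
            heappush(candidates, (_path_cost(cg, seq), seq))
        if not candidates:
            break
        emitted.append(heappop(candidates))

    return [
        Path(nodes=seq, cost=cost, index=i)
        for i, (cost, seq) in enumerate(emitted, start=1)
    ]
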