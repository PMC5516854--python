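"""End-to-end pathway reconstruction.

Given an interactome ``G = (V, E)`` with edge weights ``w_e`` in ``(0, 1]``,
a receptor set ``S`` and a transcriptional-regulator (TR) set ``T``, the
reconstruction finds the k highest-scoring loopless paths that start at any
receptor and end at any TR, where a path's score is the product of its edge
weights. Maximising the product is equivalent to minimising the sum of
per-edge costs ``c_uv = -log(w_uv)``, so the pipeline is:

1. :func:`augment` — add an artificial source ``s`` with a zero-cost edge to
   every receptor and an artificial sink ``t`` with a zero-cost edge from
   every TR, and convert weights to additive costs;
2. run :func:`pathlinker.ksp.yen_ksp` for the k least-cost ``s -> t`` paths;
3. strip the artificial endpoints and rank every node and edge by the index
   of the first path in which it appears.

The union of the first k paths grows monotonically with k, so the ranked
edge list defines a nested family of reconstructions, and by construction
every reconstruction edge lies on some receptor-to-TR path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .graph_io import Interactome, RoleSet
from .ksp import SINK, SOURCE, Path, astar_shortest_path, reverse_distances, yen_ksp

__all__ = [
    "DEFAULT_K",
    "Reconstruction",
    "augment",
    "reconstruct",
    "ranked_edges",
    "ranked_nodes",
    "shortest_paths_baseline",
]

logger = logging.getLogger(__name__)

#: Default number of paths; large enough that reconstructions of curated
#: pathways saturate, reflecting heavy edge reuse among short paths.
DEFAULT_K = 20_000

Edge = tuple[str, str]


def augment(g: Interactome, roles: RoleSet) -> nx.DiGraph:
    """Build the additive cost graph with artificial source and sink.

    Every real edge ``(u, v)`` gets cost ``-log(w_uv)``; the ``|S|`` edges out
    of the source and ``|T|`` edges into the sink get cost 0. Real edges into
    receptors and out of TRs are retained — paths may traverse receptors and
    TRs as intermediates; only path endpoints are constrained.
    """
    for sentinel in (SOURCE, SINK):
        if sentinel in g.nodes:
            raise ValueError(f"interactome contains reserved node name {sentinel!r}")
    if not roles.receptors or not roles.trs:
        raise ValueError("receptor and TR sets must be non-empty")
    cg = nx.DiGraph()
    cg.add_nodes_from(g.graph.nodes)
    for u, v, w in g.edges():
        cg.add_edge(u, v, cost=-math.log(w), weight=w)
    for r in roles.receptors:
        cg.add_edge(SOURCE, r, cost=0.0, weight=1.0)
    for t in roles.trs:
        cg.add_edge(t, SINK, cost=0.0, weight=1.0)
    return cg


@dataclass
class Reconstruction:
    """The ordered receptor-to-TR paths and first-path-index rankings.

    ``paths`` hold real nodes only (artificial endpoints stripped) and are
    re-indexed 1..n in emission order. ``edge_first_index`` /
    ``node_first_index`` map each edge / node to the index of the first path
    containing it, which is its rank in the reconstruction.
    """

    paths: list[Path]
    edge_first_index: dict[Edge, int] = field(default_factory=dict)
    node_first_index: dict[str, int] = field(default_factory=dict)
    k_used: int = 0

    @classmethod
    def from_paths(cls, paths: list[Path], k_used: int) -> "Reconstruction":
        efi: dict[Edge, int] = {}
        nfi: dict[str, int] = {}
        for p in paths:
            for n in p.nodes:
                nfi.setdefault(n, p.index)
            for e in p.edges():
                efi.setdefault(e, p.index)
        return cls(paths=paths, edge_first_index=efi, node_first_index=nfi, k_used=k_used)

    def edges_up_to(self, k: int) -> set[Edge]:
        """Edge set of the union of the first ``k`` paths (the G_k network)."""
        out: set[Edge] = set()
        for p in self.paths[:k]:
            out.update(p.edges())
        return out


def reconstruct(
    g: Interactome,
    roles: RoleSet,
    k: int = DEFAULT_K,
    use_astar: bool = True,
) -> Reconstruction:
    """Compute the k highest-scoring receptor-to-TR paths and their rankings.

    Degenerate two-node ``s -> x -> t`` paths (a node that is both a receptor
    and a TR, contributing no real interaction) are filtered out; remaining
    paths are re-indexed consecutively. Raises if no receptor can reach any
    TR.
    """
    cg = augment(g, roles)
    raw = yen_ksp(cg, k, use_astar=use_astar)
    if not raw:
        raise ValueError(
            "no receptor-to-TR path exists: the receptor set cannot reach the "
            "TR set in this interactome"
        )
    paths: list[Path] = []
    for p in raw:
        stripped = p.nodes[1:-1]
        if len(stripped) < 2:  # s -> x -> t carries no real interaction
            continue
        paths.append(Path(nodes=stripped, cost=p.cost, index=len(paths) + 1))
    if not paths:
        raise ValueError(
            "all receptor-to-TR paths were degenerate (no real interaction)"
        )
    return Reconstruction.from_paths(paths, k_used=k)


def ranked_edges(rec: Reconstruction) -> list[tuple[Edge, int]]:
    """Edges ordered by first-path index; within a path, by traversal position.

    Edges sharing an index are ties for evaluation purposes (they enter a
    precision-recall computation as one block).
    """
    if not rec.paths:
        raise ValueError("empty reconstruction")
    out: list[tuple[Edge, int]] = []
    listed: set[Edge] = set()
    for p in rec.paths:
        for e in p.edges():
            if e not in listed and rec.edge_first_index[e] == p.index:
                listed.add(e)
                out.append((e, p.index))
    return out


def ranked_nodes(rec: Reconstruction) -> list[tuple[str, int]]:
    """Nodes ordered by first-path index; within a path, by traversal position."""
    if not rec.paths:
        raise ValueError("empty reconstruction")
    out: list[tuple[str, int]] = []
    listed: set[str] = set()
    for p in rec.paths:
        for n in p.nodes:
            if n not in listed and rec.node_first_index[n] == p.index:
                listed.add(n)
                out.append((n, p.index))
    return out


def shortest_paths_baseline(g: Interactome, roles: RoleSet) -> set[Edge]:
    """Union of one least-cost path per (receptor, TR) pair.

    The single-subnetwork baseline: no ranking, just the edge union of
    all-pairs shortest receptor-to-TR paths under the same deterministic
    (cost, lexicographic-sequence) tie rule. Unreachable pairs are skipped
    with a warning.
    """
    cg = augment(g, roles)
    # dist-to-sink underestimates dist to any specific TR (the sink edge
    # costs 0), so the one table guides every per-pair search admissibly.
    h = reverse_distances(cg, SINK)
    edges: set[Edge] = set()
    for r in sorted(roles.receptors):
        for t in sorted(roles.trs):
            if r == t:
                continue
            res = astar_shortest_path(cg, r, t, h=h)
            if res is None:
                logger.warning("no path from receptor %r to TR %r; skipped", r, t)
                continue
            seq = res[1]
            edges.update(zip(seq, seq[1:]))
    return edges
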