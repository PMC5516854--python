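"""Reading and writing interactomes, node-role files, pathway truth sets and
reconstruction outputs.

File formats are deliberately minimal, tab-separated text:

* **Interactome TSV** — columns ``tail``, ``head``, ``weight`` and an optional
  fourth direction flag (``U`` marks a physically undirected interaction that
  is expanded to both directions). Lines starting with ``#`` are comments.
  Weights are probability-like reals in ``(0, 1]``.
* **Role files** — one node identifier per line, or a combined two-column
  ``node<TAB>role`` file with role in ``{receptor, tr}``.
* **Pathway truth TSV** — columns ``tail``, ``head`` (extra columns ignored).
* **Reconstruction outputs** — ``<prefix>-ranked-edges.tsv`` and
  ``<prefix>-paths.tsv``; see :func:`write_reconstruction`.

Identifiers are opaque, case-sensitive strings; no mapping is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Interactome",
    "RoleSet",
    "PathwayTruth",
    "InteractomeParseError",
    "read_interactome",
    "write_interactome",
    "read_roles",
    "read_combined_roles",
    "write_roles",
    "read_pathway",
    "write_pathway",
    "write_reconstruction",
    "read_reconstruction",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class InteractomeParseError(ValueError):
    """A malformed line in an interactome / pathway / role file."""


@dataclass
class Interactome:
    """A weighted directed protein interaction network.

    Wraps a :class:`networkx.DiGraph` whose edges carry a ``weight``
    attribute in ``(0, 1]``. Invariants (no self-loops, no duplicate edges,
    weight domain) are enforced at construction time.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        clamp_epsilon: float | None = None,
    ) -> "Interactome":
        """Build an interactome from ``(tail, head, weight)`` triples.

        Self-loops are dropped (with a logged count); parallel duplicates are
        collapsed keeping the maximum weight. Weights outside ``(0, 1]``
        raise ``ValueError`` unless ``clamp_epsilon`` is given, in which case
        non-positive weights are replaced by that epsilon (so ``-log`` stays
        finite); weights above 1 are always rejected.
        """
        g = nx.DiGraph()
        n_loops = 0
        for tail, head, w in edges:
            if tail == head:
                n_loops += 1
                continue
            if w > 1.0:
                raise ValueError(f"edge ({tail}, {head}): weight {w} > 1")
            if w <= 0.0:
                if clamp_epsilon is None:
                    raise ValueError(f"edge ({tail}, {head}): weight {w} <= 0")
                w = clamp_epsilon
            if g.has_edge(tail, head):
                if w > g[tail][head]["weight"]:
                    g[tail][head]["weight"] = w
            else:
                g.add_edge(tail, head, weight=w)
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            yield u, v, w

    def weight(self, tail: str, head: str) -> float:
        return self.graph[tail][head]["weight"]

    def has_edge(self, tail: str, head: str) -> bool:
        return self.graph.has_edge(tail, head)

    def edge_set(self) -> set[Edge]:
        return set(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected_skeleton(self) -> nx.Graph:
        """The undirected view used for hop-distance computations."""
        return self.graph.to_undirected(as_view=False)


@dataclass(frozen=True)
class RoleSet:
    """The receptor set S and transcriptional-regulator set T of a pathway."""

    receptors: frozenset[str]
    trs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.receptors:
            raise ValueError("receptor set is empty")
        if not self.trs:
            raise ValueError("TR set is empty")

    @classmethod
    def validated(
        cls, receptors: Iterable[str], trs: Iterable[str], g: Interactome
    ) -> "RoleSet":
        """Intersect candidate role members against the interactome's nodes.

        Members absent from the graph are dropped with a logged warning; an
        empty intersection for either role is an error, because no
        receptor-to-TR path could then exist.
        """
        nodes = g.nodes
        recs, ts = set(receptors), set(trs)
        for name, members in (("receptor", recs), ("TR", ts)):
            for m in sorted(members - nodes):
                logger.warning("%s %r is not in the interactome; dropped", name, m)
        recs &= nodes
        ts &= nodes
        if not recs:
            raise ValueError("no receptor is present in the interactome")
        if not ts:
            raise ValueError("no TR is present in the interactome")
        return cls(frozenset(recs), frozenset(ts))


@dataclass(frozen=True)
class PathwayTruth:
    """Curated pathway interactions used as evaluation positives."""

    positive_edges: frozenset[Edge]

    @property
    def positive_nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.positive_edges for n in e)

    def restricted_to(self, g: Interactome) -> "PathwayTruth":
        """Keep only positives that exist in the interactome (evaluation rule)."""
        return PathwayTruth(
            frozenset(e for e in self.positive_edges if g.has_edge(*e))
        )


def _data_lines(path: FilePath) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_interactome(
    path: str | FilePath,
    undirected_policy: str = "expand",
    clamp_epsilon: float | None = None,
) -> Interactome:
    """Read a tab-separated weighted edge list into an :class:`Interactome`.

    Parameters
    ----------
    path:
        TSV file with columns tail, head, weight[, direction-flag].
    undirected_policy:
        ``"expand"`` duplicates a ``U``-flagged edge in both directions at the
        same weight; ``"reject"`` raises on any such flag.
    clamp_epsilon:
        If given, weights <= 0 are clamped to this value instead of raising.
    """
    if undirected_policy not in ("expand", "reject"):
        raise ValueError(f"unknown undirected_policy {undirected_policy!r}")
    path = FilePath(path)
    triples: list[tuple[str, str, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise InteractomeParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        tail, head = fields[0], fields[1]
        try:
            w = float(fields[2])
        except ValueError:
            raise InteractomeParseError(
                f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
            ) from None
        if not math.isfinite(w):
            raise InteractomeParseError(f"{path}:{lineno}: non-finite weight {w}")
        undirected = len(fields) >= 4 and fields[3].strip().upper() == "U"
        if undirected and undirected_policy == "reject":
            raise InteractomeParseError(
                f"{path}:{lineno}: undirected edge not allowed under policy 'reject'"
            )
        triples.append((tail, head, w))
        if undirected:
            triples.append((head, tail, w))
    try:
        return Interactome.from_edges(triples, clamp_epsilon=clamp_epsilon)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_interactome(g: Interactome, path: str | FilePath) -> None:
    with open(path, "w") as fh:
        fh.write("#tail\thead\tweight\n")
        for u, v in sorted(g.graph.edges):
            fh.write(f"{u}\t{v}\t{g.weight(u, v):.17g}\n")


def _read_node_list(path: FilePath) -> set[str]:
    out: set[str] = set()
    for _lineno, fields in _data_lines(path):
        out.add(fields[0].strip())
    return out


def read_roles(
    receptor_path: str | FilePath, tr_path: str | FilePath, g: Interactome
) -> RoleSet:
    """Read one-node-per-line receptor and TR files, validated against ``g``."""
    receptors = _read_node_list(FilePath(receptor_path))
    trs = _read_node_list(FilePath(tr_path))
    return RoleSet.validated(receptors, trs, g)


def read_combined_roles(path: str | FilePath, g: Interactome) -> RoleSet:
    """Read a two-column ``node<TAB>role`` file with role in {receptor, tr}."""
    path = FilePath(path)
    receptors: set[str] = set()
    trs: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InteractomeParseError(
                f"{path}:{lineno}: expected 'node<TAB>role'"
            )
        node, role = fields[0].strip(), fields[1].strip().lower()
        if role == "receptor":
            receptors.add(node)
        elif role == "tr":
            trs.add(node)
        else:
            raise InteractomeParseError(
                f"{path}:{lineno}: unknown role {fields[1]!r} (expected receptor/tr)"
            )
    return RoleSet.validated(receptors, trs, g)


def write_roles(roles: RoleSet, receptor_path: str | FilePath, tr_path: str | FilePath) -> None:
    for members, p in ((roles.receptors, receptor_path), (roles.trs, tr_path)):
        with open(p, "w") as fh:
            fh.write("#node\n")
            for n in sorted(members):
                fh.write(f"{n}\n")


def read_pathway(path: str | FilePath, g: Interactome | None = None) -> PathwayTruth:
    """Read a pathway edge list; optionally restrict to edges present in ``g``."""
    path = FilePath(path)
    edges: set[Edge] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InteractomeParseError(
                f"{path}:{lineno}: expected >=2 tab-separated fields"
            )
        edges.add((fields[0], fields[1]))
    truth = PathwayTruth(frozenset(edges))
    if g is not None:
        truth = truth.restricted_to(g)
    return truth


def write_pathway(truth: PathwayTruth, path: str | FilePath) -> None:
    with open(path, "w") as fh:
        fh.write("#tail\thead\n")
        for u, v in sorted(truth.positive_edges):
            fh.write(f"{u}\t{v}\n")


def write_reconstruction(rec, prefix: str | FilePath) -> tuple[FilePath, FilePath]:
    """Write a reconstruction's ranked edges and paths as two TSV files.

    ``<prefix>-ranked-edges.tsv`` holds tail, head, first-path-index rows
    sorted ascending by index, ties by position along the path then
    lexicographically. ``<prefix>-paths.tsv`` holds path index, path score and
    the pipe-joined node sequence (artificial endpoints already stripped).
    """
    from .core import Reconstruction, ranked_edges  # local import avoids a cycle

    if not isinstance(rec, Reconstruction) or not rec.paths:
        raise ValueError("reconstruction is empty; nothing to write")
    prefix = FilePath(prefix)
    edges_path = prefix.parent / (prefix.name + "-ranked-edges.tsv")
    paths_path = prefix.parent / (prefix.name + "-paths.tsv")
    with open(edges_path, "w") as fh:
        fh.write("#tail\thead\tfirst_path_index\n")
        for (u, v), idx in ranked_edges(rec):
            fh.write(f"{u}\t{v}\t{idx}\n")
    with open(paths_path, "w") as fh:
        fh.write("#path_index\tpath_score\tpath\n")
        for p in rec.paths:
            fh.write(f"{p.index}\t{p.score:.17g}\t{'|'.join(p.nodes)}\n")
    return edges_path, paths_path


def read_reconstruction(prefix: str | FilePath):
    """Read back what :func:`write_reconstruction` wrote.

    Returns ``(paths, ranked)`` where ``paths`` is a list of
    ``(index, score, node_tuple)`` and ``ranked`` is the ordered list of
    ``((tail, head), first_path_index)``.
    """
    prefix = FilePath(prefix)
    paths: list[tuple[int, float, tuple[str, ...]]] = []
    for lineno, fields in _data_lines(prefix.parent / (prefix.name + "-paths.tsv")):
        if len(fields) != 3:
            raise InteractomeParseError(f"paths file line {lineno}: expected 3 fields")
        paths.append((int(fields[0]), float(fields[1]), tuple(fields[2].split("|"))))
    ranked: list[tuple[Edge, int]] = []
    for lineno, fields in _data_lines(
        prefix.parent / (prefix.name + "-ranked-edges.tsv")
    ):
        if len(fields) != 3:
            raise InteractomeParseError(f"edges file line {lineno}: expected 3 fields")
        ranked.append(((fields[0], fields[1]), int(fields[2])))
    return paths, ranked
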