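"""Ranked-edge evaluation of pathway reconstructions.

A reconstruction method emits an ordered list of (item, index) pairs — edges
or nodes ranked by first-path index or by walk flux. Against a curated
pathway (the positives) and a seeded subsample of non-pathway interactions
(the negatives) we compute precision-recall curves, where items sharing an
index enter as one block: ranks within one path are artifacts of traversal
order, not evidence.

Also here: the pathway-adjacent-negative exclusion (drop negatives touching
a pathway protein before subsampling), hop distance of an interaction from
the pathway, receptor/TR recovery ranks, seeded perturbation of the input
role sets, micro-aggregation of curves across pathways, and the random-walk
-with-restarts (RWR) baseline ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .graph_io import Interactome, PathwayTruth, RoleSet

__all__ = [
    "EvalConfig",
    "PRPoint",
    "PRCurve",
    "UNRANKED",
    "subsample_negatives",
    "precision_recall",
    "edge_distance_from_pathway",
    "exclude_adjacent_negatives",
    "recovery_ranks",
    "perturb_roles",
    "rwr_baseline",
    "aggregate_pr",
    "node_sets_from_edges",
]

Edge = tuple[str, str]

#: Sentinel recovery rank for a node never covered by any ranked edge.
UNRANKED = math.inf


@dataclass(frozen=True)
class EvalConfig:
    """Knobs of one evaluation run.

    neg_ratio — negatives sampled per positive (default 50; held fixed
    across methods being compared). exclude_adjacent — drop pathway-adjacent
    negatives before subsampling. level — rank edges or nodes.
    """

    neg_ratio: float = 50.0
    seed: int = 0
    exclude_adjacent: bool = False
    level: str = "edge"

    def __post_init__(self) -> None:
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be > 0")
        if self.level not in ("edge", "node"):
            raise ValueError(f"level must be 'edge' or 'node', got {self.level!r}")


@dataclass(frozen=True)
class PRPoint:
    threshold_index: int
    tp: int
    fp: int
    precision: float
    recall: float


@dataclass
class PRCurve:
    """Precision-recall evaluated at each distinct rank threshold."""

    points: list[PRPoint] = field(default_factory=list)
    positives_total: int = 0

    def recall_precision(self) -> list[tuple[float, float]]:
        return [(p.recall, p.precision) for p in self.points]

    def precision_at_recall(self, recall: float) -> float:
        """Highest precision among thresholds reaching at least ``recall``."""
        cands = [p.precision for p in self.points if p.recall >= recall]
        return max(cands) if cands else 0.0

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#threshold_index\ttp\tfp\tprecision\trecall\n")
            for p in self.points:
                fh.write(
                    f"{p.threshold_index}\t{p.tp}\t{p.fp}\t"
                    f"{p.precision:.10g}\t{p.recall:.10g}\n"
                )


def subsample_negatives(
    universe: Iterable[Hashable],
    positives: Iterable[Hashable],
    cfg: EvalConfig,
) -> set:
    """Seeded uniform sample without replacement from universe minus positives.

    Sample size is ``round(neg_ratio * |positives|)``, clamped to the pool
    size. Reproducible: the pool is sorted before sampling, so the result
    depends only on (seed, universe, positives).
    """
    universe = set(universe)
    positives = set(positives)
    if not positives <= universe:
        raise ValueError("positives must be a subset of the universe")
    pool = sorted(universe - positives)
    if not pool:
        raise ValueError("no negative candidates: universe equals positives")
    size = min(round(cfg.neg_ratio * len(positives)), len(pool))
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    return {pool[i] for i in idx}


def precision_recall(
    ranked: Sequence[tuple[Hashable, int]],
    positives: Iterable[Hashable],
    negatives: Iterable[Hashable],
) -> PRCurve:
    """Precision-recall over a ranked item list with block ties.

    Items in neither set are ignored. At each distinct index threshold t,
    precision = TP/(TP+FP) and recall = TP/|positives| counting every item
    with index <= t; items sharing an index enter together.
    """
    positives = set(positives)
    negatives = set(negatives)
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    if not positives:
        raise ValueError("positives set is empty")
    scored = [
        (idx, item)
        for item, idx in ranked
        if item in positives or item in negatives
    ]
    scored.sort(key=lambda t: t[0])
    curve = PRCurve(positives_total=len(positives))
    tp = fp = 0
    i = 0
    while i < len(scored):
        idx = scored[i][0]
        while i < len(scored) and scored[i][0] == idx:
            if scored[i][1] in positives:
                tp += 1
            else:
                fp += 1
            i += 1
        curve.points.append(
            PRPoint(
                threshold_index=idx,
                tp=tp,
                fp=fp,
                precision=tp / (tp + fp),
                recall=tp / len(positives),
            )
        )
    return curve


def _hops_to_pathway(g: Interactome, truth: PathwayTruth) -> dict[str, float]:
    """Undirected hop distance from every node to the nearest pathway protein."""
    skel = g.undirected_skeleton()
    sources = [n for n in truth.positive_nodes if n in skel]
    if not sources:
        return {}
    return dict(
        nx.multi_source_dijkstra_path_length(skel, sources, weight=None)
    )


def edge_distance_from_pathway(
    e: Edge,
    truth: PathwayTruth,
    g: Interactome,
    _hops: dict[str, float] | None = None,
) -> float:
    """Hop distance of an interaction from the pathway.

    0 for a true positive; 1 for a pathway-adjacent interaction (at least one
    endpoint is a pathway protein); otherwise 1 + the smaller endpoint's
    undirected hop distance to the nearest pathway protein; +inf if neither
    endpoint can reach the pathway. ``_hops`` lets callers reuse the
    breadth-first table across many edges.
    """
    if e in truth.positive_edges:
        return 0.0
    hops = _hops if _hops is not None else _hops_to_pathway(g, truth)
    d = min(hops.get(e[0], math.inf), hops.get(e[1], math.inf))
    return 1.0 + d


def exclude_adjacent_negatives(
    negatives: Iterable[Edge], truth: PathwayTruth, g: Interactome
) -> set[Edge]:
    """Drop negatives with at least one pathway-protein endpoint.

    Applied *before* subsampling when configured: such interactions are too
    close to the pathway to be confident non-members, and removing them can
    only remove false positives from the precision denominator.
    """
    hops = _hops_to_pathway(g, truth)
    return {
        e
        for e in negatives
        if edge_distance_from_pathway(e, truth, g, _hops=hops) != 1.0
    }


def distance_histogram(
    ranked: Sequence[tuple[Edge, int]],
    truth: PathwayTruth,
    g: Interactome,
    depth: int | None = None,
) -> dict[float, int]:
    """Count ranked interactions by distance-from-pathway, up to ``depth`` items."""
    hops = _hops_to_pathway(g, truth)
    items = ranked if depth is None else ranked[:depth]
    hist: dict[float, int] = {}
    for e, _idx in items:
        d = edge_distance_from_pathway(e, truth, g, _hops=hops)
        hist[d] = hist.get(d, 0) + 1
    return hist


def recovery_ranks(
    ranked: Sequence[tuple[Edge, int]], targets: Iterable[str]
) -> dict[str, float]:
    """First index at which each target node appears in any ranked edge.

    Measures how quickly a method recovers the pathway's receptors or TRs;
    nodes never covered map to the :data:`UNRANKED` sentinel.
    """
    out = {t: UNRANKED for t in targets}
    for (u, v), idx in ranked:
        for n in (u, v):
            if n in out and idx < out[n]:
                out[n] = idx
    return out


def perturb_roles(
    roles: RoleSet,
    fraction: float,
    mode: str,
    candidate_pool: Iterable[str] = (),
    seed: int = 0,
) -> RoleSet:
    """Randomly remove or add a fraction of each role set (robustness protocol).

    ``remove`` drops ``round(fraction * |set|)`` members uniformly, seeded and
    independent between receptors and TRs; ``add`` inserts that many nodes
    sampled from ``candidate_pool`` (which must be disjoint from the set being
    grown). Raises if a removal would empty a set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if mode not in ("remove", "add"):
        raise ValueError(f"mode must be 'remove' or 'add', got {mode!r}")
    rng = np.random.default_rng(seed)
    pool = sorted(set(candidate_pool))
    new_sets: list[frozenset[str]] = []
    for members in (roles.receptors, roles.trs):
        members_sorted = sorted(members)
        n_change = round(fraction * len(members_sorted))
        if mode == "remove":
            if n_change >= len(members_sorted):
                raise ValueError("removal would empty a role set")
            drop = set(
                members_sorted[i]
                for i in rng.choice(len(members_sorted), size=n_change, replace=False)
            )
            new_sets.append(frozenset(m for m in members_sorted if m not in drop))
        else:
            cands = [c for c in pool if c not in members]
            if n_change > len(cands):
                raise ValueError("candidate pool too small for requested additions")
            add = set(
                cands[i] for i in rng.choice(len(cands), size=n_change, replace=False)
            ) if n_change else set()
            new_sets.append(frozenset(members) | add)
    return RoleSet(new_sets[0], new_sets[1])


def rwr_stationary(
    g: Interactome,
    roles: RoleSet,
    teleport: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Stationary node probabilities of a restart walk from the receptors.

    At each step the walk restarts uniformly on the receptor set with
    probability ``teleport``; otherwise it moves along an out-edge with
    probability proportional to edge weight. Dangling nodes always restart.
    Power iteration to an L1 change below ``tol``.
    """
    if not 0.0 < teleport <= 1.0:
        raise ValueError("teleport must be in (0, 1]")
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty interactome")
    pos = {u: i for i, u in enumerate(nodes)}
    restart = np.zeros(n)
    for r in roles.receptors:
        restart[pos[r]] = 1.0 / len(roles.receptors)

    # Row-stochastic transition over out-edge weights; dangling rows are empty
    # (their probability mass teleports).
    rows, cols, vals = [], [], []
    for u in nodes:
        out = g.graph[u]
        tot = sum(d["weight"] for d in out.values())
        if tot <= 0:
            continue
        for v, d in out.items():
            rows.append(pos[u])
            cols.append(pos[v])
            vals.append(d["weight"] / tot)
    trans = np.zeros((n, n))
    trans[rows, cols] = vals
    dangling = trans.sum(axis=1) == 0.0

    p = restart.copy()
    q = teleport
    for _ in range(max_iter):
        walk_mass = (1.0 - q) * p
        p_next = q * restart + walk_mass @ trans + walk_mass[dangling].sum() * restart
        resid = float(np.abs(p_next - p).sum())
        p = p_next
        if resid < tol:
            return {u: float(p[pos[u]]) for u in nodes}
    raise RuntimeError(
        f"RWR power iteration did not converge in {max_iter} iterations "
        f"(last L1 residual {resid:.3e})"
    )


def rwr_baseline(
    g: Interactome,
    roles: RoleSet,
    teleport: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> list[tuple[Edge, int]]:
    """Edges ranked by stationary flux ``f(u,v) = p(u) * w(u,v) / sum_x w(u,x)``.

    Descending flux, ties broken lexicographically; ranks are 1-based and
    distinct, so downstream precision-recall sees no tied blocks.
    """
    p = rwr_stationary(g, roles, teleport=teleport, tol=tol, max_iter=max_iter)
    flux: list[tuple[float, Edge]] = []
    for u in sorted(g.nodes):
        out = g.graph[u]
        tot = sum(d["weight"] for d in out.values())
        for v in sorted(out):
            flux.append((p[u] * out[v]["weight"] / tot, (u, v)))
    flux.sort(key=lambda t: (-t[0], t[1]))
    return [(e, i) for i, (_f, e) in enumerate(flux, start=1)]


def aggregate_pr(
    per_pathway: Sequence[
        tuple[Sequence[tuple[Hashable, int]], Iterable[Hashable], Iterable[Hashable]]
    ],
) -> PRCurve:
    """Micro-aggregated precision-recall across pathways.

    Each entry is ``(ranked, positives, negatives)`` for one pathway. Items
    are tagged with their pathway's position so the same interaction in two
    pathways counts as two distinct items, then all pairs are pooled into a
    single block-tied curve over the pooled positives and negatives.
    """
    if not per_pathway:
        raise ValueError("need at least one pathway")
    pooled_ranked: list[tuple[Hashable, int]] = []
    pooled_pos: set = set()
    pooled_neg: set = set()
    for tag, (ranked, positives, negatives) in enumerate(per_pathway):
        pooled_ranked.extend(((tag, item), idx) for item, idx in ranked)
        pooled_pos.update((tag, item) for item in positives)
        pooled_neg.update((tag, item) for item in negatives)
    return precision_recall(pooled_ranked, pooled_pos, pooled_neg)


def node_sets_from_edges(
    negative_edges: Iterable[Edge], truth: PathwayTruth
) -> tuple[set[str], set[str]]:
    """Node-level positives and negatives for protein-recovery evaluation.

    Positives are the pathway proteins; negatives are endpoints of the
    sampled negative edges that are not pathway proteins.
    """
    positives = set(truth.positive_nodes)
    negatives = {
        n for e in negative_edges for n in e if n not in positives
    }
    return positives, negatives
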