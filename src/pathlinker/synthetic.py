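"""Seeded synthetic interactomes with planted receptor-to-TR pathways.

The generator emulates the shape of the real inputs — a sparse directed
background network with probability-like edge weights, a receptor set, a TR
set, and a ground-truth pathway — without any external data. A planted
pathway is a set of simple receptor-to-TR paths whose edge weights are drawn
from a distribution well above the background, so the true signaling routes
are the highest-scoring paths and recovery is checkable exactly.

Everything is a pure function of a :class:`FixtureSpec`: the same spec
yields byte-identical files. The PRNG is numpy's PCG64 via
``numpy.random.default_rng``; the spec (including the generator name) is
recorded in a JSON sidecar when fixtures are written to disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np

from .graph_io import (
    Interactome,
    PathwayTruth,
    RoleSet,
    write_interactome,
    write_pathway,
    write_roles,
)

__all__ = [
    "FixtureSpec",
    "generate_interactome",
    "plant_pathway",
    "make_fixture",
    "write_fixture",
    "worked_example",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults define the standard recovery benchmark: a 200-node background at
    mean out-degree ~2 with weak edges (weights U(0.05, 0.4)), and 4 planted
    receptor-to-TR paths of 2-3 edges with strong edges (U(0.7, 0.95)) —
    roughly the weight separation between high- and low-evidence
    interactions in probabilistically weighted interactomes.
    """

    n_nodes: int = 200
    edge_prob: float = 0.01
    n_receptors: int = 4
    n_trs: int = 4
    n_planted_paths: int = 4
    path_length: tuple[int, int] = (2, 3)  # edges per planted path, inclusive
    w_background: tuple[float, float] = (0.05, 0.4)
    w_planted: tuple[float, float] = (0.7, 0.95)
    shared_interiors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0.0 <= self.edge_prob < 1.0:
            raise ValueError(
                "edge_prob must be in [0, 1): 1 would imply >= n(n-1) edges"
            )
        if self.n_receptors < 1 or self.n_trs < 1:
            raise ValueError("need at least one receptor and one TR")
        if self.n_receptors + self.n_trs > self.n_nodes:
            raise ValueError("more roles than nodes")
        if self.n_planted_paths < max(self.n_receptors, self.n_trs):
            raise ValueError(
                "need at least max(n_receptors, n_trs) planted paths so every "
                "receptor and TR lies on one"
            )
        lo, hi = self.path_length
        if lo < 1 or hi < lo:
            raise ValueError("path_length must be a (low, high) range with low >= 1")
        for lo_w, hi_w in (self.w_background, self.w_planted):
            if not 0.0 < lo_w <= hi_w <= 1.0:
                raise ValueError("weight bounds must satisfy 0 < low <= high <= 1")

    def node_names(self) -> list[str]:
        width = len(str(self.n_nodes - 1))
        return [f"n{i:0{width}d}" for i in range(self.n_nodes)]


def generate_interactome(spec: FixtureSpec) -> Interactome:
    """Directed G(n, p) background with i.i.d. uniform weights, no self-loops."""
    rng = np.random.default_rng(spec.seed)
    names = spec.node_names()
    n = spec.n_nodes
    triples: list[tuple[str, str, float]] = []
    if spec.edge_prob > 0.0:
        mask = rng.random((n, n)) < spec.edge_prob
        np.fill_diagonal(mask, False)
        lo, hi = spec.w_background
        tails, heads = np.nonzero(mask)
        weights = rng.uniform(lo, hi, size=len(tails))
        triples = [
            (names[t], names[h], float(w))
            for t, h, w in zip(tails, heads, weights)
        ]
    g = Interactome.from_edges(triples)
    g.graph.add_nodes_from(names)
    return g


def plant_pathway(
    g: Interactome, spec: FixtureSpec
) -> tuple[Interactome, RoleSet, PathwayTruth]:
    """Insert high-weight receptor-to-TR paths into a background network.

    Receptors, TRs and (by default) the interior nodes of different paths are
    disjoint; planted paths therefore cannot recombine into hybrid paths, and
    "the first |planted| paths recover exactly the planted edges" is a
    well-posed ground truth. With ``shared_interiors=True`` interiors are
    drawn independently per path and may overlap, mimicking pathway
    convergence. Planted edges overwrite colliding background edges; every
    receptor and every TR lies on at least one planted path. Returns a new
    interactome (the input is not modified), the role set and the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    names = spec.node_names()
    roles_needed = spec.n_receptors + spec.n_trs
    order = [names[i] for i in rng.permutation(len(names))]
    receptors = sorted(order[: spec.n_receptors])
    trs = sorted(order[spec.n_receptors : roles_needed])
    interior_pool = order[roles_needed:]

    lo_len, hi_len = spec.path_length
    lengths = rng.integers(lo_len, hi_len + 1, size=spec.n_planted_paths)
    interiors_needed = int((lengths - 1).sum())
    if not spec.shared_interiors and interiors_needed > len(interior_pool):
        raise ValueError(
            f"planted paths need {interiors_needed} distinct interior nodes but "
            f"only {len(interior_pool)} non-role nodes exist"
        )

    out = Interactome(g.graph.copy())
    planted: set[tuple[str, str]] = set()
    w_lo, w_hi = spec.w_planted
    pool_cursor = 0
    for i, length in enumerate(lengths):
        # Cycle roles so every receptor and TR is covered.
        r = receptors[i % len(receptors)]
        t = trs[i % len(trs)]
        n_interior = int(length) - 1
        if spec.shared_interiors:
            idx = rng.choice(len(interior_pool), size=n_interior, replace=False)
            interior = [interior_pool[j] for j in idx]
        else:
            interior = interior_pool[pool_cursor : pool_cursor + n_interior]
            pool_cursor += n_interior
        seq = [r, *interior, t]
        for u, v in zip(seq, seq[1:]):
            w = float(rng.uniform(w_lo, w_hi))
            out.graph.add_edge(u, v, weight=w)
            planted.add((u, v))
    roles = RoleSet(frozenset(receptors), frozenset(trs))
    return out, roles, PathwayTruth(frozenset(planted))


def make_fixture(spec: FixtureSpec) -> tuple[Interactome, RoleSet, PathwayTruth]:
    """Generate a background network and plant a pathway in one call."""
    return plant_pathway(generate_interactome(spec), spec)


def write_fixture(spec: FixtureSpec, prefix: str | FilePath) -> dict[str, str]:
    """Write network/roles/pathway TSVs plus a JSON metadata sidecar."""
    prefix = FilePath(prefix)
    g, roles, truth = make_fixture(spec)
    files = {
        "network": str(prefix) + "-network.tsv",
        "receptors": str(prefix) + "-receptors.txt",
        "trs": str(prefix) + "-trs.txt",
        "pathway": str(prefix) + "-pathway.tsv",
        "meta": str(prefix) + "-meta.json",
    }
    write_interactome(g, files["network"])
    write_roles(roles, files["receptors"], files["trs"])
    write_pathway(truth, files["pathway"])
    meta = dataclasses.asdict(spec)
    meta["rng"] = "numpy.random.default_rng (PCG64)"
    with open(files["meta"], "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return files


def worked_example() -> tuple[Interactome, RoleSet, PathwayTruth]:
    """The fixed hand-checkable two-branch network.

    Receptor R reaches TR X through a strong branch (R->A->X, both weights
    0.9, path score 0.81) and a weak branch (R->B->X, both 0.5, score 0.25).
    The truth is the strong branch. Useful for by-hand verification of path
    ranking, first-path-index maps and the shortest-path baseline.
    """
    g = Interactome.from_edges(
        [("R", "A", 0.9), ("A", "X", 0.9), ("R", "B", 0.5), ("B", "X", 0.5)]
    )
    roles = RoleSet(frozenset({"R"}), frozenset({"X"}))
    truth = PathwayTruth(frozenset({("R", "A"), ("A", "X")}))
    return g, roles, truth
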