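"""Linear phosphorylation pathway extraction from the KSR network.

A pathway here is an ordered chain of >= 2 distinct proteins in which every
consecutive pair is a kinase -> substrate edge (e.g. A -> B -> C when A
phosphorylates B and B phosphorylates C).  Pathways are not curated
database pathways; they are raw linear cascades read off the KSR graph.

Two rules shape the pathway set:

* Distance pre-filter: a KSR edge whose endpoints are farther than two hops
  apart in the PPI network cannot be bridged by a common interaction
  partner, so it can never contribute to a scaffolded pathway and is
  dropped before enumeration.
* Sub-path closure: every contiguous sub-chain (length >= 2) of a pathway
  is itself a pathway — a long cascade may lack a scaffold while its
  sub-chains have one.

Pathways are simple (no repeated protein), which keeps enumeration finite
on cyclic KSR graphs.  "Length" counts proteins, so a single KSR edge is a
length-2 pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .network import CompositeNetwork, KSRNetwork

logger = logging.getLogger(__name__)

Pathway = tuple[str, ...]

__all__ = [
    "Pathway",
    "PathwaySet",
    "PathwayOverflowError",
    "filter_ksr_by_distance",
    "enumerate_pathways",
    "subpaths",
]

#: Default ceiling on pathway length (protein count).  Observed cascades in
#: composite phosphorylation networks rarely exceed five proteins; the
#: ceiling bounds worst-case enumeration on dense KSR subgraphs.
DEFAULT_MAX_LENGTH = 8

#: Guard against combinatorial blow-up in pathological inputs.
DEFAULT_MAX_PATHWAYS = 1_000_000


class PathwayOverflowError(RuntimeError):
    """Raised when enumeration would exceed the configured pathway ceiling."""


@dataclass
class PathwaySet:
    """A deduplicated set of pathways plus the filter settings that made it."""

    pathways: frozenset[Pathway]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(sorted(self.pathways))

    def __contains__(self, p: Pathway) -> bool:
        return tuple(p) in self.pathways

    def of_length(self, length: int) -> set[Pathway]:
        return {p for p in self.pathways if len(p) == length}


def filter_ksr_by_distance(
    composite: CompositeNetwork, max_distance: int = 2
) -> KSRNetwork:
    """Drop KSR edges whose endpoints lie farther than ``max_distance`` in PPI.

    An edge with an endpoint absent from the PPI network is removed too
    (its distance is unreachable, hence greater than any cutoff).
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    ppi = composite.ppi
    kept = KSRNetwork()
    # One truncated BFS per distinct kinase covers all its substrates.
    by_kinase: dict[str, list[str]] = {}
    for k, s in composite.ksr.edges():
        by_kinase.setdefault(k, []).append(s)
    for k, substrates in by_kinase.items():
        if k not in ppi:
            continue
        reach = nx.single_source_shortest_path_length(
            ppi.graph, k, cutoff=max_distance
        )
        for s in substrates:
            if s in reach:
                kept.add_edge(k, s)
    return kept


def subpaths(pathway: Pathway, min_length: int = 2) -> set[Pathway]:
    """All contiguous sub-sequences of ``pathway`` with >= min_length proteins."""
    n = len(pathway)
    return {
        pathway[i:j]
        for i in range(n)
        for j in range(i + min_length, n + 1)
    }


def enumerate_pathways(
    ksr: KSRNetwork,
    min_length: int = 2,
    max_length: int | None = DEFAULT_MAX_LENGTH,
    closure: bool = True,
    max_pathways: int = DEFAULT_MAX_PATHWAYS,
) -> PathwaySet:
    """Enumerate every simple KSR chain within the length bounds.

    Depth-first search from every kinase (edge source); every prefix of a
    DFS path with >= ``min_length`` proteins is recorded — a pathway must
    start at a kinase but need not end at a leaf.  With ``closure`` on,
    contiguous sub-paths are added and the set deduplicated.  Because every
    internal node of a chain is itself an edge source, closure adds nothing
    new; it is kept explicit as a contract.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    if max_length is not None and max_length < min_length:
        raise ValueError("max_length must be >= min_length")

    found: set[Pathway] = set()
    roots = sorted(ksr.kinases())
    for root in roots:
        # Iterative DFS over simple paths.
        stack: list[tuple[Pathway, frozenset[str]]] = [((root,), frozenset((root,)))]
        while stack:
            path, seen = stack.pop()
            if len(path) >= min_length:
                found.add(path)
                if len(found) > max_pathways:
                    raise PathwayOverflowError(
                        f"more than {max_pathways} pathways; "
                        "tighten max_length or raise the ceiling"
                    )
            if max_length is not None and len(path) >= max_length:
                continue
            for nxt in sorted(ksr.substrates_of(path[-1])):
                if nxt not in seen:
                    stack.append((path + (nxt,), seen | {nxt}))

    if closure:
        closed: set[Pathway] = set()
        for p in found:
            closed |= subpaths(p, min_length)
        if max_length is not None:
            closed = {p for p in closed if len(p) <= max_length}
        found |= closed

    return PathwaySet(
        pathways=frozenset(found),
        provenance={
            "min_length": min_length,
            "max_length": max_length,
            "closure": closure,
            "max_pathways": max_pathways,
            "n_pathways": len(found),
        },
    )
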