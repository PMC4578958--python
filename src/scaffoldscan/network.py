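"""Domain types for the composite signaling network.

A composite network joins an undirected protein-protein interaction (PPI)
graph with a directed kinase-substrate relationship (KSR) graph over a
shared (possibly partially overlapping) protein identifier space.

Homotypic interactions (self-pairs, a protein interacting with itself) are
first-class edges: they are stored, counted in the edge total, and written
back out, but they contribute nothing to the degree used by path
computations, shuffling, or degree-matched sampling — a self-loop cannot
mediate a path between two other proteins.  They are consulted only by the
homotypic (homodimerization) analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "PPINetwork",
    "KSRNetwork",
    "CompositeNetwork",
    "load_ppi",
    "load_ksr",
    "write_ppi",
    "write_ksr",
    "build_composite",
]


class ParseError(ValueError):
    """Raised for a malformed edge-list line; message names the line number."""


def _check_id(token: str) -> str:
    if not token or any(ch.isspace() for ch in token):
        raise ValueError(f"invalid protein identifier: {token!r}")
    return token


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge, used for set membership."""
    return (a, b) if a <= b else (b, a)


class PPINetwork:
    """Undirected PPI graph with explicit self-pairs.

    Internally the simple (loop-free) part lives in a :class:`networkx.Graph`;
    self-pairs are kept in a separate set so that ``degree`` and ``neighbors``
    never see them.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.Graph()
        self._self_pairs: set[str] = set()
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -------------------------------------------------

    def add_protein(self, p: str) -> None:
        self._g.add_node(_check_id(p))

    def add_edge(self, a: str, b: str) -> None:
        a, b = _check_id(a), _check_id(b)
        if a == b:
            self._g.add_node(a)
            self._self_pairs.add(a)
        else:
            self._g.add_edge(a, b)

    def remove_edge(self, a: str, b: str) -> None:
        if a == b:
            self._self_pairs.discard(a)
        else:
            self._g.remove_edge(a, b)

    def copy(self) -> "PPINetwork":
        net = PPINetwork()
        net._g = self._g.copy()
        net._self_pairs = set(self._self_pairs)
        return net

    # -- queries ------------------------------------------------------

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_proteins(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Total edge count, homotypic pairs included."""
        return self._g.number_of_edges() + len(self._self_pairs)

    @property
    def n_simple_edges(self) -> int:
        """Edge count excluding homotypic pairs."""
        return self._g.number_of_edges()

    @property
    def self_interacting(self) -> frozenset[str]:
        return frozenset(self._self_pairs)

    @property
    def graph(self) -> nx.Graph:
        """The loop-free interaction graph (do not mutate)."""
        return self._g

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def degree(self, p: str) -> int:
        """Number of distinct non-self interaction partners."""
        return self._g.degree(p)

    def neighbors(self, p: str) -> set[str]:
        return set(self._g.neighbors(p))

    def has_edge(self, a: str, b: str) -> bool:
        if a == b:
            return a in self._self_pairs
        return self._g.has_edge(a, b)

    def has_self_pair(self, p: str) -> bool:
        return p in self._self_pairs

    def edges(self, include_self: bool = True) -> Iterator[tuple[str, str]]:
        """Iterate edges in canonical form, deterministically sorted."""
        simple = sorted(canonical_edge(a, b) for a, b in self._g.edges)
        yield from simple
        if include_self:
            yield from ((p, p) for p in sorted(self._self_pairs))

    def degree_sequence(self) -> dict[str, int]:
        return {p: self._g.degree(p) for p in self._g.nodes}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.proteins == other.proteins
            and set(self.edges()) == set(other.edges())
        )

    def __repr__(self) -> str:
        return (
            f"PPINetwork({self.n_proteins} proteins, {self.n_edges} edges, "
            f"{len(self._self_pairs)} homotypic)"
        )


class KSRNetwork:
    """Directed kinase -> substrate graph."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.DiGraph()
        for k, s in edges:
            self.add_edge(k, s)

    def add_edge(self, kinase: str, substrate: str) -> None:
        self._g.add_edge(_check_id(kinase), _check_id(substrate))

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        yield from sorted(self._g.edges)

    def kinases(self) -> set[str]:
        """All edge sources (proteins known to phosphorylate something)."""
        return {k for k, _ in self._g.edges}

    def substrates_of(self, kinase: str) -> set[str]:
        if kinase not in self._g:
            return set()
        return set(self._g.successors(kinase))

    def kinases_of(self, substrate: str) -> set[str]:
        if substrate not in self._g:
            return set()
        return set(self._g.predecessors(substrate))

    def has_edge(self, kinase: str, substrate: str) -> bool:
        return self._g.has_edge(kinase, substrate)

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KSRNetwork):
            return NotImplemented
        return set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:
        return f"KSRNetwork({len(self.proteins)} proteins, {self.n_edges} edges)"


@dataclass(frozen=True)
class CompositeNetwork:
    """A PPI network and a KSR network over a shared identifier space."""

    ppi: PPINetwork
    ksr: KSRNetwork

    @property
    def n_ppi_edges(self) -> int:
        return self.ppi.n_edges

    @property
    def n_ksr_edges(self) -> int:
        return self.ksr.n_edges

    @property
    def shared_proteins(self) -> set[str]:
        return self.ppi.proteins & self.ksr.proteins

    def __repr__(self) -> str:
        return (
            f"CompositeNetwork({self.n_ppi_edges} PPI edges, "
            f"{self.n_ksr_edges} KSR edges, "
            f"{len(self.shared_proteins)} shared proteins)"
        )


def build_composite(ppi: PPINetwork, ksr: KSRNetwork) -> CompositeNetwork:
    return CompositeNetwork(ppi=ppi, ksr=ksr)


# ---------------------------------------------------------------------------
# Edge-list I/O.  Tab- or whitespace-delimited on read, tab on write;
# lines beginning '#' are comments.
# ---------------------------------------------------------------------------


def _iter_records(path: str | Path, header: bool = False) -> Iterator[tuple[int, list[str]]]:
    skipped_header = not header
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 fields, got {len(fields)}")
            yield lineno, fields


def load_ppi(path: str | Path, header: bool = False) -> PPINetwork:
    """Read a 2-column PPI edge list; (A,B)/(B,A) and duplicates collapse."""
    net = PPINetwork()
    n = 0
    for _, fields in _iter_records(path, header=header):
        net.add_edge(fields[0], fields[1])
        n += 1
    if n == 0:
        logger.warning("no PPI edges read from %s", path)
    return net


def load_ksr(path: str | Path, header: bool = False) -> KSRNetwork:
    """Read a 2-column kinase->substrate edge list; duplicates collapse."""
    net = KSRNetwork()
    n = 0
    for _, fields in _iter_records(path, header=header):
        net.add_edge(fields[0], fields[1])
        n += 1
    if n == 0:
        logger.warning("no KSR edges read from %s", path)
    return net


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")


def write_ksr(net: KSRNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# kinase\tsubstrate\n")
        for k, s in net.edges():
            fh.write(f"{k}\t{s}\n")
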