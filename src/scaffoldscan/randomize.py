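"""Degree-preserving PPI randomization and permutation-based FDR control.

The null model rewires the real PPI network by repeated partner exchange:
two interaction pairs A-B and C-D are drawn at random and replaced by A-D
and B-C, provided neither proposed pair occurs in the real network (nor,
in this implementation, in the current shuffled network, and neither is a
self-pair — either would silently change edge count or degrees).  Each
protein keeps its exact interaction degree, so any scaffold-like signal a
candidate shows in the shuffled data reflects degree alone.

For a candidate scaffold SP and a pathway-length cutoff l, the false
discovery rate is estimated as FDR = M/N, where N is the number of real
pathways of length >= l that SP scaffolds and M is the mean of the same
count over the randomized networks (full pipeline rerun per shuffle:
distance filter, pathway enumeration, common-interactor scan).  Selecting
per candidate the smallest l with FDR <= q* bounds the association-weighted
integral FDR by q*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import CompositeNetwork, KSRNetwork, PPINetwork, canonical_edge
from .pathways import (
    DEFAULT_MAX_LENGTH,
    DEFAULT_MAX_PATHWAYS,
    Pathway,
    enumerate_pathways,
    filter_ksr_by_distance,
)
from .scaffolds import CandidateAssociation, scan_candidates

logger = logging.getLogger(__name__)

__all__ = [
    "ShuffleResult",
    "FDRTable",
    "PredictionSet",
    "PathwayOptions",
    "shuffle_ppi",
    "run_scan",
    "build_fdr_table",
    "select_predictions",
]


@dataclass(frozen=True)
class PathwayOptions:
    """Settings shared by the real and randomized pipeline runs."""

    max_distance: int = 2
    min_length: int = 2
    max_length: int | None = DEFAULT_MAX_LENGTH
    closure: bool = True
    max_pathways: int = DEFAULT_MAX_PATHWAYS


@dataclass
class ShuffleResult:
    network: PPINetwork
    attempts: int
    accepted_swaps: int

    @property
    def mean_swaps_per_edge(self) -> float:
        """Average number of times an edge was rewired (each swap touches 2)."""
        e = self.network.n_simple_edges
        return 2.0 * self.accepted_swaps / e if e else 0.0


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_ppi(
    ppi: PPINetwork,
    reference: PPINetwork | None = None,
    n_attempts: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ShuffleResult:
    """Degree-preserving partner-exchange shuffle of the PPI network.

    ``reference`` is the real network whose pairs a rewiring may not
    recreate (defaults to ``ppi`` itself).  ``n_attempts`` defaults to the
    (non-self) edge count, which rewires each edge about twice on average.
    Homotypic pairs are carried through untouched.  Networks with fewer
    than two non-self edges are returned unchanged with a warning.
    """
    rng = _as_rng(seed)
    if reference is None:
        reference = ppi
    edges = [canonical_edge(a, b) for a, b in ppi.edges(include_self=False)]
    n_edges = len(edges)
    if n_edges < 2:
        logger.warning("fewer than two non-self edges; returning network unchanged")
        return ShuffleResult(network=ppi.copy(), attempts=0, accepted_swaps=0)
    if n_attempts is None:
        n_attempts = n_edges

    reference_set = {canonical_edge(a, b) for a, b in reference.edges(include_self=False)}
    current = set(edges)

    # Pre-draw randomness: two distinct edge indices plus an orientation bit
    # per attempt.
    if n_attempts:
        idx_i = rng.integers(0, n_edges, size=n_attempts)
        idx_j = rng.integers(0, n_edges - 1, size=n_attempts)
        idx_j = np.where(idx_j >= idx_i, idx_j + 1, idx_j)
        flips = rng.integers(0, 2, size=n_attempts)
    else:
        idx_i = idx_j = flips = np.empty(0, dtype=int)

    accepted = 0
    for i, j, flip in zip(idx_i, idx_j, flips):
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose a-d, b-c
        if a == d or b == c:
            continue
        e1 = canonical_edge(a, d)
        e2 = canonical_edge(b, c)
        if e1 == e2:
            continue
        if e1 in reference_set or e2 in reference_set:
            continue
        if e1 in current or e2 in current:
            continue
        current.discard(edges[i])
        current.discard(edges[j])
        current.add(e1)
        current.add(e2)
        edges[i] = e1
        edges[j] = e2
        accepted += 1

    shuffled = PPINetwork()
    for p in ppi.proteins:
        shuffled.add_protein(p)
    for e in current:
        shuffled.add_edge(*e)
    for p in ppi.self_interacting:
        shuffled.add_edge(p, p)
    return ShuffleResult(network=shuffled, attempts=int(n_attempts), accepted_swaps=accepted)


def run_scan(
    ppi: PPINetwork, ksr: KSRNetwork, opts: PathwayOptions = PathwayOptions()
) -> list[CandidateAssociation]:
    """Full scaffold scan: distance filter, pathway enumeration, candidate scan."""
    composite = CompositeNetwork(ppi=ppi, ksr=ksr)
    filtered = filter_ksr_by_distance(composite, max_distance=opts.max_distance)
    pathway_set = enumerate_pathways(
        filtered,
        min_length=opts.min_length,
        max_length=opts.max_length,
        closure=opts.closure,
        max_pathways=opts.max_pathways,
    )
    return scan_candidates(composite, pathway_set)


def _scaffold_pathway_map(
    associations: list[CandidateAssociation],
) -> dict[str, set[Pathway]]:
    out: dict[str, set[Pathway]] = {}
    for a in associations:
        out.setdefault(a.scaffold, set()).add(a.pathway)
    return out


@dataclass
class FDRTable:
    """Per (candidate, length-cutoff) permutation FDR estimates.

    ``table`` columns: scaffold, l, n_real, m_mean, m_var, fdr.
    ``associations`` are the real-network associations the table was built
    from; ``provenance`` records seeds and settings.
    """

    table: pd.DataFrame
    associations: list[CandidateAssociation] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def rows_for(self, scaffold: str) -> pd.DataFrame:
        return self.table[self.table["scaffold"] == scaffold]


def build_fdr_table(
    composite: CompositeNetwork,
    n_random: int = 1000,
    seed: int = 0,
    pathway_opts: PathwayOptions = PathwayOptions(),
    swap_rounds: int | None = None,
) -> FDRTable:
    """Estimate FDR = M/N for every candidate at every length cutoff.

    For each of ``n_random`` degree-preserving shuffles the full pipeline
    is rerun (the distance filter depends on the PPI) and, for every
    candidate observed in the real network, the number of shuffled pathways
    of length >= l it scaffolds is counted.  Replicate seeds derive from
    the master ``seed`` via a spawned seed sequence, recorded in provenance.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")

    associations = run_scan(composite.ppi, composite.ksr, pathway_opts)
    real_map = _scaffold_pathway_map(associations)
    candidates = sorted(real_map)

    # (scaffold, l) grid: l from min_length to the candidate's longest real pathway.
    grid: list[tuple[str, int]] = []
    n_real: dict[tuple[str, int], int] = {}
    for sp in candidates:
        lengths = [len(p) for p in real_map[sp]]
        for l in range(pathway_opts.min_length, max(lengths) + 1):
            key = (sp, l)
            n = sum(1 for p in real_map[sp] if len(p) >= l)
            if n > 0:
                grid.append(key)
                n_real[key] = n

    m_sum = {key: 0.0 for key in grid}
    m_sumsq = {key: 0.0 for key in grid}
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_random)
    for child in children:
        rng = np.random.default_rng(child)
        shuffled = shuffle_ppi(
            composite.ppi, reference=composite.ppi, n_attempts=swap_rounds, seed=rng
        ).network
        rand_assoc = run_scan(shuffled, composite.ksr, pathway_opts)
        rand_map = _scaffold_pathway_map(rand_assoc)
        for sp, l in grid:
            m = sum(1 for p in rand_map.get(sp, ()) if len(p) >= l)
            m_sum[(sp, l)] += m
            m_sumsq[(sp, l)] += m * m

    rows = []
    for sp, l in grid:
        n = n_real[(sp, l)]
        mean = m_sum[(sp, l)] / n_random
        var = m_sumsq[(sp, l)] / n_random - mean * mean
        rows.append(
            {
                "scaffold": sp,
                "l": l,
                "n_real": n,
                "m_mean": mean,
                "m_var": max(var, 0.0),
                "fdr": mean / n,
            }
        )
    table = pd.DataFrame(
        rows, columns=["scaffold", "l", "n_real", "m_mean", "m_var", "fdr"]
    )
    return FDRTable(
        table=table,
        associations=associations,
        provenance={
            "n_random": n_random,
            "seed": seed,
            "swap_rounds": swap_rounds,
            "pathway_opts": vars(pathway_opts) | {},
        },
    )


@dataclass
class PredictionSet:
    """Accepted (scaffold, pathway) associations at a chosen FDR cutoff."""

    associations: list[CandidateAssociation]
    per_scaffold_cutoff: dict[str, int]
    q_star: float
    integral_fdr: float

    @property
    def scaffolds(self) -> set[str]:
        return {a.scaffold for a in self.associations}

    @property
    def pathways(self) -> set[Pathway]:
        return {a.pathway for a in self.associations}

    def scaffold_pathways(self) -> dict[str, set[Pathway]]:
        return _scaffold_pathway_map(self.associations)


def select_predictions(
    table: FDRTable,
    associations: list[CandidateAssociation] | None = None,
    q_star: float = 0.01,
) -> PredictionSet:
    """Retain, per candidate, pathways at the smallest cutoff with FDR <= q*.

    A candidate with no cutoff meeting q* is dropped entirely.  The
    integral FDR is the retained-pathway-weighted mean of the per-candidate
    FDRs at their chosen cutoffs; it is <= q* by construction.
    """
    if associations is None:
        associations = table.associations
    df = table.table
    cutoffs: dict[str, int] = {}
    fdr_at_cutoff: dict[str, float] = {}
    if len(df):
        ok = df[df["fdr"] <= q_star]
        for sp, sub in ok.groupby("scaffold"):
            l_star = int(sub["l"].min())
            cutoffs[sp] = l_star
            fdr_at_cutoff[sp] = float(
                sub.loc[sub["l"] == l_star, "fdr"].iloc[0]
            )
    retained = [
        a
        for a in associations
        if a.scaffold in cutoffs and a.pathway_length >= cutoffs[a.scaffold]
    ]
    m_total = 0
    mq_total = 0.0
    counts: dict[str, int] = {}
    for a in retained:
        counts[a.scaffold] = counts.get(a.scaffold, 0) + 1
    for sp, m in counts.items():
        m_total += m
        mq_total += m * fdr_at_cutoff[sp]
    integral = mq_total / m_total if m_total else 0.0
    return PredictionSet(
        associations=retained,
        per_scaffold_cutoff=cutoffs,
        q_star=q_star,
        integral_fdr=integral,
    )
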