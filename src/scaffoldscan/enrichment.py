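"""Downstream statistics on a prediction set.

Covers known-scaffold recovery, homotypic (self-interaction) and
heterotypic (scaffold-scaffold PPI) enrichment with degree-matched
controls, shared-pathway complex analysis, intrinsic/extrinsic
phosphorylation regulation of scaffolds, phosphosite profiling, and
generic hypergeometric term enrichment.

All enrichment p-values are one-sided upper-tail hypergeometric
probabilities.  Degree- and length-matched controls draw from geometric
bins (ratio 2: degree 1, 2-3, 4-7, ...) so that a matched sample
reproduces the reference group's degree (or size) profile without copying
its identity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import KSRNetwork, PPINetwork
from .pathways import Pathway
from .randomize import PredictionSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "RegulationCase",
    "PhosphositeTable",
    "GroupSiteSummary",
    "hypergeom_sf",
    "recovery_stats",
    "homotypic_analysis",
    "degree_matched_sample",
    "heterotypic_analysis",
    "shared_pathway_ppi",
    "intrinsic_cases",
    "extrinsic_cases",
    "regulation_null",
    "phosphosite_profile",
    "term_enrichment",
    "load_sites",
]


# ---------------------------------------------------------------------------
# Hypergeometric machinery
# ---------------------------------------------------------------------------


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing n from N with K successes.

    Parameters follow the gene-set convention: k observed hits in a sample
    of n, against K marked elements in a population of N.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """Observed-vs-expected overlap with a hypergeometric upper-tail p."""

    k: int
    K: int
    n: int
    N: int
    expected: float
    fold: float
    p_value: float
    sensitivity: float | None = None
    term: str | None = None
    p_adjusted: float | None = None


def _enrich(k: int, K: int, n: int, N: int, **extra) -> EnrichmentResult:
    expected = n * K / N
    fold = math.inf if expected == 0 and k > 0 else (k / expected if expected else 0.0)
    return EnrichmentResult(
        k=k, K=K, n=n, N=N,
        expected=expected, fold=fold,
        p_value=hypergeom_sf(k, K, n, N),
        **extra,
    )


def recovery_stats(
    predicted: set[str], known: set[str], proteome_size: int
) -> EnrichmentResult:
    """Enrichment of curated known scaffolds among the predictions.

    Expected overlap for a random draw of |predicted| proteins from a
    proteome of ``proteome_size`` is |predicted| * |known| / proteome_size;
    fold is observed/expected and sensitivity the recovered fraction of the
    known set.
    """
    if not known:
        raise ValueError("empty known-scaffold set")
    if proteome_size < len(predicted | known):
        raise ValueError("proteome_size smaller than the union of the two sets")
    k = len(predicted & known)
    return _enrich(
        k=k, K=len(known), n=len(predicted), N=proteome_size,
        sensitivity=k / len(known),
    )


def homotypic_analysis(ppi: PPINetwork, scaffolds: set[str]) -> EnrichmentResult:
    """Are self-interacting (homodimer-forming) proteins enriched among scaffolds?

    Sample = scaffolds present in the PPI network; population = all PPI
    proteins; successes = proteins with a homotypic pair.
    """
    present = scaffolds & ppi.proteins
    dropped = scaffolds - present
    if dropped:
        logger.warning("%d scaffolds absent from the PPI network dropped", len(dropped))
    if not present:
        raise ValueError("no scaffolds present in the PPI network")
    selfers = ppi.self_interacting
    return _enrich(
        k=len(present & selfers),
        K=len(selfers),
        n=len(present),
        N=ppi.n_proteins,
    )


# ---------------------------------------------------------------------------
# Degree-matched controls
# ---------------------------------------------------------------------------


def _geom_bin(value: int) -> int:
    """Geometric bin index with ratio 2: 0 -> 0, 1 -> 1, 2-3 -> 2, 4-7 -> 3 ..."""
    return 0 if value <= 0 else value.bit_length()


def _binned(values: Mapping[str, int]) -> dict[int, list[str]]:
    bins: dict[int, list[str]] = {}
    for p in sorted(values):
        bins.setdefault(_geom_bin(values[p]), []).append(p)
    return bins


def _matched_pick(
    bins: dict[int, list[str]],
    target_bin: int,
    forbidden: set[str],
    fallback: set[str],
    rng: np.random.Generator,
) -> str:
    """Pick uniformly from the target bin, widening to the nearest non-empty
    bin; as a last resort allow ``fallback`` members (e.g. the reference set
    itself) that are not yet taken."""
    order = sorted(bins, key=lambda b: (abs(b - target_bin), b))
    for allow_fallback in (False, True):
        for b in order:
            avoid = forbidden if allow_fallback else forbidden | fallback
            pool = [p for p in bins[b] if p not in avoid]
            if pool:
                return pool[int(rng.integers(len(pool)))]
    raise RuntimeError("candidate pool exhausted")


def degree_matched_sample(
    ppi: PPINetwork,
    reference: set[str],
    seed: int | np.random.Generator = 0,
) -> set[str]:
    """Sample |reference| distinct proteins matching the reference degrees.

    One protein is drawn, without replacement, from the geometric degree
    bin of each reference protein; empty bins fall back to the nearest
    non-empty one (and, when the non-reference pool is exhausted, to unused
    reference proteins, so matching the whole network returns the network).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reference = reference & ppi.proteins
    degrees = ppi.degree_sequence()
    bins = _binned(degrees)
    chosen: set[str] = set()
    for p in sorted(reference):
        pick = _matched_pick(bins, _geom_bin(degrees[p]), chosen, reference, rng)
        chosen.add(pick)
    return chosen


def _internal_edges(ppi: PPINetwork, group: set[str]) -> int:
    """Non-self PPI edges with both endpoints inside ``group``."""
    return sum(
        1 for p in group for q in ppi.neighbors(p) if q in group and q > p
    )


def heterotypic_analysis(
    ppi: PPINetwork,
    scaffolds: set[str],
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[int, float]:
    """PPIs among scaffolds vs. the degree-matched expectation.

    Returns (observed internal edge count, mean internal edge count over
    ``n_reps`` degree-matched random protein sets).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scaffolds = scaffolds & ppi.proteins
    observed = _internal_edges(ppi, scaffolds)
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_reps):
        sample = degree_matched_sample(ppi, scaffolds, rng)
        total += _internal_edges(ppi, sample)
    return observed, total / n_reps


def shared_pathway_ppi(
    predictions: PredictionSet,
    ppi: PPINetwork,
    n_reps: int = 10_000,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Do scaffolds sharing a pathway interact with each other?

    Returns (number of unordered scaffold pairs co-associated with at least
    one identical pathway, how many of those pairs are PPI-adjacent, and
    the mean adjacent count among ``n_reps`` draws of equally many
    degree-matched random pairs).
    """
    by_scaffold = predictions.scaffold_pathways()
    scaffolds = sorted(by_scaffold)
    sharing = [
        (a, b)
        for a, b in itertools.combinations(scaffolds, 2)
        if by_scaffold[a] & by_scaffold[b]
    ]
    if not sharing:
        logger.warning("no scaffold pairs share a pathway")
        return 0, 0, 0.0
    with_ppi = sum(1 for a, b in sharing if ppi.has_edge(a, b))

    rng = np.random.default_rng(seed)
    degrees = ppi.degree_sequence()
    bins = _binned(degrees)
    total = 0
    for _ in range(n_reps):
        count = 0
        for a, b in sharing:
            x = _matched_pick(bins, _geom_bin(degrees.get(a, 0)), set(), set(), rng)
            y = _matched_pick(bins, _geom_bin(degrees.get(b, 0)), {x}, set(), rng)
            if ppi.has_edge(x, y):
                count += 1
        total += count
    return len(sharing), with_ppi, total / n_reps


# ---------------------------------------------------------------------------
# Regulation of the scaffolds themselves
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class RegulationCase:
    """A phosphorylation event coordinating a scaffold with its pathway.

    Intrinsic: a kinase member of the pathway phosphorylates the scaffold.
    Extrinsic: a kinase outside the pathway phosphorylates both the
    scaffold and a pathway member (``co_target``).
    """

    scaffold: str
    pathway: Pathway
    kinase: str
    mode: str
    co_target: str | None = None


def _scaffold_pathway_pairs(predictions: PredictionSet) -> list[tuple[str, Pathway]]:
    return sorted({(a.scaffold, a.pathway) for a in predictions.associations})


def _count_intrinsic(
    pairs: Iterable[tuple[str, Pathway]], ksr: KSRNetwork, collect: bool = False
):
    cases = []
    count = 0
    for scaffold, pathway in pairs:
        for kinase in pathway:
            if ksr.has_edge(kinase, scaffold):
                count += 1
                if collect:
                    cases.append(
                        RegulationCase(scaffold, pathway, kinase, "intrinsic")
                    )
    return (count, cases) if collect else (count, None)


def _count_extrinsic(
    pairs: Iterable[tuple[str, Pathway]], ksr: KSRNetwork, collect: bool = False
):
    cases = []
    count = 0
    for scaffold, pathway in pairs:
        members = set(pathway)
        for kinase in ksr.kinases_of(scaffold):
            if kinase in members:
                continue
            for co_target in pathway:
                if ksr.has_edge(kinase, co_target):
                    count += 1
                    if collect:
                        cases.append(
                            RegulationCase(
                                scaffold, pathway, kinase, "extrinsic", co_target
                            )
                        )
    return (count, cases) if collect else (count, None)


def intrinsic_cases(predictions: PredictionSet, ksr: KSRNetwork) -> list[RegulationCase]:
    """All (scaffold, pathway, kinase) triples with an in-pathway kinase
    phosphorylating the scaffold."""
    _, cases = _count_intrinsic(_scaffold_pathway_pairs(predictions), ksr, collect=True)
    return sorted(cases)


def extrinsic_cases(predictions: PredictionSet, ksr: KSRNetwork) -> list[RegulationCase]:
    """All (scaffold, pathway, kinase, co_target) tuples with an outside
    kinase phosphorylating both scaffold and a pathway member."""
    _, cases = _count_extrinsic(_scaffold_pathway_pairs(predictions), ksr, collect=True)
    return sorted(cases)


def regulation_null(
    predictions: PredictionSet,
    ksr: KSRNetwork,
    proteome: set[str],
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Expected intrinsic/extrinsic case counts under random scaffolds.

    Each replicate replaces every distinct scaffold with a protein drawn
    uniformly without replacement from ``proteome`` (pathway associations
    kept) and recounts both case types; means over replicates returned.
    """
    pairs = _scaffold_pathway_pairs(predictions)
    scaffolds = sorted({s for s, _ in pairs})
    if len(proteome) < len(scaffolds):
        raise ValueError("proteome smaller than the scaffold set")
    pool = sorted(proteome)
    rng = np.random.default_rng(seed)
    tot_in = tot_ex = 0.0
    for _ in range(n_reps):
        picks = rng.choice(len(pool), size=len(scaffolds), replace=False)
        mapping = {s: pool[i] for s, i in zip(scaffolds, picks)}
        remapped = [(mapping[s], pw) for s, pw in pairs]
        tot_in += _count_intrinsic(remapped, ksr)[0]
        tot_ex += _count_extrinsic(remapped, ksr)[0]
    return tot_in / n_reps, tot_ex / n_reps


# ---------------------------------------------------------------------------
# Phosphosite profiling
# ---------------------------------------------------------------------------


class PhosphositeTable:
    """Known phosphorylation sites: (protein, position, residue) records."""

    RESIDUES = frozenset("STY")

    def __init__(self, records: Iterable[tuple[str, int, str]] = ()) -> None:
        self._records: set[tuple[str, int, str]] = set()
        for protein, position, residue in records:
            self.add(protein, position, residue)

    def add(self, protein: str, position: int, residue: str) -> None:
        position = int(position)
        if position < 1:
            raise ValueError(f"phosphosite position must be >= 1, got {position}")
        if residue not in self.RESIDUES:
            raise ValueError(f"phosphosite residue must be S/T/Y, got {residue!r}")
        self._records.add((protein, position, residue))

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[tuple[str, int, str]]:
        return sorted(self._records)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for protein, _, _ in self._records:
            out[protein] = out.get(protein, 0) + 1
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# protein\tposition\tresidue\n")
            for protein, position, residue in self.records():
                fh.write(f"{protein}\t{position}\t{residue}\n")


def load_sites(path: str | Path) -> PhosphositeTable:
    table = PhosphositeTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            table.add(fields[0], int(fields[1]), fields[2])
    return table


@dataclass
class GroupSiteSummary:
    n_proteins: int
    mean_sites: float
    frac_at_least_1: float
    frac_at_least_5: float


def _site_summary(counts: Mapping[str, int], group: Iterable[str]) -> GroupSiteSummary:
    group = sorted(group)
    per = [counts.get(p, 0) for p in group]
    n = len(per)
    if n == 0:
        return GroupSiteSummary(0, 0.0, 0.0, 0.0)
    return GroupSiteSummary(
        n_proteins=n,
        mean_sites=sum(per) / n,
        frac_at_least_1=sum(c >= 1 for c in per) / n,
        frac_at_least_5=sum(c >= 5 for c in per) / n,
    )


def phosphosite_profile(
    sites: PhosphositeTable,
    group: set[str],
    background: set[str],
    length_table: Mapping[str, int] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, GroupSiteSummary]:
    """Per-protein phosphosite statistics for a group vs. a background.

    Returns mean sites per protein and the fractions with >= 1 and >= 5
    sites for both sets.  With ``length_table`` given (protein -> residue
    count), an additional ``background_length_matched`` summary resamples
    the background matched on geometric protein-length bins, averaging the
    statistics over ``n_reps`` draws — the control showing the group's
    excess is not a protein-size artifact.
    """
    if not group or not background:
        raise ValueError("group and background must be non-empty")
    counts = sites.counts()
    out = {
        "group": _site_summary(counts, group),
        "background": _site_summary(counts, background),
    }
    if length_table is not None:
        rng = np.random.default_rng(seed)
        pool = sorted(background - group)
        bins = _binned({p: length_table.get(p, 0) for p in pool})
        means = np.zeros(3)
        for _ in range(n_reps):
            chosen: set[str] = set()
            for p in sorted(group):
                pick = _matched_pick(
                    bins, _geom_bin(length_table.get(p, 0)), chosen, set(), rng
                )
                chosen.add(pick)
            s = _site_summary(counts, chosen)
            means += (s.mean_sites, s.frac_at_least_1, s.frac_at_least_5)
        means /= n_reps
        out["background_length_matched"] = GroupSiteSummary(
            n_proteins=len(group),
            mean_sites=float(means[0]),
            frac_at_least_1=float(means[1]),
            frac_at_least_5=float(means[2]),
        )
    return out


# ---------------------------------------------------------------------------
# Generic term enrichment
# ---------------------------------------------------------------------------


def term_enrichment(
    membership: Mapping[str, set[str]],
    group: set[str],
    background: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term in a membership table.

    ``membership`` maps term -> annotated proteins.  Group must be a subset
    of background; terms with no background members are skipped.  Results
    are sorted by raw p and carry Benjamini-Hochberg adjusted values.
    """
    if not group <= background:
        raise ValueError("group must be a subset of background")
    N = len(background)
    n = len(group)
    results: list[EnrichmentResult] = []
    for term in sorted(membership):
        members = membership[term] & background
        if not members:
            logger.debug("term %s has no background members; skipped", term)
            continue
        k = len(group & members)
        results.append(_enrich(k=k, K=len(members), n=n, N=N, term=term))
    if results:
        _, adj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
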