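"""Candidate scaffold detection and single-input-module (SIM) motif counting.

A scaffold protein tethers the members of a kinase cascade together; the
operational signature used here is stringent: a candidate must show a PPI
with *every* member of a pathway (common-interactor criterion).  Scaffolds
and adaptors are not distinguished, and kinases themselves are eligible
candidates.

The corresponding network motif is the single-input module: one protein
interacting with a set of proteins that form a linear KSR cascade.  Motif
occurrences are counted as (protein, cascade) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .network import CompositeNetwork, PPINetwork
from .pathways import Pathway, PathwaySet, enumerate_pathways

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateAssociation",
    "MotifCount",
    "common_interactors",
    "scan_candidates",
    "count_sim_motifs",
]


@dataclass(frozen=True, order=True)
class CandidateAssociation:
    """A (candidate scaffold, pathway) pair passing the common-interactor scan.

    ``scaffold_degree`` is the candidate's PPI degree n and
    ``pathway_length`` the pathway's protein count l — the two quantities
    the permutation null corrects for.
    """

    scaffold: str
    pathway: Pathway
    scaffold_degree: int
    pathway_length: int


@dataclass(frozen=True)
class MotifCount:
    cascade_length: int
    observed: int


def common_interactors(
    ppi: PPINetwork, pathway: Pathway, exclude_members: bool = True
) -> set[str]:
    """Proteins with a PPI to every member of ``pathway``.

    A member counts as interacting with itself only through an explicit
    homotypic pair.  A pathway member absent from the PPI network makes the
    result empty (logged, not an error).
    """
    sets = []
    for m in pathway:
        if m not in ppi:
            logger.debug("pathway member %s absent from PPI network", m)
            return set()
        nbrs = ppi.neighbors(m)
        if ppi.has_self_pair(m):
            nbrs.add(m)
        sets.append(nbrs)
    common = set.intersection(*sorted(sets, key=len))
    if exclude_members:
        common -= set(pathway)
    return common


def scan_candidates(
    composite: CompositeNetwork,
    pathways: PathwaySet,
    allow_member_scaffold: bool = False,
) -> list[CandidateAssociation]:
    """One association per (common interactor, pathway) pair.

    Deterministic order: by scaffold identifier, then pathway tuple.
    """
    ppi = composite.ppi
    out: list[CandidateAssociation] = []
    for pathway in pathways:
        for scaffold in common_interactors(
            ppi, pathway, exclude_members=not allow_member_scaffold
        ):
            out.append(
                CandidateAssociation(
                    scaffold=scaffold,
                    pathway=pathway,
                    scaffold_degree=ppi.degree(scaffold),
                    pathway_length=len(pathway),
                )
            )
    out.sort()
    return out


def count_sim_motifs(composite: CompositeNetwork, cascade_length: int) -> MotifCount:
    """Count SIM motifs with a cascade of exactly ``cascade_length`` proteins.

    A motif is a (protein, cascade) pair where the cascade is a simple KSR
    chain and the protein (not itself a cascade member) interacts with all
    of its members.
    """
    if cascade_length < 2:
        raise ValueError("cascade_length must be >= 2")
    cascades = enumerate_pathways(
        composite.ksr,
        min_length=cascade_length,
        max_length=cascade_length,
        closure=False,
    )
    observed = sum(
        len(common_interactors(composite.ppi, c)) for c in cascades
    )
    return MotifCount(cascade_length=cascade_length, observed=observed)
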