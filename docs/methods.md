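# Methods

## Model and assumptions

The object of study is a composite signaling network: an undirected PPI
graph G over protein identifiers and a directed KSR graph D (kinase →
substrate) over a partially overlapping identifier space. Identifiers are
opaque tokens; no aliasing or symbol normalization is attempted, so the
caller is responsible for harmonizing identifiers across the two inputs.

A *pathway* is an ordered chain of ≥ 2 distinct proteins whose consecutive
pairs are KSR edges. "Length" counts proteins, so one KSR edge is a
length-2 pathway. Pathways are required to be simple; on a cyclic KSR
graph an unconstrained DFS enumeration would not terminate, and a protein
appearing twice in one cascade has no physical reading here. Every
contiguous sub-chain of a pathway is also a pathway (a long cascade may
lack a scaffold while a sub-chain has one). Enumeration starts from every
edge source; since every internal node of a chain is itself an edge
source, the explicit closure step is provably redundant, which the test
suite verifies rather than assumes.

A *candidate scaffold* for a pathway is a protein, not itself a member,
with a PPI to every member. This is deliberately stringent
(partial-coverage scaffolds are out of scope) and does not distinguish
scaffolds from adaptors. Kinases are eligible candidates. A pathway member
can only count as interacting with itself through an explicit homotypic
pair, and member-candidates are excluded by default (flag
`allow_member_scaffold` to include them).

Homotypic (self) interactions are stored as real edges and included in
edge counts, but contribute nothing to degree, paths, shuffling, or
degree matching: a self-loop cannot mediate a path, and treating it as
degree would distort the degree-preserving null. They are consulted only
by the homodimerization analysis.

KSR edges whose endpoints are more than `max_distance` (default 2) PPI
hops apart are dropped before enumeration: a pair without a common
neighbor cannot participate in any scaffolded pathway, so the filter is
exact for the scan, not an approximation. Edges with an endpoint absent
from the PPI network are likewise dropped (distance = unreachable).

## Null model and FDR

The null rewires G by partner exchange: draw two distinct non-self edges
A–B and C–D (orientation of the second edge randomized), propose A–D and
B–C, and accept only if neither proposed pair (i) is a self-pair, (ii)
occurs in the *real* network, or (iii) occurs in the current shuffled
network. Checks (i) and (iii) go beyond the classical description, which
screens only against the real data; without them a swap could silently
create duplicate or self edges and break the degree/edge-count invariant
the null depends on. Attempts default to the edge count, which rewires
each edge about twice on average (each accepted swap touches two edges;
the acceptance rate on sparse networks is near 1).

For candidate SP and length cutoff l, `FDR(SP, l) = M/N`: N = number of
real pathways of length ≥ l scaffolded by SP, M = mean of that count over
`n_random` shuffled networks, with the entire pipeline (distance filter →
enumeration → scan) recomputed per shuffle because the distance filter
depends on the PPI. Counting in the shuffled network is done for the same
node SP, which preserves its degree by construction. Rows with N = 0 are
omitted (no hypothesis). Per candidate the smallest l with FDR ≤ q* is
kept (candidate dropped if none); retained associations are those of
length ≥ l*. The integral FDR Σmᵢqᵢ/Σmᵢ over retained candidates is ≤ q*
because it is a weighted mean of values each ≤ q*; the suite asserts it on
every run.

The estimate's resolution is 1/(n_random·N): with 50 randomizations a
candidate scaffolding a single pathway can only receive FDR ∈ {0, 0.02,
0.04, …}, so q* = 0.01 either accepts it at M = 0 or rejects it outright.
This granularity, not the scan, dominates behavior at small n_random, and
is why production runs should use the 1000-replicate default.

Reproducibility: replicate seeds are spawned from the master seed via
`numpy.random.SeedSequence`, recorded in provenance; the FDR table is
bit-for-bit reproducible given (networks, seed, n_random).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `max_distance` | 2 | PPI-hop cutoff for the KSR pre-filter (hops) |
| `min_length` / `max_length` | 2 / 8 | pathway protein-count bounds; the ceiling is an enumeration guard, with an explicit overflow error past `max_pathways` (10⁶) |
| `n_random` | 1000 | shuffled replicates for M |
| `swap_rounds` | edge count | shuffle attempts per replicate |
| `q_star` | 0.01 | per-candidate FDR cutoff |

## Downstream statistics

All enrichment p-values are one-sided upper-tail hypergeometric (the
question is always excess, never depletion), computed via
`scipy.stats.hypergeom.sf` and cross-checked in tests against exhaustive
PMF summation. Term enrichment additionally reports Benjamini–Hochberg
adjusted values.

Degree-matched controls sample one protein per reference protein from
geometric degree bins (ratio 2: degree 1, 2–3, 4–7, …), without
replacement, falling back to the nearest non-empty bin and, when the
non-reference pool is exhausted, to unused reference proteins. Geometric
bins reflect that degree distinguishability is multiplicative in
heavy-tailed networks; "similar degree" has no canonical definition, so
the bin rule is stated rather than hidden. The same binning matches
protein lengths in the phosphosite size-control.

Regulation cases are counted as tuples — (scaffold, pathway, kinase) for
intrinsic, (scaffold, pathway, kinase, co-target) for extrinsic — so one
scaffold–pathway pair can contribute several cases. Intrinsic and
extrinsic sets are disjoint by the kinase-in-pathway predicate. The
random-scaffold null resamples the scaffold identities uniformly from a
caller-supplied proteome (population sizes differ by analysis and are
always explicit arguments, never implicit).

## Synthetic study conditions

The generator emulates the statistical shape of curated composite
networks at one tenth scale: 1,200 proteins; a configuration-model PPI
background with power-law degrees (γ = 2.5, minimum degree 3, ≈ 4,700–
5,400 edges after simplification); 2% homotypic pairs; 24 kinase cascades
of lengths 2–5 (60 chain edges) plus 50 random kinase→substrate edges
(110 KSR edges total); 18 planted scaffolds, each wired by PPI edges to
every member of **two** cascades — real scaffolds predominantly serve
multiple pathways, and a scaffold with several real pathways receives an
FDR estimate fine enough to resolve at q* = 0.01 even with few
randomizations. Phosphosite counts are Poisson (mean 12 on scaffolds, 2
on background); only means are characterized in real data, so the
distribution family is a modeling choice. Complex wiring and
intrinsic/extrinsic regulatory wiring default to off; analyses that study
those effects enable them explicitly.

What the generator does *not* emulate: identifier noise and database
merge artifacts, confidence-weighted or directionally annotated PPIs,
correlated false negatives (study bias), cell-type specificity, and
overlapping cascades sharing kinases. Passing tests therefore demonstrate
the machinery's correctness and its operating characteristics under a
clean planted-signal regime, not performance on real interactomes.

## Numerical and degenerate-input choices

Distances use a hop-count BFS on the loop-free graph; the unreachable
sentinel is +inf and pairs with a protein absent from the network are
reported in a distinct "absent" bin. Histogram fractions sum to 1 across
all bins. Empty edge files load as empty networks with a warning; a
malformed line is a parse error naming the line number. Networks with
fewer than two non-self edges are returned unshuffled with a warning.
Empty prediction sets evaluate to sensitivity 0 and empirical FDR 0 by
convention (logged). Fold enrichment with zero expectation reports
infinity (k > 0) or 0 (k = 0). Ties in candidate ordering are broken by
(scaffold id, pathway tuple), making all outputs deterministic.

## Problem sizes used by the test and acceptance runs

Oracle comparisons run on graphs of ≤ 60 nodes (distances), ≤ 15 nodes
(pathway enumeration), ≤ 40 nodes (scan). The end-to-end recovery check
runs the default study conditions over 10 generated worlds at 50
randomizations each; the acceptance script uses 3 worlds at 50
randomizations plus a 10,000-edge shuffle calibration. These sizes were
chosen so a full run completes comfortably on a single core while leaving
the estimates' Monte-Carlo error well inside the asserted margins.

## Known limitations

Candidates interacting with only a subset of pathway members are not
considered; scoring is per (candidate, cutoff) and ignores correlation
between nested cutoffs; the shuffle's reject-against-real rule makes the
null slightly conservative on dense neighborhoods; `n_random` below a few
hundred quantizes FDR values coarsely (see above); and the generator's
planted cascades are member-disjoint, so shared-component cross-talk
between pathways is absent from the synthetic regime.
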