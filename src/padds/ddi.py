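"""Candidate domain-domain interactions and their counting statistics.

Under the mediation assumption, every observed protein-protein
interaction is accounted for by at least one pair of domains, one on
each interacting protein.  For an unordered domain pair (i, j) over a
network of n proteins and m interactions:

* ``O_ij`` — interacting protein pairs where one protein carries i and
  the other carries j;
* ``N_ij`` — non-interacting pairs likewise, the negative class being
  all C(n, 2) protein pairs minus the m interactions;
* ``C_ij`` — proteins in which i and j co-occur (for i = j, proteins
  carrying i).

The association score ``O/(O+N)`` is the fraction of carrier pairs that
interact; the modified association score ``O^2/(O + alpha*N)``
interpolates between raw coverage (alpha = 0, where it equals O) and
specificity-weighted coverage (alpha = 1, where it equals the
association score times O).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

__all__ = [
    "Pair",
    "unordered_pair",
    "PPINetwork",
    "CandidateDDI",
    "DDIContext",
    "enumerate_candidates",
    "association_score",
    "modified_association",
]

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


def unordered_pair(a: str, b: str) -> Pair:
    """Canonical (sorted) representation of an unordered id pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """An undirected protein interaction network: n proteins, m edges."""

    proteins: FrozenSet[str]
    interactions: FrozenSet[Pair]

    def __post_init__(self) -> None:
        for p, q in self.interactions:
            if p not in self.proteins or q not in self.proteins:
                raise ValueError(f"interaction ({p}, {q}) has endpoint outside proteins")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        proteins: Iterable[str] | None = None,
        include_self: bool = False,
    ) -> "PPINetwork":
        """Build a network from an edge list.

        Duplicate and reversed-duplicate edges collapse with a logged
        warning; self-edges are dropped unless ``include_self``.
        ``proteins`` may widen the universe beyond edge endpoints.
        """
        seen: Set[Pair] = set()
        n_dup = n_self = 0
        for a, b in edges:
            if a == b and not include_self:
                n_self += 1
                continue
            pair = unordered_pair(a, b)
            if pair in seen:
                n_dup += 1
            seen.add(pair)
        if n_dup:
            logger.warning("collapsed %d duplicate interaction(s)", n_dup)
        if n_self:
            logger.warning("dropped %d self-interaction(s)", n_self)
        universe = set(proteins) if proteins is not None else set()
        for p, q in seen:
            universe.add(p)
            universe.add(q)
        return cls(proteins=frozenset(universe), interactions=frozenset(seen))

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def m(self) -> int:
        return len(self.interactions)

    @property
    def n_noninteracting(self) -> int:
        """Size of the negative class: C(n, 2) - m."""
        return self.n * (self.n - 1) // 2 - self.m


@dataclass(frozen=True)
class CandidateDDI:
    """An unordered domain pair that can explain >= 1 observed interaction.

    ``multiplicity`` counts the observed interactions this pair explains
    more than once (both proteins carry both domains) — tie-break
    material, not part of O.
    """

    domain_i: str
    domain_j: str
    O: int
    N: int
    C: int
    explained_ppis: FrozenSet[Pair]
    multiplicity: int = 0

    def __post_init__(self) -> None:
        if self.O != len(self.explained_ppis):
            raise ValueError("O must equal the number of explained interactions")
        if min(self.O, self.N, self.C) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def pair(self) -> Pair:
        return (self.domain_i, self.domain_j)


@dataclass(frozen=True)
class DDIContext:
    """All candidate DDIs of a network plus shared bookkeeping.

    ``explainers`` maps each interaction with at least one annotated
    endpoint pair to the candidates able to explain it; interactions
    where no domain pair exists are listed in ``unexplainable`` rather
    than silently dropped.
    """

    network: PPINetwork
    candidates: Mapping[Pair, CandidateDDI]
    maxC: int
    explainers: Mapping[Pair, Tuple[Pair, ...]]
    unexplainable: Tuple[Pair, ...]


def enumerate_candidates(
    network: PPINetwork, annotations: Mapping[str, Set[str] | FrozenSet[str]]
) -> DDIContext:
    """Enumerate candidate DDIs of a network and compute O, N, C.

    A candidate (i, j) exists iff some interaction has i on one endpoint
    and j on the other.  The negative universe for N is the network's own
    n proteins; unannotated proteins carry no domains but still count
    toward the C(n, 2) pair universe.
    """
    domains_of: Dict[str, FrozenSet[str]] = {
        p: frozenset(annotations.get(p, ())) for p in network.proteins
    }

    explained: Dict[Pair, Set[Pair]] = {}
    multi: Dict[Pair, int] = {}
    explainers: Dict[Pair, Tuple[Pair, ...]] = {}
    unexplainable: List[Pair] = []
    for ppi in sorted(network.interactions):
        p, q = ppi
        placements: Dict[Pair, int] = {}
        for i in domains_of[p]:
            for j in domains_of[q]:
                dpair = unordered_pair(i, j)
                placements[dpair] = placements.get(dpair, 0) + 1
        if not placements:
            unexplainable.append(ppi)
            continue
        explainers[ppi] = tuple(sorted(placements))
        for dpair, count in placements.items():
            explained.setdefault(dpair, set()).add(ppi)
            if count >= 2:
                multi[dpair] = multi.get(dpair, 0) + 1

    carriers: Dict[str, Set[str]] = {}
    for p, doms in domains_of.items():
        for d in doms:
            carriers.setdefault(d, set()).add(p)

    candidates: Dict[Pair, CandidateDDI] = {}
    for dpair in sorted(explained):
        i, j = dpair
        ppis = frozenset(explained[dpair])
        if i == j:
            a = carriers[i]
            total = len(a) * (len(a) - 1) // 2
            c = len(a)
        else:
            a, b = carriers[i], carriers[j]
            inter = len(a & b)
            total = len(a) * len(b) - inter - inter * (inter - 1) // 2
            c = inter
        o = len(ppis)
        n = total - o
        if n < 0:
            raise AssertionError(f"negative N for candidate {dpair}")
        candidates[dpair] = CandidateDDI(
            domain_i=i,
            domain_j=j,
            O=o,
            N=n,
            C=c,
            explained_ppis=ppis,
            multiplicity=multi.get(dpair, 0),
        )

    max_c = max((c.C for c in candidates.values()), default=0)
    if unexplainable:
        logger.warning(
            "%d interaction(s) have no annotated domain pair and cannot be explained",
            len(unexplainable),
        )
    return DDIContext(
        network=network,
        candidates=candidates,
        maxC=max_c,
        explainers=explainers,
        unexplainable=tuple(unexplainable),
    )


def association_score(O: int, N: int) -> float:
    """Probability-of-interaction estimate O / (O + N).

    Undefined when no protein pair carries the domain combination.
    """
    if O + N == 0:
        raise ValueError("association score undefined for O = N = 0")
    return O / (O + N)


def modified_association(O: int, N: int, alpha: float) -> float:
    """Tunable association score O^2 / (O + alpha * N).

    ``alpha`` in [0, 1] sets the tolerance for non-interacting carrier
    pairs: 0 reduces to the observed-interaction count O, 1 to the
    association score times O.  Returns 0 when the denominator vanishes
    (O = 0 and alpha * N = 0).
    """
    if O < 0 or N < 0:
        raise ValueError("counts must be non-negative")
    if O + N == 0:
        raise ValueError("modified association undefined for O = N = 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    denom = O + alpha * N
    if denom == 0:
        return 0.0
    return O * O / denom
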