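"""Parameter-dependent DDI selection (PADDS).

Given a PPI network and per-protein domain annotations, PADDS extracts a
small set of domain-domain interactions whose carrier pairs reconstitute
every observed interaction, while trying to keep the benefit of the
chosen set above that of any same-coverage alternative.

Scoring
-------
Each candidate pair carries a *benefit*

    B = O^2 / (O + alpha * N) + C^2 / maxC

combining the modified association score with a co-occurrence bonus
(domains that appear together within a protein often interact).  During
selection, candidates whose observed pairs are partly accounted for are
discounted to a *reassessed benefit*

    B_r = ((O - E) / O) * B - s * E

where E counts the already-covered observed pairs and s (default 0.01)
is a small redundancy penalty.

Selection
---------
Repeatedly, every still-useful candidate d is evaluated in five phases:
(1) d seeds a *main* set; its best-scoring overlapping competitor seeds
an *alternative* set.  (2) The two sets are grown alternately — first
the main set, then the alternative — each time admitting the highest
reassessed benefit among candidates overlapping the interactions the
opposite set explains but the growing set does not yet, until both sets
explain the same outstanding interactions.  (3) Each set is totalled:
members admitted on their original benefit contribute B, members
admitted during growth contribute their reassessed benefit at admission
time.  (4) d is *flagged* when its main set strictly beats the
alternative set; otherwise it keeps the main/alternative ratio.  (5) The
best flagged candidate (or, failing any flag, the best ratio) joins the
*final* set, and the interactions it explains are never evaluated again.

Ties are broken in order: minimum N, maximum O, maximum multiply-
explained interactions, maximum C, maximum unique interactions
explained, maximum benefit, then a seeded random draw, so runs are
reproducible bit for bit.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import (
    Callable,
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

import numpy as np

from .ddi import (
    CandidateDDI,
    DDIContext,
    Pair,
    PPINetwork,
    enumerate_candidates,
    modified_association,
)

__all__ = [
    "PaddsConfig",
    "ScoredDDI",
    "SetMember",
    "SelectionState",
    "PaddsResult",
    "ConvergenceError",
    "benefit",
    "reassessed_benefit",
    "total_benefit",
    "tie_break",
    "PaddsSelection",
    "run_padds",
    "run_alpha_sweep",
    "core_set",
    "default_alpha_grid",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The main/alternative growth loop exceeded its iteration guard."""


@dataclass(frozen=True)
class PaddsConfig:
    """Run parameters.

    ``alpha`` in [0, 1] biases selection from rewarding observed
    interactions (0) to penalizing non-observed ones (1); ``s`` is the
    redundancy penalty of the reassessed benefit; ``seed`` feeds the
    random tie-breaker; ``max_iterations`` guards the growth loop
    (default 10x the candidate count).
    """

    alpha: float
    s: float = 0.01
    seed: int = 0
    max_iterations: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("s must be non-negative")


@dataclass(frozen=True)
class SetMember:
    """A DDI inside a main/alternative set during one evaluation."""

    pair: Pair
    benefit: float
    reassessed: float
    added_by: str  # "original" | "reassessed"


@dataclass(frozen=True)
class ScoredDDI:
    """A final-set member with its counts and selection bookkeeping."""

    candidate: CandidateDDI
    benefit: float
    selection_score: float
    flagged: bool
    selection_order: int

    @property
    def pair(self) -> Pair:
        return self.candidate.pair


@dataclass
class SelectionState:
    """Mutable picture of a run: chosen DDIs and covered interactions."""

    final: List[ScoredDDI] = field(default_factory=list)
    explained: Set[Pair] = field(default_factory=set)

    @property
    def final_pairs(self) -> Set[Pair]:
        return {s.pair for s in self.final}


@dataclass(frozen=True)
class PaddsResult:
    """Outcome of one run: the final set ranked by benefit."""

    ranked: Tuple[ScoredDDI, ...]
    config: PaddsConfig
    unexplainable: Tuple[Pair, ...]

    @property
    def pairs(self) -> Tuple[Pair, ...]:
        return tuple(s.pair for s in self.ranked)


def benefit(O: int, N: int, C: int, maxC: int, alpha: float) -> float:
    """Candidate benefit: modified association plus co-occurrence bonus.

    The bonus C^2 / maxC vanishes when no co-occurrence was observed at
    all (maxC = 0) and equals C exactly when C = maxC.
    """
    score = modified_association(O, N, alpha)
    if maxC > 0:
        score += C * C / maxC
    elif C > 0:
        raise ValueError("maxC must be >= 1 when any C > 0")
    return score


def reassessed_benefit(B: float, O: int, E: int, s: float) -> float:
    """Discount a benefit for already-covered observed pairs."""
    if O < 1:
        raise ValueError("a candidate with O = 0 cannot exist")
    if not 0 <= E <= O:
        raise ValueError("E must lie in [0, O]")
    return (O - E) / O * B - s * E


def total_benefit(members: Iterable[SetMember]) -> float:
    """Total accumulative benefit of a main/alternative set.

    Members admitted on their original benefit contribute B; members
    admitted during growth contribute the reassessed benefit they were
    admitted with.
    """
    return sum(
        m.benefit if m.added_by == "original" else m.reassessed for m in members
    )


def tie_break(
    d1: CandidateDDI,
    d2: CandidateDDI,
    rng: random.Random,
    benefit_of: Callable[[Pair], float] | None = None,
) -> CandidateDDI:
    """Resolve a tie between two candidates.

    Criteria, in order: minimum N, maximum O, maximum count of multiply-
    explained interactions, maximum C, maximum unique interactions
    explained, maximum benefit; any remaining tie is broken by the
    seeded generator.
    """
    k1, k2 = (_tb_key(d, benefit_of) for d in (d1, d2))
    if k1 > k2:
        return d1
    if k2 > k1:
        return d2
    return rng.choice(sorted((d1, d2), key=lambda d: d.pair))


def _tb_key(d: CandidateDDI, benefit_of: Callable[[Pair], float] | None) -> Tuple:
    b = benefit_of(d.pair) if benefit_of is not None else 0.0
    return (-d.N, d.O, d.multiplicity, d.C, len(d.explained_ppis), b)


class PaddsSelection:
    """One PADDS run over a fixed candidate context.

    Interaction coverage is held as boolean vectors over the explainable
    interactions and candidate membership as a candidates x interactions
    matrix, so the overlap and redundancy counts of the growth loop are
    single mat-vec products.  Evaluations are cached between selection
    rounds and invalidated only when the newly covered interactions
    touch the region of candidates an evaluation examined, which keeps
    later rounds local.
    """

    def __init__(self, context: DDIContext, config: PaddsConfig) -> None:
        self.context = context
        self.config = config
        self.rng = random.Random(config.seed)
        self.pairs: List[Pair] = sorted(context.candidates)
        self.index: Dict[Pair, int] = {p: i for i, p in enumerate(self.pairs)}
        ppis = sorted({p for c in context.candidates.values() for p in c.explained_ppis})
        self._ppi_order = ppis
        ppi_index = {ppi: i for i, ppi in enumerate(ppis)}
        n_cand, n_ppi = len(self.pairs), len(ppis)
        self.M = np.zeros((n_cand, n_ppi), dtype=bool)
        for i, pair in enumerate(self.pairs):
            for ppi in context.candidates[pair].explained_ppis:
                self.M[i, ppi_index[ppi]] = True
        self._Mf = self.M.astype(np.float64)
        cands = [context.candidates[p] for p in self.pairs]
        self.O = np.array([c.O for c in cands], dtype=np.float64)
        self.B = np.array(
            [benefit(c.O, c.N, c.C, context.maxC, config.alpha) for c in cands]
        )
        self.state = SelectionState()
        self._covered = np.zeros(n_ppi, dtype=bool)
        self._in_final = np.zeros(n_cand, dtype=bool)
        self._guard = config.max_iterations or max(10 * n_cand, 100)
        # cache: index -> (flagged, score, region) where region marks the
        # interactions whose coverage status the evaluation depended on
        self._cache: Dict[int, Tuple[bool, float, np.ndarray]] = {}

    # -- helpers -----------------------------------------------------------

    def _candidate(self, i: int) -> CandidateDDI:
        return self.context.candidates[self.pairs[i]]

    def _reassessed_all(self, accounted: np.ndarray) -> np.ndarray:
        """Vector of reassessed benefits w.r.t. an accounted-PPI vector."""
        e = self._Mf @ accounted.astype(np.float64)
        return (self.O - e) / self.O * self.B - self.config.s * e

    def _best(self, indices: Sequence[int], values: Mapping[int, float]) -> int:
        """Index with the highest value; exact ties go to the tie-breaker."""
        top = max(values[i] for i in indices)
        tied = sorted(i for i in indices if values[i] == top)
        winner = tied[0]
        for other in tied[1:]:
            chosen = tie_break(
                self._candidate(winner),
                self._candidate(other),
                self.rng,
                benefit_of=lambda p: self.B[self.index[p]],
            )
            winner = self.index[chosen.pair]
        return winner

    def _argmax_eligible(self, values: np.ndarray, eligible: np.ndarray) -> int:
        idx = np.flatnonzero(eligible)
        vals = values[idx]
        top = vals.max()
        tied = idx[vals == top]
        if len(tied) == 1:
            return int(tied[0])
        return self._best([int(t) for t in tied], {int(t): float(top) for t in tied})

    def _mask_to_ppis(self, mask: np.ndarray) -> FrozenSet[Pair]:
        return frozenset(self._ppi_order[i] for i in np.flatnonzero(mask))

    # -- the five-phase evaluation ----------------------------------------

    def evaluate_ddi(self, pair: Pair) -> Tuple[bool, float]:
        """Evaluate one candidate against its best set of alternatives.

        Returns ``(flagged, score)`` where ``score`` is the main set's
        total benefit when flagged and the main/alternative total-benefit
        ratio otherwise.
        """
        flagged, score, _ = self._evaluate(self.index[pair])
        return flagged, score

    def _evaluate(self, d: int) -> Tuple[bool, float, np.ndarray]:
        covered = self._covered
        if self._in_final[d]:
            raise ValueError(f"{self.pairs[d]} is already in the final set")
        main_cov = self.M[d] & ~covered
        if not main_cov.any():
            raise ValueError(f"{self.pairs[d]} explains no outstanding interaction")

        eligible = ~self._in_final
        eligible[d] = False
        main_members: List[SetMember] = [
            SetMember(self.pairs[d], float(self.B[d]), float(self.B[d]), "original")
        ]
        alt_members: List[SetMember] = []
        alt_cov = np.zeros_like(covered)
        region = main_cov.copy()

        # Phase 1: strongest competitor overlapping d seeds the
        # alternative set on its (final-set-reassessed) benefit.
        overlaps = self._Mf @ main_cov.astype(np.float64)
        seed_ok = eligible & (overlaps > 0)
        if seed_ok.any():
            values = self._reassessed_all(covered)
            j = self._argmax_eligible(values, seed_ok)
            alt_members.append(
                SetMember(self.pairs[j], float(self.B[j]), float(values[j]), "original")
            )
            alt_cov = self.M[j] & ~covered
            eligible[j] = False
            region |= self.M[j]

        # Phase 2: alternate growth toward coverage equality.  The
        # growing set admits the best reassessed candidate among those
        # overlapping what the opposite set explains and it does not.
        guard = self._guard
        grow_main = True
        stalled = 0
        while not np.array_equal(main_cov, alt_cov):
            guard -= 1
            if guard < 0:
                raise ConvergenceError(
                    f"evaluation of {self.pairs[d]} exceeded the iteration guard "
                    f"({self._guard})"
                )
            target = (alt_cov & ~main_cov) if grow_main else (main_cov & ~alt_cov)
            grown = False
            if target.any():
                overlaps = self._Mf @ target.astype(np.float64)
                ok = eligible & (overlaps > 0)
                if ok.any():
                    accounted = covered | main_cov | alt_cov
                    values = self._reassessed_all(accounted)
                    j = self._argmax_eligible(values, ok)
                    member = SetMember(
                        self.pairs[j], float(self.B[j]), float(values[j]), "reassessed"
                    )
                    if grow_main:
                        main_members.append(member)
                        main_cov = main_cov | (self.M[j] & ~covered)
                    else:
                        alt_members.append(member)
                        alt_cov = alt_cov | (self.M[j] & ~covered)
                    eligible[j] = False
                    region |= self.M[j]
                    grown = True
            if grown:
                stalled = 0
            else:
                stalled += 1
                if stalled >= 2:  # neither side can close its gap
                    break
            grow_main = not grow_main

        # Phases 3 and 4.
        b_tot_main = total_benefit(main_members)
        b_tot_alt = total_benefit(alt_members)
        # The evaluation depended on the coverage status of every
        # interaction reachable from the examined candidates.
        touched = self._Mf @ region.astype(np.float64) > 0
        full_region = region | self.M[touched].any(axis=0)
        if b_tot_main > b_tot_alt:
            return True, b_tot_main, full_region
        if b_tot_alt <= 0:
            raise AssertionError(
                "an unflagged evaluation requires a non-empty alternative set"
            )
        return False, b_tot_main / b_tot_alt, full_region

    # -- outer loop --------------------------------------------------------

    def _active(self) -> List[int]:
        useful = self.M[:, ~self._covered].any(axis=1) if (~self._covered).any() else (
            np.zeros(len(self.pairs), dtype=bool)
        )
        return [int(i) for i in np.flatnonzero(useful & ~self._in_final)]

    def select_next(self) -> ScoredDDI:
        """Phase 5: evaluate every active candidate and admit the winner."""
        active = self._active()
        if not active:
            raise RuntimeError("no candidate explains an outstanding interaction")
        # Evaluation order: descending final-set-reassessed benefit, ties
        # by pair id, so random tie-break consumption is reproducible.
        current = self._reassessed_all(self._covered)
        active.sort(key=lambda j: (-current[j], self.pairs[j]))
        flagged: Dict[int, float] = {}
        ratios: Dict[int, float] = {}
        for j in active:
            cached = self._cache.get(j)
            if cached is None:
                is_flagged, score, region = self._evaluate(j)
                self._cache[j] = (is_flagged, score, region)
            else:
                is_flagged, score, _ = cached
            (flagged if is_flagged else ratios)[j] = score
        if flagged:
            winner = self._best(sorted(flagged), flagged)
            score, was_flagged = flagged[winner], True
        else:
            winner = self._best(sorted(ratios), ratios)
            score, was_flagged = ratios[winner], False
        chosen = ScoredDDI(
            candidate=self._candidate(winner),
            benefit=float(self.B[winner]),
            selection_score=score,
            flagged=was_flagged,
            selection_order=len(self.state.final),
        )
        self.state.final.append(chosen)
        self._in_final[winner] = True
        new_bits = self.M[winner] & ~self._covered
        self._covered = self._covered | self.M[winner]
        self.state.explained = set(self._mask_to_ppis(self._covered))
        # Drop cached evaluations whose examined region the selection touched.
        self._cache = {
            j: entry
            for j, entry in self._cache.items()
            if j != winner and not (entry[2] & new_bits).any()
        }
        return chosen

    def run(self) -> PaddsResult:
        """Select DDIs until every explainable interaction is covered."""
        n_rounds = 0
        limit = len(self._ppi_order) + 1
        while not self._covered.all():
            n_rounds += 1
            if n_rounds > limit:
                raise ConvergenceError("selection failed to make progress")
            self.select_next()
        ranked = sorted(
            self.state.final,
            key=lambda s: (-s.benefit,)
            + tuple(-x for x in _tb_key(s.candidate, None))
            + (s.pair,),
        )
        return PaddsResult(
            ranked=tuple(ranked),
            config=self.config,
            unexplainable=self.context.unexplainable,
        )


def run_padds(
    network: PPINetwork,
    annotations: Mapping[str, Set[str] | FrozenSet[str]],
    config: PaddsConfig,
    context: DDIContext | None = None,
) -> PaddsResult:
    """Extract a ranked final DDI set for one value of alpha.

    Deterministic given identical inputs and ``config.seed``.  A
    pre-built candidate :class:`~padds.ddi.DDIContext` may be supplied to
    amortize enumeration across an alpha sweep.
    """
    if context is None:
        context = enumerate_candidates(network, annotations)
    result = PaddsSelection(context, config).run()
    logger.info(
        "alpha=%.2f: %d DDI(s) selected; %d interaction(s) unexplainable",
        config.alpha,
        len(result.ranked),
        len(result.unexplainable),
    )
    return result


def default_alpha_grid(step: float = 0.1) -> Tuple[float, ...]:
    """The usual sweep grid 0.0, step, ..., 1.0."""
    n = round(1.0 / step)
    return tuple(round(i * step, 10) for i in range(n + 1))


def run_alpha_sweep(
    network: PPINetwork,
    annotations: Mapping[str, Set[str] | FrozenSet[str]],
    alphas: Sequence[float] = default_alpha_grid(),
    s: float = 0.01,
    seed: int = 0,
) -> Dict[float, PaddsResult]:
    """Run PADDS once per alpha over a shared candidate context."""
    context = enumerate_candidates(network, annotations)
    return {
        alpha: run_padds(
            network,
            annotations,
            PaddsConfig(alpha=alpha, s=s, seed=seed),
            context=context,
        )
        for alpha in alphas
    }


def core_set(results: Iterable[PaddsResult | Iterable[Pair]]) -> Set[Pair]:
    """DDIs selected at every provided alpha — the parameter-robust core."""
    sets = [
        set(r.pairs) if isinstance(r, PaddsResult) else set(r) for r in results
    ]
    if not sets:
        return set()
    return set.intersection(*sets)
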