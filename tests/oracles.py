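"""Brute-force reference implementations used only as test oracles.

Everything here enumerates exhaustively (double loops over all protein
pairs, all placements), independent of the package's counting code, and
is only run at tiny problem sizes.
"""

import itertools
import random
from typing import Dict, Iterable, Mapping, Set, Tuple

Pair = Tuple[str, str]


def pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def brute_force_counts(
    proteins: Iterable[str],
    edges: Set[Pair],
    annotations: Mapping[str, Set[str]],
) -> Dict[Pair, Tuple[int, int, int, int]]:
    """O, N, C and multiplicity for every domain pair seen across an edge,
    by scanning all protein pairs and all domain placements."""
    proteins = sorted(proteins)
    observed: Dict[Pair, int] = {}
    nonint: Dict[Pair, int] = {}
    multi: Dict[Pair, int] = {}
    candidates: Set[Pair] = set()
    for p, q in itertools.combinations(proteins, 2):
        placements: Dict[Pair, int] = {}
        for i in annotations.get(p, set()):
            for j in annotations.get(q, set()):
                placements[pair(i, j)] = placements.get(pair(i, j), 0) + 1
        is_edge = pair(p, q) in edges
        for dp, count in placements.items():
            if is_edge:
                observed[dp] = observed.get(dp, 0) + 1
                if count >= 2:
                    multi[dp] = multi.get(dp, 0) + 1
                candidates.add(dp)
            else:
                nonint[dp] = nonint.get(dp, 0) + 1
    out = {}
    for dp in candidates:
        i, j = dp
        if i == j:
            c = sum(1 for p in proteins if i in annotations.get(p, set()))
        else:
            c = sum(
                1
                for p in proteins
                if {i, j} <= annotations.get(p, set())
            )
        out[dp] = (observed.get(dp, 0), nonint.get(dp, 0), c, multi.get(dp, 0))
    return out


def brute_force_predictions(
    ddis: Iterable[Pair],
    annotations: Mapping[str, Set[str]],
    proteins: Iterable[str],
) -> Set[Pair]:
    """All-pairs scan of predicted interactions."""
    ddis = {pair(*d) for d in ddis}
    predicted = set()
    for p, q in itertools.combinations(sorted(proteins), 2):
        for i in annotations.get(p, set()):
            for j in annotations.get(q, set()):
                if pair(i, j) in ddis:
                    predicted.add(pair(p, q))
    return predicted


def brute_force_overlap_clusters(intervals, k: int):
    """Single-linkage closure over the >=k-residue-overlap relation by
    repeated sweeps (no union-find)."""
    clusters = [{idx} for idx in range(len(intervals))]

    def overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)

    changed = True
    while changed:
        changed = False
        for x, y in itertools.combinations(range(len(clusters)), 2):
            if any(
                overlap(intervals[i], intervals[j]) >= k
                for i in clusters[x]
                for j in clusters[y]
            ):
                clusters[x] |= clusters[y]
                del clusters[y]
                changed = True
                break
    return clusters


def random_instance(rng: random.Random, max_proteins: int = 12):
    """A small random network + annotation for oracle comparisons."""
    n = rng.randint(2, max_proteins)
    proteins = [f"p{i}" for i in range(n)]
    n_domains = rng.randint(1, 6)
    domains = [f"d{i}" for i in range(n_domains)]
    annotations = {
        p: {d for d in domains if rng.random() < 0.5} for p in proteins
    }
    all_pairs = [pair(a, b) for a, b in itertools.combinations(proteins, 2)]
    edges = {pr for pr in all_pairs if rng.random() < 0.3}
    return proteins, edges, annotations
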