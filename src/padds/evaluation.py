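"""Scoring selected DDI sets against the network and reference DDIs.

A selected set of domain pairs predicts an interaction for *every*
protein pair carrying one of its pairs, not just the observed ones.  The
operational negative class is all C(n, 2) pairs of the n network
proteins minus the m known interactions, so TP/FP/TN/FN partition the
pair universe exactly: TP + FN = m and FP + TN = C(n, 2) - m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

from .ddi import Pair, PPINetwork, unordered_pair

__all__ = [
    "ConfusionCounts",
    "RocPoint",
    "predict_ppis",
    "confusion",
    "roc_curve",
    "reference_recall",
    "match_reference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over protein pairs."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def fpr(self) -> float:
        return self.FP / (self.FP + self.TN) if self.FP + self.TN else 0.0


@dataclass(frozen=True)
class RocPoint:
    """One rank cutoff of a ROC sweep."""

    cutoff: int
    counts: ConfusionCounts

    @property
    def tpr(self) -> float:
        return self.counts.tpr

    @property
    def fpr(self) -> float:
        return self.counts.fpr


def predict_ppis(
    ddis: Iterable[Pair],
    annotations: Mapping[str, Set[str] | FrozenSet[str]],
    proteins: Iterable[str],
) -> Set[Pair]:
    """All unordered protein pairs carrying any of the given domain pairs.

    A pair (p, q), p != q, is predicted when some DDI (i, j) has i among
    p's domains and j among q's (either placement).
    """
    proteins = sorted(set(proteins))
    carriers: Dict[str, List[str]] = {}
    for p in proteins:
        for d in annotations.get(p, ()):  # unannotated proteins carry nothing
            carriers.setdefault(d, []).append(p)
    predicted: Set[Pair] = set()
    for i, j in set(map(lambda ij: unordered_pair(*ij), ddis)):
        for p in carriers.get(i, ()):
            for q in carriers.get(j, ()):
                if p != q:
                    predicted.add(unordered_pair(p, q))
    return predicted


def confusion(predicted: Set[Pair], network: PPINetwork) -> ConfusionCounts:
    """Confusion counts of a predicted pair set over the network universe."""
    interacting = network.interactions
    tp = len(predicted & interacting)
    fp = len(predicted) - tp
    fn = network.m - tp
    tn = network.n_noninteracting - fp
    if tn < 0:
        raise ValueError("predictions extend outside the network's pair universe")
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def roc_curve(
    ranked_ddis: Sequence[Pair],
    annotations: Mapping[str, Set[str] | FrozenSet[str]],
    network: PPINetwork,
) -> List[RocPoint]:
    """Cumulative confusion counts at every rank cutoff 0..len(ranked).

    Predictions are unions over the top-r DDIs, so both rates are
    non-decreasing in the cutoff.
    """
    points = [RocPoint(0, confusion(set(), network))]
    predicted: Set[Pair] = set()
    for r, ddi in enumerate(ranked_ddis, start=1):
        predicted |= predict_ppis([ddi], annotations, network.proteins)
        points.append(RocPoint(r, confusion(predicted, network)))
    return points


def match_reference(
    ddi: Pair,
    reference: Set[Pair],
    labels_of: Callable[[str], Iterable[str]] | None = None,
) -> bool:
    """Whether a (possibly multi-label) domain pair hits a reference pair.

    Reference DDIs are single-label pairs; a merged domain matches when
    *any* of its member labels does.  Comparison is case-folded exact
    label equality.
    """
    i, j = ddi
    labels_i = [l.casefold() for l in (labels_of(i) if labels_of else (i,))]
    labels_j = [l.casefold() for l in (labels_of(j) if labels_of else (j,))]
    for a in labels_i:
        for b in labels_j:
            if unordered_pair(a, b) in reference:
                return True
    return False


def reference_recall(
    ranked_ddis: Sequence[Pair],
    reference: Iterable[Pair],
    cutoffs: Sequence[int],
    universe: Iterable[Pair] | None = None,
    labels_of: Callable[[str], Iterable[str]] | None = None,
) -> List[Tuple[int, float, float]]:
    """Recall and precision of the ranking against a reference DDI list.

    Recall at cutoff r is the fraction of *retrievable* reference DDIs
    (those matched by the candidate ``universe``, defaulting to the
    ranking itself) found among the top r; precision is matches / r.
    Returns ``(cutoff, recall, precision)`` triples.
    """
    ref = {unordered_pair(a.casefold(), b.casefold()) for a, b in reference}
    pool = list(universe) if universe is not None else list(ranked_ddis)
    retrievable = {
        r for r in ref if any(match_reference(d, {r}, labels_of) for d in pool)
    }
    out: List[Tuple[int, float, float]] = []
    for cutoff in cutoffs:
        top = ranked_ddis[:cutoff]
        hits = {
            r for r in retrievable if any(match_reference(d, {r}, labels_of) for d in top)
        }
        recall = len(hits) / len(retrievable) if retrievable else 0.0
        precision = len(hits) / cutoff if cutoff else 0.0
        out.append((cutoff, recall, precision))
    return out
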