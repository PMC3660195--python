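"""Multi-database protein-domain annotation merging.

Different annotation databases assign overlapping, inconsistently
labelled domains to the same protein.  The merging procedure reconciles
them in three steps, applied per protein:

* **Step I** collapses tandem repeats: records with identical labels from
  one database become a single record spanning from the first start to
  the last end, inter-repeat sequence included.
* **Step II** merges annotations between every pair of databases
  (including each database with itself): records are grouped when they
  overlap by at least ``k`` residues (default 10) *and* their labels are
  equivalent (:mod:`padds.labels`).  Groups become multi-label domains.
* **Step III** agglomerates the Step II groups from all database pairs
  into a final annotation, iterating until no two groups both overlap by
  ``k`` and carry equivalent label sets.  Iteration is what recovers
  equivalences a single pairwise comparison misses (an "abc-atpase" /
  "smc" pair bridged by "abc-smc5").

Two deliberately simple baselines are provided for comparison:
:func:`naive_merge` (every record is its own domain) and
:func:`sequence_only_merge` (overlap closure ignoring labels).  The
three strategies bracket each other: naive >= merged >= sequence-only in
unique-domain count on any input.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .labels import (
    DEFAULT_TRIVIAL_WORDS,
    NO_OVERRIDES,
    EquivalenceOverrides,
    labels_equivalent,
    multilabel_equivalent,
)

__all__ = [
    "DomainAnnotation",
    "MergedDomain",
    "MergeReport",
    "AnnotationSummary",
    "DEFAULT_OVERLAP_K",
    "merge_tandem_repeats",
    "sequence_overlap_length",
    "merge_database_pair",
    "build_final_annotation",
    "merge_proteome",
    "naive_merge",
    "sequence_only_merge",
    "summarize",
]

#: Default minimum number of continuous shared residues for two
#: annotations to be considered co-located.  The merged output is
#: reported to be insensitive to values in roughly 1-30.
DEFAULT_OVERLAP_K = 10


class UnknownProteinError(ValueError):
    """An annotation references a protein absent from the proteome."""


@dataclass(frozen=True)
class DomainAnnotation:
    """One database's assignment of a labelled domain to a residue interval.

    Coordinates are 1-based closed intervals, the residue-numbering
    convention of the source databases.
    """

    protein_id: str
    database: str
    label: str
    start: int
    end: int
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("domain label must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for "
                f"{self.protein_id}/{self.label}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("E-value must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> Tuple:
        ev = self.evalue if self.evalue is not None else -1.0
        return (self.protein_id, self.database, self.start, self.end, self.label, ev)


@dataclass(frozen=True)
class MergedDomain:
    """A multi-label domain with a representative interval and provenance.

    ``start``/``end`` span the union of the member intervals; ``labels``
    is the union of member labels; ``members`` are the source annotation
    records (post tandem-collapse expansion back to the raw records).
    """

    protein_id: str
    labels: FrozenSet[str]
    start: int
    end: int
    members: Tuple[DomainAnnotation, ...]
    #: set when a protein carries several final domains whose
    #: alphabetically-first labels coincide; keeps assigned labels unique
    #: per protein so the merged output can be re-fed as an annotation set
    assigned_label: Optional[str] = None

    @property
    def canonical_label(self) -> str:
        """The assigned "new" label: alphabetically first member label,
        disambiguated when a protein repeats it at another position."""
        return self.assigned_label or min(self.labels)

    def sort_key(self) -> Tuple:
        return (self.protein_id, self.start, self.end, tuple(sorted(self.labels)))


@dataclass
class MergeReport:
    """Provenance of a merge: label map plus unmerged-overlap exceptions.

    ``label_map`` maps ``(protein_id, new_label, start, end)`` to the
    source ``(database, original_label)`` pairs it absorbed (the interval
    disambiguates same-label domains at different positions).
    ``exceptions`` lists ``(protein_id, label_a, label_b)`` pairs that
    overlapped in sequence by >= k residues but were not similar enough
    to merge — the starting point for user-defined override pairs.
    """

    label_map: Dict[Tuple[str, str, int, int], Tuple[Tuple[str, str], ...]] = field(
        default_factory=dict
    )
    exceptions: List[Tuple[str, str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class AnnotationSummary:
    """Proteome-wide annotation statistics."""

    n_proteins_annotated: int
    fraction_proteins_annotated: float
    residues_covered: int
    fraction_residues_covered: float
    n_domain_instances: int
    n_unique_domains: int
    avg_domains_per_protein: float


def sequence_overlap_length(
    d1: Tuple[int, int] | DomainAnnotation | MergedDomain,
    d2: Tuple[int, int] | DomainAnnotation | MergedDomain,
) -> int:
    """Length of the intersection of two 1-based closed intervals (0 if
    disjoint)."""
    s1, e1 = _interval(d1)
    s2, e2 = _interval(d2)
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def _interval(d) -> Tuple[int, int]:
    if isinstance(d, tuple):
        return d
    return (d.start, d.end)


# ---------------------------------------------------------------------------
# Step I
# ---------------------------------------------------------------------------

def merge_tandem_repeats(
    annotations: Sequence[DomainAnnotation],
) -> List[DomainAnnotation]:
    """Collapse same-label repeats of one protein/database into one record.

    The collapsed record spans from the minimum start to the maximum end,
    inter-repeat sequence included; no gap limit is imposed (repeat copy
    number is not resolvable from threshold-dependent annotations, so it
    is deliberately not preserved).  Records with distinct labels pass
    through unchanged.
    """
    if not annotations:
        return []
    keys = {(a.protein_id, a.database) for a in annotations}
    if len(keys) > 1:
        raise ValueError("tandem-repeat merging operates on one protein and database")
    by_label: Dict[str, List[DomainAnnotation]] = {}
    for ann in sorted(annotations, key=DomainAnnotation.sort_key):
        by_label.setdefault(ann.label, []).append(ann)
    out = []
    for label in sorted(by_label):
        group = by_label[label]
        if len(group) == 1:
            out.append(group[0])
        else:
            evalues = [a.evalue for a in group if a.evalue is not None]
            out.append(
                DomainAnnotation(
                    protein_id=group[0].protein_id,
                    database=group[0].database,
                    label=label,
                    start=min(a.start for a in group),
                    end=max(a.end for a in group),
                    evalue=min(evalues) if evalues else None,
                )
            )
    out.sort(key=DomainAnnotation.sort_key)
    return out


# ---------------------------------------------------------------------------
# Step II
# ---------------------------------------------------------------------------

def _compatible(
    a: DomainAnnotation,
    b: DomainAnnotation,
    k: int,
    overrides: EquivalenceOverrides,
    trivial_words,
) -> bool:
    return sequence_overlap_length(a, b) >= k and labels_equivalent(
        a.label, b.label, overrides, trivial_words
    )


def merge_database_pair(
    protein_id: str,
    annots_a: Sequence[DomainAnnotation],
    annots_b: Sequence[DomainAnnotation],
    k: int = DEFAULT_OVERLAP_K,
    overrides: EquivalenceOverrides = NO_OVERRIDES,
    trivial_words=DEFAULT_TRIVIAL_WORDS,
) -> Tuple[List[MergedDomain], List[Tuple[str, str]]]:
    """Merge one protein's annotations between two databases.

    Records are grouped by complete linkage: every pair within a group
    must overlap by >= ``k`` residues *and* have equivalent labels, so a
    group never chains through an intermediate.  Returns the merged
    domains plus the overlapping-but-nonequivalent label pairs
    (candidate exceptions).

    For a database merged with itself pass the same sequence twice (or
    an empty ``annots_b``); records are pooled without duplication.
    """
    pool = list(annots_a)
    if annots_b is not annots_a and list(annots_b) != list(annots_a):
        pool += list(annots_b)
    pool.sort(key=DomainAnnotation.sort_key)
    groups: List[List[DomainAnnotation]] = []
    for ann in pool:
        for group in groups:
            if all(_compatible(ann, m, k, overrides, trivial_words) for m in group):
                group.append(ann)
                break
        else:
            groups.append([ann])
    exceptions = [
        tuple(sorted((a.label, b.label)))
        for a, b in itertools.combinations(pool, 2)
        if sequence_overlap_length(a, b) >= k
        and not labels_equivalent(a.label, b.label, overrides, trivial_words)
    ]
    merged = [
        MergedDomain(
            protein_id=protein_id,
            labels=frozenset(m.label for m in group),
            start=min(m.start for m in group),
            end=max(m.end for m in group),
            members=tuple(group),
        )
        for group in groups
    ]
    merged.sort(key=MergedDomain.sort_key)
    return merged, sorted(set(exceptions))


# ---------------------------------------------------------------------------
# Step III
# ---------------------------------------------------------------------------

def _share_member(a: MergedDomain, b: MergedDomain) -> bool:
    return bool(set(a.members) & set(b.members))


def build_final_annotation(
    protein_id: str,
    all_pairwise_results: Sequence[Sequence[MergedDomain]],
    k: int = DEFAULT_OVERLAP_K,
    overrides: EquivalenceOverrides = NO_OVERRIDES,
    trivial_words=DEFAULT_TRIVIAL_WORDS,
    candidate_exceptions: Iterable[Tuple[str, str]] = (),
) -> Tuple[List[MergedDomain], MergeReport]:
    """Agglomerate all pairwise merge results into one final annotation.

    Two groups merge when their representative intervals overlap by
    >= ``k`` and their label sets are equivalent through any member
    label, or when they share a source record (the same record placed in
    two different pairwise groups must end in a single final domain).
    Agglomeration iterates to a fixpoint, which is what detects
    equivalences missed by any single pairwise comparison.

    ``candidate_exceptions`` are the Step II overlapping-but-distinct
    label pairs; only those still split across final domains are kept in
    the report (pairs reconciled transitively are no exceptions).
    """
    items = sorted(
        (d for result in all_pairwise_results for d in result),
        key=MergedDomain.sort_key,
    )
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(items)), 2):
            a, b = items[i], items[j]
            if _share_member(a, b) or (
                sequence_overlap_length(a, b) >= k
                and multilabel_equivalent(a.labels, b.labels, overrides, trivial_words)
            ):
                merged = MergedDomain(
                    protein_id=protein_id,
                    labels=a.labels | b.labels,
                    start=min(a.start, b.start),
                    end=max(a.end, b.end),
                    members=tuple(
                        dict.fromkeys(itertools.chain(a.members, b.members))
                    ),
                )
                items = [d for n, d in enumerate(items) if n not in (i, j)]
                items.append(merged)
                items.sort(key=MergedDomain.sort_key)
                changed = True
                break

    # Assign new labels: alphabetically first member label, suffixed when
    # the same protein repeats it at a distinct position (otherwise the
    # final set could not be re-read as a plain annotation table without
    # the repeats collapsing as tandem copies).
    counts: Dict[str, int] = {}
    relabelled: List[MergedDomain] = []
    for dom in items:
        base = min(dom.labels)
        counts[base] = counts.get(base, 0) + 1
        assigned = base if counts[base] == 1 else f"{base}/{counts[base]}"
        relabelled.append(
            MergedDomain(
                protein_id=dom.protein_id,
                labels=dom.labels,
                start=dom.start,
                end=dom.end,
                members=dom.members,
                assigned_label=assigned,
            )
        )
    items = relabelled

    report = MergeReport()
    label_of: Dict[str, str] = {}
    for dom in items:
        new_label = dom.canonical_label
        for lbl in dom.labels:
            label_of[lbl] = new_label
        sources = sorted({(m.database, m.label) for m in dom.members})
        report.label_map[(protein_id, new_label, dom.start, dom.end)] = tuple(sources)
    for la, lb in sorted(set(candidate_exceptions)):
        if label_of.get(la) != label_of.get(lb):
            report.exceptions.append((protein_id, la, lb))
    return items, report


# ---------------------------------------------------------------------------
# Whole-proteome driver
# ---------------------------------------------------------------------------

def _group_annotations(
    annotations: Iterable[DomainAnnotation],
) -> Dict[str, Dict[str, List[DomainAnnotation]]]:
    grouped: Dict[str, Dict[str, List[DomainAnnotation]]] = {}
    for ann in annotations:
        grouped.setdefault(ann.protein_id, {}).setdefault(ann.database, []).append(ann)
    return grouped


def merge_proteome(
    annotations: Iterable[DomainAnnotation],
    proteome: Mapping[str, int],
    k: int = DEFAULT_OVERLAP_K,
    overrides: EquivalenceOverrides = NO_OVERRIDES,
    trivial_words=DEFAULT_TRIVIAL_WORDS,
) -> Tuple[List[MergedDomain], MergeReport]:
    """Apply Steps I-III to every protein of a proteome.

    ``proteome`` maps protein id to sequence length and is used for
    validation only.  The result is independent of database order and of
    the input record order: proteins, databases and records are processed
    in sorted order and grouping is deterministic.

    Raises :class:`UnknownProteinError` for annotations referencing
    proteins absent from the proteome, and ``ValueError`` for intervals
    extending past the sequence end.
    """
    annotations = list(annotations)
    for ann in annotations:
        if ann.protein_id not in proteome:
            raise UnknownProteinError(
                f"annotation references unknown protein {ann.protein_id!r}"
            )
        if ann.end > proteome[ann.protein_id]:
            raise ValueError(
                f"annotation [{ann.start}, {ann.end}] exceeds length "
                f"{proteome[ann.protein_id]} of protein {ann.protein_id}"
            )

    final: List[MergedDomain] = []
    report = MergeReport()
    for protein_id, by_db in sorted(_group_annotations(annotations).items()):
        # Step I per database, remembering which raw records each
        # collapsed record stands for so provenance survives to the end.
        collapsed: Dict[str, List[DomainAnnotation]] = {}
        raw_members: Dict[DomainAnnotation, Tuple[DomainAnnotation, ...]] = {}
        for db in sorted(by_db):
            step1 = merge_tandem_repeats(by_db[db])
            collapsed[db] = step1
            raws = sorted(by_db[db], key=DomainAnnotation.sort_key)
            for rec in step1:
                raw_members[rec] = tuple(r for r in raws if r.label == rec.label)
        # Step II over every unordered database pair, self-pairs included.
        pairwise: List[List[MergedDomain]] = []
        candidate_exceptions: List[Tuple[str, str]] = []
        dbs = sorted(collapsed)
        for da, db_ in itertools.combinations_with_replacement(dbs, 2):
            merged, exc = merge_database_pair(
                protein_id, collapsed[da], collapsed[db_], k, overrides, trivial_words
            )
            pairwise.append(merged)
            candidate_exceptions.extend(exc)
        # Step III.
        domains, prot_report = build_final_annotation(
            protein_id, pairwise, k, overrides, trivial_words, candidate_exceptions
        )
        # Expand collapsed members back to the raw input records.
        for dom in domains:
            raws = tuple(
                dict.fromkeys(
                    r for m in dom.members for r in raw_members.get(m, (m,))
                )
            )
            final.append(
                MergedDomain(
                    protein_id=dom.protein_id,
                    labels=dom.labels,
                    start=dom.start,
                    end=dom.end,
                    members=raws,
                    assigned_label=dom.assigned_label,
                )
            )
        report.label_map.update(prot_report.label_map)
        report.exceptions.extend(prot_report.exceptions)

    final.sort(key=MergedDomain.sort_key)
    return final, report


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def naive_merge(annotations: Iterable[DomainAnnotation]) -> List[MergedDomain]:
    """Aggregation baseline: every annotation record is its own domain."""
    out = [
        MergedDomain(
            protein_id=a.protein_id,
            labels=frozenset([a.label]),
            start=a.start,
            end=a.end,
            members=(a,),
        )
        for a in sorted(annotations, key=DomainAnnotation.sort_key)
    ]
    return out


def sequence_only_merge(
    annotations: Iterable[DomainAnnotation], k: int = DEFAULT_OVERLAP_K
) -> List[MergedDomain]:
    """Sequence-overlap baseline: label-blind single-linkage closure.

    Tandem repeats are collapsed first (as in Step I), then per protein
    every chain of records overlapping by >= ``k`` residues fuses into one
    cluster regardless of labels.  This underestimates domain counts
    whenever distinct domains share sequence position.
    """
    final: List[MergedDomain] = []
    for protein_id, by_db in sorted(_group_annotations(annotations).items()):
        pool: List[DomainAnnotation] = []
        for db in sorted(by_db):
            pool.extend(merge_tandem_repeats(by_db[db]))
        pool.sort(key=DomainAnnotation.sort_key)
        parent = list(range(len(pool)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(len(pool)), 2):
            if sequence_overlap_length(pool[i], pool[j]) >= k:
                parent[find(i)] = find(j)
        clusters: Dict[int, List[DomainAnnotation]] = {}
        for i, ann in enumerate(pool):
            clusters.setdefault(find(i), []).append(ann)
        for members in clusters.values():
            final.append(
                MergedDomain(
                    protein_id=protein_id,
                    labels=frozenset(m.label for m in members),
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    members=tuple(members),
                )
            )
    final.sort(key=MergedDomain.sort_key)
    return final


def summarize(
    domains: Sequence[MergedDomain], proteome: Mapping[str, int]
) -> AnnotationSummary:
    """Proteome-wide statistics of an annotation set.

    Residue coverage counts each residue once however many domains cover
    it.  Unique domains are counted as distinct label sets proteome-wide;
    the average is domain instances over proteome size.
    """
    n_proteins = len(proteome)
    total_residues = sum(proteome.values())
    by_protein: Dict[str, List[Tuple[int, int]]] = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, []).append((d.start, d.end))
    covered = 0
    for intervals in by_protein.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e + 1:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s + 1
    return AnnotationSummary(
        n_proteins_annotated=len(by_protein),
        fraction_proteins_annotated=(len(by_protein) / n_proteins) if n_proteins else 0.0,
        residues_covered=covered,
        fraction_residues_covered=(covered / total_residues) if total_residues else 0.0,
        n_domain_instances=len(domains),
        n_unique_domains=len({d.labels for d in domains}),
        avg_domains_per_protein=(len(domains) / n_proteins) if n_proteins else 0.0,
    )
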