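"""Readers and writers for the toolkit's plain-text formats.

All tables are tab-separated with a mandatory header line; lines
starting with ``#`` are comments.  Writers emit rows in sorted order so
outputs are diffable and byte-identical across runs, and every writer's
output round-trips through its paired reader.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ddi import Pair, PPINetwork, unordered_pair
from .labels import EquivalenceOverrides
from .merging import DomainAnnotation, MergedDomain, MergeReport
from .selection import PaddsResult

__all__ = [
    "InputError",
    "read_proteome",
    "write_proteome_fasta",
    "read_annotations",
    "write_annotations",
    "read_ppis",
    "write_ppis",
    "read_trivial_words",
    "write_trivial_words",
    "read_overrides",
    "write_overrides",
    "read_reference_ddis",
    "write_merged_domains",
    "read_merged_domains",
    "write_label_map",
    "write_exceptions",
    "write_ddi_table",
    "read_ddi_table",
    "write_core_set",
    "write_roc_table",
    "write_recall_table",
    "write_run_metadata",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """A named, user-facing input problem (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_proteome(path: str | Path) -> Dict[str, int]:
    """Read a FASTA proteome into a protein-id -> length mapping.

    Only lengths are used downstream.  Duplicate ids and zero-length
    records are rejected; a file whose first record line is not a FASTA
    header raises a parse error naming the line.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise InputError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}"
                )
            break
    else:
        logger.warning("%s: empty proteome file", path)
        return {}
    lengths: Dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise InputError(f"{path}: duplicate protein id {record.id!r}")
        if len(record.seq) < 1:
            raise InputError(f"{path}: zero-length sequence for {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


def write_proteome_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic TSV plumbing
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty table (a header line is required)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return df


def _write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["protein_id", "database", "label", "start", "end", "evalue"]


def read_annotations(
    path: str | Path,
    evalue_cutoff: Optional[float] = None,
    proteome: Optional[Mapping[str, int]] = None,
) -> List[DomainAnnotation]:
    """Read a domain annotation table.

    With an E-value cutoff, rows whose E-value exceeds it are dropped
    and counted in the log (rows without an E-value — curated
    annotations — are always kept).  With a proteome, coordinates are
    checked against sequence lengths.
    """
    df = _read_table(path, ANNOTATION_COLUMNS[:5])
    out: List[DomainAnnotation] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        evalue = None
        raw = getattr(row, "evalue", None)
        if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
            text = str(raw).strip()
            if text and text.lower() != "nan":
                evalue = float(text)
        try:
            ann = DomainAnnotation(
                protein_id=str(row.protein_id),
                database=str(row.database),
                label=str(row.label),
                start=int(row.start),
                end=int(row.end),
                evalue=evalue,
            )
        except ValueError as exc:
            raise InputError(f"{path}: {exc}") from exc
        if evalue_cutoff is not None and evalue is not None and evalue > evalue_cutoff:
            n_dropped += 1
            continue
        if proteome is not None:
            if ann.protein_id not in proteome:
                raise InputError(
                    f"{path}: annotation references unknown protein {ann.protein_id!r}"
                )
            if ann.end > proteome[ann.protein_id]:
                raise InputError(
                    f"{path}: [{ann.start}, {ann.end}] exceeds length of {ann.protein_id}"
                )
        out.append(ann)
    if n_dropped:
        logger.info("%s: dropped %d row(s) above E-value cutoff", path, n_dropped)
    out.sort(key=DomainAnnotation.sort_key)
    return out


def write_annotations(path: str | Path, annotations: Iterable[DomainAnnotation]) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "database": a.database,
            "label": a.label,
            "start": a.start,
            "end": a.end,
            "evalue": "" if a.evalue is None else f"{a.evalue:.6g}",
        }
        for a in sorted(annotations, key=DomainAnnotation.sort_key)
    ]
    _write_table(path, pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


# ---------------------------------------------------------------------------
# PPIs
# ---------------------------------------------------------------------------

def read_ppis(path: str | Path, proteins: Optional[Iterable[str]] = None) -> PPINetwork:
    """Read an undirected two-column edge list into a network.

    Duplicates (either orientation) collapse and self-edges drop, both
    with a logged warning.
    """
    df = _read_table(path, ["protein_a", "protein_b"])
    edges = [(str(a), str(b)) for a, b in zip(df["protein_a"], df["protein_b"])]
    return PPINetwork.from_edges(edges, proteins=proteins)


def write_ppis(path: str | Path, network: PPINetwork) -> None:
    rows = [{"protein_a": a, "protein_b": b} for a, b in sorted(network.interactions)]
    _write_table(path, pd.DataFrame(rows, columns=["protein_a", "protein_b"]))


# ---------------------------------------------------------------------------
# Label configuration
# ---------------------------------------------------------------------------

def read_trivial_words(path: str | Path) -> frozenset:
    """One lower-case word per line; blank lines and ``#`` comments skipped."""
    words = set()
    for line in Path(path).read_text().splitlines():
        word = line.strip()
        if word and not word.startswith("#"):
            words.add(word.lower())
    return frozenset(words)


def write_trivial_words(path: str | Path, words: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{w}\n" for w in sorted(words)))


def read_overrides(path: str | Path) -> EquivalenceOverrides:
    """Read override pairs: ``labelA<TAB>labelB<TAB>{equivalent|distinct}``."""
    equivalent: List[Tuple[str, str]] = []
    distinct: List[Tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3 or parts[2] not in ("equivalent", "distinct"):
            raise InputError(
                f"{path}: line {lineno}: expected 'labelA<TAB>labelB<TAB>"
                f"{{equivalent|distinct}}', got {line!r}"
            )
        (equivalent if parts[2] == "equivalent" else distinct).append(
            (parts[0], parts[1])
        )
    try:
        return EquivalenceOverrides.from_pairs(equivalent=equivalent, distinct=distinct)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_overrides(path: str | Path, overrides: EquivalenceOverrides) -> None:
    lines = [
        f"{a}\t{b}\tequivalent" for a, b in sorted(overrides.force_equivalent)
    ] + [f"{a}\t{b}\tdistinct" for a, b in sorted(overrides.force_distinct)]
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def read_reference_ddis(path: str | Path) -> Set[Pair]:
    """Two-column reference DDI list (domain label pairs), case-folded."""
    df = _read_table(path, ["domain_a", "domain_b"])
    return {
        unordered_pair(str(a).casefold(), str(b).casefold())
        for a, b in zip(df["domain_a"], df["domain_b"])
    }


# ---------------------------------------------------------------------------
# Merge outputs
# ---------------------------------------------------------------------------

def write_merged_domains(path: str | Path, domains: Iterable[MergedDomain]) -> None:
    """Merged annotation table: the standard columns with ``database`` =
    ``merged``, ``label`` = canonical label, plus the full label set."""
    rows = [
        {
            "protein_id": d.protein_id,
            "database": "merged",
            "label": d.canonical_label,
            "start": d.start,
            "end": d.end,
            "evalue": "",
            "all_labels": ";".join(sorted(d.labels)),
        }
        for d in sorted(domains, key=MergedDomain.sort_key)
    ]
    _write_table(path, pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["all_labels"]))


def read_merged_domains(path: str | Path) -> List[MergedDomain]:
    df = _read_table(path, ["protein_id", "label", "start", "end"])
    out = []
    for row in df.itertuples(index=False):
        labels = getattr(row, "all_labels", None)
        label_set = (
            frozenset(str(labels).split(";"))
            if labels is not None and not (isinstance(labels, float) and math.isnan(labels))
            else frozenset([str(row.label)])
        )
        out.append(
            MergedDomain(
                protein_id=str(row.protein_id),
                labels=label_set,
                start=int(row.start),
                end=int(row.end),
                members=(),
            )
        )
    return out


def write_label_map(path: str | Path, report: MergeReport) -> None:
    rows = [
        {
            "protein_id": pid,
            "new_label": new_label,
            "start": start,
            "end": end,
            "database": db,
            "original_label": label,
        }
        for (pid, new_label, start, end), sources in sorted(report.label_map.items())
        for db, label in sources
    ]
    _write_table(
        path,
        pd.DataFrame(
            rows,
            columns=["protein_id", "new_label", "start", "end", "database", "original_label"],
        ),
    )


def write_exceptions(path: str | Path, report: MergeReport) -> None:
    rows = [
        {"protein_id": pid, "label_a": a, "label_b": b}
        for pid, a, b in sorted(report.exceptions)
    ]
    _write_table(path, pd.DataFrame(rows, columns=["protein_id", "label_a", "label_b"]))


# ---------------------------------------------------------------------------
# DDI outputs
# ---------------------------------------------------------------------------

DDI_COLUMNS = ["rank", "domain_i", "domain_j", "O", "N", "C", "benefit", "alpha"]


def write_ddi_table(path: str | Path, result: PaddsResult) -> None:
    rows = [
        {
            "rank": rank,
            "domain_i": s.candidate.domain_i,
            "domain_j": s.candidate.domain_j,
            "O": s.candidate.O,
            "N": s.candidate.N,
            "C": s.candidate.C,
            "benefit": f"{s.benefit:.10g}",
            "alpha": f"{result.config.alpha:g}",
        }
        for rank, s in enumerate(result.ranked, start=1)
    ]
    _write_table(path, pd.DataFrame(rows, columns=DDI_COLUMNS))


def read_ddi_table(path: str | Path) -> List[Pair]:
    """Ranked domain pairs from a DDI table (rank order preserved)."""
    df = _read_table(path, ["rank", "domain_i", "domain_j"])
    df = df.assign(rank=df["rank"].astype(int)).sort_values("rank")
    return [
        unordered_pair(str(i), str(j))
        for i, j in zip(df["domain_i"], df["domain_j"])
    ]


def write_core_set(path: str | Path, core: Iterable[Pair]) -> None:
    rows = [
        {"domain_i": i, "domain_j": j} for i, j in sorted(core)
    ]
    _write_table(path, pd.DataFrame(rows, columns=["domain_i", "domain_j"]))


def write_roc_table(path: str | Path, points) -> None:
    rows = [
        {
            "cutoff": p.cutoff,
            "TP": p.counts.TP,
            "FP": p.counts.FP,
            "TN": p.counts.TN,
            "FN": p.counts.FN,
            "tpr": f"{p.tpr:.10g}",
            "fpr": f"{p.fpr:.10g}",
        }
        for p in points
    ]
    _write_table(
        path, pd.DataFrame(rows, columns=["cutoff", "TP", "FP", "TN", "FN", "tpr", "fpr"])
    )


def write_recall_table(path: str | Path, rows: Iterable[Tuple[int, float, float]]) -> None:
    frame = pd.DataFrame(
        [
            {"cutoff": c, "recall": f"{r:.10g}", "precision": f"{p:.10g}"}
            for c, r, p in rows
        ],
        columns=["cutoff", "recall", "precision"],
    )
    _write_table(path, frame)


def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    """Sidecar YAML with the exact configuration of a run (no timestamps,
    so reruns are byte-identical)."""
    Path(path).write_text(yaml.safe_dump(dict(metadata), sort_keys=True))
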