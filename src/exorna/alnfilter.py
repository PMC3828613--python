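"""Post-processing of genome alignments.

Spliced SAM/BAM records are reduced to per-read block lists (CIGAR N runs
open a new block, deletions stay within a block), then filtered in a fixed
order — multi-mapped reads, alignments spanning fewer than 20 reference
bases, records below mapping quality 10 — with exact funnel accounting.
Kept records are assigned to one of three genomic compartments: rRNA
(decided upstream by the rRNA partition), known gene (any block overlaps
an annotated exon by at least one base) or unknown.

Coordinates are 0-based half-open throughout, matching BED semantics.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import TranscriptModel

RRNA_LABEL = "rRNA"
KNOWN_LABEL = "known_gene"
UNKNOWN_LABEL = "unknown"

# CIGAR ops by pysam code
_REF_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X extend the current block
_SPLICE_OP = 3  # N closes the block
_NOREF_OPS = {1, 4, 5, 6}  # I, S, H, P consume no reference


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    reference: str
    strand: str
    blocks: Tuple[Tuple[int, int], ...]
    mapq: int
    multiplicity: int = 1

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class FilterFunnel:
    input_records: int = 0
    removed_multimapped: int = 0
    removed_short: int = 0
    removed_low_mapq: int = 0
    kept: int = 0

    def validate(self) -> None:
        total = (
            self.removed_multimapped
            + self.removed_short
            + self.removed_low_mapq
            + self.kept
        )
        if total != self.input_records:
            raise ValueError("filter funnel does not conserve records")


def blocks_from_cigar(
    cigartuples: Sequence[Tuple[int, int]], pos: int, read_id: str = "?"
) -> Tuple[Tuple[int, int], ...]:
    """Reference blocks implied by a CIGAR starting at ``pos``."""
    blocks: List[Tuple[int, int]] = []
    start = cur = pos
    for op, length in cigartuples:
        if length < 0:
            raise ValueError(f"{read_id}: negative CIGAR run")
        if op in _REF_BLOCK_OPS:
            cur += length
        elif op == _SPLICE_OP:
            if cur > start:
                blocks.append((start, cur))
            start = cur = cur + length
        elif op in _NOREF_OPS:
            continue
        else:
            raise ValueError(f"{read_id}: unsupported CIGAR op code {op}")
    if cur > start:
        blocks.append((start, cur))
    if not blocks:
        raise ValueError(f"{read_id}: CIGAR consumes no reference bases")
    return tuple(blocks)


def load_alignments(path: str) -> List[AlignmentRecord]:
    """Read mapped records from SAM/BAM; multiplicity from the NH tag when
    present, else from the number of mapped records sharing a read id."""
    raw = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"{rec.query_name}: mapped record without CIGAR")
            blocks = blocks_from_cigar(
                rec.cigartuples, rec.reference_start, rec.query_name or "?"
            )
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            raw.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    blocks,
                    rec.mapping_quality,
                    nh,
                )
            )
    counts = Counter(name for name, *_ in raw)
    out = []
    for name, ref, strand, blocks, mapq, nh in raw:
        mult = int(nh) if nh is not None else counts[name]
        out.append(AlignmentRecord(name, ref, strand, blocks, mapq, mult))
    return out


def remove_multimapped(
    records: Iterable[AlignmentRecord],
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord]]:
    """Drop every record of any read reported at more than one location."""
    kept, removed = [], []
    for r in records:
        (removed if r.multiplicity > 1 else kept).append(r)
    return kept, removed


def apply_quality_length_filters(
    records: Iterable[AlignmentRecord],
    min_aligned_len: int = 20,
    min_mapq: int = 10,
) -> Tuple[List[AlignmentRecord], int, int]:
    """Length filter first, then MAPQ; returns (kept, n_short, n_low_mapq).

    A record failing both is counted once, under the length stage.
    """
    kept: List[AlignmentRecord] = []
    n_short = n_lowq = 0
    for r in records:
        if r.aligned_length < min_aligned_len:
            n_short += 1
        elif r.mapq < min_mapq:
            n_lowq += 1
        else:
            kept.append(r)
    return kept, n_short, n_lowq


def run_filters(
    records: Sequence[AlignmentRecord],
    min_aligned_len: int = 20,
    min_mapq: int = 10,
) -> Tuple[List[AlignmentRecord], FilterFunnel]:
    """All three filters in the documented order, with funnel accounting."""
    funnel = FilterFunnel(input_records=len(records))
    uniq, multi = remove_multimapped(records)
    funnel.removed_multimapped = len(multi)
    kept, n_short, n_lowq = apply_quality_length_filters(
        uniq, min_aligned_len, min_mapq
    )
    funnel.removed_short = n_short
    funnel.removed_low_mapq = n_lowq
    funnel.kept = len(kept)
    funnel.validate()
    return kept, funnel


def build_exon_index(models: Iterable[TranscriptModel]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for m in models:
        for s, e in m.exons:
            trees[m.chrom].addi(s, e)
    return dict(trees)


def assign_compartment(
    record: AlignmentRecord,
    exon_index: Dict[str, IntervalTree],
    rrna_read_ids: FrozenSet[str] = frozenset(),
) -> str:
    """rRNA (from the partition stage), known_gene (any block overlaps an
    exon by >= 1 base) or unknown."""
    if record.read_id in rrna_read_ids:
        return RRNA_LABEL
    tree = exon_index.get(record.reference)
    if tree is not None:
        for s, e in record.blocks:
            if tree.overlap(s, e):
                return KNOWN_LABEL
    return UNKNOWN_LABEL


def compartment_counts(
    records: Iterable[AlignmentRecord],
    exon_index: Dict[str, IntervalTree],
    n_rrna_reads: int = 0,
) -> pd.DataFrame:
    """Fraction of reads per compartment, with rRNA-partition reads folded
    in as a separate row (they never reach the genome alignments)."""
    labels = Counter(assign_compartment(r, exon_index) for r in records)
    labels[RRNA_LABEL] += n_rrna_reads
    total = sum(labels.values())
    rows = [
        {
            "compartment": name,
            "reads": labels.get(name, 0),
            "percent": round(100.0 * labels.get(name, 0) / total, 1) if total else 0.0,
        }
        for name in (RRNA_LABEL, KNOWN_LABEL, UNKNOWN_LABEL)
    ]
    return pd.DataFrame(rows)


def filter_funnel_report(funnel: FilterFunnel) -> pd.DataFrame:
    """Per-stage counts and percentages of input; empty input reports 0%."""
    funnel.validate()
    n = funnel.input_records
    rows = []
    for stage, count in (
        ("input", funnel.input_records),
        ("removed_multimapped", funnel.removed_multimapped),
        ("removed_short", funnel.removed_short),
        ("removed_low_mapq", funnel.removed_low_mapq),
        ("kept", funnel.kept),
    ):
        rows.append(
            {
                "stage": stage,
                "records": count,
                "percent_of_input": round(100.0 * count / n, 1) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_bed(records: Iterable[AlignmentRecord], path: str) -> None:
    """Split-block BED: chrom, start, end, read_id, score=MAPQ, strand."""
    with open(path, "w") as fh:
        for r in records:
            for s, e in r.blocks:
                fh.write(f"{r.reference}\t{s}\t{e}\t{r.read_id}\t{r.mapq}\t{r.strand}\n")


def read_ids(records: Iterable[AlignmentRecord]) -> Set[str]:
    return {r.read_id for r in records}
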