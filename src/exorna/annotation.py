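"""Transcript models and GTF input/output.

Internally every coordinate is 0-based half-open; GTF on disk is 1-based
inclusive and converted at the boundary. Transcript records carry their
biotype (``gene_type`` attribute, GENCODE vocabulary: ``protein_coding``,
``snoRNA``, ``snRNA``, ``miRNA``, ``lincRNA``, ``Mt_tRNA`` ...); coding
transcripts additionally carry CDS intervals, which detection uses as the
coverage target in place of the exon union.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from . import intervals as iv

PROTEIN_CODING = "protein_coding"

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform of a gene model.

    ``exons`` and ``cds`` are sorted non-overlapping 0-based half-open
    intervals in genome coordinates; ``cds`` is non-empty exactly for
    protein-coding transcripts and must lie within the exon union.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...] = ()
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        if not iv.is_sorted_disjoint(self.exons):
            raise ValueError(f"{self.transcript_id}: exons not sorted/disjoint")
        if self.cds and not iv.is_sorted_disjoint(self.cds):
            raise ValueError(f"{self.transcript_id}: CDS not sorted/disjoint")
        coding = self.biotype == PROTEIN_CODING
        if coding != bool(self.cds):
            raise ValueError(
                f"{self.transcript_id}: CDS must be present iff biotype is "
                f"{PROTEIN_CODING} (biotype={self.biotype!r}, n_cds={len(self.cds)})"
            )
        if self.cds and not iv.contains(self.exons, self.cds):
            raise ValueError(f"{self.transcript_id}: CDS not contained in exons")
        if not self.gene_name:
            object.__setattr__(self, "gene_name", self.gene_id)

    @property
    def is_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def coverage_target(self) -> Tuple[str, Tuple[Tuple[int, int], ...]]:
        """Detection target: CDS for coding transcripts, exon union otherwise."""
        if self.is_coding:
            return "CDS", self.cds
        return "exon", self.exons


def write_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    """Write transcript/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{m.biotype}"; gene_name "{m.gene_name}";'
            )
            rows = [("transcript", m.span[0], m.span[1])]
            rows += [("exon", s, e) for s, e in m.exons]
            rows += [("CDS", s, e) for s, e in m.cds]
            for feature, s, e in rows:
                fh.write(
                    f"{m.chrom}\texorna\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str) -> List[TranscriptModel]:
    """Parse exon and CDS features grouped by transcript_id."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _, feature, start, end, _, strand, _, attr_str = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = dict(_ATTR_RE.findall(attr_str))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF {feature} without transcript_id: {line!r}")
            meta.setdefault(
                tid,
                (
                    attrs.get("gene_id", tid),
                    chrom,
                    strand,
                    attrs.get("gene_type", attrs.get("gene_biotype", "")),
                    attrs.get("gene_name", ""),
                ),
            )
            interval = (int(start) - 1, int(end))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(interval)
    models = []
    for tid, (gene_id, chrom, strand, biotype, gene_name) in meta.items():
        t_exons = tuple(iv.merge(exons.get(tid, [])))
        t_cds = tuple(iv.merge(cds.get(tid, [])))
        if not biotype:
            biotype = PROTEIN_CODING if t_cds else "misc_RNA"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                biotype=biotype,
                exons=t_exons,
                cds=t_cds,
                gene_name=gene_name,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span, m.transcript_id))
    return models
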