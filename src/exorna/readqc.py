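"""Raw-read trimming and filtering, applied before any mapping.

Three steps, in order: exact adapter suffix trimming, 3' low-quality tail
trimming, and minimum-length filtering. Signal-level filters of the
sequencing instrument (off-scale signal, polyclonal wells, residual
ionogram values) cannot be reconstructed from FASTQ and are carried as an
explicit no-op counter in the report so the read funnel stays complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

from .seqio import FastqRead, PHRED_OFFSET
from .simdata import DEFAULT_ADAPTER


@dataclass
class QcParams:
    adapter: str = DEFAULT_ADAPTER
    min_overlap_for_adapter: int = 5
    quality_threshold: int = 15
    # the study retained reads down to 6 bp after trimming
    min_length_after: int = 6

    def validate(self) -> None:
        if self.min_overlap_for_adapter < 1:
            raise ValueError("min_overlap_for_adapter must be >= 1")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_length_after < 1:
            raise ValueError("min_length_after must be >= 1")


@dataclass
class QcReport:
    input_reads: int = 0
    adapter_trimmed: int = 0
    quality_trimmed: int = 0
    removed_short: int = 0
    passed: int = 0
    signal_filter_removed: int = 0  # instrument-level filters: no-op on FASTQ

    def validate(self) -> None:
        if self.removed_short + self.passed != self.input_reads:
            raise ValueError("QcReport does not reconcile: short + passed != input")


def trim_adapter(read: FastqRead, params: QcParams) -> FastqRead:
    """Remove the longest read suffix that exactly matches an adapter
    prefix of length >= ``min_overlap_for_adapter``; no-op otherwise."""
    seq = read.sequence
    adapter = params.adapter
    if not seq or not adapter:
        return read
    max_k = min(len(seq), len(adapter))
    for k in range(max_k, params.min_overlap_for_adapter - 1, -1):
        if seq.endswith(adapter[:k]):
            return FastqRead(read.read_id, seq[:-k], read.quality[:-k])
    return read


def trim_low_quality_tail(read: FastqRead, params: QcParams) -> FastqRead:
    """Remove the trailing maximal run of bases with Q < quality_threshold."""
    cut = len(read.quality)
    thr = params.quality_threshold + PHRED_OFFSET
    while cut > 0 and ord(read.quality[cut - 1]) < thr:
        cut -= 1
    if cut == len(read.quality):
        return read
    return FastqRead(read.read_id, read.sequence[:cut], read.quality[:cut])


def filter_reads(
    reads: Iterable[FastqRead], params: QcParams
) -> Tuple[List[FastqRead], QcReport]:
    """Drop reads shorter than ``min_length_after``; report reconciles."""
    params.validate()
    kept: List[FastqRead] = []
    report = QcReport()
    for r in reads:
        report.input_reads += 1
        if len(r) < params.min_length_after:
            report.removed_short += 1
        else:
            kept.append(r)
            report.passed += 1
    report.validate()
    return kept, report


def process_reads(
    reads: Iterable[FastqRead], params: QcParams
) -> Tuple[List[FastqRead], QcReport]:
    """Full QC: adapter trim, quality trim, length filter, one report."""
    params.validate()
    trimmed: List[FastqRead] = []
    n_adapter = n_quality = 0
    for r in reads:
        t = trim_adapter(r, params)
        if len(t) < len(r):
            n_adapter += 1
        t2 = trim_low_quality_tail(t, params)
        if len(t2) < len(t):
            n_quality += 1
        trimmed.append(t2)
    kept, report = filter_reads(trimmed, params)
    report.adapter_trimmed = n_adapter
    report.quality_trimmed = n_quality
    return kept, report


def report_tsv(report: QcReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for name in (
            "input_reads",
            "adapter_trimmed",
            "quality_trimmed",
            "signal_filter_removed",
            "removed_short",
            "passed",
        ):
            fh.write(f"{name}\t{getattr(report, name)}\n")
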