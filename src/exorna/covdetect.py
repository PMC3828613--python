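"""Coverage-fraction transcript detection and biotype summaries.

Low-depth libraries dominated by rRNA fragments produce spuriously high
RPKM values on barely-covered transcripts, so detection here is based on
*breadth* of coverage instead: the fraction of a transcript's target —
CDS for protein-coding transcripts, exon union for non-coding ones —
covered by at least one aligned block.

Detection rules:

* cellular sample: detected iff coverage fraction > 0.9 (strict);
* exosomal samples: reads of all exosomal samples are pooled; a
  transcript is detected in sample S iff the pooled fraction > 0.9 AND
  the sample-S fraction > 0.5.

A gene is detected when any of its isoforms is; summaries report the
protein-coding/non-coding split per sample and gene-symbol counts per
non-coding biotype, plus overlap statistics between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from . import intervals as iv
from .alnfilter import AlignmentRecord
from .annotation import PROTEIN_CODING, TranscriptModel

CELLULAR_RULE = "cellular_90"
EXOSOME_RULE = "exosome_pooled90_sample50"


@dataclass(frozen=True)
class CoverageResult:
    transcript_id: str
    target: str  # "CDS" or "exon"
    target_length: int
    covered: int

    def __post_init__(self) -> None:
        if self.covered > self.target_length:
            raise ValueError(f"{self.transcript_id}: covered > target length")

    @property
    def fraction(self) -> float:
        return self.covered / self.target_length if self.target_length else 0.0


@dataclass(frozen=True)
class DetectionCall:
    transcript_id: str
    sample: str
    detected: bool
    rule: str
    fraction: float


def transcript_coverage(
    blocks: Sequence[Tuple[int, int]],
    model: TranscriptModel,
    target: str,
) -> CoverageResult:
    """Covered bases = |union(blocks) ∩ union(target intervals)|.

    Blocks on either strand count; overlapping blocks are counted once.
    """
    if target == "CDS":
        if not model.is_coding:
            raise ValueError(
                f"{model.transcript_id}: CDS coverage requested for "
                f"non-coding biotype {model.biotype!r}"
            )
        target_ivs = model.cds
    elif target == "exon":
        target_ivs = model.exons
    else:
        raise ValueError(f"unknown coverage target {target!r}")
    covered = iv.intersect_length(blocks, target_ivs) if blocks else 0
    return CoverageResult(
        model.transcript_id, target, iv.total_length(target_ivs), covered
    )


def coverage_for_model(
    blocks: Sequence[Tuple[int, int]], model: TranscriptModel
) -> CoverageResult:
    """Coverage over the model's natural target (CDS if coding, else exons)."""
    target, _ = model.coverage_target()
    return transcript_coverage(blocks, model, target)


def blocks_by_reference(
    records: Iterable[AlignmentRecord],
) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for r in records:
        out.setdefault(r.reference, []).extend(r.blocks)
    return out


def detect_cellular(coverage: CoverageResult, sample: str) -> DetectionCall:
    """Detected iff the coverage fraction exceeds 0.9 (strictly)."""
    return DetectionCall(
        coverage.transcript_id,
        sample,
        coverage.fraction > 0.9,
        CELLULAR_RULE,
        coverage.fraction,
    )


def detect_exosomal(
    pooled: CoverageResult, per_sample: Mapping[str, CoverageResult]
) -> List[DetectionCall]:
    """Pooled fraction > 0.9 gates detection; each sample must then exceed
    0.5 on its own reads."""
    worst = max((c.fraction for c in per_sample.values()), default=0.0)
    if pooled.fraction < worst - 1e-12:
        raise ValueError(
            f"{pooled.transcript_id}: pooled coverage {pooled.fraction:.4f} below a "
            f"per-sample fraction {worst:.4f}; pooling must dominate"
        )
    gate = pooled.fraction > 0.9
    return [
        DetectionCall(
            pooled.transcript_id,
            sample,
            gate and cov.fraction > 0.5,
            EXOSOME_RULE,
            cov.fraction,
        )
        for sample, cov in per_sample.items()
    ]


def gene_level_detect(
    calls: Iterable[DetectionCall], models: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Collapse isoform calls to genes: a gene is detected iff any isoform
    is. Returns one row per detected gene (gene_id, gene_name, biotype).

    Detected isoforms of one gene with conflicting non-coding biotypes are
    reported once under the lexicographically smallest biotype, with a
    warning; a gene with any detected coding isoform is protein_coding.
    """
    by_tid = {m.transcript_id: m for m in models}
    detected: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    for call in calls:
        if not call.detected:
            continue
        m = by_tid[call.transcript_id]
        detected.setdefault(m.gene_id, set()).add(m.biotype)
        names[m.gene_id] = m.gene_name
    rows = []
    for gene_id in sorted(detected):
        biotypes = detected[gene_id]
        if PROTEIN_CODING in biotypes:
            biotype = PROTEIN_CODING
        else:
            if len(biotypes) > 1:
                warnings.warn(
                    f"{gene_id}: detected isoforms with conflicting non-coding "
                    f"biotypes {sorted(biotypes)}; reporting the first"
                )
            biotype = min(biotypes)
        rows.append(
            {"gene_id": gene_id, "gene_name": names[gene_id], "biotype": biotype}
        )
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "biotype"])


def biotype_summary(
    detected: Mapping[str, pd.DataFrame],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample summaries of detected genes.

    Returns (class_table, noncoding_table): the first gives the
    protein-coding vs non-coding percentage split per sample (one
    decimal); the second counts gene symbols per non-coding biotype,
    sorted descending by the first sample's column.
    """
    samples = list(detected)
    class_rows = []
    for kind in (PROTEIN_CODING, "non_coding"):
        row = {"transcript_type": kind}
        for s in samples:
            df = detected[s]
            n = len(df)
            if kind == PROTEIN_CODING:
                count = int((df["biotype"] == PROTEIN_CODING).sum())
            else:
                count = int((df["biotype"] != PROTEIN_CODING).sum())
            row[s] = round(100.0 * count / n, 1) if n else 0.0
        class_rows.append(row)
    class_table = pd.DataFrame(class_rows)

    biotypes: Set[str] = set()
    for s in samples:
        df = detected[s]
        biotypes |= set(df.loc[df["biotype"] != PROTEIN_CODING, "biotype"])
    nc_rows = []
    for b in sorted(biotypes):
        row = {"biotype": b}
        for s in samples:
            df = detected[s]
            row[s] = int((df["biotype"] == b).sum())
        nc_rows.append(row)
    nc_table = pd.DataFrame(nc_rows, columns=["biotype"] + samples)
    if samples and len(nc_table):
        nc_table = nc_table.sort_values(
            [samples[0], "biotype"], ascending=[False, True]
        ).reset_index(drop=True)
    return class_table, nc_table


def overlap_sets(
    sets: Mapping[str, Set[str]], cellular: str | None = None
) -> Dict[str, object]:
    """Pairwise and three-way intersections of gene-symbol sets, plus the
    percentage of each non-cellular set present in the cellular set."""
    names = list(sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    threeway = None
    if len(names) >= 3:
        inter = set(sets[names[0]])
        for n in names[1:]:
            inter &= sets[n]
        threeway = len(inter)
    pct_in_cellular: Dict[str, float] = {}
    if cellular is not None:
        base = sets[cellular]
        for n in names:
            if n == cellular:
                continue
            size = len(sets[n])
            pct_in_cellular[n] = (
                round(100.0 * len(sets[n] & base) / size, 1) if size else 0.0
            )
    return {"pairwise": pairwise, "threeway": threeway, "pct_in_cellular": pct_in_cellular}


def coverage_table(results: Iterable[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "target": c.target,
                "target_length": c.target_length,
                "covered": c.covered,
                "fraction": c.fraction,
            }
            for c in results
        ]
    )


def calls_table(calls: Iterable[DetectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "sample": c.sample,
                "detected": c.detected,
                "rule": c.rule,
                "fraction": c.fraction,
            }
            for c in calls
        ]
    )
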