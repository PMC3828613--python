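"""Synthetic reference and read-library generator.

Builds a toy reference — a random background chromosome with embedded
multi-exon gene loci, plus a free-standing set of ribosomal RNA analogs
(28S/18S/5.8S/5S) — and simulates read libraries that emulate the two
regimes seen in extracellular-vesicle sequencing:

* **exosome-like**: ~97% of reads are rRNA *fragments* that tile the full
  length of each subunit (degraded rRNA rather than intact molecules),
  with the small remainder drawn from transcripts and intergenic space;
* **cell-like**: ~24% rRNA, the majority of reads from annotated
  transcripts.

Fragments span a broad size range (30-500 nt by default). Every simulated
read gets a ground-truth record (origin class, source, interval and genome
alignment blocks), and truth alignments can be emitted as spliced SAM so
the downstream stages run without an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from . import intervals as iv
from .annotation import PROTEIN_CODING, TranscriptModel, write_gtf
from .seqio import FastqRead, PHRED_OFFSET, revcomp, write_fasta, write_fastq

# Ion-P1-style adapter appended to fragment 3' ends
DEFAULT_ADAPTER = "CCTCTCTATGGGCAGTCGGTGAT"

RRNA_CLASS = "rRNA"
TRANSCRIPT_CLASS = "transcript"
INTERGENIC_CLASS = "intergenic"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class IsoformSpec:
    transcript_id: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...] = ()


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    biotype: str
    strand: str
    isoforms: Tuple[IsoformSpec, ...]
    gene_name: str = ""


@dataclass(frozen=True)
class ToyReferenceSpec:
    """Blueprint for the toy genome, rRNA set and gene annotation."""

    chromosome_length: int
    rrna_refs: Tuple[Tuple[str, int], ...]
    gene_specs: Tuple[GeneSpec, ...] = ()
    seed: int = 0
    chrom_name: str = "chrT"
    # optionally embed one copy of the first rRNA into the genome, to
    # exercise the partition-before-genome ordering downstream
    embed_rrna: bool = False

    def validate(self) -> None:
        names = [n for n, _ in self.rrna_refs]
        if len(set(names)) != len(names):
            raise ValueError("rRNA reference names must be unique")
        for _, length in self.rrna_refs:
            if length < 1:
                raise ValueError("rRNA length must be positive")
        for g in self.gene_specs:
            for iso in g.isoforms:
                if not iv.is_sorted_disjoint(iso.exons):
                    raise ValueError(f"{iso.transcript_id}: bad exon intervals")
                if iso.exons[-1][1] > self.chromosome_length:
                    raise ValueError(
                        f"{iso.transcript_id}: exons exceed chromosome length"
                    )
                if iso.cds and not iv.contains(iso.exons, iso.cds):
                    raise ValueError(f"{iso.transcript_id}: CDS outside exons")
        # ambiguous truth: two genes on one strand with identical exon chains
        seen: Dict[Tuple, str] = {}
        for g in self.gene_specs:
            for iso in g.isoforms:
                key = (g.strand, iso.exons)
                other = seen.get(key)
                if other is not None and other != g.gene_id:
                    raise ValueError(
                        f"genes {other} and {g.gene_id} share strand and exact "
                        "exon structure; truth would be ambiguous"
                    )
                seen[key] = g.gene_id


@dataclass
class LibraryProfile:
    """Read-sampling parameters for one simulated library.

    ``rrna_fraction`` is the probability a read is an rRNA fragment; the
    remaining mass is split between annotated transcripts (weighted by
    ``transcript_abundances``) and intergenic background (weight
    ``intergenic_weight`` on the same scale as the abundances).
    ``quality_model`` is (mean Phred, 3' decay length d): the final ``3*d``
    bases decay exponentially with e-folding length ``d``.
    """

    n_reads: int
    rrna_fraction: float
    transcript_abundances: Dict[str, float]
    fragment_length_range: Tuple[int, int] = (30, 500)
    spliced_allowed: bool = True
    quality_model: Tuple[int, int] = (35, 4)
    adapter: str = DEFAULT_ADAPTER
    adapter_rate: float = 0.0
    rrna_weights: Optional[Dict[str, float]] = None
    intergenic_weight: float = 0.0
    error_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.rrna_fraction <= 1.0:
            raise ValueError("rrna_fraction must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        lo, hi = self.fragment_length_range
        if not 1 <= lo <= hi:
            raise ValueError("fragment_length_range must satisfy 1 <= min <= max")
        if any(w < 0 for w in self.transcript_abundances.values()):
            raise ValueError("abundances must be non-negative")
        if self.rrna_fraction < 1.0 and not (
            any(w > 0 for w in self.transcript_abundances.values())
            or self.intergenic_weight > 0
        ):
            raise ValueError("need at least one positive non-rRNA source weight")
        if not 0.0 <= self.adapter_rate <= 1.0:
            raise ValueError("adapter_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read.

    ``origin_interval`` is in source coordinates (transcript, rRNA subunit
    or chromosome); ``blocks`` are the genome alignment blocks (empty for
    rRNA-origin reads, which have no genome placement).
    """

    read_id: str
    origin_class: str
    origin_name: str
    origin_interval: Tuple[int, int]
    blocks: Tuple[Tuple[int, int], ...] = ()
    strand: str = "+"


@dataclass
class ToyReference:
    genome: Dict[str, str]
    rrna: Dict[str, str]
    models: List[TranscriptModel]
    spec: ToyReferenceSpec

    @property
    def chrom(self) -> str:
        return self.spec.chrom_name

    def model(self, transcript_id: str) -> TranscriptModel:
        for m in self.models:
            if m.transcript_id == transcript_id:
                return m
        raise KeyError(transcript_id)

    def transcript_sequence(self, model: TranscriptModel) -> str:
        seq = "".join(self.genome[model.chrom][s:e] for s, e in model.exons)
        return revcomp(seq) if model.strand == "-" else seq


# ---------------------------------------------------------------------------
# reference construction


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def build_reference(spec: ToyReferenceSpec) -> ToyReference:
    """Materialise a :class:`ToyReferenceSpec` into sequences and models.

    Deterministic given ``spec.seed``. The genome is i.i.d. uniform
    A/C/G/T; rRNA sequences are drawn independently and (unless
    ``embed_rrna``) share no embedded copy in the genome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome_seq = _random_seq(rng, spec.chromosome_length)
    rrna = {name: _random_seq(rng, length) for name, length in spec.rrna_refs}

    models: List[TranscriptModel] = []
    for g in spec.gene_specs:
        for iso in g.isoforms:
            models.append(
                TranscriptModel(
                    transcript_id=iso.transcript_id,
                    gene_id=g.gene_id,
                    chrom=spec.chrom_name,
                    strand=g.strand,
                    biotype=g.biotype,
                    exons=tuple(iso.exons),
                    cds=tuple(iso.cds),
                    gene_name=g.gene_name or g.gene_id,
                )
            )

    if spec.embed_rrna and spec.rrna_refs:
        name = spec.rrna_refs[0][0]
        copy = rrna[name]
        spans = [m.span for m in models]
        gaps = iv.complement(spans, 0, spec.chromosome_length) if spans else [
            (0, spec.chromosome_length)
        ]
        slot = next((g for g in gaps if g[1] - g[0] >= len(copy)), None)
        if slot is None:
            raise ValueError("no intergenic gap large enough to embed rRNA copy")
        genome_seq = genome_seq[: slot[0]] + copy + genome_seq[slot[0] + len(copy):]

    return ToyReference(
        genome={spec.chrom_name: genome_seq}, rrna=rrna, models=models, spec=spec
    )


# ---------------------------------------------------------------------------
# coordinate mapping


def transcript_to_genome_blocks(
    model: TranscriptModel, t_start: int, t_end: int
) -> Tuple[Tuple[int, int], ...]:
    """Map a transcript-coordinate interval to genome blocks.

    Transcript coordinates run 5'->3' along the transcript; for minus-strand
    models this is right-to-left on the genome.
    """
    lt = model.exon_length
    if not 0 <= t_start < t_end <= lt:
        raise ValueError("interval outside transcript")
    if model.strand == "-":
        t_start, t_end = lt - t_end, lt - t_start
    blocks = []
    offset = 0
    for s, e in model.exons:
        length = e - s
        lo = max(t_start, offset)
        hi = min(t_end, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return tuple(blocks)


# ---------------------------------------------------------------------------
# library simulation


def _quality_string(length: int, model: Tuple[int, int]) -> str:
    mean_q, decay = model
    q = np.full(length, mean_q, dtype=float)
    if decay > 0:
        tail = min(3 * decay, length)
        # distance from the 3' end, in the decaying zone
        dist = np.arange(tail - 1, -1, -1, dtype=float)
        q[length - tail:] = mean_q * np.exp(-(3 * decay - dist) / decay)
    q = np.clip(np.rint(q), 2, 41).astype(int)
    return "".join(chr(int(x) + PHRED_OFFSET) for x in q)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def simulate_library(
    profile: LibraryProfile, reference: ToyReference, seed: int
) -> Tuple[List[FastqRead], List[ReadTruth]]:
    """Draw ``profile.n_reads`` reads with per-read ground truth.

    Each read: choose origin class (rRNA with probability
    ``rrna_fraction``), then a source weighted by its abundance, then a
    fragment uniform over the source. Fragment length is uniform over the
    profile range, clamped at the top to the source length.
    """
    profile.validate()
    fmin, fmax = profile.fragment_length_range

    for tid in profile.transcript_abundances:
        reference.model(tid)  # raises KeyError if absent

    # rRNA sources
    if profile.rrna_weights is not None:
        unknown = set(profile.rrna_weights) - set(reference.rrna)
        if unknown:
            raise ValueError(f"unknown rRNA subunits in weights: {sorted(unknown)}")
        r_names = sorted(n for n, w in profile.rrna_weights.items() if w > 0)
        r_weights = np.array([profile.rrna_weights[n] for n in r_names], dtype=float)
    else:
        r_names = sorted(reference.rrna)
        r_weights = np.array([len(reference.rrna[n]) for n in r_names], dtype=float)

    # transcript + intergenic sources
    t_ids = sorted(t for t, w in profile.transcript_abundances.items() if w > 0)
    t_models = {t: reference.model(t) for t in t_ids}
    t_seqs = {t: reference.transcript_sequence(m) for t, m in t_models.items()}

    chrom = reference.chrom
    genome = reference.genome[chrom]
    gene_spans = [m.span for m in reference.models]
    intergenic = [
        g
        for g in iv.complement(gene_spans, 0, len(genome))
        if g[1] - g[0] >= fmin
    ]

    offenders = [n for n in r_names if len(reference.rrna[n]) < fmin]
    offenders += [t for t in t_ids if len(t_seqs[t]) < fmin]
    if profile.rrna_fraction > 0 and not r_names:
        raise ValueError("rrna_fraction > 0 but no positive-weight rRNA source")
    if offenders:
        raise ValueError(
            "minimum fragment length exceeds source length for: "
            + ", ".join(sorted(offenders))
        )
    if profile.intergenic_weight > 0 and not intergenic:
        raise ValueError("no intergenic region can hold the minimum fragment length")

    src_names = t_ids + ([INTERGENIC_CLASS] if profile.intergenic_weight > 0 else [])
    src_weights = np.array(
        [profile.transcript_abundances[t] for t in t_ids]
        + ([profile.intergenic_weight] if profile.intergenic_weight > 0 else []),
        dtype=float,
    )
    if profile.rrna_fraction < 1.0 and profile.n_reads > 0 and src_weights.sum() <= 0:
        raise ValueError("no positive non-rRNA source weight")

    rng = np.random.default_rng(seed)
    r_p = r_weights / r_weights.sum() if len(r_weights) else r_weights
    s_p = src_weights / src_weights.sum() if src_weights.sum() > 0 else src_weights
    ig_lengths = np.array([e - s for s, e in intergenic], dtype=float)

    reads: List[FastqRead] = []
    truths: List[ReadTruth] = []
    for i in range(profile.n_reads):
        rid = f"read{i:06d}"
        if rng.random() < profile.rrna_fraction:
            name = r_names[rng.choice(len(r_names), p=r_p)]
            src = reference.rrna[name]
            flen = int(rng.integers(fmin, min(fmax, len(src)) + 1))
            start = int(rng.integers(0, len(src) - flen + 1))
            frag = src[start:start + flen]
            truth = ReadTruth(rid, RRNA_CLASS, name, (start, start + flen))
        else:
            j = int(rng.choice(len(src_names), p=s_p))
            name = src_names[j]
            if name == INTERGENIC_CLASS:
                k = int(rng.choice(len(intergenic), p=ig_lengths / ig_lengths.sum()))
                gs, ge = intergenic[k]
                flen = int(rng.integers(fmin, min(fmax, ge - gs) + 1))
                start = gs + int(rng.integers(0, (ge - gs) - flen + 1))
                frag = genome[start:start + flen]
                truth = ReadTruth(
                    rid,
                    INTERGENIC_CLASS,
                    chrom,
                    (start, start + flen),
                    ((start, start + flen),),
                )
            else:
                model = t_models[name]
                tseq = t_seqs[name]
                if profile.spliced_allowed:
                    flen = int(rng.integers(fmin, min(fmax, len(tseq)) + 1))
                    t0 = int(rng.integers(0, len(tseq) - flen + 1))
                else:
                    ok = [e for e in model.exons if e[1] - e[0] >= fmin]
                    if not ok:
                        raise ValueError(
                            f"{name}: no exon can hold an unspliced fragment"
                        )
                    lens = np.array([e[1] - e[0] for e in ok], dtype=float)
                    s_ex, e_ex = ok[int(rng.choice(len(ok), p=lens / lens.sum()))]
                    flen = int(rng.integers(fmin, min(fmax, e_ex - s_ex) + 1))
                    gpos = s_ex + int(rng.integers(0, (e_ex - s_ex) - flen + 1))
                    # plus-orientation transcript coordinate of the fragment
                    plus = sum(
                        min(e, gpos) - s
                        for s, e in model.exons
                        if s < gpos
                    )
                    t0 = plus
                    if model.strand == "-":
                        t0 = len(tseq) - (plus + flen)
                frag = tseq[t0:t0 + flen]
                blocks = transcript_to_genome_blocks(model, t0, t0 + flen)
                truth = ReadTruth(
                    rid,
                    TRANSCRIPT_CLASS,
                    name,
                    (t0, t0 + flen),
                    blocks,
                    model.strand,
                )
        frag = _apply_errors(rng, frag, profile.error_rate)
        if profile.adapter and rng.random() < profile.adapter_rate:
            frag = frag + profile.adapter
        qual = _quality_string(len(frag), profile.quality_model)
        reads.append(FastqRead(rid, frag, qual))
        truths.append(truth)
    return reads, truths


# ---------------------------------------------------------------------------
# truth output


def emit_truth_alignments(
    truths: Sequence[ReadTruth],
    reference: ToyReference,
    path: str,
    mapq: int = 60,
) -> None:
    """Write truth placements as SAM.

    Spliced transcript reads get N-gapped CIGARs spanning introns;
    rRNA-origin reads are emitted unmapped to the genome (the rRNA
    partition stage is responsible for them).
    """
    chrom = reference.chrom
    chrom_len = len(reference.genome[chrom])
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for t in truths:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = t.read_id
            if t.origin_class == RRNA_CLASS:
                a.is_unmapped = True
                sam.write(a)
                continue
            if t.blocks[0][0] < 0 or t.blocks[-1][1] > chrom_len:
                raise ValueError(f"{t.read_id}: truth blocks outside reference")
            a.reference_id = 0
            a.reference_start = t.blocks[0][0]
            a.mapping_quality = mapq
            a.is_reverse = t.strand == "-"
            cigar = []
            for k, (s, e) in enumerate(t.blocks):
                if k:
                    cigar.append((3, s - t.blocks[k - 1][1]))  # N
                cigar.append((0, e - s))  # M
            a.cigartuples = cigar
            a.set_tag("NH", 1)
            sam.write(a)


def write_truth_table(truths: Sequence[ReadTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin_class\torigin_name\tstart\tend\tstrand\tblocks\n")
        for t in truths:
            blocks = ",".join(f"{s}-{e}" for s, e in t.blocks)
            fh.write(
                f"{t.read_id}\t{t.origin_class}\t{t.origin_name}\t"
                f"{t.origin_interval[0]}\t{t.origin_interval[1]}\t{t.strand}\t{blocks}\n"
            )


# ---------------------------------------------------------------------------
# default study conditions


def default_reference_spec(seed: int = 0) -> ToyReferenceSpec:
    """Toy analog of the real reference: 4 rRNA subunits (scaled down)
    and a small annotated chromosome with coding and non-coding loci."""
    genes = (
        GeneSpec(
            "GENE_GAPDH",
            PROTEIN_CODING,
            "+",
            (
                IsoformSpec(
                    "GAPDH-201",
                    ((2000, 2300), (2800, 3200), (3700, 4100)),
                    ((2100, 2300), (2800, 3200), (3700, 4000)),
                ),
                IsoformSpec(
                    "GAPDH-202",
                    ((2000, 2300), (3700, 4100)),
                    ((2100, 2300), (3700, 4000)),
                ),
            ),
            gene_name="GAPDH",
        ),
        GeneSpec(
            "GENE_B",
            PROTEIN_CODING,
            "-",
            (
                IsoformSpec(
                    "GENEB-201",
                    ((7000, 7400), (7900, 8300), (8800, 9200)),
                    ((7100, 7400), (7900, 8300), (8800, 9100)),
                ),
            ),
            gene_name="GENEB",
        ),
        GeneSpec(
            "GENE_C",
            PROTEIN_CODING,
            "+",
            (
                IsoformSpec(
                    "GENEC-201",
                    ((12000, 12500), (13000, 13500)),
                    ((12100, 12500), (13000, 13400)),
                ),
                IsoformSpec(
                    "GENEC-202",
                    ((12000, 12500), (14000, 14500)),
                    ((12100, 12500), (14000, 14400)),
                ),
            ),
            gene_name="GENEC",
        ),
        GeneSpec(
            "GENE_LINC",
            "lincRNA",
            "+",
            (IsoformSpec("LINC-201", ((17000, 17600), (18100, 18600))),),
            gene_name="LINC1",
        ),
        GeneSpec(
            "GENE_SNORD",
            "snoRNA",
            "+",
            (IsoformSpec("SNORD-201", ((20000, 20130),)),),
            gene_name="SNORD1",
        ),
        GeneSpec(
            "GENE_SNRNP",
            "snRNA",
            "-",
            (IsoformSpec("SNRNP-201", ((21000, 21160),)),),
            gene_name="RNU1",
        ),
        GeneSpec(
            "GENE_MIR",
            "miRNA",
            "+",
            (IsoformSpec("MIR-201", ((22000, 22085),)),),
            gene_name="MIR1",
        ),
        GeneSpec(
            "GENE_MT_TRNA",
            "Mt_tRNA",
            "+",
            (IsoformSpec("MTTRNA-201", ((23000, 23072),)),),
            gene_name="MT-T1",
        ),
        GeneSpec(
            "GENE_ZERO",
            PROTEIN_CODING,
            "+",
            (
                IsoformSpec(
                    "ZERO-201",
                    ((26000, 26400), (26900, 27300)),
                    ((26100, 26400), (26900, 27200)),
                ),
            ),
            gene_name="ZEROX",
        ),
    )
    return ToyReferenceSpec(
        chromosome_length=60_000,
        rrna_refs=(("28S", 2000), ("18S", 1200), ("5.8S", 160), ("5S", 120)),
        gene_specs=genes,
        seed=seed,
    )


# abundance tables for the two library regimes; keys are transcript ids of
# the default reference, values are relative read weights (not RPKM)
_CELL_ABUNDANCES = {
    "GAPDH-201": 0.25,
    "GAPDH-202": 0.08,
    "GENEB-201": 0.15,
    "GENEC-201": 0.12,
    "GENEC-202": 0.06,
    "LINC-201": 0.08,
    "SNORD-201": 0.10,
    "SNRNP-201": 0.06,
    "MIR-201": 0.05,
    "MTTRNA-201": 0.05,
    "ZERO-201": 0.0,
}

_EXOSOME_ABUNDANCES = {
    "GAPDH-201": 0.20,
    "GAPDH-202": 0.05,
    "GENEB-201": 0.10,
    "GENEC-201": 0.08,
    "GENEC-202": 0.04,
    "LINC-201": 0.05,
    "SNORD-201": 0.20,
    "SNRNP-201": 0.12,
    "MIR-201": 0.08,
    "MTTRNA-201": 0.08,
    "ZERO-201": 0.0,
}

# 18S/28S dominate the rRNA fragment pool
_RRNA_WEIGHTS = {"28S": 5.0, "18S": 4.0, "5.8S": 0.5, "5S": 0.5}


def exosome_profile(n_reads: int = 20_000, **overrides) -> LibraryProfile:
    """Exosome-like library: ~97% fragmented rRNA, transcripts ~2%,
    intergenic ~1% of reads."""
    prof = LibraryProfile(
        n_reads=n_reads,
        rrna_fraction=0.97,
        transcript_abundances=dict(_EXOSOME_ABUNDANCES),
        rrna_weights=dict(_RRNA_WEIGHTS),
        intergenic_weight=0.5,
        adapter_rate=0.2,
    )
    return replace(prof, **overrides)


def cell_profile(n_reads: int = 20_000, **overrides) -> LibraryProfile:
    """Cell-like library: ~24% rRNA, most reads from annotated genes."""
    prof = LibraryProfile(
        n_reads=n_reads,
        rrna_fraction=0.24,
        transcript_abundances=dict(_CELL_ABUNDANCES),
        rrna_weights=dict(_RRNA_WEIGHTS),
        intergenic_weight=0.30,
        adapter_rate=0.2,
    )
    return replace(prof, **overrides)


def write_reference(reference: ToyReference, outdir: str) -> Dict[str, str]:
    """Write genome/rRNA FASTA and annotation GTF; returns the path map."""
    import os

    paths = {
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "rrna_fasta": os.path.join(outdir, "rrna.fa"),
        "annotation_gtf": os.path.join(outdir, "annotation.gtf"),
    }
    write_fasta(reference.genome, paths["genome_fasta"])
    write_fasta(reference.rrna, paths["rrna_fasta"])
    write_gtf(reference.models, paths["annotation_gtf"])
    return paths
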