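"""Isoform abundance by expectation-maximization, and RPKM.

Reads compatible with several isoforms (shared exons) cannot be assigned
by counting alone. The generative model: a read comes from isoform i with
probability θ_i (a simplex over the isoform set) and falls uniformly
along its effective length ℓ_i. The E-step apportions each read's unit
mass over its compatible isoforms ∝ θ_i/ℓ_i; the M-step renormalizes
θ from the assigned masses. The observed-data log-likelihood is
non-decreasing across iterations and total mass is conserved exactly.

Effective length is the transcript target length (no fragment-length
correction). RPKM = 1e9 · mass / (ℓ · total mapped reads), and the
alternative detection rule keeps a transcript when RPKM > 1 in at least
one sample — deliberately kept separate from coverage-based detection so
the two approaches can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .alnfilter import AlignmentRecord
from .annotation import TranscriptModel


@dataclass
class CompatibilityMatrix:
    """Read-isoform compatibility, stored as equivalence classes.

    ``classes`` maps a sorted tuple of isoform indices to the number of
    reads compatible with exactly that set. ``n_dropped`` counts reads
    compatible with no isoform.
    """

    isoform_ids: List[str]
    effective_lengths: np.ndarray
    classes: Dict[Tuple[int, ...], int]
    n_dropped: int = 0

    @property
    def n_reads(self) -> int:
        return sum(self.classes.values())

    def validate(self) -> None:
        if np.any(self.effective_lengths <= 0):
            raise ValueError("effective lengths must be positive")
        for key in self.classes:
            if not key:
                raise ValueError("empty compatibility class")


@dataclass
class AbundanceEstimate:
    isoform_id: str
    theta: float
    mass: float
    rpkm: float = float("nan")


def _compatible(
    blocks: Sequence[Tuple[int, int]],
    exon_union: Sequence[Tuple[int, int]],
    tolerance: int,
) -> bool:
    """Blocks lie in the exon union and junctions match exon boundaries.

    Consecutive blocks must skip exactly one inter-exon gap: block k ends
    at the end of union exon j and block k+1 starts at the start of union
    exon j+1, each within ``tolerance`` bases.
    """
    if not iv.contains(exon_union, blocks):
        return False
    merged_blocks = iv.merge(blocks)
    if len(merged_blocks) == 1:
        return True
    for k in range(len(merged_blocks) - 1):
        gap_s, gap_e = merged_blocks[k][1], merged_blocks[k + 1][0]
        ok = False
        for j in range(len(exon_union) - 1):
            if (
                abs(exon_union[j][1] - gap_s) <= tolerance
                and abs(exon_union[j + 1][0] - gap_e) <= tolerance
            ):
                ok = True
                break
        if not ok:
            return False
    return True


def build_compatibility(
    records: Iterable[AlignmentRecord],
    models: Sequence[TranscriptModel],
    tolerance: int = 0,
) -> CompatibilityMatrix:
    """Compatibility of each read with each isoform; incompatible-with-all
    reads are dropped and counted."""
    ids = [m.transcript_id for m in models]
    index = {tid: i for i, tid in enumerate(ids)}
    unions = {m.transcript_id: iv.merge(m.exons) for m in models}
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    lengths = np.array([iv.total_length(m.exons) for m in models], dtype=float)
    classes: Dict[Tuple[int, ...], int] = {}
    n_dropped = 0
    for rec in records:
        compat = tuple(
            sorted(
                index[m.transcript_id]
                for m in by_chrom.get(rec.reference, [])
                if _compatible(rec.blocks, unions[m.transcript_id], tolerance)
            )
        )
        if not compat:
            n_dropped += 1
            continue
        classes[compat] = classes.get(compat, 0) + 1
    matrix = CompatibilityMatrix(ids, lengths, classes, n_dropped)
    matrix.validate()
    return matrix


def em_abundance(
    matrix: CompatibilityMatrix, max_iter: int = 1000, tol: float = 1e-8
) -> List[AbundanceEstimate]:
    """Run EM to convergence (max |Δθ| < tol) or ``max_iter``.

    Isoforms with no compatible reads end at θ = 0. Raises on an empty
    matrix (no compatible reads at all).
    """
    n_iso = len(matrix.isoform_ids)
    n = matrix.n_reads
    if n == 0:
        raise ValueError("compatibility matrix holds no reads")
    ell = matrix.effective_lengths
    keys = list(matrix.classes)
    counts = np.array([matrix.classes[k] for k in keys], dtype=float)
    members = [np.array(k, dtype=int) for k in keys]

    theta = np.full(n_iso, 1.0 / n_iso)
    prev_ll = -np.inf
    for _ in range(max_iter):
        mass = np.zeros(n_iso)
        ll = 0.0
        for idx, cnt in zip(members, counts):
            w = theta[idx] / ell[idx]
            tot = w.sum()
            if tot <= 0.0:
                # class momentarily starved (underflow); split evenly
                w = np.full(len(idx), 1.0 / len(idx))
                tot = 1.0
            else:
                ll += cnt * np.log(tot)
            mass[idx] += cnt * w / tot
        new_theta = mass / n
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        prev_ll = ll
        if delta < tol:
            break
    mass = np.zeros(n_iso)
    for idx, cnt in zip(members, counts):
        w = theta[idx] / ell[idx]
        tot = w.sum()
        if tot > 0:
            mass[idx] += cnt * w / tot
        else:
            mass[idx] += cnt / len(idx)
    return [
        AbundanceEstimate(matrix.isoform_ids[i], float(theta[i]), float(mass[i]))
        for i in range(n_iso)
    ]


def rpkm(mass: float, effective_length: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of target per million mapped reads."""
    if effective_length <= 0:
        raise ValueError("effective length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return 1e9 * mass / (effective_length * total_mapped_reads)


def add_rpkm(
    estimates: Sequence[AbundanceEstimate],
    matrix: CompatibilityMatrix,
    total_mapped_reads: int,
) -> List[AbundanceEstimate]:
    out = []
    for est, ell in zip(estimates, matrix.effective_lengths):
        out.append(
            AbundanceEstimate(
                est.isoform_id,
                est.theta,
                est.mass,
                rpkm(est.mass, float(ell), float(total_mapped_reads)),
            )
        )
    return out


def rpkm_detect(
    estimates_by_sample: Mapping[str, Sequence[AbundanceEstimate]],
    threshold: float = 1.0,
) -> Set[str]:
    """Transcripts with RPKM strictly above ``threshold`` in >= 1 sample
    (the "RPKM approach", for comparison with coverage detection)."""
    kept: Set[str] = set()
    for ests in estimates_by_sample.values():
        for e in ests:
            if e.rpkm > threshold:
                kept.add(e.isoform_id)
    return kept


def abundance_table(
    estimates_by_sample: Mapping[str, Sequence[AbundanceEstimate]],
    models: Sequence[TranscriptModel],
) -> pd.DataFrame:
    gene_of = {m.transcript_id: m.gene_id for m in models}
    rows = []
    for sample, ests in estimates_by_sample.items():
        for e in ests:
            rows.append(
                {
                    "sample": sample,
                    "transcript_id": e.isoform_id,
                    "gene_id": gene_of.get(e.isoform_id, ""),
                    "theta": e.theta,
                    "mass": e.mass,
                    "rpkm": e.rpkm,
                }
            )
    return pd.DataFrame(rows)
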