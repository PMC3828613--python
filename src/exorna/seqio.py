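"""FASTA/FASTQ reading and writing (Biopython-backed)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class FastqRead:
    """A single read: sequence plus Phred+33 quality string of equal length."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> List[int]:
        return [ord(c) - PHRED_OFFSET for c in self.quality]


def write_fasta(seqs: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[FastqRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str) -> List[FastqRead]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(
            FastqRead(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + PHRED_OFFSET) for q in quals),
            )
        )
    return out
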