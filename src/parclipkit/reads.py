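"""FASTQ records and duplicate collapsing."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO


class FastqRead(NamedTuple):
    id: str
    sequence: str
    quality: str


class CollapsedRead(NamedTuple):
    """One distinct sequence with its copy number (id of the first occurrence)."""

    read_id: str
    sequence: str
    copies: int


def read_fastq(path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> Path:
    # plain 4-line records; constant-quality simulated libraries make SeqRecord
    # construction pointless overhead
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    return path


def collapse_duplicates(reads: Iterable) -> list[CollapsedRead]:
    """Collapse identical sequences (case-insensitive), preserving copy numbers.

    Accepts FastqRead or any (id, sequence, ...) tuples.  Order of first
    occurrence is preserved, which keeps downstream tie-breaking deterministic.
    """
    table: dict[str, list] = {}
    for r in reads:
        seq = r[1].upper()
        entry = table.get(seq)
        if entry is None:
            table[seq] = [r[0], 1]
        else:
            entry[1] += 1
    return [CollapsedRead(rid, seq, n) for seq, (rid, n) in table.items()]
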