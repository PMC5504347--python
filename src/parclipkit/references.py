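"""Categorized transcript-space reference universe.

All downstream analyses run in transcript space: mature mRNA sequences with
5'UTR/CDS/3'UTR boundaries, tRNA gene bodies with per-position cloverleaf
element annotations, and rRNA species.  Coordinates are 1-based inclusive
throughout.  Sequences are normalized to the DNA alphabet (U -> T, upcased)
at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("mRNA", "tRNA", "rRNA", "other")

#: tRNA cloverleaf structural elements and their one-letter file codes.
TRNA_ELEMENTS = (
    "acceptor-5p",
    "D-stem",
    "D-loop",
    "anticodon-stem",
    "anticodon-loop",
    "variable",
    "T-stem",
    "T-loop",
    "acceptor-3p",
    "other",
)
ELEMENT_TO_CODE = {
    "acceptor-5p": "A",
    "D-stem": "D",
    "D-loop": "d",
    "anticodon-stem": "C",
    "anticodon-loop": "c",
    "variable": "V",
    "T-stem": "T",
    "T-loop": "t",
    "acceptor-3p": "Z",
    "other": "O",
}
CODE_TO_ELEMENT = {v: k for k, v in ELEMENT_TO_CODE.items()}

_ALPHABET = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Raised when a reference universe violates its invariants."""


def normalize_sequence(seq: str) -> str:
    """Upcase and convert RNA U to DNA T; reject characters outside A/C/G/T/N."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ReferenceError(f"sequence contains invalid characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class ReferenceSeq:
    """One reference sequence with its RNA category."""

    id: str
    category: str
    sequence: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ReferenceError(
                f"unknown category {self.category!r} for {self.id!r}; "
                f"expected one of {CATEGORIES}"
            )
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) == 0:
            raise ReferenceError(f"empty sequence for {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MrnaRegions:
    """5'UTR/CDS/3'UTR lengths of one mRNA (1-based transcript coordinates)."""

    ref_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self):
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ReferenceError(f"negative UTR length for {self.ref_id!r}")
        if self.cds_len <= 0:
            raise ReferenceError(f"non-positive CDS length for {self.ref_id!r}")

    @property
    def total(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        """1-based position of the first CDS nucleotide."""
        return self.utr5_len + 1

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    def region_of(self, pos: int) -> str:
        """Region containing a 1-based transcript position."""
        if pos < 1 or pos > self.total:
            raise ReferenceError(
                f"position {pos} outside transcript {self.ref_id!r} (1..{self.total})"
            )
        if pos <= self.utr5_len:
            return "5'UTR"
        if pos <= self.utr5_len + self.cds_len:
            return "CDS"
        return "3'UTR"


@dataclass(frozen=True)
class TrnaAnnotation:
    """Isoacceptor identity and per-position cloverleaf element of one tRNA gene."""

    ref_id: str
    amino_acid: str
    anticodon: str
    element_map: tuple[str, ...]

    def __post_init__(self):
        if len(self.anticodon) != 3:
            raise ReferenceError(
                f"anticodon {self.anticodon!r} of {self.ref_id!r} is not 3 nt"
            )
        bad = set(self.element_map) - set(TRNA_ELEMENTS)
        if bad:
            raise ReferenceError(
                f"unknown structural elements {sorted(bad)} for {self.ref_id!r}"
            )
        if "D-loop" not in self.element_map:
            raise ReferenceError(f"tRNA {self.ref_id!r} has no D-loop positions")

    @property
    def family(self) -> str:
        """Isoacceptor family label, e.g. 'Lys-UUU'."""
        return f"{self.amino_acid}-{self.anticodon}"

    def element_at(self, pos: int) -> str:
        """Structural element at a 1-based position."""
        return self.element_map[pos - 1]

    def positions_of(self, element: str) -> tuple[int, ...]:
        """All 1-based positions belonging to a structural element."""
        return tuple(i + 1 for i, e in enumerate(self.element_map) if e == element)


@dataclass
class ReferenceSet:
    """Validated collection of categorized references with their annotations."""

    sequences: dict[str, ReferenceSeq] = field(default_factory=dict)
    mrna_regions: dict[str, MrnaRegions] = field(default_factory=dict)
    trna_annotations: dict[str, TrnaAnnotation] = field(default_factory=dict)

    @classmethod
    def from_parts(cls, sequences, mrna_regions=(), trna_annotations=()) -> "ReferenceSet":
        """Build and validate a set from iterables of the three record types."""
        seqs: dict[str, ReferenceSeq] = {}
        for s in sequences:
            if s.id in seqs:
                raise ReferenceError(f"duplicate reference id {s.id!r}")
            seqs[s.id] = s
        rs = cls(
            sequences=seqs,
            mrna_regions={r.ref_id: r for r in mrna_regions},
            trna_annotations={t.ref_id: t for t in trna_annotations},
        )
        rs.validate()
        return rs

    def __len__(self) -> int:
        return len(self.sequences)

    def ids(self) -> list[str]:
        return list(self.sequences)

    def get(self, ref_id: str) -> ReferenceSeq:
        return self.sequences[ref_id]

    def category_of(self, ref_id: str) -> str:
        return self.sequences[ref_id].category

    def by_category(self, category: str) -> list[ReferenceSeq]:
        return [s for s in self.sequences.values() if s.category == category]

    def family_of(self, ref_id: str) -> str:
        return self.trna_annotations[ref_id].family

    def validate(self) -> None:
        """Check the cross-reference invariants; raise ReferenceError on breach."""
        if not self.sequences:
            raise ReferenceError("no sequences")
        for rid, reg in self.mrna_regions.items():
            if rid not in self.sequences:
                raise ReferenceError(f"regions refer to unknown reference {rid!r}")
        for rid, ann in self.trna_annotations.items():
            if rid not in self.sequences:
                raise ReferenceError(f"tRNA annotation refers to unknown reference {rid!r}")
        for seq in self.sequences.values():
            if seq.category == "mRNA":
                reg = self.mrna_regions.get(seq.id)
                if reg is None:
                    raise ReferenceError(f"missing region annotation for mRNA {seq.id!r}")
                if reg.total != seq.length:
                    raise ReferenceError(
                        f"region sum {reg.total} ≠ length {seq.length} for {seq.id!r}"
                    )
                if reg.cds_len % 3 != 0:
                    warnings.warn(
                        f"CDS length {reg.cds_len} of {seq.id!r} is not divisible by 3; "
                        "the trailing partial codon is excluded from codon-level analyses",
                        stacklevel=2,
                    )
            elif seq.category == "tRNA":
                ann = self.trna_annotations.get(seq.id)
                if ann is None:
                    raise ReferenceError(f"missing tRNA annotation for {seq.id!r}")
                if len(ann.element_map) != seq.length:
                    raise ReferenceError(
                        f"element map of {seq.id!r} covers {len(ann.element_map)} positions, "
                        f"sequence has {seq.length}"
                    )


def load_references(fasta_path, regions_path, trna_path) -> ReferenceSet:
    """Load a ReferenceSet from FASTA plus the two annotation tables.

    FASTA headers carry the category as ``>id category=<mRNA|tRNA|rRNA|other>``.
    ``regions_path`` is a TSV with columns ref_id/utr5_len/cds_len/utr3_len;
    ``trna_path`` has ref_id/amino_acid/anticodon/elements where ``elements``
    is one code letter per position (see ELEMENT_TO_CODE).
    """
    sequences = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ReferenceError(f"duplicate reference id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        category = None
        for token in rec.description.split():
            if token.startswith("category="):
                category = token.split("=", 1)[1]
        if category is None:
            raise ReferenceError(f"FASTA header of {rec.id!r} lacks a category= tag")
        sequences.append(ReferenceSeq(rec.id, category, str(rec.seq)))
    if not sequences:
        raise ReferenceError(f"no sequences in {fasta_path}")

    regions = []
    rtab = pd.read_csv(regions_path, sep="\t", dtype={"ref_id": str})
    for col in ("ref_id", "utr5_len", "cds_len", "utr3_len"):
        if col not in rtab.columns:
            raise ReferenceError(f"{regions_path} lacks required column {col!r}")
    for row in rtab.itertuples(index=False):
        regions.append(
            MrnaRegions(row.ref_id, int(row.utr5_len), int(row.cds_len), int(row.utr3_len))
        )

    trnas = []
    ttab = pd.read_csv(trna_path, sep="\t", dtype=str)
    for col in ("ref_id", "amino_acid", "anticodon", "elements"):
        if col not in ttab.columns:
            raise ReferenceError(f"{trna_path} lacks required column {col!r}")
    for row in ttab.itertuples(index=False):
        try:
            emap = tuple(CODE_TO_ELEMENT[c] for c in row.elements)
        except KeyError as exc:
            raise ReferenceError(
                f"unknown element code {exc.args[0]!r} for {row.ref_id!r}"
            ) from None
        trnas.append(TrnaAnnotation(row.ref_id, row.amino_acid, row.anticodon, emap))

    return ReferenceSet.from_parts(sequences, regions, trnas)


def write_references(refset: ReferenceSet, out_dir) -> dict[str, Path]:
    """Write a ReferenceSet into ``out_dir``; round-trips through load_references."""
    refset.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "references.fasta",
        "regions": out / "regions.tsv",
        "trna": out / "trna.tsv",
    }
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=f"category={s.category}")
        for s in refset.sequences.values()
    ]
    SeqIO.write(records, str(paths["fasta"]), "fasta")

    pd.DataFrame(
        [
            {
                "ref_id": r.ref_id,
                "utr5_len": r.utr5_len,
                "cds_len": r.cds_len,
                "utr3_len": r.utr3_len,
            }
            for r in refset.mrna_regions.values()
        ],
        columns=["ref_id", "utr5_len", "cds_len", "utr3_len"],
    ).to_csv(paths["regions"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "ref_id": t.ref_id,
                "amino_acid": t.amino_acid,
                "anticodon": t.anticodon,
                "elements": "".join(ELEMENT_TO_CODE[e] for e in t.element_map),
            }
            for t in refset.trna_annotations.values()
        ],
        columns=["ref_id", "amino_acid", "anticodon", "elements"],
    ).to_csv(paths["trna"], sep="\t", index=False)
    return paths
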