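"""Exhaustive-equivalent read alignment and transition-class diagnostics.

Reads are placed on the sense strand of every reference at every offset and
all placements achieving the minimal Hamming distance (up to ``max_mm``
substitutions, default 2) are retained.  For speed the search is seeded with a
pigeonhole k-mer index: a read with at most two mismatches must carry at least
one of three disjoint exact 5-mers, so candidate diagonals are looked up
exactly and verified with vectorized comparisons.  Reads shorter than 15 nt or
containing N fall back to a full scan, so the hit set always equals the
brute-force definition.

The transition class of a placement is the cross-link diagnostic: d0 (perfect
match), d1TC (exactly one reference-T -> read-C substitution, the 4SU
signature), d1other, or d2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .references import ReferenceSet

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as int8 0..4; raise on anything else."""
    arr = _CODE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"read contains invalid characters: {bad}")
    return arr


class TransitionClass(str, Enum):
    D0 = "d0"
    D1TC = "d1TC"
    D1OTHER = "d1other"
    D2 = "d2"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Mismatch:
    ref_pos: int  # 1-based on the reference
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class Hit:
    ref_id: str
    start: int  # 1-based
    mismatches: tuple[Mismatch, ...]


@dataclass
class AlignedRead:
    read_id: str
    sequence: str
    hits: tuple[Hit, ...]
    copies: int = 1

    @property
    def mapped(self) -> bool:
        return len(self.hits) > 0

    @property
    def n_mismatch(self) -> int | None:
        return len(self.hits[0].mismatches) if self.hits else None

    @property
    def unique(self) -> bool:
        return len(self.hits) == 1

    @property
    def length(self) -> int:
        return len(self.sequence)


def hit_class(hit: Hit) -> TransitionClass:
    n = len(hit.mismatches)
    if n == 0:
        return TransitionClass.D0
    if n == 2:
        return TransitionClass.D2
    mm = hit.mismatches[0]
    if mm.ref_base == "T" and mm.read_base == "C":
        return TransitionClass.D1TC
    return TransitionClass.D1OTHER


def classify(aligned: AlignedRead) -> TransitionClass:
    """Transition class of an aligned read, computed on its first best hit."""
    if not aligned.mapped:
        return TransitionClass.UNMAPPED
    return hit_class(aligned.hits[0])


def class_ambiguous(aligned: AlignedRead) -> bool:
    """True when equally good placements disagree on the transition class."""
    if len(aligned.hits) <= 1:
        return False
    return len({hit_class(h) for h in aligned.hits}) > 1


class Aligner:
    """Sense-strand aligner over a ReferenceSet, exhaustive up to ``max_mm``."""

    SEED_K = 5

    def __init__(self, refset: ReferenceSet, max_mm: int = 2):
        if max_mm < 0:
            raise ValueError("max_mm must be >= 0")
        self.refset = refset
        self.max_mm = max_mm
        self._ids: list[str] = list(refset.sequences)
        self._seqs: list[str] = [refset.sequences[i].sequence for i in self._ids]
        self._arrs: list[np.ndarray] = [encode(s) for s in self._seqs]
        self._index: dict[str, list[tuple[int, int]]] = {}
        k = self.SEED_K
        for ridx, s in enumerate(self._seqs):
            for p in range(len(s) - k + 1):
                kmer = s[p : p + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((ridx, p))

    # -- candidate generation --------------------------------------------

    def _pigeonhole_candidates(self, seq: str) -> set[tuple[int, int]]:
        k = self.SEED_K
        L = len(seq)
        cand: set[tuple[int, int]] = set()
        for off in (0, k, 2 * k):
            for ridx, p in self._index.get(seq[off : off + k], ()):
                start0 = p - off
                if start0 >= 0 and start0 + L <= len(self._seqs[ridx]):
                    cand.add((ridx, start0))
        return cand

    def _exhaustive_candidates(self, arr: np.ndarray) -> list[tuple[int, int]]:
        L = len(arr)
        out = []
        read_has_n = (arr == _N_CODE).any()
        for ridx, rarr in enumerate(self._arrs):
            if len(rarr) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(rarr, L)
            neq = win != arr
            if read_has_n:
                neq = neq | (arr == _N_CODE)
            neq = neq | (win == _N_CODE)
            counts = neq.sum(axis=1)
            for s0 in np.nonzero(counts <= self.max_mm)[0]:
                out.append((ridx, int(s0)))
        return out

    # -- alignment --------------------------------------------------------

    def align(self, sequence: str, read_id: str = "read", copies: int = 1) -> AlignedRead:
        seq = sequence.upper()
        arr = encode(seq)
        L = len(seq)
        if L == 0:
            raise ValueError("empty read")
        if L >= 3 * self.SEED_K and "N" not in seq:
            candidates: Iterable[tuple[int, int]] = sorted(self._pigeonhole_candidates(seq))
        else:
            candidates = self._exhaustive_candidates(arr)

        found: list[tuple[int, int, int, np.ndarray]] = []
        best = self.max_mm
        for ridx, s0 in candidates:
            sub = self._arrs[ridx][s0 : s0 + L]
            mask = (sub != arr) | (sub == _N_CODE) | (arr == _N_CODE)
            nm = int(mask.sum())
            if nm <= self.max_mm:
                found.append((nm, ridx, s0, np.nonzero(mask)[0]))
                if nm < best:
                    best = nm
        if not found:
            return AlignedRead(read_id, seq, (), copies)
        nm_min = min(f[0] for f in found)
        hits = []
        for nm, ridx, s0, pos in found:
            if nm != nm_min:
                continue
            rseq = self._seqs[ridx]
            mms = tuple(
                Mismatch(int(s0 + o + 1), rseq[s0 + o], seq[o]) for o in pos
            )
            hits.append(Hit(self._ids[ridx], s0 + 1, mms))
        hits.sort(key=lambda h: (h.ref_id, h.start))
        return AlignedRead(read_id, seq, tuple(hits), copies)

    def align_many(self, reads: Iterable) -> list[AlignedRead]:
        """Align FastqRead / CollapsedRead tuples; copies are carried through."""
        out = []
        for r in reads:
            copies = r[2] if len(r) > 2 and isinstance(r[2], int) else 1
            out.append(self.align(r[1], read_id=r[0], copies=copies))
        return out


def align_read(sequence: str, refset: ReferenceSet, max_mm: int = 2,
               aligner: Aligner | None = None) -> AlignedRead:
    """One-shot convenience wrapper around :class:`Aligner`."""
    if aligner is None:
        aligner = Aligner(refset, max_mm=max_mm)
    return aligner.align(sequence)


ANALYSES = ("mrna", "trna", "rrna", "composition")
_RRNA_CLASSES = {TransitionClass.D0, TransitionClass.D1TC, TransitionClass.D1OTHER}
MIN_READ_LEN = 15  # global floor, the smallest length any analysis admits


def filter_for_analysis(reads: Sequence, analysis: str) -> list:
    """Apply the per-analysis transition-class and length filters.

    mrna/trna keep d1TC reads of >= 20 nt; rrna keeps d0/d1TC/d1other of
    >= 15 nt; composition keeps every mapped read of >= 15 nt.  Reads whose
    equally good placements disagree on class are excluded from the
    positional (mrna/trna/rrna) analyses but kept for composition.
    Elements must expose transition_class / ambiguous / length attributes.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    out = []
    for r in reads:
        cls = r.transition_class
        if cls == TransitionClass.UNMAPPED or r.length < MIN_READ_LEN:
            continue
        if analysis in ("mrna", "trna"):
            if cls == TransitionClass.D1TC and not r.ambiguous and r.length >= 20:
                out.append(r)
        elif analysis == "rrna":
            if cls in _RRNA_CLASSES and not r.ambiguous:
                out.append(r)
        else:  # composition
            out.append(r)
    return out


# -- SAM interchange -------------------------------------------------------

def write_sam(aligned_reads: Sequence[AlignedRead], refset: ReferenceSet, path) -> None:
    """Write alignments as SAM (primary + secondary records, NM tags)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": rid, "LN": refset.sequences[rid].length} for rid in refset.sequences
        ],
    }
    tid = {rid: i for i, rid in enumerate(refset.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for ar in aligned_reads:
            if not ar.mapped:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = ar.read_id
                a.query_sequence = ar.sequence
                a.is_unmapped = True
                a.set_tag("XC", ar.copies)
                fh.write(a)
                continue
            for i, hit in enumerate(ar.hits):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = ar.read_id
                a.query_sequence = ar.sequence
                a.reference_id = tid[hit.ref_id]
                a.reference_start = hit.start - 1
                a.cigartuples = [(0, len(ar.sequence))]
                a.mapping_quality = 255
                a.is_secondary = i > 0
                a.set_tag("NM", len(hit.mismatches))
                a.set_tag("XC", ar.copies)
                fh.write(a)


def read_sam(path, refset: ReferenceSet, max_mm: int = 2) -> list[AlignedRead]:
    """Load pre-aligned sense-strand reads from SAM into AlignedRead records.

    Mismatches are recomputed against the reference sequences, so the input
    only needs correct placements.  Reverse-strand or gapped records are
    rejected; placements with more than ``max_mm`` substitutions are dropped,
    and only minimal-mismatch placements per read are retained.
    """
    import pysam

    grouped: dict[str, list] = {}
    copies: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                grouped.setdefault(rec.query_name, [])
                copies[rec.query_name] = int(rec.get_tag("XC")) if rec.has_tag("XC") else 1
                continue
            if rec.is_reverse:
                raise ValueError(
                    f"read {rec.query_name!r}: reverse-strand records are not supported"
                )
            if any(op != 0 for op, _ in rec.cigartuples or []):
                raise ValueError(
                    f"read {rec.query_name!r}: only ungapped (all-match CIGAR) records "
                    "are supported"
                )
            grouped.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start, rec.query_sequence)
            )
            copies[rec.query_name] = int(rec.get_tag("XC")) if rec.has_tag("XC") else 1

    out = []
    for qname, places in grouped.items():
        hits = []
        seq = None
        for ref_id, start0, qseq in places:
            if qseq is not None:
                seq = qseq.upper()
            if seq is None:
                continue
            ref = refset.sequences[ref_id].sequence
            if start0 + len(seq) > len(ref):
                raise ValueError(f"read {qname!r} extends past reference {ref_id!r}")
            mms = tuple(
                Mismatch(start0 + o + 1, ref[start0 + o], seq[o])
                for o in range(len(seq))
                if ref[start0 + o] != seq[o]
                or ref[start0 + o] == "N"
                or seq[o] == "N"
            )
            if len(mms) <= max_mm:
                hits.append(Hit(ref_id, start0 + 1, mms))
        if hits:
            nm_min = min(len(h.mismatches) for h in hits)
            hits = sorted(
                (h for h in hits if len(h.mismatches) == nm_min),
                key=lambda h: (h.ref_id, h.start),
            )
        out.append(AlignedRead(qname, seq or "", tuple(hits), copies.get(qname, 1)))
    return out
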