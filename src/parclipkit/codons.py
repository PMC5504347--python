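"""In-frame codon-run census and reporter spacer construction.

A maximal run of length k (k consecutive identical in-frame codons, or
consecutive members of a codon set) is counted once at k — a (AAA)_3 run is
one run of 3, not two overlapping runs of 2.  Frame is CDS frame 0; a
trailing partial codon is trimmed with a warning.  The alternative
sliding-window convention (a k-run contributes k-j+1 windows at each j) is
available via ``mode="sliding"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGT")


class Run(NamedTuple):
    codon_index: int  # 0-based index of the first codon of the run
    length: int  # number of consecutive codons


class SetRun(NamedTuple):
    codon_index: int
    length: int
    composition: dict  # codon -> count within the run


def _codons_of(sequence: str) -> list[str]:
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"CDS contains invalid characters: {sorted(bad)}")
    trailing = len(seq) % 3
    if trailing:
        warnings.warn(
            f"CDS length {len(seq)} not divisible by 3; trailing {trailing} nt trimmed",
            stacklevel=3,
        )
        seq = seq[: len(seq) - trailing]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _normalize_codon(codon: str) -> str:
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or set(c) - _ALPHABET:
        raise ValueError(f"invalid codon {codon!r}")
    return c


def codon_runs(sequence: str, codon: str) -> list[Run]:
    """Maximal in-frame runs of one codon (including runs of length 1).

    Codons may be given in RNA letters (U is normalized to T).
    """
    codon = _normalize_codon(codon)
    runs: list[Run] = []
    current = 0
    for i, c in enumerate(_codons_of(sequence)):
        if c == codon:
            current += 1
        elif current:
            runs.append(Run(i - current, current))
            current = 0
    if current:
        n = len(sequence) // 3
        runs.append(Run(n - current, current))
    return runs


def codon_set_runs(sequence: str, codons: Iterable[str]) -> list[SetRun]:
    """Maximal in-frame runs where any member of ``codons`` extends the run."""
    cset = {_normalize_codon(c) for c in codons}
    if not cset:
        raise ValueError("empty codon set")
    runs: list[SetRun] = []
    current: list[str] = []
    start = 0
    for i, c in enumerate(_codons_of(sequence)):
        if c in cset:
            if not current:
                start = i
            current.append(c)
        elif current:
            comp = {k: current.count(k) for k in sorted(set(current))}
            runs.append(SetRun(start, len(current), comp))
            current = []
    if current:
        comp = {k: current.count(k) for k in sorted(set(current))}
        runs.append(SetRun(start, len(current), comp))
    return runs


@dataclass
class RunCensus:
    """Histogram of maximal run lengths (k >= min_k) across a CDS collection."""

    codon: str | tuple
    histogram: dict  # k -> number of runs
    max_k: int  # 0 when no qualifying run exists
    runs: list  # (cds_id, codon_index, k)
    mode: str = "maximal"


def census(
    cds_collection: Mapping[str, str],
    codon,
    min_k: int = 2,
    mode: str = "maximal",
) -> RunCensus:
    """Aggregate codon-run histogram over a collection of CDS sequences.

    ``codon`` may be a single codon or an iterable of codons (a set run).
    ``mode="maximal"`` counts each maximal run once at its full length;
    ``mode="sliding"`` counts, for every k, each window of k consecutive
    target codons (a maximal run of length k contributes k-j+1 windows at j).
    """
    if mode not in ("maximal", "sliding"):
        raise ValueError(f"unknown census mode {mode!r}")
    single = isinstance(codon, str)
    histogram: dict[int, int] = {}
    all_runs = []
    max_k = 0
    for cds_id, seq in cds_collection.items():
        runs = codon_runs(seq, codon) if single else codon_set_runs(seq, codon)
        for r in runs:
            k = r.length
            if k >= min_k:
                all_runs.append((cds_id, r.codon_index, k))
                max_k = max(max_k, k)
                if mode == "maximal":
                    histogram[k] = histogram.get(k, 0) + 1
                else:
                    for j in range(min_k, k + 1):
                        histogram[j] = histogram.get(j, 0) + (k - j + 1)
    return RunCensus(
        codon=codon if single else tuple(sorted({c.upper() for c in codon})),
        histogram=dict(sorted(histogram.items())),
        max_k=max_k,
        runs=all_runs,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# reporter spacers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacerSpec:
    """A stall-reporter spacer: a codon pattern repeated to 12 codons."""

    label: str
    codons: tuple[str, ...]
    repeat: int
    expected_peptide: str


#: the reporter spacers: a neutral Thr-Ser control, poly-lysine via AAA or
#: AAG, and poly-arginine via AGA
SPACERS = {
    "ThrSer6": SpacerSpec("ThrSer6", ("ACT", "AGC"), 6, "TS" * 6),
    "AAA12": SpacerSpec("AAA12", ("AAA",), 12, "K" * 12),
    "AAG12": SpacerSpec("AAG12", ("AAG",), 12, "K" * 12),
    "AGA12": SpacerSpec("AGA12", ("AGA",), 12, "R" * 12),
}


def build_spacer(spec: SpacerSpec) -> str:
    """Concatenate the codon pattern and verify its conceptual translation."""
    for c in spec.codons:
        if len(c) != 3 or set(c.upper()) - _ALPHABET:
            raise ValueError(f"invalid codon {c!r} in spacer {spec.label!r}")
    seq = "".join(spec.codons).upper() * spec.repeat
    peptide = str(Seq(seq).translate())
    if peptide != spec.expected_peptide:
        raise ValueError(
            f"spacer {spec.label!r} translates to {peptide}, expected {spec.expected_peptide}"
        )
    return seq


def write_spacer_fasta(specs: Sequence[SpacerSpec], path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(build_spacer(s)), id=s.label, description=f"peptide={s.expected_peptide}")
        for s in specs
    ]
    SeqIO.write(records, str(path), "fasta")
    return path
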