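"""Seeded simulator for 4SU cross-linking (PAR-CLIP) read libraries.

The generator emulates the statistical read signature of a PAR-CLIP library
over a transcript-space reference universe: reads drawn from tRNA/mRNA/rRNA
classes with configurable weights (default 4:2:1), a planted cross-link
contact uridine per read that is emitted as C with probability ``p_conv``,
uniform substitution sequencing errors, and per-isoacceptor enrichment
factors on top of a shared tRNA abundance vector.  A matching background
library models total-cellular tRNA sequencing (hydrolysis fragments covering
the 5' or 3' half of each gene, no cross-link conversions, no enrichment).

Every read is logged in a ground-truth ledger (:class:`SimTruth`) so that
recovery of the planted parameters can be asserted downstream.  All
randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reads import FastqRead
from .references import (
    MrnaRegions,
    ReferenceSeq,
    ReferenceSet,
    TrnaAnnotation,
)

CLASS_ORDER = ("tRNA", "mRNA", "rRNA")
_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the study conditions."""

    seed: int = 0
    n_reads_parclip: int = 200_000
    n_reads_background: int = 200_000
    #: read mixture over RNA classes, ~4:2:1
    class_weights: dict = field(
        default_factory=lambda: {"tRNA": 4 / 7, "mRNA": 2 / 7, "rRNA": 1 / 7}
    )
    #: per-gene sampling probabilities; None -> geometric decay over the
    #: reference's tRNA genes (a skewed, realistic abundance spectrum)
    trna_abundance: dict | None = None
    #: isoacceptor-family fold enrichment in the PAR-CLIP library
    enrichment: dict = field(default_factory=lambda: {"Lys-UUU": 10.0, "Lys-CUU": 2.0})
    #: probability that a read's contact uridine is read out as C
    p_conv: float = 0.7
    #: per-base substitution sequencing-error probability
    err_rate: float = 0.001
    read_len_range: tuple[int, int] = (20, 40)
    #: tRNA PAR-CLIP reads cover the 5' end (32 nt) of the gene body
    trna_read_len: int = 32
    trna_start_jitter: int = 0
    mrna_region_weights: tuple[float, float, float] = (0.1, 0.8, 0.1)
    mrna_abundance: dict | None = None  # None -> uniform over mRNAs
    #: per-species [(center, sd), ...] read-start placement; None -> one
    #: central hotspot per species
    rrna_hotspots: dict | None = None
    rrna_species_weights: dict | None = None  # None -> uniform over species

    def validate(self) -> None:
        weights = np.array([self.class_weights.get(c, 0.0) for c in CLASS_ORDER])
        if (weights < 0).any() or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class_weights must be nonnegative and sum to 1")
        if not 0 <= self.p_conv <= 1:
            raise ValueError("p_conv must be in [0, 1]")
        if not 0 <= self.err_rate <= 1:
            raise ValueError("err_rate must be in [0, 1]")
        if any(f <= 0 for f in self.enrichment.values()):
            raise ValueError("enrichment factors must be > 0")
        lo, hi = self.read_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid read_len_range")
        rw = np.asarray(self.mrna_region_weights, dtype=float)
        if (rw < 0).any() or not math.isclose(rw.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("mrna_region_weights must sum to 1")


@dataclass
class SimTruth:
    """Per-read ground truth plus per-library realized summaries."""

    table: pd.DataFrame
    class_counts: dict
    effective_weights: dict

    def __len__(self) -> int:
        return len(self.table)


TRUTH_COLUMNS = [
    "read_id",
    "ref_id",
    "category",
    "start",
    "end",
    "contact_pos",
    "converted",
    "error_positions",
    "truncated",
]


def _resolve_abundance(refset: ReferenceSet, config: SimConfig) -> tuple[list[str], np.ndarray]:
    genes = [s.id for s in refset.by_category("tRNA")]
    if not genes:
        raise ValueError("reference set has no tRNA genes")
    if config.trna_abundance is None:
        w = np.array([0.85**i for i in range(len(genes))])
    else:
        missing = set(config.trna_abundance) - set(genes)
        if missing:
            raise ValueError(f"trna_abundance names unknown genes: {sorted(missing)}")
        w = np.array([config.trna_abundance.get(g, 0.0) for g in genes], dtype=float)
        if w.sum() <= 0:
            raise ValueError("trna_abundance sums to zero")
    return genes, w / w.sum()


def _t_positions(seq: str) -> np.ndarray:
    return np.array([i + 1 for i, b in enumerate(seq) if b == "T"], dtype=np.int64)


def _apply_errors(rng, seq_list: list[str], n_err: int, protect: int | None) -> list[int]:
    """Substitute n_err random bases in place (0-based protect index excluded)."""
    L = len(seq_list)
    candidates = [i for i in range(L) if i != protect]
    if n_err >= len(candidates):
        picks = candidates
    else:
        picks = list(rng.choice(len(candidates), size=n_err, replace=False))
        picks = [candidates[i] for i in picks]
    out = []
    for i in sorted(picks):
        alt = _ALT[seq_list[i]]
        seq_list[i] = alt[int(rng.integers(3))]
        out.append(i)
    return out


def simulate_parclip(refset: ReferenceSet, config: SimConfig) -> tuple[list[FastqRead], SimTruth]:
    """Generate the cross-linked library and its ground-truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reads_parclip

    weights = np.array([config.class_weights.get(c, 0.0) for c in CLASS_ORDER])
    for ci, cname in enumerate(CLASS_ORDER):
        if weights[ci] > 0 and not refset.by_category(cname):
            raise ValueError(f"class {cname} has weight > 0 but no references")

    genes, abundance = _resolve_abundance(refset, config)
    fams = [refset.trna_annotations[g].family for g in genes]
    enr = np.array([config.enrichment.get(f, 1.0) for f in fams])
    eff = abundance * enr
    eff = eff / eff.sum()

    mrnas = [s.id for s in refset.by_category("mRNA")]
    if config.mrna_abundance is None:
        mprobs = np.full(len(mrnas), 1.0 / len(mrnas)) if mrnas else np.array([])
    else:
        mprobs = np.array([config.mrna_abundance.get(m, 0.0) for m in mrnas], dtype=float)
        mprobs = mprobs / mprobs.sum()

    species = [s.id for s in refset.by_category("rRNA")]
    hotspots = config.rrna_hotspots
    if hotspots is None:
        hotspots = {
            sid: [(refset.sequences[sid].length * 2 / 3, max(3.0, refset.sequences[sid].length / 40))]
            for sid in species
        }
    if config.rrna_species_weights is None:
        sprobs = np.full(len(species), 1.0 / len(species)) if species else np.array([])
    else:
        sprobs = np.array(
            [config.rrna_species_weights.get(s, 0.0) for s in species], dtype=float
        )
        sprobs = sprobs / sprobs.sum()

    # per-gene contact candidates: D-loop Ts are preferred (the paper's
    # cross-link signature), any footprint T is the fallback
    dloop_ts = {}
    for g in genes:
        ann = refset.trna_annotations[g]
        seq = refset.sequences[g].sequence
        dloop_ts[g] = np.array(
            [p for p in ann.positions_of("D-loop") if seq[p - 1] == "T"], dtype=np.int64
        )
    all_ts = {rid: _t_positions(s.sequence) for rid, s in refset.sequences.items()}

    # vectorized structural draws, in fixed order for determinism
    classes = rng.choice(len(CLASS_ORDER), size=n, p=weights)
    idx_t = np.nonzero(classes == 0)[0]
    idx_m = np.nonzero(classes == 1)[0]
    idx_r = np.nonzero(classes == 2)[0]

    gene_pick = rng.choice(len(genes), size=len(idx_t), p=eff) if len(idx_t) else np.array([], int)
    jitter = (
        rng.integers(0, config.trna_start_jitter + 1, size=len(idx_t))
        if config.trna_start_jitter > 0
        else np.zeros(len(idx_t), dtype=np.int64)
    )

    lo, hi = config.read_len_range
    m_pick = rng.choice(len(mrnas), size=len(idx_m), p=mprobs) if len(idx_m) else np.array([], int)
    m_len = rng.integers(lo, hi + 1, size=len(idx_m))
    m_region = rng.choice(3, size=len(idx_m), p=np.asarray(config.mrna_region_weights))
    m_u = rng.random(len(idx_m))

    r_pick = rng.choice(len(species), size=len(idx_r), p=sprobs) if len(idx_r) else np.array([], int)
    r_len = rng.integers(lo, hi + 1, size=len(idx_r))
    r_hot_u = rng.random(len(idx_r))
    r_z = rng.standard_normal(len(idx_r))

    conv_flag = rng.random(n) < config.p_conv

    ref_arr = np.empty(n, dtype=object)
    start_arr = np.zeros(n, dtype=np.int64)
    len_arr = np.zeros(n, dtype=np.int64)
    trunc_arr = np.zeros(n, dtype=bool)

    for j, i in enumerate(idx_t):
        g = genes[gene_pick[j]]
        glen = refset.sequences[g].length
        start = 1 + int(jitter[j])
        L = config.trna_read_len
        if start + L - 1 > glen:
            L = glen - start + 1
            trunc_arr[i] = True
        ref_arr[i], start_arr[i], len_arr[i] = g, start, L

    for j, i in enumerate(idx_m):
        m = mrnas[m_pick[j]]
        reg = refset.mrna_regions[m]
        tlen = refset.sequences[m].length
        L = int(m_len[j])
        if L > tlen:
            L, trunc_arr[i] = tlen, True
        bounds = (
            (1, reg.utr5_len),
            (reg.cds_start, reg.cds_end),
            (reg.cds_end + 1, tlen),
        )[int(m_region[j])]
        span = bounds[1] - bounds[0] + 1
        anchor = bounds[0] + int(m_u[j] * span) if span > 0 else 1 + int(m_u[j] * tlen)
        start = min(max(anchor - L // 2, 1), tlen - L + 1)
        ref_arr[i], start_arr[i], len_arr[i] = m, start, L

    for j, i in enumerate(idx_r):
        sid = species[r_pick[j]]
        slen = refset.sequences[sid].length
        L = int(r_len[j])
        if L > slen:
            L, trunc_arr[i] = slen, True
        spots = hotspots.get(sid) or [(slen / 2, max(3.0, slen / 40))]
        center, sd = spots[int(r_hot_u[j] * len(spots))]
        start = int(round(center - L / 2 + r_z[j] * sd))
        start = min(max(start, 1), slen - L + 1)
        ref_arr[i], start_arr[i], len_arr[i] = sid, start, L

    n_err = rng.binomial(len_arr, config.err_rate)

    reads: list[FastqRead] = []
    rows: list[tuple] = []
    for i in range(n):
        rid = ref_arr[i]
        start, L = int(start_arr[i]), int(len_arr[i])
        end = start + L - 1
        refseq = refset.sequences[rid].sequence
        category = refset.sequences[rid].category

        if category == "tRNA":
            cand = dloop_ts[rid]
            cand = cand[(cand >= start) & (cand <= end)]
            if len(cand) == 0:
                cand = all_ts[rid]
                cand = cand[(cand >= start) & (cand <= end)]
        else:
            cand = all_ts[rid]
            cand = cand[(cand >= start) & (cand <= end)]
        contact = int(cand[rng.integers(len(cand))]) if len(cand) else None

        converted = bool(conv_flag[i]) and contact is not None
        seq_list = list(refseq[start - 1 : end])
        if converted:
            seq_list[contact - start] = "C"
        err_local: list[int] = []
        if n_err[i] > 0:
            protect = contact - start if converted else None
            err_local = _apply_errors(rng, seq_list, int(n_err[i]), protect)
        seq = "".join(seq_list)
        read_id = f"par{i:07d}"
        reads.append(FastqRead(read_id, seq, "I" * L))
        rows.append(
            (
                read_id,
                rid,
                category,
                start,
                end,
                contact,
                converted,
                ",".join(str(start + e) for e in err_local),
                bool(trunc_arr[i]),
            )
        )

    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    table["contact_pos"] = table["contact_pos"].astype("Int64")
    class_counts = table["category"].value_counts().to_dict()
    truth = SimTruth(table, class_counts, dict(zip(genes, eff)))
    return reads, truth


def simulate_background(refset: ReferenceSet, config: SimConfig) -> tuple[list[FastqRead], SimTruth]:
    """Generate the total-cellular tRNA background library (no enrichment).

    Reads are hydrolysis-style fragments covering either the 5' or the 3'
    half of the gene body (fair coin), sampled proportionally to the shared
    abundance vector, with sequencing errors but no cross-link conversions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_reads_background
    genes, abundance = _resolve_abundance(refset, config)

    gene_pick = rng.choice(len(genes), size=n, p=abundance)
    half_pick = rng.integers(0, 2, size=n)

    start_arr = np.zeros(n, dtype=np.int64)
    len_arr = np.zeros(n, dtype=np.int64)
    for i in range(n):
        glen = refset.sequences[genes[gene_pick[i]]].length
        h = glen - glen // 2  # 5' half length (ceil)
        if half_pick[i] == 0:
            start_arr[i], len_arr[i] = 1, h
        else:
            start_arr[i], len_arr[i] = h + 1, glen - h
    n_err = rng.binomial(len_arr, config.err_rate)

    reads: list[FastqRead] = []
    rows: list[tuple] = []
    for i in range(n):
        g = genes[gene_pick[i]]
        start, L = int(start_arr[i]), int(len_arr[i])
        end = start + L - 1
        seq_list = list(refset.sequences[g].sequence[start - 1 : end])
        err_local: list[int] = []
        if n_err[i] > 0:
            err_local = _apply_errors(rng, seq_list, int(n_err[i]), None)
        read_id = f"bg{i:07d}"
        reads.append(FastqRead(read_id, "".join(seq_list), "I" * L))
        rows.append(
            (
                read_id,
                g,
                "tRNA",
                start,
                end,
                None,
                False,
                ",".join(str(start + e) for e in err_local),
                False,
            )
        )

    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    table["contact_pos"] = table["contact_pos"].astype("Int64")
    truth = SimTruth(table, {"tRNA": n}, dict(zip(genes, abundance)))
    return reads, truth


# -- truth ledger I/O ------------------------------------------------------

def write_truth(truth: SimTruth, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#class_counts\t" + json.dumps(truth.class_counts) + "\n")
        fh.write("#effective_weights\t" + json.dumps(truth.effective_weights) + "\n")
        tab = truth.table.copy()
        tab["converted"] = tab["converted"].astype(int)
        tab["truncated"] = tab["truncated"].astype(int)
        tab.to_csv(fh, sep="\t", index=False)
    return path


def read_truth(path) -> SimTruth:
    path = Path(path)
    class_counts: dict = {}
    effective_weights: dict = {}
    header_lines = 0
    with open(path) as fh:
        lines = fh.readlines()
    ncols = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            header_lines += 1
            try:
                key, payload = line[1:].rstrip("\n").split("\t", 1)
                if key == "class_counts":
                    class_counts = json.loads(payload)
                elif key == "effective_weights":
                    effective_weights = json.loads(payload)
            except (ValueError, json.JSONDecodeError):
                raise ValueError(f"{path}: malformed metadata at line {lineno}") from None
            continue
        nfields = line.rstrip("\n").count("\t") + 1
        if ncols is None:
            ncols = nfields
            if line.rstrip("\n").split("\t") != TRUTH_COLUMNS:
                raise ValueError(f"{path}: unexpected header at line {lineno}")
        elif nfields != ncols and line.strip():
            raise ValueError(
                f"{path}: line {lineno}: expected {ncols} fields, found {nfields}"
            )
    table = pd.read_csv(
        path, sep="\t", comment="#", dtype={"read_id": str, "error_positions": str}
    )
    table["contact_pos"] = table["contact_pos"].astype("Int64")
    table["converted"] = table["converted"].astype(bool)
    table["truncated"] = table["truncated"].astype(bool)
    table["error_positions"] = table["error_positions"].fillna("")
    return SimTruth(table, class_counts, effective_weights)


def validate_truth(reads, truth: SimTruth) -> None:
    """Enforce the one-to-one correspondence between reads and truth rows."""
    if len(reads) != len(truth.table):
        raise ValueError(
            f"truth row count {len(truth.table)} ≠ read count {len(reads)}"
        )


# -- synthetic reference universe -----------------------------------------

#: cloverleaf element codes of the 76-nt tRNA template, one per position
TRNA_TEMPLATE_ELEMENTS = (
    "A" * 7  # acceptor stem, 5' side (1-7)
    + "O" * 2  # connectors 8-9
    + "D" * 4  # D-stem 10-13
    + "d" * 8  # D-loop 14-21
    + "D" * 4  # D-stem 22-25
    + "O"  # 26
    + "C" * 5  # anticodon stem 27-31
    + "c" * 7  # anticodon loop 32-38
    + "C" * 5  # anticodon stem 39-43
    + "V" * 5  # variable loop 44-48
    + "T" * 5  # T-stem 49-53
    + "t" * 7  # T-loop 54-60
    + "T" * 5  # T-stem 61-65
    + "Z" * 11  # acceptor stem 3' side + NCCA (66-76)
)

#: 1-based conserved positions of the template.  The D-loop carries a single
#: uridine (the canonical position-16 dihydrouridine site) so that the
#: cross-link contact, and hence the planted conversion probability, is
#: concentrated on one identifiable position per gene.
_TRNA_CONSERVED = {8: "T", 14: "A", 16: "T", 18: "G", 19: "G", 21: "A",
                   33: "T", 53: "G", 54: "T", 55: "T", 56: "C", 58: "A",
                   61: "C", 74: "C", 75: "C", 76: "A"}
_DLOOP_RANGE = range(14, 22)

TRNA_FAMILIES = [
    ("Lys", "UUU", 2),
    ("Lys", "CUU", 2),
    ("Arg", "UCU", 1),
    ("Arg", "CCG", 1),
    ("Glu", "CUC", 1),
    ("Glu", "UUC", 1),
    ("Gly", "GCC", 1),
    ("Gly", "CCC", 1),
    ("Asp", "GUC", 1),
    ("Val", "AAC", 1),
    ("Ala", "AGC", 1),
    ("Leu", "CAA", 1),
    ("Ser", "GCU", 1),
    ("Pro", "AGG", 1),
    ("Thr", "AGU", 1),
    ("Ile", "AAU", 1),
    ("Phe", "GAA", 1),
    ("His", "GUG", 1),
]

_MRNA_SHAPES = [
    (90, 600, 210),
    (60, 450, 150),
    (120, 900, 240),
    (75, 720, 180),
    (100, 510, 160),
    (80, 630, 190),
]

_RRNA_LENGTHS = {"5S": 121, "5.8S": 157, "18S": 1869, "28S": 2000}

#: read-start placement emulating the observed rRNA contact regions
DEFAULT_RRNA_HOTSPOTS = {
    "5S": [(108.0, 4.0)],
    "18S": [(697.0, 5.0), (762.0, 6.0)],
    "28S": [(1200.0, 8.0)],
    "5.8S": [(80.0, 5.0)],
}
DEFAULT_RRNA_SPECIES_WEIGHTS = {"5S": 0.4, "18S": 0.4, "5.8S": 0.1, "28S": 0.1}


def synthetic_references(seed: int = 2024) -> ReferenceSet:
    """Build the desk-scale reference universe the simulator runs against.

    20 tRNA genes over 18 isoacceptor families (Lys-UUU and Lys-CUU carry two
    gene copies each), 6 mRNAs with realistic region proportions, 4 rRNA
    species and one 'other' RNA.  Gene bodies are random apart from the
    conserved template positions, so reads place uniquely with overwhelming
    probability.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(length, alphabet="ACGT"):
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))

    seqs: list[ReferenceSeq] = []
    trnas: list[TrnaAnnotation] = []
    emap = tuple(
        {
            "A": "acceptor-5p", "D": "D-stem", "d": "D-loop", "C": "anticodon-stem",
            "c": "anticodon-loop", "V": "variable", "T": "T-stem", "t": "T-loop",
            "Z": "acceptor-3p", "O": "other",
        }[ch]
        for ch in TRNA_TEMPLATE_ELEMENTS
    )
    for aa, anticodon, ncopies in TRNA_FAMILIES:
        for copy in range(1, ncopies + 1):
            gid = f"tRNA-{aa}-{anticodon}-{copy}"
            body = []
            for pos in range(1, 77):
                if pos in _TRNA_CONSERVED:
                    body.append(_TRNA_CONSERVED[pos])
                elif 34 <= pos <= 36:
                    body.append(anticodon[pos - 34].replace("U", "T"))
                elif pos in _DLOOP_RANGE:
                    body.append(rand_seq(1, "ACG"))  # keep D16 the only D-loop U
                else:
                    body.append(rand_seq(1))
            seqs.append(ReferenceSeq(gid, "tRNA", "".join(body)))
            trnas.append(TrnaAnnotation(gid, aa, anticodon, emap))

    regions: list[MrnaRegions] = []
    for i, (u5, cds, u3) in enumerate(_MRNA_SHAPES, start=1):
        mid = f"mRNA-{i:02d}"
        seq = rand_seq(u5) + "ATG" + rand_seq(cds - 6) + "TAA" + rand_seq(u3)
        seqs.append(ReferenceSeq(mid, "mRNA", seq))
        regions.append(MrnaRegions(mid, u5, cds, u3))

    for sid, length in _RRNA_LENGTHS.items():
        seqs.append(ReferenceSeq(sid, "rRNA", rand_seq(length)))

    seqs.append(ReferenceSeq("snoRNA-1", "other", rand_seq(150)))
    return ReferenceSet.from_parts(seqs, regions, trnas)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """SimConfig wired for :func:`synthetic_references` (hotspots, weights)."""
    cfg = SimConfig(
        seed=seed,
        rrna_hotspots=dict(DEFAULT_RRNA_HOTSPOTS),
        rrna_species_weights=dict(DEFAULT_RRNA_SPECIES_WEIGHTS),
    )
    return replace(cfg, **overrides)
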