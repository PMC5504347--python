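import numpy as np
import pytest

from parclipkit.references import (
    MrnaRegions,
    ReferenceSeq,
    ReferenceSet,
    TrnaAnnotation,
)
from parclipkit.simulate import TRNA_TEMPLATE_ELEMENTS, synthetic_references

_CODE_TO_ELEMENT = {
    "A": "acceptor-5p",
    "D": "D-stem",
    "d": "D-loop",
    "C": "anticodon-stem",
    "c": "anticodon-loop",
    "V": "variable",
    "T": "T-stem",
    "t": "T-loop",
    "Z": "acceptor-3p",
    "O": "other",
}

TEMPLATE_ELEMENT_MAP = tuple(_CODE_TO_ELEMENT[c] for c in TRNA_TEMPLATE_ELEMENTS)


def random_refseq(rng, rid, category, length, alphabet="ACGT"):
    seq = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
    return ReferenceSeq(rid, category, seq)


@pytest.fixture(scope="session")
def synth_refs():
    """The desk-scale synthetic universe used across simulation tests."""
    return synthetic_references(seed=7)


@pytest.fixture()
def toy_refs():
    """A tiny handcrafted universe: 1 mRNA (10/60/20), 2 tRNAs, 1 rRNA, 1 other."""
    rng = np.random.default_rng(42)
    mrna = random_refseq(rng, "tx1", "mRNA", 90)
    trna_a = random_refseq(rng, "tRNA-Gly-GCC-1", "tRNA", 76)
    trna_b = random_refseq(rng, "tRNA-Lys-UUU-1", "tRNA", 76)
    rrna = random_refseq(rng, "5S", "rRNA", 121)
    other = random_refseq(rng, "misc1", "other", 60)
    return ReferenceSet.from_parts(
        [mrna, trna_a, trna_b, rrna, other],
        [MrnaRegions("tx1", 10, 60, 20)],
        [
            TrnaAnnotation("tRNA-Gly-GCC-1", "Gly", "GCC", TEMPLATE_ELEMENT_MAP),
            TrnaAnnotation("tRNA-Lys-UUU-1", "Lys", "UUU", TEMPLATE_ELEMENT_MAP),
        ],
    )
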