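import numpy as np
import pytest

from parclipkit.align import (
    AlignedRead,
    Aligner,
    Hit,
    Mismatch,
    TransitionClass,
    align_read,
    class_ambiguous,
    classify,
    filter_for_analysis,
    read_sam,
    write_sam,
)
from parclipkit.annotate import AnnotatedRead
from parclipkit.reads import CollapsedRead, FastqRead, collapse_duplicates

from _oracles import brute_force_align


def hitset(aligned):
    return {(h.ref_id, h.start, len(h.mismatches)) for h in aligned.hits}


class TestAlignRead:
    def test_exact_substring_single_hit(self, toy_refs):
        ref = toy_refs.get("tx1").sequence
        read = ref[20:45]
        ar = align_read(read, toy_refs)
        assert ar.unique and ar.n_mismatch == 0
        assert ar.hits[0] == Hit("tx1", 21, ())

    def test_verbatim_in_two_references_not_unique(self):
        from parclipkit.references import ReferenceSeq, ReferenceSet

        shared = "ACGTACGTACGTACGTACGTACGT"
        refs = ReferenceSet.from_parts(
            [
                ReferenceSeq("r1", "other", "GG" + shared + "TT"),
                ReferenceSeq("r2", "other", "AA" + shared + "CC"),
            ]
        )
        ar = align_read(shared, refs)
        assert not ar.unique and len(ar.hits) == 2
        assert {h.ref_id for h in ar.hits} == {"r1", "r2"}

    def test_three_mismatches_unmapped(self, toy_refs):
        ref = toy_refs.get("tx1").sequence
        read = list(ref[10:35])
        for i in (3, 11, 19):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        ar = align_read("".join(read), toy_refs)
        assert not ar.mapped
        assert classify(ar) == TransitionClass.UNMAPPED

    def test_mismatch_records_positions_and_bases(self, toy_refs):
        ref = toy_refs.get("5S").sequence
        read = list(ref[50:80])
        orig = read[7]
        read[7] = "A" if orig != "A" else "G"
        ar = align_read("".join(read), toy_refs)
        assert ar.hits[0].mismatches == (Mismatch(58, orig, read[7]),)

    def test_n_counts_as_mismatch_and_never_matches(self, toy_refs):
        ref = toy_refs.get("tx1").sequence
        read = ref[5:30].replace(ref[10], "N", 1)  # may replace earlier same base
        ar = align_read(read, toy_refs)
        assert ar.mapped and ar.n_mismatch == 1

    def test_invalid_character_rejected(self, toy_refs):
        with pytest.raises(ValueError, match="invalid characters"):
            align_read("ACGTXACGTACGTACG", toy_refs)

    def test_oracle_equivalence_random_panel(self, toy_refs):
        """Pigeonhole-seeded alignment equals the exhaustive Hamming oracle."""
        rng = np.random.default_rng(5)
        refs = {rid: s.sequence for rid, s in toy_refs.sequences.items()}
        aligner = Aligner(toy_refs)
        ids = list(refs)
        for _ in range(150):
            if rng.random() < 0.7:
                rid = ids[rng.integers(len(ids))]
                ref = refs[rid]
                L = int(rng.integers(15, min(41, len(ref) + 1)))
                s0 = int(rng.integers(0, len(ref) - L + 1))
                read = list(ref[s0 : s0 + L])
                for _ in range(rng.integers(0, 4)):
                    i = int(rng.integers(L))
                    read[i] = "ACGT"[rng.integers(4)]
                read = "".join(read)
            else:
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=25))
            assert hitset(aligner.align(read)) == brute_force_align(read, refs)

    def test_short_read_falls_back_to_full_scan(self, toy_refs):
        ref = toy_refs.get("tx1").sequence
        # 12 nt < 3 seeds; still must find its placement
        ar = align_read(ref[30:42], toy_refs)
        refs = {rid: s.sequence for rid, s in toy_refs.sequences.items()}
        assert hitset(ar) == brute_force_align(ref[30:42], refs)


class TestClassify:
    def _ar(self, mms, n_hits=1):
        hits = tuple(Hit(f"r{i}", 1, mms) for i in range(n_hits))
        return AlignedRead("x", "ACGT" * 5, hits)

    def test_d0(self):
        assert classify(self._ar(())) == TransitionClass.D0

    def test_d1tc(self):
        assert classify(self._ar((Mismatch(5, "T", "C"),))) == TransitionClass.D1TC

    def test_d1other(self):
        assert classify(self._ar((Mismatch(5, "G", "A"),))) == TransitionClass.D1OTHER

    def test_reverse_tc_is_d1other(self):
        assert classify(self._ar((Mismatch(5, "C", "T"),))) == TransitionClass.D1OTHER

    def test_d2(self):
        mms = (Mismatch(3, "T", "C"), Mismatch(9, "A", "G"))
        assert classify(self._ar(mms)) == TransitionClass.D2

    def test_ambiguity_flag(self):
        same = AlignedRead(
            "x",
            "ACGT" * 5,
            (Hit("a", 1, (Mismatch(2, "T", "C"),)), Hit("b", 4, (Mismatch(7, "T", "C"),))),
        )
        diff = AlignedRead(
            "x",
            "ACGT" * 5,
            (Hit("a", 1, (Mismatch(2, "T", "C"),)), Hit("b", 4, (Mismatch(7, "G", "A"),))),
        )
        assert not class_ambiguous(same)
        assert class_ambiguous(diff)

    def test_classes_partition_mapped_reads(self, toy_refs):
        """Every mapped read lands in exactly one of d0/d1TC/d1other/d2."""
        rng = np.random.default_rng(9)
        aligner = Aligner(toy_refs)
        ref = toy_refs.get("5S").sequence
        seen = set()
        for _ in range(100):
            s0 = int(rng.integers(0, 90))
            read = list(ref[s0 : s0 + 25])
            for _ in range(rng.integers(0, 3)):
                i = int(rng.integers(25))
                read[i] = "ACGT"[rng.integers(4)]
            ar = aligner.align("".join(read))
            if ar.mapped:
                cls = classify(ar)
                assert cls in {
                    TransitionClass.D0,
                    TransitionClass.D1TC,
                    TransitionClass.D1OTHER,
                    TransitionClass.D2,
                }
                seen.add(cls)
        assert TransitionClass.D0 in seen


def _annotated(cls, length, ambiguous=False):
    return AnnotatedRead(
        read_id="x",
        ref_id="r",
        category="tRNA",
        start=1,
        end=length,
        length=length,
        transition_class=cls,
        ambiguous=ambiguous,
        region=None,
        conversion_pos=None,
    )


class TestAnalysisFilters:
    def test_trna_rejects_19nt_d1tc(self):
        assert filter_for_analysis([_annotated(TransitionClass.D1TC, 19)], "trna") == []

    def test_trna_keeps_20nt_d1tc(self):
        assert len(filter_for_analysis([_annotated(TransitionClass.D1TC, 20)], "trna")) == 1

    def test_rrna_keeps_15nt_d0(self):
        assert len(filter_for_analysis([_annotated(TransitionClass.D0, 15)], "rrna")) == 1

    def test_rrna_rejects_14nt(self):
        assert filter_for_analysis([_annotated(TransitionClass.D0, 14)], "rrna") == []

    def test_mrna_rejects_d2(self):
        assert filter_for_analysis([_annotated(TransitionClass.D2, 30)], "mrna") == []

    def test_composition_keeps_any_mapped(self):
        reads = [
            _annotated(TransitionClass.D2, 15),
            _annotated(TransitionClass.D0, 40),
            _annotated(TransitionClass.D1TC, 20, ambiguous=True),
        ]
        assert len(filter_for_analysis(reads, "composition")) == 3

    def test_positional_analyses_drop_ambiguous(self):
        reads = [_annotated(TransitionClass.D1TC, 25, ambiguous=True)]
        assert filter_for_analysis(reads, "trna") == []

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ValueError, match="unknown analysis"):
            filter_for_analysis([], "mirna")


class TestCollapse:
    def test_identical_reads_collapse_with_copies(self):
        reads = [FastqRead(f"r{i}", "ACGTACGT", "I" * 8) for i in range(5)]
        out = collapse_duplicates(reads)
        assert out == [CollapsedRead("r0", "ACGTACGT", 5)]

    def test_distinct_reads_identity(self):
        reads = [FastqRead("a", "ACGTACGT", "I" * 8), FastqRead("b", "TTTTAAAA", "I" * 8)]
        assert [c.copies for c in collapse_duplicates(reads)] == [1, 1]

    def test_case_insensitive(self):
        reads = [FastqRead("a", "acgtACGT", ""), FastqRead("b", "ACGTacgt", "")]
        out = collapse_duplicates(reads)
        assert len(out) == 1 and out[0].copies == 2


class TestSamInterchange:
    def test_round_trip_preserves_hits_and_copies(self, toy_refs, tmp_path):
        rng = np.random.default_rng(3)
        aligner = Aligner(toy_refs)
        reads = []
        for rid, s in list(toy_refs.sequences.items())[:3]:
            seq = list(s.sequence[10:40])
            seq[5] = "ACGT"[rng.integers(4)]
            reads.append(CollapsedRead(f"rd_{rid}", "".join(seq), int(rng.integers(1, 5))))
        aligned = aligner.align_many(reads)
        sam = tmp_path / "out.sam"
        write_sam(aligned, toy_refs, sam)
        back = read_sam(sam, toy_refs)
        back_by_id = {a.read_id: a for a in back}
        for a in aligned:
            b = back_by_id[a.read_id]
            assert b.copies == a.copies
            assert hitset(b) == hitset(a)
            for ha, hb in zip(a.hits, b.hits):
                assert ha.mismatches == hb.mismatches

    def test_gapped_records_rejected(self, toy_refs, tmp_path):
        sam = tmp_path / "bad.sam"
        ref = list(toy_refs.sequences)[0]
        L = toy_refs.get(ref).length
        sam.write_text(
            "@HD\tVN:1.6\n"
            + "".join(f"@SQ\tSN:{r}\tLN:{toy_refs.get(r).length}\n" for r in toy_refs.sequences)
            + f"q1\t0\t{ref}\t1\t255\t10M1D10M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\n"
        )
        with pytest.raises(ValueError, match="ungapped"):
            read_sam(sam, toy_refs)
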