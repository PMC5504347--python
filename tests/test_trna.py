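import numpy as np
import pandas as pd
import pytest

from parclipkit.align import AlignedRead, Hit, Mismatch, TransitionClass
from parclipkit.annotate import AnnotatedRead
from parclipkit.trna import (
    CountTable,
    bh_fdr,
    common_dispersion,
    conversion_map,
    count_unique,
    enrichment,
    fisher_exact_2x2,
    positional_profile,
    tmm_factors,
)

from _oracles import fisher_two_sided_enumeration, tmm_oracle


def trna_read(ref_id, start, end, cls=TransitionClass.D0, conv=None, copies=1):
    return AnnotatedRead(
        read_id=f"{ref_id}:{start}:{conv}",
        ref_id=ref_id,
        category="tRNA",
        start=start,
        end=end,
        length=end - start + 1,
        transition_class=cls,
        ambiguous=False,
        region=None,
        conversion_pos=conv,
        copies=copies,
    )


class TestPositionalProfile:
    def test_five_prime_reads_concentrate_density(self, toy_refs):
        reads = [
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1TC, conv=16)
            for _ in range(10)
        ]
        prof = positional_profile(reads, toy_refs, n_bins=10)
        # footprint 1..32 of 76 nt = first 42% of the molecule
        assert prof[:5].sum() >= 0.99
        assert prof.sum() == pytest.approx(1.0)

    def test_uniform_starts_give_flat_center(self, toy_refs):
        reads = [
            trna_read("tRNA-Gly-GCC-1", s, s + 18)
            for s in range(1, 59)
        ]
        prof = positional_profile(reads, toy_refs, n_bins=10)
        center = prof[2:6]
        assert center.max() / center.min() < 1.2

    def test_empty_input_errors(self, toy_refs):
        with pytest.raises(ValueError, match="no tRNA reads"):
            positional_profile([], toy_refs)


class TestConversionMap:
    def test_ratio_is_conversions_over_coverage(self, toy_refs):
        reads = [trna_read("tRNA-Gly-GCC-1", 1, 32) for _ in range(6)] + [
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1TC, conv=16)
            for _ in range(4)
        ]
        cm = conversion_map(reads, toy_refs)
        row = cm.table[(cm.table["trna"] == "tRNA-Gly-GCC-1") & (cm.table["position"] == 16)]
        assert row["coverage"].item() == 10
        assert row["ratio"].item() == pytest.approx(0.4)

    def test_zero_coverage_positions_na_and_excluded(self):
        from parclipkit.references import ReferenceSeq, ReferenceSet, TrnaAnnotation
        from conftest import TEMPLATE_ELEMENT_MAP

        # controlled body: the only T is the D-loop contact site (pos 16)
        body = list("A" * 76)
        body[15] = "T"
        refs = ReferenceSet.from_parts(
            [ReferenceSeq("t1", "tRNA", "".join(body))],
            [],
            [TrnaAnnotation("t1", "Gly", "GCC", TEMPLATE_ELEMENT_MAP)],
        )
        reads = [trna_read("t1", 1, 32, TransitionClass.D1TC, conv=16)]
        cm = conversion_map(reads, refs)
        tail = cm.table[cm.table["position"] > 32]
        assert tail["ratio"].isna().all()
        # element means only over covered T positions
        assert cm.element_means.loc["D-loop"] == pytest.approx(1.0)
        assert cm.argmax_element == "D-loop"

    def test_d2_reads_excluded_from_coverage(self, toy_refs):
        reads = [
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1TC, conv=16),
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D2),
        ]
        cm = conversion_map(reads, toy_refs)
        row = cm.table[(cm.table["trna"] == "tRNA-Gly-GCC-1") & (cm.table["position"] == 16)]
        assert row["coverage"].item() == 1

    def test_error_classes_excluded_from_ratio_denominator(self, toy_refs):
        reads = [
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1TC, conv=16),
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D0),
            trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1OTHER),
        ]
        cm = conversion_map(reads, toy_refs)
        row = cm.table[(cm.table["trna"] == "tRNA-Gly-GCC-1") & (cm.table["position"] == 16)]
        assert row["coverage"].item() == 2  # d1other read not counted
        assert row["ratio"].item() == pytest.approx(0.5)

    def test_conversion_outside_annotation_errors(self, toy_refs):
        reads = [trna_read("tRNA-Gly-GCC-1", 1, 32, TransitionClass.D1TC, conv=99)]
        with pytest.raises(ValueError, match="outside annotation"):
            conversion_map(reads, toy_refs)


def _aligned_trna(read_id, hits, copies=1):
    return AlignedRead(read_id, "A" * 32, tuple(Hit(h, 1, ()) for h in hits), copies)


class TestCountUnique:
    def test_gene_unique_counts_for_gene_and_family(self, synth_refs):
        par = [_aligned_trna("r1", ["tRNA-Lys-UUU-1"])]
        table = count_unique(par, [], synth_refs)
        assert table.genes.loc["tRNA-Lys-UUU-1", "parclip"] == 1
        assert table.families.loc["Lys-UUU", "parclip"] == 1

    def test_two_genes_one_family_is_family_unique_only(self, synth_refs):
        par = [_aligned_trna("r1", ["tRNA-Lys-UUU-1", "tRNA-Lys-UUU-2"])]
        table = count_unique(par, [], synth_refs)
        assert table.genes["parclip"].sum() == 0
        assert table.families.loc["Lys-UUU", "parclip"] == 1

    def test_cross_family_hits_count_nowhere(self, synth_refs):
        par = [_aligned_trna("r1", ["tRNA-Lys-UUU-1", "tRNA-Lys-CUU-1"])]
        table = count_unique(par, [], synth_refs)
        assert table.genes["parclip"].sum() == 0
        assert table.families["parclip"].sum() == 0

    def test_non_trna_hits_excluded(self, synth_refs):
        par = [_aligned_trna("r1", ["tRNA-Lys-UUU-1", "mRNA-01"])]
        table = count_unique(par, [], synth_refs)
        assert table.genes["parclip"].sum() == 0

    def test_copy_weighting(self, synth_refs):
        par = [_aligned_trna("r1", ["tRNA-Lys-UUU-1"], copies=7)]
        assert count_unique(par, [], synth_refs).genes.loc["tRNA-Lys-UUU-1", "parclip"] == 7


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        x = np.random.default_rng(0).integers(1, 200, size=(40, 2))
        x[:, 1] = x[:, 0]
        assert np.allclose(tmm_factors(x), 1.0)

    def test_uniform_scaling_unit_factors(self):
        x = np.random.default_rng(1).integers(1, 200, size=(40, 2)).astype(float)
        x[:, 1] = x[:, 0] * 3
        assert np.allclose(tmm_factors(x), 1.0)

    def test_geometric_mean_one_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 500, size=(30, 2)) + rng.integers(0, 2, size=(30, 2))
            f = tmm_factors(x)
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 300, size=(50, 2))
        perm = rng.permutation(50)
        assert np.allclose(tmm_factors(x), tmm_factors(x[perm]))

    def test_inflated_gene_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.integers(20, 200, size=(50, 2)).astype(float)
        x[0, 1] *= 8  # one gene inflated 8x in one library
        assert np.allclose(tmm_factors(x), tmm_oracle(x), atol=1e-9)

    def test_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.integers(0, 400, size=(rng.integers(10, 60), 2)) + 1
            assert np.allclose(tmm_factors(x), tmm_oracle(x), atol=1e-9)

    def test_no_copositive_genes_errors(self):
        x = np.array([[5, 0], [0, 7], [3, 0]])
        with pytest.raises(ValueError, match="positive counts in both"):
            tmm_factors(x)

    def test_edger_cross_check(self, tmp_path):
        """Factors match edgeR's calcNormFactors on a fixed count table."""
        import subprocess

        rng = np.random.default_rng(6)
        x = rng.integers(1, 500, size=(30, 2))
        x[0, 1] *= 6
        np.savetxt(tmp_path / "counts.tsv", x, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.table("{tmp_path}/counts.tsv"))\n'
            "f <- calcNormFactors(x, method='TMM', refColumn=1)\n"
            "cat(sprintf('%.10f %.10f', f[1], f[2]))\n"
        )
        try:
            res = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript unavailable")
        assert res.returncode == 0, res.stderr
        expected = [float(v) for v in res.stdout.split()]
        assert np.allclose(tmm_factors(x), expected, atol=1e-6)


class TestFisher:
    def test_worked_value_5005(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_modal_table_p_one(self):
        assert fisher_exact_2x2(1, 9, 10, 90) == pytest.approx(1.0)

    def test_label_symmetry(self):
        assert fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(fisher_exact_2x2(10, 0, 0, 10))

    def test_absent_feature_is_na(self):
        assert np.isnan(fisher_exact_2x2(0, 10, 0, 20))

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0 or a + c == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_sided_enumeration(int(a), int(b), int(c), int(d)), abs=1e-12
            )


class TestBhFdr:
    def test_closed_form_three_values(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1, 1, 1, 1]), 1.0)

    def test_singleton_identity(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(2, 50))
            q = bh_fdr(p)
            assert (q >= p - 1e-12).all()
            assert ((q <= 1).all())
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_na_propagates_and_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m=2: q = (0.02, 0.04)
        assert q[0] == pytest.approx(0.02) and q[2] == pytest.approx(0.04)

    def test_reapplication_can_inflate_q(self):
        """The BH step-up transform is not idempotent: the smallest adjusted
        value is re-multiplied by m on reapplication.  Documented so the
        adjusted values are never themselves re-adjusted downstream."""
        q = bh_fdr([0.01, 0.5])
        assert np.allclose(q, [0.02, 0.5])
        assert np.allclose(bh_fdr(q), [0.04, 0.5])


def _count_table(par, bg, synth_refs=None, genes=None, families=None):
    genes = genes or [f"g{i}" for i in range(len(par))]
    fam = families or genes
    gdf = pd.DataFrame(
        {"parclip": par, "background": bg, "family": fam},
        index=pd.Index(genes, name="gene"),
    )
    fdf = gdf.groupby("family")[["parclip", "background"]].sum()
    fdf.index.name = "family"
    return CountTable(genes=gdf, families=fdf)


class TestEnrichment:
    def test_planted_tenfold_gene_recovered(self):
        rng = np.random.default_rng(9)
        base = rng.integers(500, 2000, size=30)
        par = base.copy()
        par[0] *= 10
        ct = _count_table(par.tolist(), base.tolist())
        res = enrichment(ct)
        fc = 2 ** res.genes.iloc[0]["log2fc"]
        assert fc == pytest.approx(10, rel=0.1)
        assert res.genes.iloc[0]["significant"]

    def test_gene_absent_from_both_is_na_and_outside_m(self):
        ct = _count_table([100, 0, 50], [80, 0, 60])
        res = enrichment(ct)
        assert np.isnan(res.genes.iloc[1]["p"])
        tested = res.genes["p"].notna().sum()
        assert tested == 2

    def test_stratum_split_by_cumulative_background(self):
        ct = _count_table([10, 10, 10, 10], [850, 100, 40, 10])
        res = enrichment(ct, top_fraction=0.85)
        strata = res.genes["stratum"].tolist()
        assert strata[0] == "top85" and strata[-1] == "residual"

    def test_significance_requires_positive_fold_change(self):
        # strongly depleted gene: tiny p but negative log2fc -> not flagged
        ct = _count_table([10, 1000], [1000, 1000])
        res = enrichment(ct)
        assert not res.genes.iloc[0]["significant"]
        assert res.genes.iloc[0]["q"] < 0.05


class TestCommonDispersion:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(10)
        x = rng.poisson(200, size=(200, 6))
        assert common_dispersion(x) < 0.02

    def test_overdispersed_data_detected(self):
        rng = np.random.default_rng(11)
        mu = rng.gamma(shape=2.0, scale=100, size=(300, 1)) * np.ones((1, 6))
        x = rng.poisson(mu * rng.gamma(shape=4, scale=0.25, size=(300, 6)))
        assert common_dispersion(x) > 0.1
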