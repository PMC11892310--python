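"""Allele-mining filters: threshold semantics, round trips, haplotype grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cottonmine import variants as vm
from cottonmine.errors import FormatError


def make_record(chrom="A07", pos=100, qual=600.0, impacts=("MODERATE",),
                gts=("0/0", "1/1"), gene="g1"):
    annotations = [
        vm.EffectAnnotation(allele="T", effect_terms=("missense_variant",),
                            impact=imp, gene_name=gene, gene_id=gene)
        for imp in impacts
    ]
    calls = []
    for gt in gts:
        sep = "|" if "|" in gt else "/"
        a0, a1 = gt.split(sep)
        if a0 == "." or a1 == ".":
            calls.append(vm.GenotypeCall("missing", None))
        else:
            calls.append(vm.GenotypeCall.from_alleles(int(a0), int(a1)))
    return vm.VariantRecord(chrom=chrom, pos=pos, ref="C", alts=("T",),
                            qual=qual, annotations=annotations, genotypes=calls)


@st.composite
def record_lists(draw):
    n = draw(st.integers(0, 12))
    recs = []
    for i in range(n):
        qual = draw(st.one_of(st.none(), st.floats(0, 1200, allow_nan=False)))
        impacts = tuple(draw(st.lists(
            st.sampled_from(["HIGH", "MODERATE", "LOW", "MODIFIER"]), min_size=0, max_size=3)))
        gts = tuple(draw(st.lists(
            st.sampled_from(["0/0", "0/1", "1/1", "./."]), min_size=1, max_size=4)))
        recs.append(make_record(pos=i + 1, qual=qual, impacts=impacts, gts=gts))
    return recs


class TestParsing:
    def test_round_trip_of_simulated_dataset(self, small_dataset, small_dataset_dir):
        records, samples = vm.parse_annotated_vcf(small_dataset_dir["vcf"])
        assert len(records) == small_dataset.manifest["n_variants"]
        assert samples == small_dataset.ril_ids
        geno = vm.dosage_matrix(records, samples)
        np.testing.assert_array_equal(geno.to_numpy(), small_dataset.genotypes)
        positions = [(r.chrom, r.pos) for r in records]
        expected = list(zip(small_dataset.variants["chrom"], small_dataset.variants["pos"]))
        assert positions == expected
        impacts = [r.annotations[0].impact for r in records]
        assert impacts == small_dataset.variants["impact"].tolist()

    def test_phased_separator_and_missing_ann(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=ANN,Number=.,Type=String,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=A07>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "A07\t10\t.\tA\tG\t700\t.\t.\tGT\t1|1\t0|1\n"
            "A07\t20\t.\tC\tT\t700\t.\tANN=bad\tGT\t0/0\t./.\n"
        )
        records, samples = vm.parse_annotated_vcf(vcf)
        assert [g.state for g in records[0].genotypes] == ["hom-alt", "het"]
        assert records[1].annotations == []  # malformed ANN skipped, record kept
        assert [g.state for g in records[1].genotypes] == ["hom-ref", "missing"]

    def test_missing_file_and_non_vcf(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            vm.parse_annotated_vcf(tmp_path / "nope.vcf")
        bad = tmp_path / "bad.vcf"
        bad.write_text("not a vcf\n")
        with pytest.raises(FormatError):
            vm.parse_annotated_vcf(bad)


class TestFilters:
    def test_quality_threshold_is_strict(self):
        recs = [make_record(qual=q) for q in (100.0, 500.0, 501.0, 600.0, None)]
        kept = vm.filter_quality(recs)
        assert [r.qual for r in kept] == [501.0, 600.0]
        assert vm.filter_quality([]) == []

    def test_impact_any_match_semantics(self):
        low_mod = make_record(impacts=("LOW", "MODERATE"))
        modifier = make_record(impacts=("MODIFIER",))
        assert vm.filter_impact([low_mod, modifier]) == [low_mod]
        assert vm.filter_impact([low_mod], impacts={"HIGH"}) == []

    def test_hom_alt_presence(self):
        no_alt = make_record(gts=("0/0", "0/1"))
        one_alt = make_record(gts=("0/0", "1/1"))
        assert vm.filter_homozygous_alt_present([no_alt, one_alt]) == [one_alt]

    @given(record_lists())
    def test_quality_and_impact_filters_commute(self, recs):
        a = vm.filter_impact(vm.filter_quality(recs))
        b = vm.filter_quality(vm.filter_impact(recs))
        assert a == b

    @given(record_lists(), st.floats(0, 1200, allow_nan=False), st.floats(0, 1200, allow_nan=False))
    def test_raising_min_qual_never_keeps_more(self, recs, q1, q2):
        lo, hi = min(q1, q2), max(q1, q2)
        assert len(vm.filter_quality(recs, hi)) <= len(vm.filter_quality(recs, lo))

    def test_filter_chain_matches_generator_manifest(self, small_dataset, small_dataset_dir):
        records, _ = vm.parse_annotated_vcf(small_dataset_dir["vcf"])
        chain = vm.filter_homozygous_alt_present(
            vm.filter_impact(vm.filter_quality(records))
        )
        manifest = small_dataset.manifest
        assert len(chain) == manifest["n_chain_records"]
        assert sorted(vm.genes_affected(chain)) == manifest["chain_genes"]


class TestAggregation:
    def test_genes_affected_deduplicates_and_ignores_low_impact(self):
        recs = [make_record(gene="gA"), make_record(gene="gA"),
                make_record(gene="gB", impacts=("MODIFIER",))]
        assert vm.genes_affected(recs) == {"gA"}
        assert vm.genes_affected([]) == set()

    def test_interval_subsetting_inclusive_and_monotone(self):
        recs = [make_record(pos=p) for p in (5, 10, 20)]
        assert [r.pos for r in vm.subset_by_interval(recs, "A07", 10, 10)] == [10]
        assert vm.subset_by_interval(recs, "D13", 1, 100) == []
        inner = vm.subset_by_interval(recs, "A07", 8, 15)
        outer = vm.subset_by_interval(recs, "A07", 1, 25)
        assert set(r.pos for r in inner) <= set(r.pos for r in outer)
        with pytest.raises(ValueError):
            vm.subset_by_interval(recs, "A07", 50, 10)

    def test_count_hom_alt_states(self):
        rec = make_record(gts=("0/0", "0/1", "1/1"))
        assert vm.count_hom_alt(rec) == (1, 1, 1, 0)
        rec_missing = make_record(gts=("./.", "./."))
        assert vm.count_hom_alt(rec_missing) == (0, 0, 0, 2)

    def test_counts_sum_to_sample_count_on_simulated_record(self, small_dataset, small_dataset_dir):
        records, _ = vm.parse_annotated_vcf(small_dataset_dir["vcf"])
        rec = records[0]
        counts = vm.count_hom_alt(rec)
        assert sum(counts) == len(small_dataset.ril_ids)
        col = small_dataset.genotypes[:, 0]
        assert counts == ((col == 2).sum(), (col == 1).sum(), (col == 0).sum(), 0)


class TestHaplotypes:
    def test_distinct_vector_grouping(self):
        mat = pd.DataFrame(
            [["A", "A"], ["A", "A"], ["A", "B"], ["B", "B"]],
            index=["l1", "l2", "l3", "l4"],
        )
        result = vm.count_haplotypes(mat)
        assert result.n_haplotypes == 3
        assert result.groups[("A", "A")] == ["l1", "l2"]
        assert result.unassigned == []

    def test_all_identical_is_one_haplotype(self):
        mat = pd.DataFrame([["A", "B"]] * 4, index=list("wxyz"))
        assert vm.count_haplotypes(mat).n_haplotypes == 1

    def test_missing_call_goes_to_unassigned(self):
        mat = pd.DataFrame(
            [["A", "A"], ["A", None], ["B", "B"]], index=["l1", "l2", "l3"]
        )
        result = vm.count_haplotypes(mat)
        assert result.n_haplotypes == 2
        assert result.unassigned == ["l2"]
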