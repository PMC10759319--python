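"""Domain model: parsing, pedigree reduction, zygosity, interval overlap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderscan.cohort import (
    HET,
    HOM_ALT,
    MISSING,
    AnnotatedVariant,
    GenePanel,
    Individual,
    Pedigree,
    PedigreeError,
    SVInterval,
    VariantCall,
    VariantKey,
    classify_zygosity,
    coding_overlap,
    reduce_to_index,
)
from founderscan.io import ParseError, parse_ped, parse_vcf, write_ped, write_vcf

from conftest import trio_pedigree


def _variant(pos, gene="GENE1", popaf=0.001, **calls):
    return AnnotatedVariant(
        key=VariantKey("chr1", pos, "G", "A"),
        gene=gene,
        consequence="nonsynonymous",
        population_af=popaf,
        calls={sid: VariantCall(sid, gt) for sid, gt in calls.items()},
    )


class TestVcfParsing:
    def test_ad_arithmetic_and_genotypes(self, tmp_path):
        """AD-derived fractions: hom 30/30 alt reads -> 1.0; het 12/30 -> 0.4."""
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT:AD\t1/1:0,30\t0/1:18,12\t./.:.\n"
        )
        variants, samples = parse_vcf(vcf)
        assert samples == ["S1", "S2", "S3"]
        (v,) = variants
        assert v.calls["S1"].genotype == HOM_ALT
        assert v.calls["S1"].allelic_fraction == pytest.approx(1.0)
        assert v.calls["S2"].genotype == HET
        assert v.calls["S2"].allelic_fraction == pytest.approx(0.4)
        assert v.calls["S3"].genotype == MISSING

    def test_multiallelic_split(self, tmp_path):
        """ALT=A,T yields two variants sharing chrom/pos/ref, with
        genotypes mapped per alternate allele."""
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t2/2\n"
        )
        variants, _ = parse_vcf(vcf)
        assert [str(v.key) for v in variants] == ["chr1:100:G>A", "chr1:100:G>T"]
        va, vt = variants
        assert va.calls["S1"].genotype == HET
        assert "S2" not in va.calls  # hom_ref for allele A, stored sparsely
        assert vt.calls["S1"].genotype == HET
        assert vt.calls["S2"].genotype == HOM_ALT

    def test_unannotated_variant_gets_defaults(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
        )
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "chrom\tpos\tref\talt\tgene\tconsequence\tregulatory_sources\tgnomad_af\n"
        )
        (v,), _ = parse_vcf(vcf, ann)
        assert v.gene is None
        assert v.consequence == "other"
        assert v.population_af is None
        assert v.calls["S1"].allelic_fraction is None

    def test_annotation_collision_rejected(self, tmp_path):
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "chrom\tpos\tref\talt\tgene\tconsequence\tregulatory_sources\tgnomad_af\n"
            "chr1\t1\tG\tA\tX\tother\t\t\n"
            "chr1\t1\tG\tA\tY\tother\t\t\n"
        )
        from founderscan.io import read_annotations

        with pytest.raises(ParseError, match="duplicate"):
            read_annotations(ann)


class TestPedParsing:
    def test_trio_round_trip(self, tmp_path):
        ped = trio_pedigree()
        ped_path, cohort_path = tmp_path / "p.ped", tmp_path / "c.tsv"
        write_ped(ped_path, ped)
        from founderscan.io import write_cohort_labels

        write_cohort_labels(cohort_path, ped)
        again = parse_ped(ped_path, cohort_path)
        assert again.individuals == ped.individuals

    def test_zero_parent_is_null(self, tmp_path):
        (tmp_path / "p.ped").write_text("F\tS\t0\t0\t1\t2\n")
        (tmp_path / "c.tsv").write_text("sample_id\tcohort\tis_index\nS\tcase\t1\n")
        ped = parse_ped(tmp_path / "p.ped", tmp_path / "c.tsv")
        assert ped["S"].father_id is None and ped["S"].mother_id is None

    def test_two_index_cases_rejected(self, tmp_path):
        (tmp_path / "p.ped").write_text("F\tS1\t0\t0\t1\t2\nF\tS2\t0\t0\t1\t2\n")
        (tmp_path / "c.tsv").write_text(
            "sample_id\tcohort\tis_index\nS1\tcase\t1\nS2\tcase\t1\n"
        )
        with pytest.raises(ParseError, match="index"):
            parse_ped(tmp_path / "p.ped", tmp_path / "c.tsv")

    def test_dangling_parent_rejected(self, tmp_path):
        (tmp_path / "p.ped").write_text("F\tS\tGHOST\t0\t1\t2\n")
        (tmp_path / "c.tsv").write_text("sample_id\tcohort\tis_index\nS\tcase\t1\n")
        with pytest.raises(ParseError, match="GHOST"):
            parse_ped(tmp_path / "p.ped", tmp_path / "c.tsv")


class TestVcfRoundTrip:
    def test_write_parse_identity(self, tmp_path, cohort_dir):
        variants, samples = parse_vcf(
            cohort_dir / "cohort.vcf", cohort_dir / "annotations.tsv"
        )
        out = tmp_path / "again.vcf"
        write_vcf(out, variants, samples)
        again, samples2 = parse_vcf(out, cohort_dir / "annotations.tsv")
        assert samples2 == samples
        assert len(again) == len(variants)
        for v1, v2 in zip(variants, again):
            assert v1.key == v2.key
            assert v1.calls == v2.calls
            assert (v1.gene, v1.consequence, v1.population_af) == (
                v2.gene, v2.consequence, v2.population_af
            )


class TestReduceToIndex:
    def test_family_collapses_to_index(self, trio_ped):
        retained = reduce_to_index(trio_ped)
        assert retained == {"child", "c1", "c2"}

    def test_singletons_identity_and_idempotence(self):
        people = {
            f"S{i}": Individual(f"S{i}", f"F{i}", affected=True,
                                cohort="case", is_index=True)
            for i in range(5)
        }
        ped = Pedigree(people)
        retained = reduce_to_index(ped)
        assert retained == set(people)

    def test_sizes_add_up(self):
        # 4 case families with extra members + 6 controls
        people = {}
        for f in range(4):
            people[f"I{f}"] = Individual(f"I{f}", f"F{f}", affected=True,
                                         cohort="case", is_index=True)
            people[f"X{f}"] = Individual(f"X{f}", f"F{f}", affected=True,
                                         cohort="case")
        for c in range(6):
            people[f"C{c}"] = Individual(f"C{c}", f"CF{c}", cohort="control")
        retained = reduce_to_index(Pedigree(people))
        assert len(retained) == 4 + 6

    def test_missing_index_is_an_error(self):
        people = {
            "S1": Individual("S1", "F1", affected=True, cohort="case"),
        }
        with pytest.raises(PedigreeError, match="no index"):
            reduce_to_index(Pedigree(people))


class TestZygosity:
    def test_homozygous(self, trio_ped):
        v = _variant(100, child=HOM_ALT)
        z = classify_zygosity([v], "child", trio_ped)
        assert z.status == "homozygous"
        assert z.variant_keys == (v.key,)

    def test_compound_het_confirmed_via_trio(self, trio_ped):
        va = _variant(100, child=HET, mom=HET)
        vb = _variant(200, child=HET, dad=HET)
        z = classify_zygosity([va, vb], "child", trio_ped)
        assert z.status == "compound_het_confirmed"
        assert z.phase_evidence == "trio"

    def test_cis_parents_not_confirmed(self, trio_ped):
        # both variants on the maternal side: phase known NOT to be trans
        va = _variant(100, child=HET, mom=HET)
        vb = _variant(200, child=HET, mom=HET)
        z = classify_zygosity([va, vb], "child", trio_ped)
        assert z.status == "biallelic_phase_unknown"

    def test_no_parents_phase_unknown(self):
        ped = Pedigree({
            "S": Individual("S", "F", affected=True, cohort="case", is_index=True),
        })
        va, vb = _variant(100, S=HET), _variant(200, S=HET)
        z = classify_zygosity([va, vb], "S", ped)
        assert z.status == "biallelic_phase_unknown"
        assert z.phase_evidence == "none"

    def test_single_genotyped_parent_inference(self, trio_ped):
        """One typed parent carrying exactly one variant pins the phase."""
        va = _variant(100, child=HET, mom=HET)
        vb = _variant(200, child=HET)
        z = classify_zygosity(
            [va, vb], "child", trio_ped, genotyped_samples={"child", "mom"}
        )
        assert z.status == "compound_het_confirmed"
        assert z.phase_evidence == "trio"

    def test_single_het(self, trio_ped):
        z = classify_zygosity([_variant(100, child=HET)], "child", trio_ped)
        assert z.status == "single_het"

    def test_none(self, trio_ped):
        z = classify_zygosity([_variant(100)], "child", trio_ped)
        assert z.status == "none"

    def test_mendelian_error_flagged(self, trio_ped):
        # child carries variant A that neither genotyped parent has
        va = _variant(100, child=HET)
        vb = _variant(200, child=HET, dad=HET)
        z = classify_zygosity([va, vb], "child", trio_ped)
        assert z.status == "biallelic_phase_unknown"
        assert z.phase_evidence == "mendelian_error"

    def test_three_hets_pick_two_rarest(self, trio_ped):
        va = _variant(100, popaf=0.005, child=HET, mom=HET)
        vb = _variant(200, popaf=0.0001, child=HET, dad=HET)
        vc = _variant(300, popaf=0.004, child=HET, mom=HET)
        z = classify_zygosity([va, vb, vc], "child", trio_ped)
        # rarest two are vb and vc (trans via dad/mom); va still listed
        assert set(z.variant_keys) == {va.key, vb.key, vc.key}
        assert z.status == "compound_het_confirmed"
        assert z.variant_keys[:2] == (vb.key, vc.key)

    def test_never_confirmed_without_trio_evidence(self):
        ped = Pedigree({
            "S": Individual("S", "F", affected=True, cohort="case", is_index=True),
        })
        for variants in ([_variant(100, S=HET), _variant(200, S=HET)],
                         [_variant(100, S=HOM_ALT)],
                         [_variant(100, S=HET)]):
            z = classify_zygosity(variants, "S", ped)
            assert not (z.status == "compound_het_confirmed"
                        and z.phase_evidence != "trio")


class TestCodingOverlap:
    panel = GenePanel({"G": [("chr1", 150, 160)]})

    def test_overlap(self):
        assert coding_overlap(SVInterval("chr1", 100, 200, "DEL", "S"), self.panel)

    def test_half_open_abutment(self):
        panel = GenePanel({"G": [("chr1", 200, 300)]})
        assert not coding_overlap(SVInterval("chr1", 100, 200, "DEL", "S"), panel)

    def test_wrong_chrom(self):
        assert not coding_overlap(SVInterval("chr2", 100, 200, "DEL", "S"), self.panel)

    @given(
        a=st.integers(0, 50), b=st.integers(1, 30),
        c=st.integers(0, 50), d=st.integers(1, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_per_base_membership(self, a, b, c, d):
        """Interval intersection equals brute-force base sharing, and is
        symmetric in which interval plays the query."""
        sv = SVInterval("chr1", a, a + b, "DEL", "S")
        panel = GenePanel({"G": [("chr1", c, c + d)]})
        brute = bool(set(range(a, a + b)) & set(range(c, c + d)))
        assert coding_overlap(sv, panel) == brute
        mirrored = coding_overlap(
            SVInterval("chr1", c, c + d, "DEL", "S"),
            GenePanel({"G": [("chr1", a, a + b)]}),
        )
        assert mirrored == brute
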