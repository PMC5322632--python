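"""Data model, ploidy accounting, TSV/VCF I/O, and cohort validation."""

import textwrap

import pytest
from hypothesis import given
from hypothesis import strategies as st

import varspectrum as vs
from varspectrum.variant_model import SiteCounts, GenotypeCounts

from conftest import make_cohort, make_site


@pytest.mark.parametrize("n_female, n_male, x_linked, expected", [
    (140, 148, False, 576),
    (140, 148, True, 428),
    (0, 0, False, 0),
    (0, 0, True, 0),
    (10, 0, True, 20),
])
def test_chromosome_count(n_female, n_male, x_linked, expected):
    assert vs.chromosome_count(n_female, n_male, x_linked) == expected


def test_chromosome_count_rejects_negative():
    with pytest.raises(vs.ValidationError):
        vs.chromosome_count(-1, 5, False)


class TestVariantSite:
    def test_rejects_indels_and_identical_alleles(self):
        with pytest.raises(vs.ValidationError):
            make_site(ref="A", alt="AT")
        with pytest.raises(vs.ValidationError):
            make_site(ref="A", alt="A")

    def test_concordant_damaging_requires_both_predictors(self):
        both = make_site(sift_call="damaging", polyphen_call="damaging")
        one = make_site(pos=1001, sift_call="damaging", polyphen_call="missing")
        assert both.concordant_damaging and not one.concordant_damaging


class TestCounts:
    def test_alt_count_bounded_by_chromosomes(self):
        with pytest.raises(vs.ValidationError):
            SiteCounts(alt_count=5, chrom_count=4)

    def test_genotype_allele_consistency_enforced(self):
        # 2*1 + 3 = 5 != 4 must be rejected
        with pytest.raises(vs.ValidationError):
            SiteCounts(alt_count=4, chrom_count=8,
                       genotypes=GenotypeCounts(0, 3, 1))
        ok = SiteCounts(alt_count=5, chrom_count=8, genotypes=GenotypeCounts(0, 3, 1))
        assert ok.genotypes.alt_copies == 5

    def test_absent_site_reads_as_zero_at_default_ploidy(self):
        cohort = vs.CohortCounts("AR", 288, 140, 148)
        key = ("4", 1000, "A", "G")
        assert cohort.alt_count(key) == 0
        assert cohort.chrom_count(key, x_linked=False) == 576
        assert cohort.chrom_count(key, x_linked=True) == 428


class TestPromoterInterval:
    def test_strand_aware_promoter_window(self):
        fwd = vs.promoter_interval(10_000, "+")
        rev = vs.promoter_interval(10_000, "-")
        assert (fwd.start, fwd.end) == (9_500, 10_050)
        assert (rev.start, rev.end) == (9_950, 10_500)
        assert fwd.length == rev.length == 551


class TestTsvRoundTrip:
    def _fixture(self):
        sites = [
            make_site(pos=1000, functional_class="missense",
                      sift_call="damaging", polyphen_call="damaging", in_dbsnp=True),
            make_site(pos=1500, ref="C", alt="T", functional_class="synonymous"),
            make_site(chrom="X", pos=1200, gene="GENE_X", functional_class="nonsense",
                      sift_call="damaging", polyphen_call="damaging"),
        ]
        case = make_cohort("CASE", 288, {
            sites[0].key: (5, 576),
            sites[1].key: (1, 574),   # missing individuals lower chrom_count
            sites[2].key: (2, 428),
        }, 140, 148)
        ctrl = make_cohort("CTRL", 379, {
            sites[0].key: (100, 758),
            sites[1].key: (0, 758),
            sites[2].key: (0, 568),
        }, 190, 189)
        return sites, case, ctrl

    def test_round_trip_preserves_keys_and_counts(self, tmp_path):
        sites, case, ctrl = self._fixture()
        path = tmp_path / "table.tsv"
        vs.write_variant_table(path, sites, {"CASE": case, "CTRL": ctrl})
        table = vs.read_variant_table(path)
        assert [s.key for s in table.sites] == [s.key for s in sites]
        assert [s.functional_class for s in table.sites] == \
            [s.functional_class for s in sites]
        for pop, orig in (("CASE", case), ("CTRL", ctrl)):
            got = table.cohorts[pop]
            assert got.n_individuals == orig.n_individuals
            assert got.n_female == orig.n_female
            for s in sites:
                assert got.alt_count(s.key) == orig.alt_count(s.key)
                assert got.chrom_count(s.key) == orig.chrom_count(s.key)

    def test_genotype_columns_round_trip(self, tmp_path):
        site = make_site()
        case = make_cohort("CASE", 5, {
            site.key: SiteCounts(3, 10, GenotypeCounts(3, 1, 1))}, 3, 2)
        path = tmp_path / "gt.tsv"
        vs.write_variant_table(path, [site], {"CASE": case})
        got = vs.read_variant_table(path).cohorts["CASE"]
        assert got.genotypes(site.key) == GenotypeCounts(3, 1, 1)

    def test_duplicate_site_key_rejected(self, tmp_path):
        sites, case, ctrl = self._fixture()
        path = tmp_path / "dup.tsv"
        vs.write_variant_table(path, sites + [sites[0]], {"CASE": case, "CTRL": ctrl})
        with pytest.raises(vs.VariantModelError, match="duplicate"):
            vs.read_variant_table(path)

    def test_count_passthrough_row(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\tregion_class\tfunctional_class\tsift\t"
            "polyphen\tin_dbsnp\tAR_ac\tAR_an\n"
            "4\t1000\tA\tG\tGENE_A\tcoding\tmissense\tdamaging\tdamaging\ttrue\t5\t576\n")
        table = vs.read_variant_table(path)
        assert table.cohorts["AR"].counts[("4", 1000, "A", "G")].alt_count == 5
        assert table.cohorts["AR"].counts[("4", 1000, "A", "G")].chrom_count == 576

    def test_indel_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "indel.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\tregion_class\tfunctional_class\tsift\t"
            "polyphen\tin_dbsnp\tAR_ac\tAR_an\n"
            "4\t1000\tA\tG\tGENE_A\tcoding\tmissense\tdamaging\tdamaging\ttrue\t5\t576\n"
            "4\t1001\tA\tAT\tGENE_A\tcoding\tunknown\tmissing\tmissing\tfalse\t2\t576\n")
        table = vs.read_variant_table(path)
        assert len(table.sites) == 1
        assert table.n_indels_dropped == 1

    def test_alt_count_above_chrom_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\tregion_class\tfunctional_class\tsift\t"
            "polyphen\tin_dbsnp\tAR_ac\tAR_an\n"
            "4\t1000\tA\tG\tGENE_A\tcoding\tmissense\tdamaging\tdamaging\ttrue\t600\t576\n")
        with pytest.raises(vs.VariantModelError, match="line 2"):
            vs.read_variant_table(path)


class TestVcf:
    VCF = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##INFO=<ID=AC_AR,Number=A,Type=Integer,Description="AR alt allele count">
        ##INFO=<ID=AN_AR,Number=1,Type=Integer,Description="AR allele number">
        ##contig=<ID=4>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        4\t1000\trs1\tA\tG,T\t.\t.\tAC_AR=5,2;AN_AR=576
        4\t1500\t.\tA\tAT\t.\t.\tAC_AR=3;AN_AR=576
        4\t1600\t.\tC\tT\t.\t.\tAC_AR=1;AN_AR=574
        """)

    def test_multiallelic_split_and_indel_drop(self, tmp_path, tiny_panel):
        path = tmp_path / "in.vcf"
        path.write_text(self.VCF)
        table = vs.read_variant_table(path, dialect="vcf", panel=tiny_panel)
        keys = [s.key for s in table.sites]
        assert keys == [("4", 1000, "A", "G"), ("4", 1000, "A", "T"),
                        ("4", 1600, "C", "T")]
        assert table.n_indels_dropped == 1
        # total alt copies conserved across the biallelic split
        ar = table.cohorts["AR"]
        assert ar.alt_count(keys[0]) + ar.alt_count(keys[1]) == 7
        assert ar.alt_count(keys[2]) == 1
        assert table.sites[0].in_dbsnp and not table.sites[2].in_dbsnp
        assert table.sites[0].gene == "GENE_A"

    def test_genotype_vcf_with_sample_map(self, tmp_path):
        vcf = textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##contig=<ID=4>
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
            4\t1000\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t./.
            """)
        path = tmp_path / "gt.vcf"
        path.write_text(vcf)
        table = vs.read_variant_table(
            path, dialect="vcf", sample_map={"s1": "CASE", "s2": "CASE", "s3": "CTRL"})
        case = table.cohorts["CASE"]
        key = ("4", 1000, "A", "G")
        assert case.alt_count(key) == 3
        assert case.chrom_count(key) == 4
        # missing genotype reduces the control's called chromosomes
        assert table.cohorts["CTRL"].chrom_count(key) == 0


class TestValidateCohort:
    def test_clean_cohort_empty_report(self, tiny_panel):
        site = make_site()
        cohort = make_cohort("CASE", 288, {site.key: (5, 576)}, 140, 148)
        assert vs.validate_cohort(cohort, tiny_panel, [site]) == []

    def test_genotype_mismatch_flagged(self, tiny_panel):
        cohort = vs.CohortCounts("CASE", 288, 140, 148)
        # bypass SiteCounts validation to exercise the report path
        object.__setattr__(
            sc := SiteCounts(5, 576), "genotypes", GenotypeCounts(285, 2, 1))
        cohort.counts[("4", 1000, "A", "G")] = sc
        report = vs.validate_cohort(cohort, tiny_panel)
        assert any("alt copies 4" in msg for msg in report)

    def test_site_outside_panel_flagged(self, tiny_panel):
        site = make_site(pos=5000)
        cohort = make_cohort("CASE", 288, {site.key: (5, 576)}, 140, 148)
        report = vs.validate_cohort(cohort, tiny_panel, [site])
        assert any("outside all panel intervals" in msg for msg in report)

    def test_x_linked_male_heterozygotes_flagged(self, tiny_panel):
        cohort = vs.CohortCounts("CASE", 288, 140, 148)
        # 150 diploid genotypes at an X site > 140 females
        gt = GenotypeCounts(100, 50, 0, 138, 0)
        cohort.counts[("X", 1200, "A", "G")] = SiteCounts(50, 438, gt)
        report = vs.validate_cohort(cohort, tiny_panel)
        assert any("heterozygous male" in msg for msg in report)


@given(st.integers(0, 576))
def test_genotype_count_identity(ac):
    hom_alt, het = divmod(ac, 2)
    gt = GenotypeCounts(288 - het - hom_alt, het, hom_alt)
    assert gt.alt_copies == ac
    assert gt.chromosomes == 576
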