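"""Domain types and tabular I/O."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fshdkit.core import (
    OVER_20,
    Allele4q,
    AnnotatedVariant,
    CohortFormatError,
    Genotype4q,
    MethylationProfile,
    Pedigree,
    PedigreeMember,
    format_fraction,
    parse_fraction,
    read_cohort,
    read_ped,
    read_variants,
    write_ped,
    write_report,
)

COHORT_HEADER = (
    "family_id\tsubject_id\trelation\taffected\tallele1_ru\tallele1_type\t"
    "allele2_ru\tallele2_type\t"
    + "\t".join(f"pas_cpg{i}" for i in range(1, 11)) + "\t"
    + "\t".join(f"dr1_cpg{i}" for i in range(1, 30)) + "\t"
    "sex\tage\tcss\tfcs"
)


def _cohort_tsv(*rows):
    return io.StringIO("\n".join([COHORT_HEADER, *rows]) + "\n")


def _row(subject="S1", fam="F1", pas=None, dr1=None, **overrides):
    pas = pas or ["—"] * 10
    dr1 = dr1 or ["—"] * 29
    cells = dict(
        family_id=fam, subject_id=subject, relation="proband", affected="affected",
        allele1_ru="5", allele1_type="A", allele2_ru=">20", allele2_type="B",
        sex="M", age="40", css="—", fcs="—",
    )
    cells.update(overrides)
    fixed = [cells["family_id"], cells["subject_id"], cells["relation"], cells["affected"],
             cells["allele1_ru"], cells["allele1_type"], cells["allele2_ru"], cells["allele2_type"]]
    return "\t".join(fixed + pas + dr1 + [cells["sex"], cells["age"], cells["css"], cells["fcs"]])


class TestFractionParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [("57%", 0.57), ("0.57", 0.57), ("100%", 1.0), ("0%", 0.0),
         ("0.000278", 0.000278), ("—", None), ("", None), ("na", None),
         ("not found", None), ("NA", None)],
    )
    def test_parse(self, text, expected):
        assert parse_fraction(text) == expected

    @pytest.mark.parametrize("bad", ["101%", "-3%", "1.5", "abc"])
    def test_rejects_out_of_range_and_garbage(self, bad):
        with pytest.raises(CohortFormatError):
            parse_fraction(bad, row="S1", column="pas_cpg6")

    def test_error_names_row_and_column(self):
        with pytest.raises(CohortFormatError, match="S1.*pas_cpg6"):
            parse_fraction("120%", row="S1", column="pas_cpg6")

    @given(st.integers(min_value=0, max_value=100))
    @settings(derandomize=True)
    def test_integer_percent_round_trip_is_exact(self, n):
        assert format_fraction(parse_fraction(f"{n}%")) == f"{n}%"


class TestAlleleTypes:
    def test_over_20_compares_above_any_finite_size(self):
        assert Allele4q(OVER_20, "A").numeric_size > Allele4q(20, "A").numeric_size

    def test_rejects_bad_subtype_and_size(self):
        with pytest.raises(ValueError):
            Allele4q(5, "C")
        with pytest.raises(ValueError):
            Allele4q(0, "A")

    @pytest.mark.parametrize(
        "subtypes,expected",
        [(("A", "A"), "4qA/4qA"), (("A", "B"), "4qA/4qB"),
         (("B", "A"), "4qA/4qB"), (("B", "B"), "4qB/4qB")],
    )
    def test_configuration_is_unordered(self, subtypes, expected):
        g = Genotype4q(Allele4q(5, subtypes[0]), Allele4q(10, subtypes[1]))
        assert g.configuration == expected


class TestMethylationProfile:
    def test_lengths_enforced(self):
        with pytest.raises(ValueError):
            MethylationProfile(dr1=np.zeros(28))
        with pytest.raises(ValueError):
            MethylationProfile(dux4_pas=np.zeros(11))

    def test_values_bounded(self):
        bad = np.zeros(29)
        bad[3] = 1.4
        with pytest.raises(ValueError):
            MethylationProfile(dr1=bad)

    def test_partial_vector_sites_are_none(self):
        dr1 = np.full(29, np.nan)
        dr1[0] = 0.5
        p = MethylationProfile(dr1=dr1)
        assert p.dr1_site(1) == 0.5
        assert p.dr1_site(22) is None
        assert p.pas_site(6) is None


class TestReadCohort:
    def test_percent_cells_become_fractions(self):
        pas = ["—"] * 10
        pas[5], pas[2] = "57%", "27%"
        dr1 = ["—"] * 29
        dr1[0], dr1[21] = "48%", "80%"
        (subject,) = read_cohort(_cohort_tsv(_row(pas=pas, dr1=dr1)))
        assert subject.methylation.pas_site(6) == 0.57
        assert subject.methylation.pas_site(3) == 0.27
        assert subject.methylation.dr1_site(1) == 0.48
        assert subject.methylation.dr1_site(22) == 0.80

    def test_all_dash_cells_become_absent_profile(self):
        (subject,) = read_cohort(_cohort_tsv(_row()))
        assert subject.methylation.is_absent

    def test_header_only_file_gives_empty_cohort(self):
        assert read_cohort(_cohort_tsv()) == []

    def test_missing_frequency_never_coerced_to_zero(self):
        (subject,) = read_cohort(_cohort_tsv(_row()))
        assert subject.methylation.pas_site(6) is None

    def test_malformed_cell_error_names_row_and_column(self):
        pas = ["—"] * 10
        pas[5] = "135%"
        with pytest.raises(CohortFormatError, match="S1.*pas_cpg6"):
            read_cohort(_cohort_tsv(_row(pas=pas)))

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(CohortFormatError, match="duplicate"):
            read_cohort(_cohort_tsv(_row(), _row()))

    def test_over_20_allele_parsed_as_sentinel(self):
        (subject,) = read_cohort(_cohort_tsv(_row()))
        assert subject.genotype.allele2.size_ru == OVER_20


class TestVariantTable:
    def test_reference_values(self, ref_variants):
        by_key = {v.key: v for v in ref_variants}
        assert by_key["SMCHD1:c.3841A>G"].gnomad_af == 0.000278
        assert by_key["CTCF:c.1483T>G"].gnomad_af is None  # "not found", never 0
        assert by_key["DNMT3B:c.1144C>T"].gnomad_af == 0.00053

    def test_missing_required_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tcoding_hgvs\nSMCHD1\tc.709G>A\n")
        with pytest.raises(CohortFormatError, match="coverage"):
            read_variants(path)

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\tcoding_hgvs\tcoverage\n")
        assert read_variants(path) == []

    def test_vcf_input(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CHGVS,Number=1,Type=String,Description="c">\n'
            '##INFO=<ID=COV,Number=1,Type=Integer,Description="cov">\n'
            '##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="af">\n'
            '##contig=<ID=18>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "18\t2688462\t.\tG\tA\t.\t.\tGENE=SMCHD1;CHGVS=c.709G>A;COV=100\n"
        )
        (variant,) = read_variants(vcf)
        assert variant.gene == "SMCHD1"
        assert variant.coding_hgvs == "c.709G>A"
        assert variant.coverage == 100
        assert variant.gnomad_af is None


class TestRoundTrips:
    def test_cohort_round_trip_bit_for_bit(self, ref_cohort, tmp_path):
        write_report(ref_cohort, tmp_path / "c.tsv")
        assert read_cohort(tmp_path / "c.tsv") == ref_cohort

    def test_variant_round_trip_bit_for_bit(self, ref_variants, tmp_path):
        write_report(ref_variants, tmp_path / "v.tsv")
        assert read_variants(tmp_path / "v.tsv") == ref_variants

    def test_empty_report_is_header_only(self, tmp_path):
        write_report([], tmp_path / "e.tsv")
        text = (tmp_path / "e.tsv").read_text()
        assert len(text.strip().splitlines()) == 1

    def test_single_subject_report_has_one_row(self, ref_cohort, tmp_path):
        write_report(ref_cohort[:1], tmp_path / "one.tsv")
        assert len(read_cohort(tmp_path / "one.tsv")) == 1

    def test_full_reference_cohort_has_44_rows(self, ref_cohort, tmp_path):
        write_report(ref_cohort, tmp_path / "all.tsv")
        assert len(read_cohort(tmp_path / "all.tsv")) == 44


class TestPedigree:
    def test_round_trip(self, ref_pedigrees, tmp_path):
        peds = sorted(ref_pedigrees.values(), key=lambda p: p.family_id)
        write_ped(peds, tmp_path / "f.ped")
        back = {p.family_id: p for p in read_ped(tmp_path / "f.ped")}
        assert back == ref_pedigrees

    def test_unresolved_parent_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            Pedigree("F", (PedigreeMember("kid", father_id="ghost"),))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree("F", (
                PedigreeMember("a", father_id="b"),
                PedigreeMember("b", father_id="a"),
            ))


def test_annotated_variant_validation():
    with pytest.raises(ValueError):
        AnnotatedVariant(gene="", coding_hgvs="c.1A>G")
    with pytest.raises(ValueError):
        AnnotatedVariant(gene="SMCHD1", coding_hgvs="c.1A>G", coverage=-1)
    with pytest.raises(ValueError):
        AnnotatedVariant(gene="SMCHD1", coding_hgvs="c.1A>G", gnomad_af=1.5)
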