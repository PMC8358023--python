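"""Data model invariants and file-format round trips."""

import pytest

from conftest import make_call
from ctdna.variant_io import (
    FunctionalClass,
    Material,
    SampleMeta,
    VariantCall,
    VariantIOError,
    VariantKey,
    apply_panel,
    get_panel,
    parse_functional,
    read_sample_sheet,
    read_variant_table,
    read_vcf,
    timepoint_rank,
    write_sample_sheet,
    write_variant_table,
    write_vcf,
)


class TestVariantKey:
    def test_rejects_degenerate_alleles(self):
        with pytest.raises(ValueError):
            VariantKey("12", 100, "A", "A")
        with pytest.raises(ValueError):
            VariantKey("12", 0, "A", "C")
        with pytest.raises(ValueError):
            VariantKey("12", 100, "", "C")
        with pytest.raises(ValueError):
            VariantKey("12", 100, "-", "C")

    def test_exact_string_chrom_comparison_and_normalization(self):
        assert VariantKey("12", 100, "A", "C") != VariantKey("chr12", 100, "A", "C")
        assert VariantKey("chr12", 100, "A", "C").normalized() == VariantKey("12", 100, "A", "C")


class TestVariantCall:
    def test_vaf_consistency_enforced(self):
        with pytest.raises(ValueError):
            make_call(depth=1000, alt_reads=10, vaf=0.5)
        call = make_call(depth=1000, alt_reads=10, vaf=0.01)
        assert call.vaf_pct == pytest.approx(1.0)

    def test_alt_reads_bounded_by_depth(self):
        with pytest.raises(ValueError):
            make_call(depth=10, alt_reads=11, vaf=1.0)

    def test_reads_optional_but_paired(self):
        call = make_call(depth=None, alt_reads=None, vaf=0.0174)
        assert call.depth is None
        with pytest.raises(ValueError):
            make_call(depth=100, alt_reads=None, vaf=0.5)


def test_functional_aliases_map_to_enum():
    assert parse_functional("missense_variant") is FunctionalClass.MISSENSE
    assert parse_functional("stop_gained") is FunctionalClass.STOP_GAIN
    assert parse_functional("frameshift_variant") is FunctionalClass.FRAMESHIFT
    assert parse_functional("synonymous_variant") is FunctionalClass.OTHER


def test_panels_nested_and_sized():
    v2, v3 = get_panel("v2"), get_panel("v3")
    assert len(v2.genes) == 11 and len(v3.genes) == 16
    assert set(v2.genes) < set(v3.genes)
    with pytest.raises(VariantIOError):
        get_panel("v9")


def test_timepoint_ordering():
    ranks = [timepoint_rank(t) for t in ("baseline", "eval1", "eval2", "PD")]
    assert ranks == sorted(ranks) and len(set(ranks)) == 4
    with pytest.raises(VariantIOError):
        timepoint_rank("followup3")


class TestVcf:
    def _calls(self, n=20):
        rows = []
        for i in range(n):
            rows.append(
                make_call(
                    chrom=["12", "17", "5"][i % 3],
                    pos=1000 + 97 * i,
                    ref="CT" if i % 5 == 0 else "C",
                    alt="C" if i % 5 == 0 else "A",
                    gene=["KRAS", "TP53", "APC"][i % 3],
                    fclass=list(FunctionalClass)[i % 5],
                    depth=1500 + i,
                    alt_reads=15 + i,
                    base_change=f"c.{i}A>G",
                    aa_change=f"p.Xaa{i}Yaa",
                )
            )
        return rows

    def test_round_trip_preserves_calls(self, tmp_path, cfdna_sample):
        calls = self._calls()
        path = tmp_path / "calls.vcf"
        write_vcf(calls, path, sample_id="S1")
        back = read_vcf(path, cfdna_sample)
        assert sorted(back, key=lambda c: (c.key.chrom, c.key.pos)) == sorted(
            calls, key=lambda c: (c.key.chrom, c.key.pos)
        )

    def test_depth_and_vaf_arithmetic(self, tmp_path, cfdna_sample):
        path = tmp_path / "one.vcf"
        write_vcf([make_call(depth=1000, alt_reads=10, vaf=0.01)], path)
        (call,) = read_vcf(path, cfdna_sample)
        assert (call.depth, call.alt_reads) == (1000, 10)
        assert call.vaf == pytest.approx(0.01, abs=1e-9)

    def test_multiallelic_record_split(self, tmp_path, cfdna_sample):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=12>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "12\t500\t.\tC\tA,T\t.\tPASS\t.\tDP:AD\t1000:970,20,10\n"
        )
        calls = read_vcf(path, cfdna_sample)
        assert len(calls) == 2
        assert {c.key.alt for c in calls} == {"A", "T"}
        assert {c.key.ref for c in calls} == {"C"}
        assert {c.alt_reads for c in calls} == {20, 10}

    def test_missing_depth_annotation_is_an_error(self, tmp_path, cfdna_sample):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=12>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "12\t500\t.\tC\tA\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(VariantIOError, match="AD"):
            read_vcf(path, cfdna_sample)


class TestVariantTable:
    def test_report_row_parsed_to_fraction(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "Chr\tStart\tEnd\tRef\tAlt\tFunctional\tGene\tBase change\tAA change\tVAF (%)\n"
            "12\t25398284\t25398284\tC\tA\tmissense_variant\tKRAS\tc.35G>T\tp.Gly12Val\t1.74\n"
            "5\t112175639\t112175639\tC\tT\tstop_gained\tAPC\tc.4348C>T\tp.Arg1450*\t38.41\n"
        )
        kras, apc = read_variant_table(path)
        assert kras.gene == "KRAS" and kras.aa_change == "p.Gly12Val"
        assert kras.vaf == pytest.approx(0.0174)
        assert apc.functional_class is FunctionalClass.STOP_GAIN
        assert apc.vaf == pytest.approx(0.3841)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "Chr\tStart\tEnd\tRef\tAlt\tFunctional\tGene\tBase change\tAA change\tVAF (%)\n"
        )
        assert read_variant_table(path) == []

    def test_non_numeric_vaf_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "Chr\tStart\tEnd\tRef\tAlt\tFunctional\tGene\tBase change\tAA change\tVAF (%)\n"
            "12\t100\t100\tC\tA\tmissense\tKRAS\t\t\thigh\n"
        )
        with pytest.raises(VariantIOError, match="non-numeric VAF"):
            read_variant_table(path)

    def test_fifty_call_round_trip(self, tmp_path):
        calls = [
            make_call(
                pos=1000 + 61 * i,
                gene=["KRAS", "TP53"][i % 2],
                fclass=list(FunctionalClass)[i % 6],
                depth=2000,
                alt_reads=10 + i,
                sample_id=f"S{i % 3}",
            )
            for i in range(50)
        ]
        path = tmp_path / "rt.tsv"
        write_variant_table(calls, path)
        assert read_variant_table(path) == calls


class TestSampleSheet:
    HEADER = "sample_id,patient_id,material,timepoint,panel_version\n"

    def test_round_trip_and_shared_patient(self, tmp_path):
        samples = [
            SampleMeta("S1", "P1", Material.PBMC, "baseline", "v3"),
            SampleMeta("S2", "P1", Material.CFDNA, "baseline", "v3"),
        ]
        path = tmp_path / "sheet.csv"
        write_sample_sheet(samples, path)
        back = read_sample_sheet(path)
        assert back == samples
        assert back[0].patient_id == back[1].patient_id

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(self.HEADER + "S1,P1,cfDNA,baseline,v3\nS1,P2,PBMC,baseline,v3\n")
        with pytest.raises(VariantIOError, match="duplicate sample_id"):
            read_sample_sheet(path)

    def test_unknown_material_rejected(self, tmp_path):
        path = tmp_path / "mat.csv"
        path.write_text(self.HEADER + "S1,P1,saliva,baseline,v3\n")
        with pytest.raises(VariantIOError, match="unknown material"):
            read_sample_sheet(path)


def test_panel_gating_flags_off_panel_calls():
    panel = get_panel("v2")
    in_panel = make_call(gene="KRAS")
    off_panel = make_call(pos=999, gene="PTEN")  # PTEN only in v3
    kept, flagged = apply_panel([in_panel, off_panel], panel)
    assert kept == [in_panel] and flagged == [off_panel]
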