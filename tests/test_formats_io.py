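import pytest

from magqc.formats_io import (
    AnnotationFeature,
    BinRecord,
    FeatureType,
    FormatError,
    QualityEstimate,
    parse_annotation_gff3,
    parse_annotation_tsv,
    parse_quality_table,
    read_metadata_csv,
    scan_bin_directory,
    strip_bin_extension,
    write_metadata_csv,
)
from magqc.reporting import MetadataRow

from conftest import write_fasta


class TestScanBinDirectory:
    def test_recognised_extensions_only(self, tmp_path):
        write_fasta(tmp_path / "binA.fa", {"c1": "ACGT" * 25})
        write_fasta(tmp_path / "binB.fna", {"c2": "ACGT" * 10})
        (tmp_path / "notes.txt").write_text("not a bin\n")
        records = scan_bin_directory(tmp_path)
        assert [r.bin_id for r in records] == ["binA", "binB"]
        assert records[0].contig_lengths == {"c1": 100}

    def test_case_insensitive_extension_and_stem(self, tmp_path):
        write_fasta(tmp_path / "x.FASTA", {"c1": "A" * 50})
        (records,) = scan_bin_directory(tmp_path)
        assert records.bin_id == "x"

    def test_sorted_and_idempotent(self, tmp_path):
        for name in ("zeta.fa", "alpha.fa", "mid.fna"):
            write_fasta(tmp_path / name, {name + "_c": "ACGT"})
        first = scan_bin_directory(tmp_path)
        second = scan_bin_directory(tmp_path)
        assert [r.bin_id for r in first] == ["alpha", "mid", "zeta"]
        assert first == second

    def test_empty_directory_is_error(self, tmp_path):
        (tmp_path / "readme.md").write_text("no bins here\n")
        with pytest.raises(FormatError, match="no bins found"):
            scan_bin_directory(tmp_path)

    def test_unparseable_fasta_names_file(self, tmp_path):
        (tmp_path / "bad.fa").write_text("this is not fasta\n")
        with pytest.raises(FormatError, match="bad.fa"):
            scan_bin_directory(tmp_path)


class TestQualityTable:
    HEADER = "Bin Id\tMarker lineage\tCompleteness\tContamination\tStrain heterogeneity"

    def test_checkm_tsv_with_extra_columns(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text(
            self.HEADER + "\nbinA\troot (UID1)\t95.0\t2.0\t0.0\n"
        )
        result = parse_quality_table(path)
        assert result == {"binA": QualityEstimate("binA", 95.0, 2.0, "CheckM")}

    def test_comma_separated_variant(self, tmp_path):
        path = tmp_path / "q.csv"
        path.write_text("Bin Id,Completeness,Contamination\nbinA,80.5,1.25\n")
        assert parse_quality_table(path)["binA"].completeness == 80.5

    def test_bin_ids_stripped_of_fasta_extension(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text(
            "Bin Id\tCompleteness\tContamination\nbinA.fa\t50.0\t1.0\n"
        )
        assert set(parse_quality_table(path)) == {"binA"}

    def test_completeness_above_100_is_error(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text("Bin Id\tCompleteness\tContamination\nbinA\t101.0\t2.0\n")
        with pytest.raises(FormatError, match="completeness"):
            parse_quality_table(path)

    def test_duplicate_bin_id_is_error(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text(
            "Bin Id\tCompleteness\tContamination\n"
            "binA\t95.0\t2.0\nbinA\t90.0\t1.0\n"
        )
        with pytest.raises(FormatError, match="duplicate bin id"):
            parse_quality_table(path)

    def test_missing_column_lists_found_headers(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text("Bin Id\tCompleteness\nbinA\t95.0\n")
        with pytest.raises(FormatError, match="Completeness"):
            parse_quality_table(path)

    def test_non_numeric_field_names_row(self, tmp_path):
        path = tmp_path / "q.tsv"
        path.write_text(
            "Bin Id\tCompleteness\tContamination\nbinA\thigh\t2.0\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            parse_quality_table(path)


BAKTA_HEADER = (
    "#Annotated with Bakta\n"
    "#Sequence Id\tType\tStart\tStop\tStrand\tLocus Tag\tGene\tProduct\n"
)


class TestAnnotationTsv:
    def test_trna_rrna_and_other_rows(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            BAKTA_HEADER
            + "c1\ttRNA\t10\t85\t+\tLOC1\t\ttRNA-Ala\n"
            + "c1\tcds\t100\t400\t-\tLOC2\tdnaA\treplication initiator\n"
            + "c2\trRNA\t1\t1500\t-\tLOC3\trrs\t16S ribosomal RNA\n"
        )
        feats = parse_annotation_tsv(path)
        assert [f.feature_type for f in feats] == [
            FeatureType.TRNA, FeatureType.OTHER, FeatureType.RRNA,
        ]
        assert feats[0] == AnnotationFeature(
            "c1", FeatureType.TRNA, 10, 85, "+", "tRNA-Ala", None, False
        )
        assert feats[2].length == 1500
        assert feats[2].gene == "rrs"

    def test_pseudogene_flagged_from_product(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(BAKTA_HEADER + "c1\ttRNA\t5\t80\t+\t\t\ttRNA-Gly (pseudo)\n")
        assert parse_annotation_tsv(path)[0].pseudo is True

    def test_malformed_coordinates_name_line(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(BAKTA_HEADER + "c1\ttRNA\tten\t85\t+\t\t\ttRNA-Ala\n")
        with pytest.raises(FormatError, match="line 3"):
            parse_annotation_tsv(path)


class TestAnnotationGff3:
    def test_product_attribute_and_directives(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tBakta\ttRNA\t10\t85\t.\t+\t.\tID=t1;product=tRNA-Gly\n"
            "c1\tBakta\trRNA\t200\t1699\t.\t-\t.\tID=r1;gene=rrs;"
            "product=16S ribosomal RNA\n"
        )
        trna, rrna = parse_annotation_gff3(path)
        assert trna.product == "tRNA-Gly"
        assert trna.strand == "+"
        assert rrna.gene == "rrs"
        assert rrna.length == 1500

    def test_fasta_trailer_stops_parsing(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "c1\tBakta\ttRNA\t10\t85\t.\t+\t.\tproduct=tRNA-Gly\n"
            "##FASTA\n>c1\nACGTACGT\n"
        )
        assert len(parse_annotation_gff3(path)) == 1

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text("c1\tBakta\ttRNA\t10\t85\t.\t+\t.\n")
        with pytest.raises(FormatError, match="line 1"):
            parse_annotation_gff3(path)

    def test_percent_encoded_product_is_decoded(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "c1\tBakta\trRNA\t1\t120\t.\t+\t.\tproduct=5S%20ribosomal%20RNA\n"
        )
        assert parse_annotation_gff3(path)[0].product == "5S ribosomal RNA"

    def test_unknown_strand_stored_as_question_mark(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text("c1\tsrc\ttRNA\t1\t75\t.\t.\t.\tproduct=tRNA-Ala\n")
        assert parse_annotation_gff3(path)[0].strand == "?"


def _rows():
    return [
        MetadataRow(
            bin_id=f"bin{i}",
            assembly_quality="High quality" if i else "Failed",
            completeness=95.5 - i,
            contamination=2.25 * i,
            completeness_software="CheckM v1.0.13",
            rrna_16s_recovered=bool(i),
            rrna_16s_software="Bakta v1.7.0",
            trna_extracted=18 + i,
            trna_software="Bakta v1.7.0",
            completeness_approach="Marker gene",
            size_bp=2_000_000 + i,
            n50_bp=50_000,
            max_contig_bp=120_000,
            n_contigs=80,
            rrna_5s_recovered=True,
            rrna_23s_recovered=bool(i),
        )
        for i in range(3)
    ]


class TestMetadataCsv:
    def test_header_plus_one_line_per_row(self, tmp_path):
        path = tmp_path / "meta.csv"
        write_metadata_csv(_rows(), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4

    def test_round_trip_is_field_exact(self, tmp_path):
        path = tmp_path / "meta.csv"
        rows = _rows()
        write_metadata_csv(rows, path)
        assert read_metadata_csv(path) == rows

    def test_empty_rows_is_error(self, tmp_path):
        with pytest.raises(FormatError):
            write_metadata_csv([], tmp_path / "meta.csv")


class TestDomainInvariants:
    def test_feature_length_is_one_based_inclusive(self):
        f = AnnotationFeature("c", FeatureType.RRNA, 1, 120, "+", "5S")
        assert f.length == 120

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            AnnotationFeature("c", FeatureType.TRNA, 10, 5)
        with pytest.raises(ValueError):
            AnnotationFeature("c", FeatureType.TRNA, 0, 5)

    def test_bin_record_rejects_non_positive_length(self):
        with pytest.raises(ValueError):
            BinRecord("b", "b.fa", {"c1": 0})

    def test_quality_estimate_bounds(self):
        with pytest.raises(ValueError):
            QualityEstimate("b", 101.0, 2.0)
        with pytest.raises(ValueError):
            QualityEstimate("b", 50.0, -1.0)
        # CheckM contamination legitimately exceeds 100
        assert QualityEstimate("b", 50.0, 180.0).contamination == 180.0

    @pytest.mark.parametrize(
        "name,expected",
        [("binA.fa", "binA"), ("binA.fna", "binA"), ("binA.FASTA", "binA"),
         ("binA.fa.fa", "binA.fa"), ("binA.txt", "binA.txt")],
    )
    def test_strip_exactly_one_extension(self, name, expected):
        assert strip_bin_extension(name) == expected
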