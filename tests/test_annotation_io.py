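import pytest
from hypothesis import given, settings, strategies as st

from asrna_screen import annotation_io
from asrna_screen.exceptions import (
    DuplicateIdentifierError,
    InvalidSequenceError,
    InvalidStrandError,
    MalformedRecordError,
    TableParseError,
)
from asrna_screen.records import GenomicInterval, Strand


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestGeneAnnotation:
    def test_gff3_gene_line_maps_directly(self, tmp_path):
        path = write(
            tmp_path,
            "g.gff3",
            "##gff-version 3\nchrT\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=SCOT001\n",
        )
        (rec,) = annotation_io.read_gene_annotation(path, "gff3")
        assert rec.gene_id == "SCOT001"
        assert rec.interval == GenomicInterval("chrT", 1001, 2000, Strand.PLUS)

    def test_bed6_converts_to_one_based_inclusive(self, tmp_path):
        path = write(tmp_path, "g.bed", "chrT\t1000\t2000\tSCOT001\t0\t+\n")
        (rec,) = annotation_io.read_gene_annotation(path, "bed6")
        assert (rec.interval.start, rec.interval.end) == (1001, 2000)

    def test_reversed_coordinates_raise_with_line_number(self, tmp_path):
        path = write(
            tmp_path, "g.gff3", "chrT\tsrc\tgene\t2000\t1001\t.\t+\t.\tID=SCOT001\n"
        )
        with pytest.raises(MalformedRecordError, match="line 1"):
            annotation_io.read_gene_annotation(path, "gff3")

    def test_duplicate_gene_id_raises(self, tmp_path):
        path = write(
            tmp_path,
            "g.gff3",
            "chrT\ts\tgene\t1\t10\t.\t+\t.\tID=A\nchrT\ts\tgene\t20\t30\t.\t-\t.\tID=A\n",
        )
        with pytest.raises(DuplicateIdentifierError, match="A"):
            annotation_io.read_gene_annotation(path, "gff3")

    def test_unknown_strand_for_gene_raises(self, tmp_path):
        path = write(tmp_path, "g.bed", "chrT\t0\t10\tA\t0\t.\n")
        with pytest.raises(InvalidStrandError):
            annotation_io.read_gene_annotation(path, "bed6")

    def test_sorted_by_chrom_start_then_id(self, tmp_path):
        path = write(
            tmp_path,
            "g.gff3",
            "chrB\ts\tgene\t5\t9\t.\t+\t.\tID=Z\n"
            "chrA\ts\tgene\t5\t9\t.\t+\t.\tID=B\n"
            "chrA\ts\tgene\t5\t9\t.\t-\t.\tID=A\n",
        )
        ids = [r.gene_id for r in annotation_io.read_gene_annotation(path, "gff3")]
        assert ids == ["A", "B", "Z"]


class TestSrnaCatalog:
    def test_dot_strand_is_unknown(self, tmp_path):
        path = write(tmp_path, "s.bed", "chrT\t2049\t2150\ts3\t0\t.\n")
        (rec,) = annotation_io.read_srna_catalog(path, source="cat1")
        assert rec.interval == GenomicInterval("chrT", 2050, 2150, Strand.UNKNOWN)
        assert rec.source == "cat1"

    def test_conflicting_duplicate_raises(self, tmp_path):
        path = write(tmp_path, "s.bed", "chrT\t0\t10\ts1\t0\t+\nchrT\t50\t60\ts1\t0\t+\n")
        with pytest.raises(DuplicateIdentifierError):
            annotation_io.read_srna_catalog(path)

    def test_empty_file_gives_empty_catalog(self, tmp_path):
        assert annotation_io.read_srna_catalog(write(tmp_path, "s.bed", "")) == []


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 10_000),
            st.integers(1, 500),
            st.sampled_from([Strand.PLUS, Strand.MINUS, Strand.UNKNOWN]),
        ),
        min_size=1,
        max_size=20,
        unique_by=lambda t: t[0],
    )
)
def test_bed_round_trip_preserves_intervals(tmp_path_factory, triples):
    """Writing sRNAs to BED6 and re-reading reproduces identical intervals."""
    from asrna_screen.records import SmallRNARecord

    records = [
        SmallRNARecord(f"s{i}", GenomicInterval("chrT", start, start + length - 1, strand))
        for i, (start, length, strand) in enumerate(triples)
    ]
    path = tmp_path_factory.mktemp("roundtrip") / "srnas.bed"
    annotation_io.write_bed6(records, path)
    reread = annotation_io.read_srna_catalog(path)
    assert {r.srna_id: r.interval for r in reread} == {
        r.srna_id: r.interval for r in records
    }


class TestGenome:
    def test_two_records_lengths_preserved(self, tmp_path):
        path = write(tmp_path, "g.fa", ">a\nACGT\n>b\nACGTACGT\n")
        genome = annotation_io.read_genome(path)
        assert {k: len(v) for k, v in genome.items()} == {"a": 4, "b": 8}

    def test_wrapped_record_concatenated(self, tmp_path):
        seq = "ACGT" * 40
        wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        genome = annotation_io.read_genome(write(tmp_path, "g.fa", f">a\n{wrapped}\n"))
        assert genome["a"] == seq

    def test_invalid_character_raises_with_position(self, tmp_path):
        with pytest.raises(InvalidSequenceError, match="position 3"):
            annotation_io.read_genome(write(tmp_path, "g.fa", ">a\nACXT\n"))


class TestExpressionTables:
    def test_merge_on_gene_id(self, tmp_path):
        de = write(tmp_path, "de.tsv", "gene_id\tfold\nSCO2198\t2.9\n")
        bard = write(tmp_path, "bard.tsv", "gene_id\tbard_ratio\nSCO2198\t12.4\n")
        (ev,) = annotation_io.read_expression_tables(de, bard)
        assert ev.fold_changes == {"fold": 2.9}
        assert ev.bard_ratio == 12.4

    def test_gene_only_in_bard_table(self, tmp_path):
        de = write(tmp_path, "de.tsv", "gene_id\tfold\nSCO0001\t3.0\n")
        bard = write(tmp_path, "bard.tsv", "gene_id\tbard_ratio\nSCO0002\t5.0\n")
        evidence = {e.gene_id: e for e in annotation_io.read_expression_tables(de, bard)}
        assert evidence["SCO0002"].fold_changes == {}
        assert evidence["SCO0002"].bard_ratio == 5.0

    def test_non_numeric_fold_names_cell(self, tmp_path):
        de = write(tmp_path, "de.tsv", "gene_id\tfold\nSCO0001\tn/a\n")
        with pytest.raises(TableParseError, match="fold"):
            annotation_io.read_expression_tables(de, None)

    def test_missing_cell_recorded_as_absent(self, tmp_path):
        de = write(tmp_path, "de.tsv", "gene_id\tf24\tf48\nSCO1\t\t2.5\n")
        (ev,) = annotation_io.read_expression_tables(de, None)
        assert ev.fold_changes == {"f48": 2.5}
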