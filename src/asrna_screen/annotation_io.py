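"""Readers and writers for GFF3, BED6, FASTA and the evidence TSV tables.

Everything entering the toolkit passes through here and comes out in the one
internal coordinate convention (1-based, inclusive). BED's 0-based half-open
coordinates are converted on read and write; nothing downstream ever sees
them.

TSV dialect: tab-separated, UTF-8, lines starting with ``#`` skipped.
"""
from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .exceptions import (
    DuplicateIdentifierError,
    InvalidSequenceError,
    InvalidStrandError,
    MalformedRecordError,
    TableParseError,
)
from .records import ExpressionEvidence, GeneRecord, GenomicInterval, SmallRNARecord, Strand

PathLike = Union[str, Path]

GENOME_ALPHABET = frozenset("ACGTN")

#: GFF3 feature types accepted as gene records.
_GENE_TYPES = frozenset({"gene", "CDS"})


def _iter_data_lines(path: PathLike) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _sorted_genes(records: List[GeneRecord]) -> List[GeneRecord]:
    # stable total order: (chrom, start), ties by gene_id
    return sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.gene_id))


def read_gene_annotation(path: PathLike, format: str = "gff3") -> List[GeneRecord]:
    """Load gene records from a GFF3 or BED6 file.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"gff3"`` (coordinates used as-is) or ``"bed6"`` (converted from
        0-based half-open to 1-based inclusive).

    Returns
    -------
    list of GeneRecord sorted by (chromosome, start, gene id).
    """
    if format not in ("gff3", "bed6"):
        raise ValueError(f"format must be 'gff3' or 'bed6', got {format!r}")
    records: List[GeneRecord] = []
    seen: Dict[str, int] = {}
    for lineno, line in _iter_data_lines(path):
        if format == "gff3":
            rec = _gene_from_gff3_line(line, lineno)
            if rec is None:
                continue
        else:
            rec = _gene_from_bed6_line(line, lineno)
        if rec.gene_id in seen:
            raise DuplicateIdentifierError(
                f"{path}: duplicate gene_id {rec.gene_id!r} "
                f"(lines {seen[rec.gene_id]} and {lineno})"
            )
        seen[rec.gene_id] = lineno
        records.append(rec)
    return _sorted_genes(records)


def _gene_from_gff3_line(line: str, lineno: int) -> Optional[GeneRecord]:
    fields = line.split("\t")
    if len(fields) != 9:
        raise MalformedRecordError(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
    if fields[2] not in _GENE_TYPES:
        return None
    try:
        feature = feature_from_line(line)
    except Exception as exc:  # malformed attribute column etc.
        raise MalformedRecordError(f"line {lineno}: unparseable GFF3 record ({exc})") from exc
    if feature.end < feature.start:
        raise MalformedRecordError(
            f"line {lineno}: end ({feature.end}) < start ({feature.start})"
        )
    if feature.strand not in ("+", "-"):
        raise InvalidStrandError(
            f"line {lineno}: gene strand must be '+' or '-', got {feature.strand!r}"
        )
    gene_id = feature.attributes.get("ID", [None])[0] or feature.attributes.get("Name", [None])[0]
    if not gene_id:
        raise MalformedRecordError(f"line {lineno}: gene feature lacks an ID attribute")
    product = (feature.attributes.get("product") or [""])[0]
    interval = GenomicInterval(
        feature.seqid, int(feature.start), int(feature.end), Strand.from_symbol(feature.strand)
    )
    return GeneRecord(gene_id, interval, product)


def _parse_bed6_fields(line: str, lineno: int) -> tuple[str, int, int, str, str]:
    fields = line.split("\t")
    if len(fields) < 6:
        raise MalformedRecordError(f"line {lineno}: expected >= 6 BED columns, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    try:
        bed_start, bed_end = int(start_s), int(end_s)
    except ValueError as exc:
        raise MalformedRecordError(f"line {lineno}: non-integer BED coordinate") from exc
    # BED 0-based half-open -> 1-based inclusive
    start, end = bed_start + 1, bed_end
    if end < start:
        raise MalformedRecordError(
            f"line {lineno}: end ({end}) < start ({start}) after coordinate conversion"
        )
    return chrom, start, end, name, strand


def _gene_from_bed6_line(line: str, lineno: int) -> GeneRecord:
    chrom, start, end, name, strand = _parse_bed6_fields(line, lineno)
    if strand not in ("+", "-"):
        raise InvalidStrandError(
            f"line {lineno}: gene strand must be '+' or '-', got {strand!r}"
        )
    return GeneRecord(name, GenomicInterval(chrom, start, end, Strand.from_symbol(strand)))


def read_srna_catalog(path: PathLike, source: str = "") -> List[SmallRNARecord]:
    """Load an sRNA catalog from BED6; a ``.`` strand becomes ``Strand.UNKNOWN``.

    Identical duplicate rows are collapsed; the same srna_id at different
    coordinates raises :class:`DuplicateIdentifierError`.
    """
    records: Dict[str, SmallRNARecord] = {}
    for lineno, line in _iter_data_lines(path):
        chrom, start, end, name, strand = _parse_bed6_fields(line, lineno)
        if strand not in ("+", "-", "."):
            raise InvalidStrandError(
                f"line {lineno}: sRNA strand must be '+', '-' or '.', got {strand!r}"
            )
        rec = SmallRNARecord(
            name, GenomicInterval(chrom, start, end, Strand.from_symbol(strand)), source=source
        )
        if name in records:
            if records[name].interval != rec.interval:
                raise DuplicateIdentifierError(
                    f"{path}: srna_id {name!r} re-declared with conflicting coordinates "
                    f"(line {lineno})"
                )
            continue
        records[name] = rec
    return sorted(records.values(), key=lambda r: (r.interval.chrom, r.interval.start, r.srna_id))


def write_bed6(features: Sequence[Union[GeneRecord, SmallRNARecord]], path: PathLike) -> None:
    """Write gene or sRNA records as BED6 (converting back to 0-based half-open)."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in features:
            iv = rec.interval
            name = rec.gene_id if isinstance(rec, GeneRecord) else rec.srna_id
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand.value}\n"
            )


def write_gff3(genes: Sequence[GeneRecord], path: PathLike, source: str = "asrna_screen") -> None:
    """Write gene records as a minimal GFF3 file."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            attrs = f"ID={gene.gene_id}"
            if gene.product:
                attrs += f";product={gene.product}"
            handle.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand.value}\t.\t{attrs}\n"
            )


def read_genome(path: PathLike) -> Dict[str, str]:
    """Read a FASTA genome into ``{chromosome id: uppercase sequence}``.

    Multi-line records are concatenated; any character outside {A,C,G,T,N}
    raises :class:`InvalidSequenceError` naming the chromosome and position.
    """
    genome: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise DuplicateIdentifierError(f"{path}: duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in GENOME_ALPHABET), None)
        if bad is not None:
            raise InvalidSequenceError(
                f"{path}: record {record.id!r} position {bad + 1}: "
                f"invalid character {seq[bad]!r}"
            )
        genome[record.id] = seq
    return genome


def write_genome(genome: Dict[str, str], path: PathLike, width: int = 70) -> None:
    """Write a genome mapping as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as handle:
        for chrom, seq in genome.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _read_tsv(path: PathLike) -> pd.DataFrame:
    # keep_default_na=False: only an EMPTY cell is "absent"; tokens like "n/a"
    # are parse errors, not silently-missing data
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, encoding="utf-8", keep_default_na=False
    )


def read_expression_tables(
    de_path: Optional[PathLike], bard_path: Optional[PathLike]
) -> List[ExpressionEvidence]:
    """Merge a differential-expression TSV and a BARD enrichment TSV on gene id.

    The DE table has a ``gene_id`` column plus one column per time point; the
    BARD table has ``gene_id`` and ``bard_ratio``. Empty cells are recorded as
    absent evidence, never as zero. Non-numeric cells raise
    :class:`TableParseError` naming the cell.
    """
    folds: Dict[str, Dict[str, float]] = {}
    bard: Dict[str, float] = {}
    if de_path is not None:
        de = _read_tsv(de_path)
        if "gene_id" not in de.columns:
            raise TableParseError(f"{de_path}: missing required column 'gene_id'")
        time_cols = [c for c in de.columns if c != "gene_id"]
        for row_idx, row in de.iterrows():
            gene = row["gene_id"]
            gene_folds: Dict[str, float] = {}
            for col in time_cols:
                cell = row[col]
                if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                    continue
                try:
                    gene_folds[col] = float(cell)
                except ValueError as exc:
                    raise TableParseError(
                        f"{de_path}: row {row_idx + 2}, column {col!r}: "
                        f"non-numeric fold value {cell!r}"
                    ) from exc
            folds[gene] = gene_folds
    if bard_path is not None:
        bt = _read_tsv(bard_path)
        for required in ("gene_id", "bard_ratio"):
            if required not in bt.columns:
                raise TableParseError(f"{bard_path}: missing required column {required!r}")
        for row_idx, row in bt.iterrows():
            cell = row["bard_ratio"]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                continue
            try:
                bard[row["gene_id"]] = float(cell)
            except ValueError as exc:
                raise TableParseError(
                    f"{bard_path}: row {row_idx + 2}, column 'bard_ratio': "
                    f"non-numeric value {cell!r}"
                ) from exc
    evidence = []
    for gene_id in sorted(set(folds) | set(bard)):
        evidence.append(
            ExpressionEvidence(
                gene_id,
                fold_changes=folds.get(gene_id, {}),
                bard_ratio=bard.get(gene_id),
            )
        )
    return evidence
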