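"""Shared domain types: genomic intervals, gene and sRNA records, expression evidence.

All coordinates are 1-based inclusive (GFF convention). BED input is converted
at the I/O boundary, never inside the analysis code.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .exceptions import InvalidStrandError, MalformedRecordError


class Strand(enum.Enum):
    """Strand of a genomic feature; UNKNOWN is legal only for sRNA genes."""

    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        for member in cls:
            if member.value == symbol:
                return member
        raise InvalidStrandError(f"unknown strand symbol {symbol!r}")

    @property
    def opposite(self) -> "Strand":
        if self is Strand.PLUS:
            return Strand.MINUS
        if self is Strand.MINUS:
            return Strand.PLUS
        return Strand.UNKNOWN


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on one strand of a chromosome (1-based)."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise MalformedRecordError("interval chromosome id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise MalformedRecordError(
                f"interval requires 1 <= start <= end, got {self.start}..{self.end}"
            )
        if not isinstance(self.strand, Strand):
            raise InvalidStrandError(f"strand must be a Strand, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Length of the coordinate intersection, 0 when disjoint or trans-chromosomal."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def gap_nt(self, other: "GenomicInterval") -> Optional[int]:
        """Nucleotides strictly between the intervals; 0 if they overlap or abut.

        ``None`` for intervals on different chromosomes (distance undefined).
        """
        if self.chrom != other.chrom:
            return None
        if self.overlap_nt(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end) - 1

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap_nt(other) > 0


@dataclass(frozen=True)
class GeneRecord:
    """An annotated protein-coding gene; strand is always known."""

    gene_id: str
    interval: GenomicInterval
    product: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise MalformedRecordError("gene_id must be non-empty")
        if self.interval.strand is Strand.UNKNOWN:
            raise InvalidStrandError(
                f"gene {self.gene_id}: genes must lie on a definite strand"
            )

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the start codon's first base."""
        return self.interval.start if self.interval.strand is Strand.PLUS else self.interval.end

    @property
    def three_prime_pos(self) -> int:
        """Genomic coordinate of the gene's last (3') base."""
        return self.interval.end if self.interval.strand is Strand.PLUS else self.interval.start


@dataclass(frozen=True)
class SmallRNARecord:
    """A small-RNA gene from a catalog; the strand may be unknown (ambiguous)."""

    srna_id: str
    interval: GenomicInterval
    source: str = ""
    status: str = "predicted"  # {predicted, confirmed}

    def __post_init__(self) -> None:
        if not self.srna_id:
            raise MalformedRecordError("srna_id must be non-empty")
        if self.status not in ("predicted", "confirmed"):
            raise MalformedRecordError(
                f"sRNA {self.srna_id}: status must be 'predicted' or 'confirmed'"
            )


@dataclass(frozen=True)
class ExpressionEvidence:
    """Differential-expression and RNase III-binding evidence for one gene.

    ``fold_changes`` maps a time-point label to a signed fold change in the
    rnc mutant relative to wild type; ``bard_ratio`` is the enrichment of the
    mRNA in the cleavage-dead RNase III co-immunoprecipitation (BARD). Either
    kind of evidence may be absent.
    """

    gene_id: str
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    bard_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise MalformedRecordError("gene_id must be non-empty")
        for label, value in self.fold_changes.items():
            if not math.isfinite(value) or value == 0:
                raise MalformedRecordError(
                    f"gene {self.gene_id}: fold change at {label!r} must be finite "
                    f"and nonzero, got {value!r}"
                )
        if self.bard_ratio is not None and not self.bard_ratio > 0:
            raise MalformedRecordError(
                f"gene {self.gene_id}: BARD ratio must be > 0, got {self.bard_ratio!r}"
            )
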