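"""Strand-aware classification of gene–sRNA relationships.

A small-RNA gene near a protein-coding gene can stand in a handful of
biologically distinct relationships to it. The classifier partitions every
same-chromosome pair into exactly one category:

* ``CIS_AS_5PRIME`` — antisense sRNA whose span touches the gene's 5' window
  (the ribosome binding site and start codon region); the classic cis-asRNA
  poised to block translation initiation.
* ``CUTORNA`` — convergent overlapping transcript acting on the messenger's
  3' end: antisense overlap (or an in-window gap on the 3' side) confined to
  the 3' terminus.
* ``CIS_AS_OTHER`` — any other antisense overlap or in-window antisense
  neighbour touching neither window (keeps the antisense partition total).
* ``AMBIGUOUS`` — the sRNA catalog does not record a strand, but the sRNA
  overlaps or neighbours the gene.
* ``SENSE_OVERLAP`` — same-strand overlap (not an antisense candidate).
* ``NONE`` — no overlap and the gap exceeds the adjacency window.

Precedence for antisense sRNAs touching both windows is 5' over 3': primer
and probe design in this screen targets the 5' region, so 5' evidence
dominates. "Neighbouring" has no published distance; it is the configurable
``adjacency_window`` (default 100 nt).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .exceptions import MalformedRecordError
from .records import GeneRecord, GenomicInterval, SmallRNARecord, Strand


class Category(enum.Enum):
    CIS_AS_5PRIME = "CIS_AS_5PRIME"
    CUTORNA = "CUTORNA"
    CIS_AS_OTHER = "CIS_AS_OTHER"
    AMBIGUOUS = "AMBIGUOUS"
    SENSE_OVERLAP = "SENSE_OVERLAP"
    NONE = "NONE"


#: Categories that make an sRNA a plausible antisense partner of the gene.
ANTISENSE_CATEGORIES = frozenset(
    {Category.CIS_AS_5PRIME, Category.CUTORNA, Category.CIS_AS_OTHER, Category.AMBIGUOUS}
)


@dataclass(frozen=True)
class ClassifierParams:
    """Window geometry for the orientation rules (all values in nt, >= 0).

    ``five_prime_upstream``/``five_prime_downstream`` delimit the 5' window
    around the start codon: by default 15 nt upstream (covering a typical
    ribosome binding site) through 3 nt into the coding sequence (the start
    codon itself). ``three_prime_inside``/``three_prime_downstream`` delimit
    the 3' window: the last 50 nt of the gene plus 50 nt past its end.
    """

    adjacency_window: int = 100
    five_prime_upstream: int = 15
    five_prime_downstream: int = 3
    three_prime_inside: int = 50
    three_prime_downstream: int = 50

    def __post_init__(self) -> None:
        for name in (
            "adjacency_window",
            "five_prime_upstream",
            "five_prime_downstream",
            "three_prime_inside",
            "three_prime_downstream",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class OrientationCall:
    """A classified gene–sRNA relationship."""

    gene_id: str
    srna_id: str
    category: Category
    overlap_nt: int
    gap_nt: int
    arrows: str = ""

    def __post_init__(self) -> None:
        if self.overlap_nt < 0 or self.gap_nt < 0:
            raise MalformedRecordError("overlap_nt and gap_nt must be >= 0")
        if self.overlap_nt > 0 and self.gap_nt != 0:
            raise MalformedRecordError("overlapping features have zero gap by definition")


def five_prime_window(gene: GeneRecord, params: ClassifierParams) -> GenomicInterval:
    """The strand-aware RBS + start-codon window of a gene.

    For a plus-strand gene starting at ``s`` this is
    ``[s - five_prime_upstream, s + five_prime_downstream]``; mirrored for
    minus-strand genes. Coordinates are clipped at 1.
    """
    iv = gene.interval
    if iv.strand is Strand.PLUS:
        lo = iv.start - params.five_prime_upstream
        hi = iv.start + params.five_prime_downstream
    else:
        lo = iv.end - params.five_prime_downstream
        hi = iv.end + params.five_prime_upstream
    return GenomicInterval(iv.chrom, max(1, lo), max(1, hi), iv.strand)


def three_prime_window(gene: GeneRecord, params: ClassifierParams) -> GenomicInterval:
    """The strand-aware 3'-terminus window of a gene (inside + downstream)."""
    iv = gene.interval
    inside = max(0, params.three_prime_inside - 1)
    if iv.strand is Strand.PLUS:
        lo = iv.end - inside
        hi = iv.end + params.three_prime_downstream
    else:
        lo = iv.start - params.three_prime_downstream
        hi = iv.start + inside
    return GenomicInterval(iv.chrom, max(1, lo), max(1, hi), iv.strand)


def _is_three_prime_side(gene: GeneRecord, srna: SmallRNARecord) -> bool:
    """True when a non-overlapping sRNA lies beyond the gene's 3' end."""
    if gene.interval.strand is Strand.PLUS:
        return srna.interval.start > gene.interval.end
    return srna.interval.end < gene.interval.start


def classify_pair(
    gene: GeneRecord, srna: SmallRNARecord, params: ClassifierParams = ClassifierParams()
) -> OrientationCall:
    """Classify one gene–sRNA pair into exactly one orientation category.

    The rules apply in order; the first that matches wins:

    1. unknown sRNA strand and (overlap, or gap <= adjacency_window) -> AMBIGUOUS
    2. antisense and sRNA intersects the 5' window -> CIS_AS_5PRIME
    3. antisense and (sRNA intersects the 3' window, or lies within the
       adjacency window on the 3' side) -> CUTORNA
    4. antisense with any other overlap or in-window gap -> CIS_AS_OTHER
    5. same strand with overlap -> SENSE_OVERLAP
    6. otherwise NONE
    """
    g, s = gene.interval, srna.interval
    if g.chrom != s.chrom:
        return OrientationCall(gene.gene_id, srna.srna_id, Category.NONE, 0, 0)
    overlap = g.overlap_nt(s)
    gap = g.gap_nt(s)
    assert gap is not None
    near = overlap > 0 or gap <= params.adjacency_window

    category = Category.NONE
    if s.strand is Strand.UNKNOWN:
        if near:
            category = Category.AMBIGUOUS
    elif s.strand is g.strand.opposite:
        if s.intersects(five_prime_window(gene, params)):
            category = Category.CIS_AS_5PRIME
        elif s.intersects(three_prime_window(gene, params)) or (
            overlap == 0 and near and _is_three_prime_side(gene, srna)
        ):
            category = Category.CUTORNA
        elif near:
            category = Category.CIS_AS_OTHER
    else:  # same strand
        if overlap > 0:
            category = Category.SENSE_OVERLAP
    return OrientationCall(gene.gene_id, srna.srna_id, category, overlap, gap if overlap == 0 else 0)


def classify_catalog(
    genes: Sequence[GeneRecord],
    srnas: Sequence[SmallRNARecord],
    params: ClassifierParams = ClassifierParams(),
    best_partner_only: bool = False,
) -> List[OrientationCall]:
    """Classify every gene–sRNA pair within reach; drop NONE calls.

    For each sRNA, every gene whose interval lies within ``adjacency_window``
    of it (found via an interval tree per chromosome) is classified. With
    ``best_partner_only`` one call per sRNA is kept, ties broken by smaller
    gap, then larger overlap, then lexicographic gene id. Output order is
    deterministic: (gene_id, srna_id).
    """
    by_chrom: Dict[str, IntervalTree] = {}
    gene_index: Dict[Tuple[str, int], GeneRecord] = {}
    for idx, gene in enumerate(genes):
        iv = gene.interval
        by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, idx)
        gene_index[(iv.chrom, idx)] = gene

    calls: List[OrientationCall] = []
    for srna in srnas:
        iv = srna.interval
        tree = by_chrom.get(iv.chrom)
        if tree is None:
            continue
        lo = iv.start - params.adjacency_window
        hi = iv.end + 1 + params.adjacency_window
        candidates = sorted(tree.overlap(lo, hi), key=lambda node: node.data)
        srna_calls = []
        for node in candidates:
            gene = gene_index[(iv.chrom, node.data)]
            call = classify_pair(gene, srna, params)
            if call.category is not Category.NONE:
                srna_calls.append(call)
        if best_partner_only and srna_calls:
            srna_calls = [min(srna_calls, key=lambda c: (c.gap_nt, -c.overlap_nt, c.gene_id))]
        calls.extend(srna_calls)
    calls.sort(key=lambda c: (c.gene_id, c.srna_id))
    return calls


_GENE_ARROWS = {Strand.PLUS: "->", Strand.MINUS: "<-"}
_SRNA_ARROWS = {Strand.PLUS: "=>", Strand.MINUS: "<=", Strand.UNKNOWN: "*"}


def render_arrows(
    left: Optional[GeneRecord],
    srna: SmallRNARecord,
    right: Optional[GeneRecord] = None,
) -> str:
    """Render the locus as the survey's arrow notation, left to right.

    Genes render ``->``/``<-`` by strand, the sRNA renders ``=>``/``<=`` or
    ``*`` when its strand is unknown; absent flanking genes are omitted.
    """
    tokens = []
    if left is not None:
        tokens.append(_GENE_ARROWS[left.interval.strand])
    tokens.append(_SRNA_ARROWS[srna.interval.strand])
    if right is not None:
        tokens.append(_GENE_ARROWS[right.interval.strand])
    return " ".join(tokens)


def calls_to_table(calls: Sequence[OrientationCall]):
    """Orientation calls as a tidy DataFrame (the export format of the screen)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "srna_id": c.srna_id,
                "category": c.category.value,
                "overlap_nt": c.overlap_nt,
                "gap_nt": c.gap_nt,
                "arrows": c.arrows,
            }
            for c in calls
        ],
        columns=["gene_id", "srna_id", "category", "overlap_nt", "gap_nt", "arrows"],
    )
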