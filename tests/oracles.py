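"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's interval arithmetic: intervals become
explicit position sets and every rule is evaluated by set intersection, so
agreement with the fast implementations is meaningful.
"""
from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Set, Tuple

from asrna_screen.orientation import Category, ClassifierParams
from asrna_screen.records import GeneRecord, SmallRNARecord, Strand

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def _positions(start: int, end: int) -> Set[int]:
    return set(range(start, end + 1))


def oracle_classify(
    gene: GeneRecord, srna: SmallRNARecord, params: ClassifierParams
) -> Tuple[Category, int, int]:
    """(category, overlap_nt, gap_nt) by explicit position-set enumeration."""
    g_iv, s_iv = gene.interval, srna.interval
    if g_iv.chrom != s_iv.chrom:
        return Category.NONE, 0, 0
    g = _positions(g_iv.start, g_iv.end)
    s = _positions(s_iv.start, s_iv.end)
    overlap = len(g & s)
    if overlap:
        gap = 0
    elif s_iv.start > g_iv.end:
        gap = s_iv.start - g_iv.end - 1
    else:
        gap = g_iv.start - s_iv.end - 1
    near = overlap > 0 or gap <= params.adjacency_window

    if g_iv.strand is Strand.PLUS:
        five = _positions(
            max(1, g_iv.start - params.five_prime_upstream),
            g_iv.start + params.five_prime_downstream,
        )
        three = _positions(
            max(1, g_iv.end - (params.three_prime_inside - 1)),
            g_iv.end + params.three_prime_downstream,
        )
        downstream_side = min(s) > g_iv.end
    else:
        five = _positions(
            max(1, g_iv.end - params.five_prime_downstream),
            g_iv.end + params.five_prime_upstream,
        )
        three = _positions(
            max(1, g_iv.start - params.three_prime_downstream),
            g_iv.start + (params.three_prime_inside - 1),
        )
        downstream_side = max(s) < g_iv.start

    if s_iv.strand is Strand.UNKNOWN:
        category = Category.AMBIGUOUS if near else Category.NONE
    elif s_iv.strand is not g_iv.strand:  # antisense
        if s & five:
            category = Category.CIS_AS_5PRIME
        elif s & three or (overlap == 0 and near and downstream_side):
            category = Category.CUTORNA
        elif near:
            category = Category.CIS_AS_OTHER
        else:
            category = Category.NONE
    else:
        category = Category.SENSE_OVERLAP if overlap else Category.NONE
    return category, overlap, gap


def oracle_trans_scan(
    query: str, genome: Mapping[str, str], min_identity: float
) -> List[Tuple[str, int, str, float]]:
    """All (chrom, start_1based, strand, identity) windows, unmerged, by direct comparison."""
    q = len(query)
    hits = []
    for chrom, contig in genome.items():
        for strand, seq in (("+", contig), ("-", revcomp(contig))):
            for off in range(len(seq) - q + 1):
                window = seq[off : off + q]
                ident = sum(a == b for a, b in zip(window, query)) / q
                if ident >= min_identity:
                    start = off + 1 if strand == "+" else len(contig) - (off + q) + 1
                    hits.append((chrom, start, strand, ident))
    return hits


def oracle_best_oligo(
    contig: str,
    win_lo: int,
    win_hi: int,
    gene_strand: Strand,
    min_len: int,
    max_len: int,
    tm_min: float,
    tm_max: float,
    gc_min: float,
    gc_max: float,
) -> Optional[Tuple[str, int, int]]:
    """Exhaustively scan every footprint containing [win_lo, win_hi] (1-based).

    Returns (sequence, start, end) of the winner under the published rule:
    Tm closest to the Tm-band midpoint, ties to shorter then leftmost.
    """
    candidates = []
    for start in range(1, win_lo + 1):
        for end in range(win_hi, len(contig) + 1):
            length = end - start + 1
            if not (min_len <= length <= max_len):
                continue
            footprint = contig[start - 1 : end]
            seq = footprint if gene_strand is Strand.PLUS else revcomp(footprint)
            if "N" in seq:
                continue
            at = seq.count("A") + seq.count("T")
            gc = seq.count("G") + seq.count("C")
            tm = 2 * at + 4 * gc
            gcf = gc / length
            if tm_min <= tm <= tm_max and gc_min <= gcf <= gc_max:
                midpoint = (tm_min + tm_max) / 2
                candidates.append((abs(tm - midpoint), length, start, seq, end))
    if not candidates:
        return None
    _, _, start, seq, end = min(candidates)
    return seq, start, end
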