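"""RACE oligo design, virtual RT-PCR and trans-target complementarity scans.

Melting temperatures use the Wallace rule (Tm = 2(A+T) + 4(G+C)), which is
deterministic and adequate for the short gene-specific primers used in RACE;
the Tm function is pluggable for users who prefer nearest-neighbour models.
Primer sites in the virtual PCR are exact matches only — the screen's primers
are exact genome substrings by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .exceptions import InsufficientFlankError, InvalidSequenceError
from .orientation import ClassifierParams, five_prime_window
from .records import GeneRecord, GenomicInterval, Strand

DNA_ALPHABET = frozenset("ACGT")

TmFunction = Callable[[str], float]


def wallace_tm(sequence: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C) °C."""
    return float(MeltingTemp.Tm_Wallace(sequence))


def _check_dna(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(f"invalid nucleotide(s) {sorted(bad)} in {sequence!r}")
    return seq


def reverse_complement(sequence: str) -> str:
    return str(Seq(_check_dna(sequence)).reverse_complement())


def oligo_metrics(sequence: str, tm_function: TmFunction = wallace_tm) -> Tuple[float, float, str]:
    """(melting temperature °C, GC fraction, reverse complement) of an oligo."""
    seq = _check_dna(sequence)
    return tm_function(seq), float(gc_fraction(seq)), reverse_complement(seq)


@dataclass(frozen=True)
class OligoConstraints:
    """Length / Tm / GC acceptance window for designed oligos."""

    min_len: int = 18
    max_len: int = 25
    tm_min: float = 55.0
    tm_max: float = 65.0
    gc_min: float = 0.4
    gc_max: float = 0.75

    def __post_init__(self) -> None:
        if self.min_len > self.max_len or self.min_len < 1:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.tm_min > self.tm_max:
            raise ValueError("need tm_min <= tm_max")
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")

    def admits(self, sequence: str, tm_function: TmFunction = wallace_tm) -> bool:
        tm, gc, _ = oligo_metrics(sequence, tm_function)
        return (
            self.min_len <= len(sequence) <= self.max_len
            and self.tm_min <= tm <= self.tm_max
            and self.gc_min <= gc <= self.gc_max
        )


@dataclass(frozen=True)
class OligoSpec:
    """A designed primer/probe with its genomic footprint and metrics."""

    sequence: str
    genome_interval: GenomicInterval
    tm_celsius: float
    gc_fraction: float
    role: str = "five_prime_race_primer"


def design_race_oligo(
    gene: GeneRecord,
    genome: Mapping[str, str],
    constraints: OligoConstraints = OligoConstraints(),
    window: ClassifierParams = ClassifierParams(),
    tm_function: TmFunction = wallace_tm,
    role: str = "five_prime_race_primer",
) -> Optional[OligoSpec]:
    """Design the gene-specific oligo covering the RBS and start codon.

    The oligo's genomic footprint must contain the whole 5' window
    (``five_prime_upstream`` nt before the start codon through
    ``five_prime_downstream`` nt into the gene, strand-aware) and its
    sequence is taken from the mRNA-sense strand, so it primes reverse
    transcription of the antisense transcript. Among candidates satisfying
    the constraints, the one whose Tm is closest to the midpoint of
    [tm_min, tm_max] wins; ties go to the shorter oligo, then the leftmost
    genomic position.

    Returns ``None`` when no candidate satisfies the constraints (a valid
    "no solution" outcome, distinct from the :class:`InsufficientFlankError`
    raised when the window falls off the contig).
    """
    chrom = gene.interval.chrom
    if chrom not in genome:
        raise InsufficientFlankError(f"chromosome {chrom!r} absent from genome")
    contig = genome[chrom]
    iv = gene.interval
    if iv.strand is Strand.PLUS:
        win_lo = iv.start - window.five_prime_upstream
        win_hi = iv.start + window.five_prime_downstream
    else:
        win_lo = iv.end - window.five_prime_downstream
        win_hi = iv.end + window.five_prime_upstream
    if win_lo < 1 or win_hi > len(contig):
        raise InsufficientFlankError(
            f"gene {gene.gene_id}: 5' window {win_lo}..{win_hi} extends past "
            f"contig {chrom!r} (length {len(contig)})"
        )
    window_len = win_hi - win_lo + 1
    if window_len > constraints.max_len:
        return None

    best: Optional[Tuple[float, int, int, OligoSpec]] = None
    for length in range(max(constraints.min_len, window_len), constraints.max_len + 1):
        # leftmost start so that [start, start+length-1] still contains the window
        for start in range(max(1, win_hi - length + 1), win_lo + 1):
            end = start + length - 1
            if end > len(contig):
                continue
            footprint = contig[start - 1 : end]
            sense_seq = footprint if iv.strand is Strand.PLUS else reverse_complement(footprint)
            if "N" in sense_seq:
                continue
            tm, gc, _ = oligo_metrics(sense_seq, tm_function)
            if not constraints.admits(sense_seq, tm_function):
                continue
            midpoint = (constraints.tm_min + constraints.tm_max) / 2
            key = (abs(tm - midpoint), length, start)
            spec = OligoSpec(
                sequence=sense_seq,
                genome_interval=GenomicInterval(chrom, start, end, iv.strand),
                tm_celsius=tm,
                gc_fraction=gc,
                role=role,
            )
            if best is None or key < best[:3]:
                best = (*key, spec)
    return best[3] if best is not None else None


@dataclass(frozen=True)
class AmpliconPrediction:
    """Outcome of a virtual PCR on one template."""

    found: bool
    product_length_nt: Optional[int] = None
    template_interval: Optional[GenomicInterval] = None
    fwd_match_pos: Optional[int] = None
    rev_match_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.found and self.product_length_nt is None:
            raise ValueError("found amplicons must carry a product length")


def _find_all(haystack: str, needle: str) -> List[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def _scan_one_orientation(fwd: str, rev: str, template: str) -> Optional[Tuple[int, int, int]]:
    """Shortest (length, fwd_start0, rev_site_start0) amplicon on this strand."""
    rev_rc = reverse_complement(rev)
    fwd_sites = _find_all(template, fwd)
    rev_sites = _find_all(template, rev_rc)
    if not fwd_sites or not rev_sites:
        return None
    best: Optional[Tuple[int, int, int]] = None
    for f in fwd_sites:
        for r in rev_sites:
            rev_end = r + len(rev_rc) - 1
            if r < f or rev_end < f + len(fwd) - 1:
                continue  # rev site must lie downstream of the fwd site
            length = rev_end - f + 1
            if best is None or length < best[0]:
                best = (length, f, r)
    return best


def predict_amplicon(
    fwd: str, rev: str, template: str, chrom: str = "template", min_primer_len: int = 12
) -> AmpliconPrediction:
    """Predict the PCR product two primers form on a template sequence.

    Exact-match primer sites only. The forward primer is sought on the given
    strand and the reverse primer as its reverse complement downstream; the
    same search runs on the reverse-complement template so the result does
    not depend on which primer the caller labels "forward". When several
    site pairs exist the shortest product — the dominant species in a real
    reaction — is reported. Coordinates are 1-based on the given template.
    """
    fwd, rev = _check_dna(fwd), _check_dna(rev)
    if len(fwd) < min_primer_len or len(rev) < min_primer_len:
        raise InvalidSequenceError(f"primers must be >= {min_primer_len} nt")
    template = template.upper()
    n = len(template)

    candidates: List[Tuple[int, int, int, Strand]] = []
    hit = _scan_one_orientation(fwd, rev, template)
    if hit is not None:
        candidates.append((*hit, Strand.PLUS))
    hit = _scan_one_orientation(fwd, rev, reverse_complement(template))
    if hit is not None:
        candidates.append((*hit, Strand.MINUS))
    if not candidates:
        return AmpliconPrediction(found=False)
    length, f0, r0, strand = min(candidates, key=lambda c: (c[0], c[3] is Strand.MINUS, c[1]))
    if strand is Strand.PLUS:
        start1 = f0 + 1
        end1 = f0 + length
    else:
        end1 = n - f0
        start1 = end1 - length + 1
    return AmpliconPrediction(
        found=True,
        product_length_nt=length,
        template_interval=GenomicInterval(chrom, start1, end1, strand),
        fwd_match_pos=f0 + 1,
        rev_match_pos=r0 + 1,
    )


@dataclass(frozen=True)
class TransHit:
    """A genome window nearly identical to the query — a potential trans target."""

    interval: GenomicInterval
    identity_fraction: float
    matched_length_nt: int
    strand_of_match: Strand


_ENCODE = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_trans_targets(
    query: str,
    genome: Mapping[str, str],
    min_identity: float = 0.9,
    min_len: int = 20,
) -> List[TransHit]:
    """Scan both genome strands for windows nearly identical to the query.

    Every window of length ``len(query)`` with ungapped identity >=
    ``min_identity`` is a hit; overlapping hits on the same strand are merged
    keeping the best one. Hits are ordered by (chromosome, start, strand).
    """
    if not (0 < min_identity <= 1):
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    query = _check_dna(query)
    q = len(query)
    if q < min_len:
        raise ValueError(f"query ({q} nt) shorter than min_len ({min_len})")
    q_arr = _encode(query)

    hits: List[TransHit] = []
    for chrom in sorted(genome):
        contig = genome[chrom].upper()
        if len(contig) < q:
            continue
        for strand in (Strand.PLUS, Strand.MINUS):
            seq = contig if strand is Strand.PLUS else reverse_complement(contig)
            s_arr = _encode(seq)
            # identity of every window via a sliding equality count
            n_win = len(seq) - q + 1
            matches = np.zeros(n_win, dtype=np.int32)
            for j in range(q):
                matches += (s_arr[j : j + n_win] == q_arr[j]).astype(np.int32)
            identities = matches / q
            raw = []
            for off in np.nonzero(identities >= min_identity)[0]:
                if strand is Strand.PLUS:
                    start1 = int(off) + 1
                else:
                    start1 = len(contig) - (int(off) + q) + 1
                raw.append((start1, float(identities[off])))
            # merge overlapping windows, keep the best-identity representative
            raw.sort()
            merged: List[Tuple[int, float]] = []
            for start1, ident in raw:
                if merged and start1 <= merged[-1][0] + q - 1:
                    if ident > merged[-1][1]:
                        merged[-1] = (start1, ident)
                else:
                    merged.append((start1, ident))
            for start1, ident in merged:
                hits.append(
                    TransHit(
                        interval=GenomicInterval(chrom, start1, start1 + q - 1, strand),
                        identity_fraction=ident,
                        matched_length_nt=q,
                        strand_of_match=strand,
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand_of_match.value))
    return hits
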