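"""Self-contained synthetic fixtures with machine-readable ground truth.

The generator emulates the structure of a *Streptomyces*-like screen: a
GC-rich (72% by default) toy chromosome carrying well-separated gene–sRNA
loci planted in every orientation category, expression tables whose genes
are above or below the selection thresholds by construction, and northern
band-intensity tables with planted rnc/wt ratio structure under lognormal
multiplicative noise. Every output is deterministic for a given seed, and
the ground truth is returned (and serialisable) alongside the data so tests
never re-derive it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import annotation_io
from .exceptions import GenerationError
from .northern import Response
from .orientation import Category, ClassifierParams
from .records import GeneRecord, GenomicInterval, SmallRNARecord, Strand

#: Categories planted by the locus generator, in a fixed order.
PLANTED_CATEGORIES = (
    Category.CIS_AS_5PRIME,
    Category.CUTORNA,
    Category.CIS_AS_OTHER,
    Category.AMBIGUOUS,
    Category.SENSE_OVERLAP,
    Category.NONE,
)

_RESPONSES = (
    Response.INCREASED_IN_RNC,
    Response.DECREASED_IN_RNC,
    Response.UNCHANGED,
    Response.NOT_DETECTED,
)

#: Padding on each side of a locus block; 2 * _PAD minus the widest sRNA
#: overhang must exceed the adjacency window so loci never cross-talk.
_PAD = 120


@dataclass(frozen=True)
class LocusPlan:
    """Geometry of one planted locus (local, plus-frame coordinates)."""

    category: Category
    gene_length: int
    srna_length: int
    gene_strand: Strand
    gene_local: Tuple[int, int]
    srna_local: Tuple[int, int]
    srna_strand: Strand


@dataclass
class GroundTruth:
    """What the generated data is guaranteed to contain."""

    orientation: Dict[Tuple[str, str], Category] = field(default_factory=dict)
    genes: List[str] = field(default_factory=list)
    features: List[str] = field(default_factory=list)
    fold_selected: Set[str] = field(default_factory=set)
    bard_selected: Set[str] = field(default_factory=set)
    northern_response: Dict[str, Response] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for (gene_id, srna_id), category in sorted(self.orientation.items()):
            rows.append(
                {
                    "gene_id": gene_id,
                    "srna_id": srna_id,
                    "category": category.value,
                    "fold_selected": gene_id in self.fold_selected,
                    "bard_selected": gene_id in self.bard_selected,
                    "northern_response": self.northern_response.get(srna_id, ""),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "srna_id",
                "category",
                "fold_selected",
                "bard_selected",
                "northern_response",
            ],
        )
        df["northern_response"] = df["northern_response"].map(
            lambda r: r.value if isinstance(r, Response) else r
        )
        return df


@dataclass
class LocusSet:
    """A generated toy genome with its annotation and ground truth."""

    genome: Dict[str, str]
    genes: List[GeneRecord]
    srnas: List[SmallRNARecord]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annotation_io.write_genome(self.genome, out / "genome.fa")
        annotation_io.write_gff3(self.genes, out / "genes.gff3")
        annotation_io.write_bed6(self.srnas, out / "srnas.bed")
        self.truth.to_table().to_csv(out / "truth.tsv", sep="\t", index=False)


def _plan_locus(
    category: Category, rng: np.random.Generator, params: ClassifierParams
) -> LocusPlan:
    """Plant one locus in local plus-frame coordinates; origin is the gene start."""
    gene_len = int(rng.integers(300, 601))
    a, b = 0, gene_len - 1  # gene occupies [a, b] in the local frame
    w = params.adjacency_window
    if category is Category.CIS_AS_5PRIME:
        s_lo = a - int(rng.integers(20, 61))
        s_hi = a + int(rng.integers(20, 121))
        s_strand = Strand.MINUS
    elif category is Category.CUTORNA:
        s_lo = b - int(rng.integers(10, min(41, params.three_prime_inside + 1)))
        s_hi = b + int(rng.integers(10, 81))
        s_strand = Strand.MINUS
    elif category is Category.CIS_AS_OTHER:
        s_lo = a + max(params.five_prime_downstream + 10, 60)
        s_hi = s_lo + int(rng.integers(40, 101))
        s_strand = Strand.MINUS
    elif category is Category.AMBIGUOUS:
        gap = int(rng.integers(10, min(91, w)))
        s_lo = b + gap + 1
        s_hi = s_lo + int(rng.integers(60, 121))
        s_strand = Strand.UNKNOWN
    elif category is Category.SENSE_OVERLAP:
        s_lo = a + 60
        s_hi = s_lo + int(rng.integers(40, 101))
        s_strand = Strand.PLUS
    elif category is Category.NONE:
        gap = int(rng.integers(w + 50, w + 251))
        s_lo = b + gap + 1
        s_hi = s_lo + int(rng.integers(60, 121))
        s_strand = Strand.MINUS
    else:  # pragma: no cover - exhaustive over PLANTED_CATEGORIES
        raise GenerationError(f"cannot plant category {category}")
    if s_hi - s_lo + 1 > 2 * _PAD - 60:
        raise GenerationError("sRNA too long for the locus padding")
    gene_strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
    return LocusPlan(
        category=category,
        gene_length=gene_len,
        srna_length=s_hi - s_lo + 1,
        gene_strand=gene_strand,
        gene_local=(a, b),
        srna_local=(s_lo, s_hi),
        srna_strand=s_strand,
    )


def _mirror(lo: int, hi: int, span: int) -> Tuple[int, int]:
    return span - hi, span - lo


def _flip(strand: Strand) -> Strand:
    return strand.opposite


def generate_locus_set(
    seed: int,
    n_per_category: int,
    params: ClassifierParams = ClassifierParams(),
    gc_content: float = 0.72,
    chrom: str = "chrS",
) -> LocusSet:
    """Generate a toy chromosome with ``n_per_category`` loci of each category.

    Loci are laid out left to right with enough padding that no feature of
    one locus lies within the adjacency window of another. Gene strands are
    randomised; minus-strand loci are planted by mirroring the plus-frame
    geometry, which preserves the category (strand-flip symmetry). The
    returned ground truth records the planted category of every pair, the
    planted selector membership of every gene and the planted northern
    response of every sRNA feature.
    """
    if n_per_category < 0:
        raise GenerationError("n_per_category must be >= 0")
    if not (0 <= gc_content <= 1):
        raise GenerationError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    genes: List[GeneRecord] = []
    srnas: List[SmallRNARecord] = []
    cursor = 0  # 0-based genomic offset of the current block
    idx = 0
    for category in PLANTED_CATEGORIES:
        for _ in range(n_per_category):
            idx += 1
            plan = _plan_locus(category, rng, params)
            (g_lo, g_hi), (s_lo, s_hi) = plan.gene_local, plan.srna_local
            lo = min(g_lo, s_lo) - _PAD
            hi = max(g_hi, s_hi) + _PAD
            span = hi - lo  # block-local frame: positions 0..span
            g_lo, g_hi, s_lo, s_hi = g_lo - lo, g_hi - lo, s_lo - lo, s_hi - lo
            gene_strand, srna_strand = Strand.PLUS, plan.srna_strand
            if plan.gene_strand is Strand.MINUS:
                g_lo, g_hi = _mirror(g_lo, g_hi, span)
                s_lo, s_hi = _mirror(s_lo, s_hi, span)
                gene_strand, srna_strand = Strand.MINUS, _flip(srna_strand)
            gene_id, srna_id = f"SYNG{idx:04d}", f"syns{idx:04d}"
            genes.append(
                GeneRecord(
                    gene_id,
                    GenomicInterval(chrom, cursor + g_lo + 1, cursor + g_hi + 1, gene_strand),
                    product=f"synthetic {category.value} locus",
                )
            )
            srnas.append(
                SmallRNARecord(
                    srna_id,
                    GenomicInterval(chrom, cursor + s_lo + 1, cursor + s_hi + 1, srna_strand),
                    source="synthetic",
                )
            )
            truth.orientation[(gene_id, srna_id)] = category
            truth.genes.append(gene_id)
            truth.features.append(srna_id)
            # planted selector membership cycles through the four combinations
            combo = (idx - 1) % 4
            if combo in (0, 2):
                truth.fold_selected.add(gene_id)
            if combo in (1, 2):
                truth.bard_selected.add(gene_id)
            truth.northern_response[srna_id] = _RESPONSES[(idx - 1) % len(_RESPONSES)]
            cursor += span + 1
    length = max(cursor, 200)
    bases = rng.choice(
        np.array(list("GCAT")),
        size=length,
        p=[gc_content / 2, gc_content / 2, (1 - gc_content) / 2, (1 - gc_content) / 2],
    )
    genome = {chrom: "".join(bases)}
    return LocusSet(genome=genome, genes=genes, srnas=srnas, truth=truth)


def generate_expression_tables(
    truth: GroundTruth,
    seed: int,
    fold_above: float = 3.0,
    fold_below: float = 1.5,
    time_points: Sequence[str] = ("fold_24h", "fold_48h", "fold_72h"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression and BARD tables matching the planted truth.

    Fold-selected genes get one time point drawn in [fold_above, 2*fold_above]
    — "increased at a single experimental time point" — and all other cells
    below ``fold_below`` in magnitude (random sign, never zero). BARD-selected
    genes get an enrichment ratio in [2, 250]; every other gene is either
    absent from the BARD table or carries a sub-threshold ratio below 1.
    """
    if not fold_above > fold_below:
        raise GenerationError(
            f"fold_above ({fold_above}) must exceed fold_below ({fold_below}) "
            "or selected and unselected genes cannot be separated"
        )
    rng = np.random.default_rng(seed)

    def background() -> float:
        magnitude = rng.uniform(1.01, fold_below)
        return float(magnitude if rng.random() < 0.5 else -magnitude)

    de_rows = []
    bard_rows = []
    for i, gene_id in enumerate(truth.genes):
        row = {"gene_id": gene_id}
        for col in time_points:
            row[col] = round(background(), 3)
        if gene_id in truth.fold_selected:
            chosen = time_points[int(rng.integers(0, len(time_points)))]
            row[chosen] = round(float(rng.uniform(fold_above, 2 * fold_above)), 3)
        de_rows.append(row)
        if gene_id in truth.bard_selected:
            bard_rows.append(
                {"gene_id": gene_id, "bard_ratio": round(float(rng.uniform(2.0, 250.0)), 2)}
            )
        elif i % 2 == 0:  # some unbound genes appear with sub-threshold enrichment
            bard_rows.append(
                {"gene_id": gene_id, "bard_ratio": round(float(rng.uniform(0.2, 0.9)), 2)}
            )
    de = pd.DataFrame(de_rows, columns=["gene_id", *time_points])
    bard = pd.DataFrame(bard_rows, columns=["gene_id", "bard_ratio"])
    return de, bard


_PLANTED_RATIO = {
    Response.INCREASED_IN_RNC: 4.0,
    Response.DECREASED_IN_RNC: 0.25,
    Response.UNCHANGED: 1.0,
    Response.NOT_DETECTED: 0.0,
}


def generate_northern_table(
    truth: GroundTruth,
    seed: int,
    noise_cv: float = 0.05,
    baseline: float = 0.5,
    control_level: float = 1000.0,
    time_points_h: Sequence[int] = (24, 48, 72),
) -> pd.DataFrame:
    """Northern band/5S intensity table with planted rnc/wt ratio structure.

    Detected features have a wild-type normalised level of ``baseline`` and
    an rnc level of ``baseline`` times the planted ratio (4x for increased,
    0.25x for decreased, 1x for unchanged); not_detected features have zero
    band signal in both strains. Band and control intensities carry
    independent lognormal multiplicative noise with coefficient of variation
    ``noise_cv`` (0 gives exact planted ratios).
    """
    if noise_cv < 0:
        raise GenerationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    def lognoise() -> float:
        if sigma == 0:
            return 1.0
        return float(np.exp(rng.normal(-sigma**2 / 2, sigma)))

    rows = []
    for feature in truth.features:
        response = truth.northern_response.get(feature, Response.UNCHANGED)
        ratio = _PLANTED_RATIO[response]
        for strain in ("wt", "rnc"):
            level = baseline if response is not Response.NOT_DETECTED else 0.0
            if strain == "rnc" and response is not Response.NOT_DETECTED:
                level = baseline * ratio
            for t in time_points_h:
                control = control_level * lognoise()
                band = level * control * lognoise()
                rows.append(
                    {
                        "feature": feature,
                        "strain": strain,
                        "time_h": t,
                        "band": band,
                        "control": control,
                    }
                )
    return pd.DataFrame(rows, columns=["feature", "strain", "time_h", "band", "control"])
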