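"""The candidate funnel and detection summarisation.

The screen mirrors the discovery logic used for RNase III-associated
antisense candidates in *Streptomyces coelicolor*: start from all annotated
genes, keep those whose mRNA responds to loss of RNase III (fold change above
threshold in the rnc mutant) and/or binds the enzyme (BARD enrichment), join
against the sRNA catalog for antisense/adjacent partners, and finally
intersect with the binding evidence. Counts at each stage are of distinct
gene ids — one gene with several partner sRNAs contributes several report
rows but one count.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Union

import pandas as pd

from .exceptions import TableParseError
from .orientation import (
    ANTISENSE_CATEGORIES,
    Category,
    ClassifierParams,
    OrientationCall,
    classify_catalog,
)
from .records import ExpressionEvidence, GeneRecord, SmallRNARecord


class SelectorMode(enum.Enum):
    FOLD_ONLY = "fold_only"
    BARD_ONLY = "bard_only"
    FOLD_OR_BARD = "fold_or_bard"


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the candidate funnel.

    ``fold_threshold`` is a strict lower bound — "increased by more than
    two-fold" is read as ``fold > 2.0`` — applied to signed folds, so a
    decrease never qualifies however large. Set ``strict_fold=False`` for a
    ``>=`` reading in sensitivity analyses. ``bard_min_ratio`` is the minimal
    BARD enrichment counted as binding (inclusive).
    """

    fold_threshold: float = 2.0
    selector_mode: SelectorMode = SelectorMode.FOLD_ONLY
    bard_min_ratio: float = 1.0
    strict_fold: bool = True

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ValueError("fold_threshold must be > 0")
        if not self.bard_min_ratio > 0:
            raise ValueError("bard_min_ratio must be > 0")


@dataclass
class ScreenResult:
    """Funnel counts (distinct genes) plus the per-pair report rows."""

    n_input_genes: int
    n_selected: int
    n_with_antisense_neighbor: int
    n_also_in_bard: int
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        stages = (
            self.n_also_in_bard,
            self.n_with_antisense_neighbor,
            self.n_selected,
            self.n_input_genes,
        )
        if any(a > b for a, b in zip(stages, stages[1:])):
            raise ValueError(f"funnel counts must be non-increasing, got {stages[::-1]}")


@dataclass(frozen=True)
class DetectionSummary:
    """RACE / northern outcome counts, overall and per set."""

    n_tested: int
    n_5prime_detected: int
    n_3prime_detected: int
    n_northern_positive: int
    per_set: Dict[str, "DetectionSummary"] = field(default_factory=dict)


def _fold_qualifies(evidence: ExpressionEvidence, params: ScreenParams) -> bool:
    for value in evidence.fold_changes.values():
        if value > params.fold_threshold or (not params.strict_fold and value == params.fold_threshold):
            return True
    return False


def _bard_qualifies(evidence: ExpressionEvidence, params: ScreenParams) -> bool:
    return evidence.bard_ratio is not None and evidence.bard_ratio >= params.bard_min_ratio


def filter_selected(
    evidence: Sequence[ExpressionEvidence], params: ScreenParams = ScreenParams()
) -> Set[str]:
    """Gene ids passing the expression/binding selector.

    fold_only: some time point's signed fold strictly exceeds the threshold.
    bard_only: BARD ratio present and >= ``bard_min_ratio``.
    fold_or_bard: the union of the two.
    """
    selected: Set[str] = set()
    for ev in evidence:
        by_fold = _fold_qualifies(ev, params)
        by_bard = _bard_qualifies(ev, params)
        if params.selector_mode is SelectorMode.FOLD_ONLY and by_fold:
            selected.add(ev.gene_id)
        elif params.selector_mode is SelectorMode.BARD_ONLY and by_bard:
            selected.add(ev.gene_id)
        elif params.selector_mode is SelectorMode.FOLD_OR_BARD and (by_fold or by_bard):
            selected.add(ev.gene_id)
    return selected


def run_screen(
    genes: Sequence[GeneRecord],
    srnas: Sequence[SmallRNARecord],
    evidence: Sequence[ExpressionEvidence],
    params: ScreenParams = ScreenParams(),
    classifier_params: ClassifierParams = ClassifierParams(),
) -> ScreenResult:
    """Run the full candidate funnel and assemble the per-pair report.

    Stages: all input genes -> selector-passing genes -> those with at least
    one antisense/ambiguous sRNA partner -> those additionally BARD-bound.
    """
    selected = filter_selected(evidence, params)
    ev_by_gene = {ev.gene_id: ev for ev in evidence}
    selected_genes = [g for g in genes if g.gene_id in selected]

    calls = classify_catalog(selected_genes, srnas, classifier_params)
    antisense_calls: List[OrientationCall] = [
        c for c in calls if c.category in ANTISENSE_CATEGORIES
    ]
    with_neighbor = {c.gene_id for c in antisense_calls}
    in_bard = {
        g
        for g in with_neighbor
        if g in ev_by_gene and _bard_qualifies(ev_by_gene[g], params)
    }

    srna_by_id = {s.srna_id: s for s in srnas}
    rows = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "srna_id": c.srna_id,
                "source": srna_by_id[c.srna_id].source,
                "category": c.category.value,
                "overlap_nt": c.overlap_nt,
                "gap_nt": c.gap_nt,
                "in_bard": c.gene_id in in_bard,
                "comment": "",
            }
            for c in sorted(antisense_calls, key=lambda c: (c.gene_id, c.srna_id))
        ],
        columns=[
            "gene_id",
            "srna_id",
            "source",
            "category",
            "overlap_nt",
            "gap_nt",
            "in_bard",
            "comment",
        ],
    )
    return ScreenResult(
        n_input_genes=len({g.gene_id for g in genes}),
        n_selected=len(selected & {g.gene_id for g in genes}),
        n_with_antisense_neighbor=len(with_neighbor),
        n_also_in_bard=len(in_bard),
        rows=rows,
    )


def distinct_target_genes(pairs: pd.DataFrame) -> int:
    """Number of distinct target genes among gene–sRNA pair rows."""
    if "gene_id" not in pairs.columns:
        raise TableParseError("pair table lacks a 'gene_id' column")
    return int(pairs["gene_id"].nunique())


_SET_LABELS = ("experimental", "control")
_SIGN = {"+": True, "-": False, "−": False, "–": False}


def _count_detections(df: pd.DataFrame) -> DetectionSummary:
    def positives(col: str) -> int:
        return int(df[col].sum())

    return DetectionSummary(
        n_tested=len(df),
        n_5prime_detected=positives("five_prime"),
        n_3prime_detected=positives("three_prime"),
        n_northern_positive=positives("northern"),
    )


def summarize_detections(table: Union[str, Path, pd.DataFrame]) -> DetectionSummary:
    """Summarise a RACE/northern outcome table, overall and per set.

    The table needs columns ``gene_id``, ``set`` (``experimental`` or
    ``control``) and ``five_prime``/``three_prime``/``northern`` detection
    flags coded ``+`` or ``-``.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t", comment="#", dtype=str, encoding="utf-8")
    else:
        df = table.copy()
    required = {"gene_id", "set", "five_prime", "three_prime", "northern"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"detection table lacks columns: {sorted(missing)}")
    if len(df) == 0:
        empty = DetectionSummary(0, 0, 0, 0)
        return DetectionSummary(0, 0, 0, 0, per_set={s: empty for s in _SET_LABELS})
    bad_sets = set(df["set"]) - set(_SET_LABELS)
    if bad_sets:
        raise TableParseError(f"unknown set label(s): {sorted(bad_sets)}")
    flags = df.copy()
    for col in ("five_prime", "three_prime", "northern"):
        flags[col] = df[col].str.strip().map(_SIGN)
        if flags[col].isna().any():
            bad = df.loc[flags[col].isna(), col].iloc[0]
            raise TableParseError(f"column {col!r}: detection flag must be '+' or '-', got {bad!r}")
    overall = _count_detections(flags)
    per_set = {
        label: _count_detections(flags[flags["set"] == label]) for label in _SET_LABELS
    }
    return DetectionSummary(
        overall.n_tested,
        overall.n_5prime_detected,
        overall.n_3prime_detected,
        overall.n_northern_positive,
        per_set=per_set,
    )
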