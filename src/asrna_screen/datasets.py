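"""Loaders for the bundled survey tables.

Two small TSV fixtures ship with the package: the in-silico survey of sRNA
genes antisense/adjacent to rnc-responsive mRNAs (one row per gene–sRNA
pair) and the RACE/northern outcome table for the 30 genes tested for
antisense expression, including the BARD enrichment and fold-change evidence
used by the candidate filter.
"""
from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .records import ExpressionEvidence

_PKG = "asrna_screen.data"


def _load(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t", comment="#", dtype=str)


def load_srna_gene_pairs() -> pd.DataFrame:
    """The published gene–sRNA pair survey (49 rows, 45 distinct target genes)."""
    return _load("srna_gene_pairs.tsv")


def load_race_northern_results() -> pd.DataFrame:
    """RACE and northern outcomes for the 30 genes tested for antisense expression."""
    return _load("race_northern_results.tsv")


def load_expression_evidence() -> List[ExpressionEvidence]:
    """BARD-enrichment / fold-change evidence of the experimental set as records.

    Fold changes in the source table are single values (the reported fold at
    the responsive time point); they are keyed ``"fold"``.
    """
    df = load_race_northern_results()
    evidence = []
    for _, row in df.iterrows():
        folds = {}
        if isinstance(row["fold_change"], str) and row["fold_change"].strip():
            folds["fold"] = float(row["fold_change"])
        bard = None
        if isinstance(row["bard_ratio"], str) and row["bard_ratio"].strip():
            bard = float(row["bard_ratio"])
        if folds or bard is not None:
            evidence.append(ExpressionEvidence(row["gene_id"], folds, bard))
    return evidence
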