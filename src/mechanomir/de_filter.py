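"""Differential-expression threshold filtering.

Consumes the output table of an upstream microarray analysis (feature id,
feature type, signed fold change, raw p, FDR-adjusted p) and applies the
study's triple filter -- p < 0.05, FDR < 0.05, |fold change| > 2, all strict
-- then splits survivors into the coding-gene set (pathway-analysis input)
and the precursor-miRNA set (interaction-analysis input).  The FDR values
are consumed as given; the empirical-Bayes testing that produced them is out
of scope here.

Fold changes follow the signed convention of transcriptome-analysis
software: |FC| >= 1 with the sign giving the direction, so -2.03 means
2.03-fold down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FilterCriteria",
    "SchemaError",
    "DEFAULT_CRITERIA",
    "filter_de",
    "split_by_type",
    "de_fold_change_map",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["feature_id", "feature_type", "fold_change", "p_value", "fdr"]

KNOWN_FEATURE_TYPES = ("coding", "precursor_mirna", "other")


class SchemaError(KeyError):
    """Expression table lacks a required column."""


@dataclass(frozen=True)
class FilterCriteria:
    """Strict thresholds: p < p_max, FDR < fdr_max, |FC| > abs_fc_min."""

    p_max: float = 0.05
    fdr_max: float = 0.05
    abs_fc_min: float = 2.0

    def __post_init__(self) -> None:
        if self.p_max <= 0 or self.fdr_max <= 0:
            raise ValueError("p_max and fdr_max must be positive")
        if self.abs_fc_min <= 1:
            raise ValueError("abs_fc_min must exceed 1")


DEFAULT_CRITERIA = FilterCriteria()


def _check_schema(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"expression table missing columns: {missing}")


def filter_de(
    records: pd.DataFrame, criteria: FilterCriteria = DEFAULT_CRITERIA
) -> pd.DataFrame:
    """Rows passing p < p_max AND fdr < fdr_max AND |FC| > abs_fc_min.

    All inequalities are strict; boundary values (e.g. FC exactly 2) are
    excluded.  Idempotent and order-preserving.
    """
    _check_schema(records)
    if records.empty:
        raise ValueError("expression table is empty")
    mask = (
        (records["p_value"] < criteria.p_max)
        & (records["fdr"] < criteria.fdr_max)
        & (records["fold_change"].abs() > criteria.abs_fc_min)
    )
    return records.loc[mask].copy()


def split_by_type(de_subset: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a filtered table into (coding, precursor_mirna) sets.

    Rows with any other feature type are routed to neither set, with a
    warning -- the partition over known types stays exhaustive and disjoint.
    """
    _check_schema(de_subset)
    coding = de_subset[de_subset["feature_type"] == "coding"].copy()
    mirna = de_subset[de_subset["feature_type"] == "precursor_mirna"].copy()
    n_other = len(de_subset) - len(coding) - len(mirna)
    if n_other:
        logger.warning(
            "%d DE features with unrecognised feature_type routed to 'other'",
            n_other,
        )
    return coding, mirna


def de_fold_change_map(de_subset: pd.DataFrame) -> dict[str, float]:
    """feature_id -> signed fold change mapping for interaction scoring."""
    _check_schema(de_subset)
    return dict(zip(de_subset["feature_id"], de_subset["fold_change"]))
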