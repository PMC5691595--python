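"""Skin-tissue expression filtering of predicted targets.

Predicted protein targets are only therapeutically plausible for a
pigmentation phenotype if they are actually expressed in the relevant
skin cell types — keratinocytes and melanocytes. Expression arrives as
an antibody-staining-style ordinal table (not_detected < low < medium <
high) per target and tissue; a target counts as expressed in a tissue
when its level reaches ``detected_threshold`` (default ``low``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

EXPRESSION_LEVELS = ("not_detected", "low", "medium", "high")
_LEVEL_ORDER = {lvl: i for i, lvl in enumerate(EXPRESSION_LEVELS)}


class ExpressionTable:
    """Per-target ordinal expression levels across tissues."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dupes = sorted(set(data.index[data.index.duplicated()]))
            raise ValidationError(f"duplicate target rows: {dupes}")
        bad = set(data.values.ravel()) - set(EXPRESSION_LEVELS)
        if bad:
            raise ValidationError(
                f"invalid expression level(s) {sorted(bad)}; expected one of {EXPRESSION_LEVELS}"
            )
        self.data = data

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    def level(self, target_id: str, tissue: str) -> str:
        return self.data.at[target_id, tissue]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "target_id" not in df.columns:
            raise FormatError(f"expression table {path}: missing target_id column")
        return cls(df.set_index("target_id"))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "target_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TissueClassification:
    """Partition of a target set by keratinocyte/melanocyte expression."""

    both: frozenset[str]
    keratinocyte_only: frozenset[str]
    melanocyte_only: frozenset[str]
    neither: frozenset[str]
    unmapped: frozenset[str]

    @property
    def retained(self) -> frozenset[str]:
        """Targets expressed in at least one of the two skin cell types."""
        return self.both | self.keratinocyte_only | self.melanocyte_only

    @property
    def total(self) -> int:
        return sum(
            len(s) for s in (self.both, self.keratinocyte_only, self.melanocyte_only,
                             self.neither, self.unmapped)
        )


def classify_targets(
    targets: Iterable[str],
    expression: ExpressionTable,
    detected_threshold: str = "low",
    keratinocyte_col: str = "keratinocyte",
    melanocyte_col: str = "melanocyte",
) -> TissueClassification:
    """Partition targets by expression in keratinocytes and melanocytes.

    A target is expressed in a tissue iff its level is at or above
    ``detected_threshold``. Targets absent from the table land in
    ``unmapped`` (logged). The five output sets always partition the
    input; raising the threshold can only shrink the retained set.
    """
    if detected_threshold not in EXPRESSION_LEVELS[1:]:
        raise ValidationError(
            f"detected_threshold must be one of {EXPRESSION_LEVELS[1:]}, got {detected_threshold!r}"
        )
    for col in (keratinocyte_col, melanocyte_col):
        if col not in expression.tissues:
            raise ValidationError(f"expression table missing tissue column {col!r}")
    cut = _LEVEL_ORDER[detected_threshold]
    both, k_only, m_only, neither, unmapped = set(), set(), set(), set(), set()
    for t in set(targets):
        if t not in expression.data.index:
            unmapped.add(t)
            continue
        in_k = _LEVEL_ORDER[expression.level(t, keratinocyte_col)] >= cut
        in_m = _LEVEL_ORDER[expression.level(t, melanocyte_col)] >= cut
        {(True, True): both, (True, False): k_only,
         (False, True): m_only, (False, False): neither}[(in_k, in_m)].add(t)
    if unmapped:
        logger.warning("%d target(s) absent from expression table: %s",
                       len(unmapped), sorted(unmapped))
    return TissueClassification(
        frozenset(both), frozenset(k_only), frozenset(m_only),
        frozenset(neither), frozenset(unmapped),
    )
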