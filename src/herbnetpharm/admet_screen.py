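"""Oral-absorption filtering and CYP-inhibition lead scoring.

admetSAR-style predictions arrive as *signed probabilities*: the sign
encodes the predicted class (HIA+/HIA-, Caco-2 permeable or not,
CYP isoform inhibitor or non-inhibitor) and the magnitude is the class
probability. Screening proceeds in two stages:

1. absorption gate — keep compounds predicted positive by *both* the
   human intestinal absorption (HIA) and Caco-2 permeability models
   (sign only; the magnitudes are carried for reporting, never used);
2. metabolism score — rank the survivors by

       score = sum_k  result_k * Q_k

   over the five major CYP450 isoforms k in {1A2, 2C9, 2D6, 2C19, 3A4},
   where result_k is the signed inhibition probability and Q_k is the
   published overall predictive accuracy of the isoform's classifier.
   A predicted inhibitor contributes +p*Q, a non-inhibitor -p*Q, so the
   score deliberately rewards broad CYP inhibition, the stated
   desideratum for this oral-route screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The five major drug-metabolizing CYP450 isoforms, in conventional order.
CYP_ISOFORMS = ("CYP1A2", "CYP2C9", "CYP2D6", "CYP2C19", "CYP3A4")

#: Published overall predictive accuracies (Q) of the admetSAR
#: CYP-inhibition classifiers, used as score weights by default.
DEFAULT_Q = {
    "CYP1A2": 0.8147,
    "CYP2C9": 0.8018,
    "CYP2D6": 0.8551,
    "CYP2C19": 0.8054,
    "CYP3A4": 0.6450,
}


@dataclass(frozen=True)
class AdmetRecord:
    """Signed-probability ADMET calls for one compound.

    ``hia`` and ``caco2`` are signed probabilities (+p = predicted
    absorbed/permeable); ``cyp_calls`` maps each isoform in
    :data:`CYP_ISOFORMS` to a signed inhibition probability
    (+p = predicted inhibitor, -p = predicted non-inhibitor).
    """

    compound_id: str
    hia: float
    caco2: float
    cyp_calls: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CYP_ISOFORMS) - set(self.cyp_calls)
        if missing:
            raise ValidationError(
                f"compound {self.compound_id!r}: missing CYP isoform call(s) {sorted(missing)}"
            )
        for key, p in {**dict(self.cyp_calls), "HIA": self.hia, "Caco2": self.caco2}.items():
            if not (0.0 < abs(p) <= 1.0):
                raise ValidationError(
                    f"compound {self.compound_id!r}: {key} signed probability {p} outside (0, 1]"
                )


@dataclass(frozen=True)
class AccuracyWeights:
    """Per-isoform classifier accuracies Q in (0, 1], the score weights."""

    q: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_Q))

    def __post_init__(self) -> None:
        if set(self.q) != set(CYP_ISOFORMS):
            raise ValidationError(
                f"weights must cover exactly the isoforms {CYP_ISOFORMS}, got {sorted(self.q)}"
            )
        bad = {k: v for k, v in self.q.items() if not (0.0 < v <= 1.0)}
        if bad:
            raise ValidationError(f"accuracy weights outside (0, 1]: {bad}")

    @property
    def max_score(self) -> float:
        """The attainable score bound sum_k Q_k."""
        return sum(self.q.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AccuracyWeights":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass(frozen=True)
class ScoredCompound:
    compound_id: str
    score: float
    rank: int


def _parse_signed(cell: str | float) -> float:
    """Parse a signed-probability cell, accepting the Unicode minus dialect."""
    if isinstance(cell, (int, float)):
        return float(cell)
    text = cell.strip().replace("−", "-")
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable signed probability {cell!r}") from exc


def read_admet_table(path: str | Path) -> list[AdmetRecord]:
    """Read an ADMET TSV (compound_id, HIA, Caco2, CYP1A2...CYP3A4).

    Cells are signed decimals; both ASCII hyphen and Unicode minus are
    accepted, as are explicit leading '+' signs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "HIA", "Caco2", *CYP_ISOFORMS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"ADMET table {path}: missing column(s) {sorted(missing)}")
    return [
        AdmetRecord(
            compound_id=row["compound_id"],
            hia=_parse_signed(row["HIA"]),
            caco2=_parse_signed(row["Caco2"]),
            cyp_calls={k: _parse_signed(row[k]) for k in CYP_ISOFORMS},
        )
        for _, row in df.iterrows()
    ]


def absorption_filter(records: Iterable[AdmetRecord]) -> list[AdmetRecord]:
    """Keep records predicted positive by both the HIA and Caco-2 models.

    The gate is on class sign only; order is preserved and the operation
    is idempotent.
    """
    return [r for r in records if r.hia > 0 and r.caco2 > 0]


def cyp_score(record: AdmetRecord, weights: AccuracyWeights | None = None) -> float:
    """Accuracy-weighted signed CYP-inhibition score sum_k result_k * Q_k."""
    weights = weights or AccuracyWeights()
    return sum(record.cyp_calls[k] * weights.q[k] for k in CYP_ISOFORMS)


def rank_compounds(
    records: Iterable[AdmetRecord],
    weights: AccuracyWeights | None = None,
    top_n: int | None = None,
) -> list[ScoredCompound]:
    """Rank (already absorption-filtered) compounds by CYP score, descending.

    Ties are broken by compound_id ascending; ranks are dense positions
    1..n assigned after the full sort, then truncated to ``top_n``.
    """
    if top_n is not None and top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    weights = weights or AccuracyWeights()
    scored = sorted(
        ((cyp_score(r, weights), r.compound_id) for r in records),
        key=lambda t: (-t[0], t[1]),
    )
    ranked = [ScoredCompound(cid, s, i + 1) for i, (s, cid) in enumerate(scored)]
    return ranked[:top_n] if top_n is not None else ranked


def write_leads(leads: Iterable[ScoredCompound], path: str | Path) -> None:
    pd.DataFrame(
        [{"rank": c.rank, "compound_id": c.compound_id, "score": c.score} for c in leads]
    ).to_csv(path, sep="\t", index=False)
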