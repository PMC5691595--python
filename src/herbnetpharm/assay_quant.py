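"""Relative qRT-PCR quantification by the 2^-ddCt method.

Expression of a gene of interest is measured as a cycle threshold (Ct),
normalized against a reference gene within each condition
(dCt = Ct_target - Ct_reference), and compared across conditions
(ddCt = dCt_treated - dCt_control). Assuming perfect doubling per
cycle, the fold change of the target gene in the treated condition is
2^-ddCt. With replicates, the fold change is computed on the
per-condition mean dCt; per-replicate folds are also exposed for
dispersion reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MAX_CYCLES = 45  # standard amplification protocol length


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float
    condition: str  # 'control' or 'treated'

    def __post_init__(self) -> None:
        for label, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not (0.0 < ct <= MAX_CYCLES):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {label}={ct} outside (0, {MAX_CYCLES}]"
                )
        if self.condition not in ("control", "treated"):
            raise ValidationError(f"condition must be 'control' or 'treated', got {self.condition!r}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Fold change 2^-(dCt_treated - dCt_control) for one replicate pair."""
    if treated.gene != control.gene:
        raise ValidationError(
            f"gene mismatch: treated={treated.gene!r} vs control={control.gene!r}"
        )
    return float(2.0 ** -(treated.delta_ct - control.delta_ct))


@dataclass
class FoldChangeReport:
    gene: str
    fold_change: float          # from mean dCt per condition
    replicate_folds: list[float]  # every treated x control pairing


def ddct_fold_change_replicates(
    treated: Sequence[QpcrMeasurement], control: Sequence[QpcrMeasurement]
) -> FoldChangeReport:
    """Fold change on per-condition mean dCt, with per-pair folds for spread."""
    if not treated or not control:
        raise ValidationError("need at least one measurement per condition")
    genes = {m.gene for m in [*treated, *control]}
    if len(genes) != 1:
        raise ValidationError(f"mixed genes in replicate set: {sorted(genes)}")
    mean_ddct = np.mean([m.delta_ct for m in treated]) - np.mean([m.delta_ct for m in control])
    folds = [ddct_fold_change(t, c) for t in treated for c in control]
    return FoldChangeReport(genes.pop(), float(2.0 ** -mean_ddct), folds)


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a Ct CSV (sample_id, gene, condition, ct_target, ct_reference)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "gene": str, "condition": str})
    required = {"sample_id", "gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Ct table {path}: missing column(s) {sorted(missing)}")
    return [
        QpcrMeasurement(r.sample_id, r.gene, float(r.ct_target), float(r.ct_reference), r.condition)
        for r in df.itertuples(index=False)
    ]
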