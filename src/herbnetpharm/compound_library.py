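"""Compound library loading, SMILES normalization and substructure fingerprints.

A herbal compound library is a table of constituents (id, name, SMILES,
structural class). Downstream stages consume either the canonicalized
SMILES or a binary substructure fingerprint matrix over a fixed key set.
The fingerprint backend is pluggable: a SMARTS-key dictionary evaluated
with rdkit when available, or an externally precomputed 0/1 matrix which
is only validated and reindexed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

STRUCTURAL_CLASSES = ("steroid", "terpene", "flavonoid", "fatty_acid", "other")

try:  # chemistry backend is optional; matrix-only pipelines run without it
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    _HAVE_RDKIT = True
except ImportError:  # pragma: no cover - rdkit present in the supported env
    _HAVE_RDKIT = False


@dataclass(frozen=True)
class CompoundRecord:
    """One herbal constituent."""

    compound_id: str
    name: str = ""
    smiles: str = ""
    structural_class: str = "other"
    normalization_failed: bool = False

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValidationError(f"compound {self.compound_id!r}: empty SMILES")
        if self.structural_class not in STRUCTURAL_CLASSES:
            raise ValidationError(
                f"compound {self.compound_id!r}: unknown structural class "
                f"{self.structural_class!r} (expected one of {STRUCTURAL_CLASSES})"
            )


@dataclass
class CompoundLibrary:
    """Ordered collection of compounds with unique ids."""

    records: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate compound ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def get(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)


def normalize_smiles(smiles: str, backend: str = "auto") -> tuple[str, bool]:
    """Canonicalize a SMILES string.

    Returns ``(canonical_smiles, failed)``. With the rdkit backend an
    unparseable string is returned as-is with ``failed=True`` rather than
    raising, so one bad record never aborts a library load. With
    ``backend='none'`` (or rdkit absent) the string is only
    whitespace-trimmed, which keeps fingerprint-matrix-only pipelines
    runnable without a chemistry toolkit.

    Idempotent: ``normalize(normalize(s)) == normalize(s)``.
    """
    if not smiles or not smiles.strip():
        raise ValidationError("empty SMILES string")
    s = smiles.strip()
    if backend == "none" or (backend == "auto" and not _HAVE_RDKIT):
        if backend == "auto":
            logger.warning("no chemistry backend configured; SMILES passed through as-is")
        return s, False
    if backend not in ("auto", "rdkit"):
        raise ValidationError(f"unknown SMILES backend {backend!r}")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        logger.warning("SMILES %r could not be parsed; record flagged", s)
        return s, True
    return Chem.MolToSmiles(mol), False


def load_compounds(path: str | Path, normalize: bool = True, backend: str = "auto") -> CompoundLibrary:
    """Load a compound library CSV (columns: compound_id, smiles [, name, structural_class]).

    All parseable records are returned; records whose SMILES fail
    canonicalization are carried with ``normalization_failed=True``.
    Duplicate compound ids raise :class:`ValidationError` naming the
    offenders; a missing required column raises :class:`FormatError`.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"compound_id", "smiles"} - set(df.columns)
    if missing:
        raise FormatError(f"library file {path}: missing required column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles")
        failed = False
        if normalize:
            smiles, failed = normalize_smiles(smiles, backend=backend)
        records.append(
            CompoundRecord(
                compound_id=getattr(row, "compound_id"),
                name=getattr(row, "name", ""),
                smiles=smiles,
                structural_class=getattr(row, "structural_class", "") or "other",
                normalization_failed=failed,
            )
        )
    return CompoundLibrary(records)


def write_library(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library back to CSV (round-trips with :func:`load_compounds`)."""
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in library],
            "name": [r.name for r in library],
            "smiles": [r.smiles for r in library],
            "structural_class": [r.structural_class for r in library],
        }
    ).to_csv(path, index=False)


class FingerprintMatrix:
    """Binary compound x substructure presence matrix.

    Wraps a pandas DataFrame indexed by compound id with 0/1 integer
    cells. All-zero columns (substructure keys no compound carries) are
    dropped with a logged warning, since they can never route diffusion
    mass.
    """

    def __init__(self, data: pd.DataFrame, drop_empty: bool = True):
        values = data.astype(int)
        if not values.isin([0, 1]).all().all():
            raise ValidationError("fingerprint cells must be 0 or 1")
        if values.index.duplicated().any():
            dupes = sorted(set(values.index[values.index.duplicated()]))
            raise ValidationError(f"duplicate compound ids in fingerprint matrix: {dupes}")
        if drop_empty:
            empty = [c for c in values.columns if values[c].sum() == 0]
            if empty:
                logger.warning("dropping %d all-zero substructure column(s): %s", len(empty), empty)
                values = values.drop(columns=empty)
        self.data = values

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def substructure_keys(self) -> list[str]:
        return list(self.data.columns)

    def substructures_of(self, compound_id: str) -> frozenset[str]:
        row = self.data.loc[compound_id]
        return frozenset(row.index[row == 1])

    def __eq__(self, other) -> bool:
        return isinstance(other, FingerprintMatrix) and self.data.equals(other.data)

    @classmethod
    def from_tsv(cls, path: str | Path, drop_empty: bool = True) -> "FingerprintMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, drop_empty=drop_empty)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "compound_id"
        out.to_csv(path, sep="\t")


def fingerprint_library(
    library: CompoundLibrary,
    backend: Mapping[str, str] | FingerprintMatrix | str | Path,
    drop_empty: bool = True,
) -> FingerprintMatrix:
    """Fingerprint every compound in the library.

    ``backend`` is either a SMARTS-key dictionary ``{key: smarts}``
    (evaluated with rdkit), a precomputed :class:`FingerprintMatrix`, or
    a path to a precomputed matrix TSV. For precomputed matrices the
    operation only validates coverage and reindexes rows into library
    order; a library compound absent from the matrix is an error.
    """
    if isinstance(backend, (str, Path)):
        backend = FingerprintMatrix.from_tsv(backend, drop_empty=False)
    if isinstance(backend, FingerprintMatrix):
        missing = [c for c in library.compound_ids if c not in backend.data.index]
        if missing:
            raise ValidationError(f"compound(s) missing from fingerprint matrix: {missing}")
        return FingerprintMatrix(backend.data.loc[library.compound_ids], drop_empty=drop_empty)
    # SMARTS dictionary backend
    if not _HAVE_RDKIT:
        raise ValidationError("SMARTS fingerprint backend requires rdkit; supply a matrix instead")
    patterns = {}
    for key, smarts in backend.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValidationError(f"invalid SMARTS for key {key!r}: {smarts!r}")
        patterns[key] = patt
    rows = {}
    for rec in library:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("compound %s: SMILES unparseable, all-zero fingerprint", rec.compound_id)
            rows[rec.compound_id] = {k: 0 for k in patterns}
            continue
        rows[rec.compound_id] = {k: int(mol.HasSubstructMatch(p)) for k, p in patterns.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").loc[library.compound_ids, list(backend.keys())]
    return FingerprintMatrix(df, drop_empty=drop_empty)
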