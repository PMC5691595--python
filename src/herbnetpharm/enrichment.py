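"""Gene-set over-representation analysis of predicted target sets.

One-sided hypergeometric test per gene set: with a universe of N genes
of which K belong to the set, and a query of n genes of which k overlap
the set, the enrichment p-value is the upper tail P(X >= k) of
Hypergeometric(N, K, n). P-values are adjusted across the collection by
Benjamini-Hochberg step-up FDR. Gene sets travel in GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


class GeneSetCollection:
    """Named gene sets restricted to a universe.

    Members outside the universe are dropped (count logged); a set left
    empty after restriction is dropped entirely.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe = frozenset(universe)
        if not self.universe:
            raise ValidationError("empty gene universe")
        self.sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            members = frozenset(members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            kept = members & self.universe
            dropped = len(members) - len(kept)
            if dropped:
                logger.info("set %s: dropped %d member(s) outside universe", name, dropped)
            if kept:
                self.sets[name] = kept
            else:
                logger.warning("set %s: no members in universe, dropped", name)

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file (name <tab> description <tab> member...).

        If no universe is given, the union of all set members is used.
        """
        sets = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
                sets[fields[0]] = [m for m in fields[2:] if m]
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets, universe)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                fh.write("\t".join([name, "na", *sorted(self.sets[name])]) + "\n")


@dataclass
class EnrichmentResult:
    """Per-set enrichment table, sorted by p ascending."""

    table: pd.DataFrame  # columns: set_name, k, K, n, N, p, q

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    @property
    def best_set(self) -> str:
        return self.table.iloc[0]["set_name"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation across a collection.

    The query is first restricted to the collection's universe (logged);
    BH adjustment spans all sets in the collection. Ties in p sort by
    set name for a stable report.
    """
    query = frozenset(query)
    restricted = query & collection.universe
    if len(restricted) < len(query):
        logger.info("query restricted to universe: %d -> %d genes", len(query), len(restricted))
    N = len(collection.universe)
    n = len(restricted)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(restricted & members)
        # P(X >= k) = sf(k-1); k=0 gives exactly 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].tolist()) if len(df) else []
    df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(df)
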