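"""Synthetic inputs with known ground truth for every pipeline stage.

No raw inputs of the original screen are publicly deposited, so each
consumer module is exercised on generated data whose dimensions mirror
the printed study tallies: a 48-compound herbal library split
18/13/11/3/3 across steroids, terpenes, flavonoids, fatty acids and
others; an admetSAR-style table in which exactly 37 compounds pass the
double absorption gate; a drug-target network in which substructure
sharing carries target signal (the statistical structure SDTNBI
assumes); a two-tissue expression table; and gene-set collections with
one planted enriched set.

Every generator is a pure function of :class:`SynthConfig` — two runs
with the same config produce identical objects and byte-identical
files — and emits a ground-truth sidecar so tests never re-derive truth
from generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .admet_screen import CYP_ISOFORMS, AdmetRecord
from .compound_library import (
    CompoundLibrary,
    CompoundRecord,
    FingerprintMatrix,
    normalize_smiles,
)
from .errors import ValidationError
from .tissue_filter import EXPRESSION_LEVELS, ExpressionTable

_CLASS_NAMES = ("steroid", "terpene", "flavonoid", "fatty_acid", "other")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; defaults mirror the printed tallies."""

    seed: int = 0
    n_compounds: int = 48
    class_mix: tuple[int, ...] = (18, 13, 11, 3, 3)  # steroid/terpene/flavonoid/fatty_acid/other
    admet_pass_count: int = 37

    # substructure-drug-target network
    n_substructures: int = 30
    n_planted: int = 20             # substructures with a planted target association
    n_drugs: int = 100
    n_targets: int = 20
    substructure_rate: float = 0.10  # P(drug carries a given substructure)
    planted_strength: float = 0.95   # P(carrier drug gains the associated target)
    noise_edge_rate: float = 0.1     # P(drug gains one extra random target)
    n_queries: int = 20

    # expression table
    detection_rate_keratinocyte: float = 0.8
    detection_rate_melanocyte: float = 0.7

    # gene sets
    n_gene_sets: int = 10
    gene_set_size: int = 10
    enriched_set_name: str = "planted_pathway"
    enrichment_factor: float = 5.0
    enriched_query_size: int = 15

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.admet_pass_count < 0:
            raise ValidationError("counts must be positive")
        if self.admet_pass_count > self.n_compounds:
            raise ValidationError("admet_pass_count cannot exceed n_compounds")
        if sum(self.class_mix) != self.n_compounds:
            raise ValidationError(
                f"class_mix {self.class_mix} must sum to n_compounds={self.n_compounds}"
            )
        if self.n_planted > self.n_substructures:
            raise ValidationError("n_planted cannot exceed n_substructures")

    def planted_associations(self) -> list[tuple[str, str, float]]:
        """(substructure_key, target_id, strength) triples, subs cycled over targets."""
        return [
            (f"S{i:02d}", f"T{i % self.n_targets:02d}", self.planted_strength)
            for i in range(self.n_planted)
        ]


def _rng(config: SynthConfig, tag: int) -> np.random.Generator:
    # independent stream per generator so adding one never perturbs another
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


# --- compound library -------------------------------------------------------

_SMILES_PARTS = ("C", "CC", "CCO", "c1ccccc1", "C(=O)O", "CN", "CO", "C=C")


def gen_compound_library(config: SynthConfig) -> CompoundLibrary:
    """A library in the study's class mix with simple valid SMILES."""
    rng = _rng(config, 1)
    records = []
    i = 0
    for cls, count in zip(_CLASS_NAMES, config.class_mix):
        for _ in range(count):
            n_frag = int(rng.integers(1, 4))
            smiles = "".join(rng.choice(_SMILES_PARTS) for _ in range(n_frag))
            smiles, _ = normalize_smiles(smiles)  # emit canonical form so files round-trip
            records.append(
                CompoundRecord(
                    compound_id=f"C{i + 1:02d}",
                    name=f"{cls}_{i + 1:02d}",
                    smiles=smiles,
                    structural_class=cls,
                )
            )
            i += 1
    return CompoundLibrary(records)


# --- ADMET table ------------------------------------------------------------


@dataclass
class SynthAdmet:
    records: list[AdmetRecord]
    pass_ids: list[str]  # ground truth: ids planted HIA+ and Caco-2+


def gen_admet_table(config: SynthConfig, compound_ids: Sequence[str] | None = None) -> SynthAdmet:
    """Signed-probability ADMET calls with a planted absorption pass count.

    Exactly ``admet_pass_count`` compounds are positive for both HIA and
    Caco-2; each failing compound is negative for at least one of the
    two. CYP calls are uniform(0.5, 1) magnitudes with random signs.
    """
    rng = _rng(config, 2)
    ids = list(compound_ids) if compound_ids is not None else [
        f"C{i + 1:02d}" for i in range(config.n_compounds)
    ]
    passing = set(rng.choice(ids, size=config.admet_pass_count, replace=False))
    records = []
    for cid in ids:
        hia_mag, caco_mag = rng.uniform(0.5, 1.0, size=2)
        if cid in passing:
            hia, caco = hia_mag, caco_mag
        else:
            which = rng.integers(0, 3)  # 0: HIA-, 1: Caco-, 2: both negative
            hia = -hia_mag if which in (0, 2) else hia_mag
            caco = -caco_mag if which in (1, 2) else caco_mag
        cyps = {
            k: float(rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0]))
            for k in CYP_ISOFORMS
        }
        records.append(AdmetRecord(cid, float(hia), float(caco), cyps))
    return SynthAdmet(records, sorted(passing))


def write_admet_tsv(records: Iterable[AdmetRecord], path: str | Path) -> None:
    """Write records in the signed-decimal TSV dialect (explicit '+' signs)."""
    with open(path, "w") as fh:
        fh.write("compound_id\tHIA\tCaco2\t" + "\t".join(CYP_ISOFORMS) + "\n")
        for r in records:
            cells = [r.hia, r.caco2] + [r.cyp_calls[k] for k in CYP_ISOFORMS]
            fh.write(r.compound_id + "\t" + "\t".join(f"{c:+.4f}" for c in cells) + "\n")


# --- DTI network with planted substructure-target signal --------------------


@dataclass
class SynthDTI:
    dti: list[tuple[str, str]]
    fingerprints: FingerprintMatrix          # known drugs
    query_fingerprints: FingerprintMatrix    # query compounds (not in the network)
    truth: pd.DataFrame                      # query_id, planted_substructure, expected_target


def gen_dti_with_signal(config: SynthConfig) -> SynthDTI:
    """A DTI network in which substructure sharing predicts target sharing.

    Each of the first ``n_planted`` substructure keys is associated with
    one target; a drug carrying a planted key gains the associated
    target with probability ``planted_strength``. Drugs additionally
    gain one uniformly random target with probability
    ``noise_edge_rate`` (and any drug left target-less gets one, so no
    known drug is dangling). Queries carry exactly one planted key plus
    background keys drawn from the non-planted pool, and the truth table
    names the target each query is expected to recover.
    """
    planted = config.planted_associations()
    if not planted:
        raise ValidationError("need at least one planted association")
    rng = _rng(config, 3)
    subs = [f"S{i:02d}" for i in range(config.n_substructures)]
    drugs = [f"D{i:02d}" for i in range(config.n_drugs)]
    targets = [f"T{i:02d}" for i in range(config.n_targets)]
    assoc = {s: t for s, t, _ in planted}
    strength = {s: st for s, _, st in planted}

    fp = (rng.random((config.n_drugs, config.n_substructures)) < config.substructure_rate).astype(int)
    edges: set[tuple[str, str]] = set()
    for i, d in enumerate(drugs):
        # guarantee at least one substructure so every drug is reachable
        if fp[i].sum() == 0:
            fp[i, rng.integers(0, config.n_substructures)] = 1
        for j, s in enumerate(subs):
            if fp[i, j] and s in assoc and rng.random() < strength[s]:
                edges.add((d, assoc[s]))
        if rng.random() < config.noise_edge_rate or not any(e[0] == d for e in edges):
            edges.add((d, str(rng.choice(targets))))
    fingerprints = FingerprintMatrix(pd.DataFrame(fp, index=drugs, columns=subs), drop_empty=False)

    n_bg = config.n_substructures - config.n_planted
    queries, truth_rows = {}, []
    planted_keys = [s for s, _, _ in planted]
    for q in range(config.n_queries):
        qid = f"Q{q:02d}"
        key = planted_keys[q % len(planted_keys)]
        row = {s: 0 for s in subs}
        row[key] = 1
        if n_bg:
            for j in range(config.n_planted, config.n_substructures):
                if rng.random() < config.substructure_rate:
                    row[subs[j]] = 1
        queries[qid] = row
        truth_rows.append(
            {"query_id": qid, "planted_substructure": key, "expected_target": assoc[key]}
        )
    qfp = FingerprintMatrix(
        pd.DataFrame.from_dict(queries, orient="index")[subs], drop_empty=False
    )
    return SynthDTI(sorted(edges), fingerprints, qfp, pd.DataFrame(truth_rows))


def permute_dti_targets(dti: Sequence[tuple[str, str]], seed: int) -> list[tuple[str, str]]:
    """Null model: shuffle the target column, destroying substructure signal."""
    drugs = [d for d, _ in dti]
    targets = [t for _, t in dti]
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(targets))
    return sorted(set(zip(drugs, shuffled)))


def write_dti_tsv(dti: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(dti, columns=["drug_id", "target_id"]).to_csv(path, sep="\t", index=False)


# --- expression table -------------------------------------------------------


@dataclass
class SynthExpression:
    table: ExpressionTable
    truth: pd.DataFrame  # target_id, in_keratinocyte, in_melanocyte


def gen_expression_table(targets: Sequence[str], config: SynthConfig) -> SynthExpression:
    """Two-tissue ordinal expression with per-tissue detection rates."""
    rng = _rng(config, 4)
    detected_levels = EXPRESSION_LEVELS[1:]
    rows, truth_rows = {}, []
    for t in targets:
        in_k = bool(rng.random() < config.detection_rate_keratinocyte)
        in_m = bool(rng.random() < config.detection_rate_melanocyte)
        rows[t] = {
            "keratinocyte": str(rng.choice(detected_levels)) if in_k else "not_detected",
            "melanocyte": str(rng.choice(detected_levels)) if in_m else "not_detected",
        }
        truth_rows.append({"target_id": t, "in_keratinocyte": in_k, "in_melanocyte": in_m})
    table = ExpressionTable(pd.DataFrame.from_dict(rows, orient="index"))
    return SynthExpression(table, pd.DataFrame(truth_rows))


# --- gene sets --------------------------------------------------------------


@dataclass
class SynthGeneSets:
    sets: dict[str, list[str]]
    universe: list[str]
    query: list[str]
    enriched_set_name: str


def gen_gene_sets(
    universe: Sequence[str], config: SynthConfig, query: Sequence[str] | None = None
) -> SynthGeneSets:
    """Gene-set collection with one set over-sampled from a query set.

    The planted set draws its members with weight ``enrichment_factor``
    for query genes versus 1 for the rest of the universe; the remaining
    sets are uniform draws. The query defaults to a deterministic sample
    of ``enriched_query_size`` universe genes.
    """
    rng = _rng(config, 5)
    universe = sorted(universe)
    size = min(config.gene_set_size, len(universe))
    if query is None:
        query = sorted(
            rng.choice(universe, size=min(config.enriched_query_size, len(universe)), replace=False)
        )
    query = sorted(set(query) & set(universe))
    weights = np.array([config.enrichment_factor if g in set(query) else 1.0 for g in universe])
    weights = weights / weights.sum()
    sets: dict[str, list[str]] = {
        config.enriched_set_name: sorted(
            rng.choice(universe, size=size, replace=False, p=weights)
        )
    }
    for i in range(config.n_gene_sets - 1):
        sets[f"random_set_{i:02d}"] = sorted(rng.choice(universe, size=size, replace=False))
    return SynthGeneSets(sets, list(universe), list(query), config.enriched_set_name)


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "synthetic", *sets[name]]) + "\n")


# --- one-call bundle --------------------------------------------------------


def write_all(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every input format into a directory; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from .compound_library import write_library

    library = gen_compound_library(config)
    paths["library"] = out / "library.csv"
    write_library(library, paths["library"])

    admet = gen_admet_table(config, library.compound_ids)
    paths["admet"] = out / "admet.tsv"
    write_admet_tsv(admet.records, paths["admet"])
    paths["admet_truth"] = out / "admet_pass_truth.txt"
    paths["admet_truth"].write_text("\n".join(admet.pass_ids) + "\n")

    net = gen_dti_with_signal(config)
    paths["dti"] = out / "dti.tsv"
    write_dti_tsv(net.dti, paths["dti"])
    paths["fingerprints"] = out / "fingerprints.tsv"
    net.fingerprints.to_tsv(paths["fingerprints"])
    paths["query_fingerprints"] = out / "query_fingerprints.tsv"
    net.query_fingerprints.to_tsv(paths["query_fingerprints"])
    paths["dti_truth"] = out / "dti_truth.tsv"
    net.truth.to_csv(paths["dti_truth"], sep="\t", index=False)

    targets = sorted({t for _, t in net.dti})
    expr = gen_expression_table(targets, config)
    paths["expression"] = out / "expression.tsv"
    expr.table.to_tsv(paths["expression"])
    paths["expression_truth"] = out / "expression_truth.tsv"
    expr.truth.to_csv(paths["expression_truth"], sep="\t", index=False)

    gs = gen_gene_sets(targets, config)
    paths["gene_sets"] = out / "gene_sets.gmt"
    write_gmt(gs.sets, paths["gene_sets"])
    paths["gene_sets_truth"] = out / "gene_sets_truth.txt"
    paths["gene_sets_truth"].write_text(
        f"enriched_set\t{gs.enriched_set_name}\nquery\t{','.join(gs.query)}\n"
    )
    return paths
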