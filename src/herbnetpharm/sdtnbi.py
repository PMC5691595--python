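"""Substructure-drug-target network-based inference (SDTNBI).

Targets of a query compound — typically a new chemical entity with no
known pharmacology — are predicted by diffusing resource over a
tripartite network: substructure keys link to the known drugs that carry
them, and drugs link to their known protein targets. The query is never
a node of the network; it injects unit mass through the substructures it
shares with the network.

The kernel is the parameterless degree-normalized resource-allocation
process this method family is built on, in three hops:

1. unit mass splits equally over the query's in-network substructures;
2. each substructure splits its mass over the drugs carrying it;
3. each drug splits its mass over its known targets.

Mass reaching a drug with no (remaining) targets is accounted in
``leaked_mass`` rather than renormalized away, so resource totals are
conserved exactly and reached-target scores are never silently inflated.
Hops 2 and 3 optionally penalize hub neighbors via degree exponents (see
:class:`DiffusionParams`); the default exponents of zero give the plain
equal split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .compound_library import FingerprintMatrix
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionParams:
    """Hop weighting for the diffusion kernel.

    At hop 2 (substructure -> drug) each receiving drug is weighted by
    its substructure-degree to the power ``-drug_degree_exponent``; at
    hop 3 (drug -> target) each receiving target is weighted by its
    drug-degree to the power ``-target_degree_exponent``. Weights are
    normalized among the sender's neighbors, so total mass is conserved
    for any exponents. Zero exponents (the default) recover the base
    equal-split kernel.
    """

    drug_degree_exponent: float = 0.0
    target_degree_exponent: float = 0.0


class SDTNetwork:
    """Tripartite substructure-drug-target network with degree indices.

    Built from a drug-target interaction (DTI) edge list and a
    substructure fingerprint matrix over the known drugs. Node ids must
    be disjoint across the three classes. Drugs that carry substructures
    but have no targets are kept and flagged dangling: mass reaching
    them leaks.
    """

    def __init__(
        self,
        drug_target_edges: Iterable[tuple[str, str]],
        substructure_drug_edges: Iterable[tuple[str, str]],
    ):
        dt = list(drug_target_edges)
        sd = list(substructure_drug_edges)
        if not dt:
            raise ValidationError("empty drug-target edge list")
        n_dup = len(dt) - len(set(dt))
        if n_dup:
            logger.info("deduplicated %d repeated drug-target edge(s)", n_dup)
        self.drug_target_edges: frozenset[tuple[str, str]] = frozenset(dt)
        self.substructure_drug_edges: frozenset[tuple[str, str]] = frozenset(sd)
        for a, b in self.drug_target_edges | self.substructure_drug_edges:
            if a == b:
                raise ValidationError(f"self-loop on id {a!r}")

        self.drug_to_targets: dict[str, frozenset[str]] = {}
        self.target_to_drugs: dict[str, frozenset[str]] = {}
        self.sub_to_drugs: dict[str, frozenset[str]] = {}
        self.drug_to_subs: dict[str, frozenset[str]] = {}
        for d, t in sorted(self.drug_target_edges):
            self.drug_to_targets.setdefault(d, set()).add(t)
            self.target_to_drugs.setdefault(t, set()).add(d)
        for s, d in sorted(self.substructure_drug_edges):
            self.sub_to_drugs.setdefault(s, set()).add(d)
            self.drug_to_subs.setdefault(d, set()).add(s)
        self.drug_to_targets = {k: frozenset(v) for k, v in self.drug_to_targets.items()}
        self.target_to_drugs = {k: frozenset(v) for k, v in self.target_to_drugs.items()}
        self.sub_to_drugs = {k: frozenset(v) for k, v in self.sub_to_drugs.items()}
        self.drug_to_subs = {k: frozenset(v) for k, v in self.drug_to_subs.items()}

        self.drugs = frozenset(self.drug_to_targets) | frozenset(self.drug_to_subs)
        self.targets = frozenset(self.target_to_drugs)
        self.substructures = frozenset(self.sub_to_drugs)
        overlap = (self.drugs & self.targets) | (self.drugs & self.substructures) | (
            self.targets & self.substructures
        )
        if overlap:
            raise ValidationError(f"ids shared across node classes: {sorted(overlap)}")
        self.dangling_drugs = frozenset(d for d in self.drugs if d not in self.drug_to_targets)

    def without_edges(self, edges: Iterable[tuple[str, str]]) -> "SDTNetwork":
        """A copy with the given drug-target edges removed (CV folds)."""
        removed = set(edges)
        remaining = self.drug_target_edges - removed
        return SDTNetwork(remaining, self.substructure_drug_edges)


def read_dti(path: str | Path) -> list[tuple[str, str]]:
    """Read a DTI edge list TSV with header columns drug_id, target_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"drug_id", "target_id"} - set(df.columns)
    if missing:
        raise FormatError(f"DTI file {path}: missing column(s) {sorted(missing)}")
    return list(df[["drug_id", "target_id"]].itertuples(index=False, name=None))


def build_sdt_network(
    dti: Iterable[tuple[str, str]] | str | Path,
    fingerprints: FingerprintMatrix,
) -> SDTNetwork:
    """Assemble the tripartite network from a DTI edge list and fingerprints.

    Every drug appearing in the DTI must have a fingerprint row; a drug
    with an all-zero fingerprint is kept with a warning (it can receive
    no diffusion mass but its targets remain scoreable via other drugs).
    """
    if isinstance(dti, (str, Path)):
        dti = read_dti(dti)
    dti = list(dti)
    dti_drugs = {d for d, _ in dti}
    missing = sorted(dti_drugs - set(fingerprints.compound_ids))
    if missing:
        raise ValidationError(f"drug(s) in DTI without fingerprint rows: {missing}")
    sd_edges = []
    for d in sorted(dti_drugs):
        subs = fingerprints.substructures_of(d)
        if not subs:
            logger.warning("drug %s has an all-zero fingerprint; kept without substructure edges", d)
        sd_edges.extend((s, d) for s in subs)
    network = SDTNetwork(dti, sd_edges)
    if network.dangling_drugs:
        logger.warning("%d dangling drug(s) without targets: %s",
                       len(network.dangling_drugs), sorted(network.dangling_drugs))
    return network


@dataclass
class DiffusionResult:
    """Resource landed on targets for one query, with leak accounting."""

    query_id: str
    resource: dict[str, float]
    leaked_mass: float

    @property
    def total_mass(self) -> float:
        return sum(self.resource.values()) + self.leaked_mass


@dataclass
class TargetPrediction:
    query_id: str
    ranked_targets: list[tuple[str, float]]
    k: int


def diffuse(
    network: SDTNetwork,
    query_substructures: Iterable[str],
    query_id: str = "query",
    params: DiffusionParams | None = None,
) -> DiffusionResult:
    """Run the three-hop resource-allocation diffusion for one query.

    Query substructure keys absent from the network are dropped with a
    warning; if none remain the result is empty with ``leaked_mass=1.0``.
    The invariant ``sum(resource) + leaked_mass == 1`` holds to 1e-12.
    """
    params = params or DiffusionParams()
    keys = sorted(set(query_substructures))
    present = [s for s in keys if s in network.substructures]
    absent = sorted(set(keys) - set(present))
    if absent:
        logger.warning("query %s: %d substructure key(s) not in network: %s",
                       query_id, len(absent), absent)
    if not present:
        logger.warning("query %s: no substructure overlaps the network; all mass leaks", query_id)
        return DiffusionResult(query_id, {}, 1.0)

    resource: dict[str, float] = {}
    leaked = 0.0
    sub_mass = 1.0 / len(present)
    for s in present:
        drugs = network.sub_to_drugs[s]
        dw = {d: len(network.drug_to_subs[d]) ** -params.drug_degree_exponent for d in drugs}
        dz = sum(dw.values())
        for d in drugs:
            drug_mass = sub_mass * dw[d] / dz
            targets = network.drug_to_targets.get(d, frozenset())
            if not targets:
                leaked += drug_mass
                continue
            tw = {
                t: len(network.target_to_drugs[t]) ** -params.target_degree_exponent
                for t in targets
            }
            tz = sum(tw.values())
            for t in targets:
                resource[t] = resource.get(t, 0.0) + drug_mass * tw[t] / tz
    return DiffusionResult(query_id, resource, leaked)


def predict_targets(
    network: SDTNetwork,
    query_substructures: Iterable[str],
    k: int = 20,
    query_id: str = "query",
    params: DiffusionParams | None = None,
) -> TargetPrediction:
    """Top-k targets by diffusion resource (ties broken by target id)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    result = diffuse(network, query_substructures, query_id=query_id, params=params)
    ranked = sorted(result.resource.items(), key=lambda kv: (-kv[1], kv[0]))
    return TargetPrediction(query_id, ranked[:k], k)


def predict_for_library(
    network: SDTNetwork,
    fingerprints: FingerprintMatrix,
    k: int = 20,
    params: DiffusionParams | None = None,
) -> list[TargetPrediction]:
    """Per-compound top-k predictions for every row of a query fingerprint matrix."""
    return [
        predict_targets(network, fingerprints.substructures_of(cid), k=k, query_id=cid, params=params)
        for cid in fingerprints.compound_ids
    ]


def write_predictions(predictions: Iterable[TargetPrediction], path: str | Path) -> None:
    rows = [
        {"query_id": p.query_id, "rank": i + 1, "target_id": t, "score": s}
        for p in predictions
        for i, (t, s) in enumerate(p.ranked_targets)
    ]
    pd.DataFrame(rows, columns=["query_id", "rank", "target_id", "score"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class CVReport:
    """Link-prediction cross-validation summary."""

    scheme: str
    fold_aucs: list[float]
    seed: int
    n_edges: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def cross_validate(
    network: SDTNetwork,
    scheme: str = "kfold:10",
    seed: int = 0,
    negatives_per_positive: int = 10,
    params: DiffusionParams | None = None,
) -> CVReport:
    """Hold-out validation of the diffusion ranking on known DTI edges.

    Edges are split into folds (``kfold:N`` or ``loo``). For each fold
    the held-out edges are removed, each affected drug is re-scored as a
    query through its own substructures on the reduced network, and every
    held-out positive edge is compared against ``negatives_per_positive``
    uniformly sampled non-edges of the same drug. The per-fold AUC is
    computed over the pooled positive/negative scores; folds and
    negative sampling are reproducible from ``seed``.
    """
    edges = sorted(network.drug_target_edges)
    if scheme == "loo":
        n_folds = len(edges)
    elif scheme.startswith("kfold:"):
        n_folds = int(scheme.split(":", 1)[1])
        if len(edges) < n_folds:
            raise ValidationError(
                f"{scheme} needs at least {n_folds} drug-target edges, have {len(edges)}"
            )
    else:
        raise ValueError(f"unknown CV scheme {scheme!r} (expected 'kfold:N' or 'loo')")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    folds = [sorted(edges[i] for i in order[f::n_folds]) for f in range(n_folds)]
    all_targets = sorted(network.targets)

    fold_aucs = []
    for fold in folds:
        if not fold:
            continue
        train = network.without_edges(fold)
        scores_by_drug: dict[str, dict[str, float]] = {}
        labels, scores = [], []
        for d, t in fold:
            if d not in scores_by_drug:
                res = diffuse(train, train.drug_to_subs.get(d, frozenset()),
                              query_id=d, params=params)
                scores_by_drug[d] = res.resource
            pos_score = scores_by_drug[d].get(t, 0.0)
            candidates = [x for x in all_targets if (d, x) not in network.drug_target_edges]
            neg = rng.choice(
                candidates, size=min(negatives_per_positive, len(candidates)), replace=False
            )
            labels.append(1)
            scores.append(pos_score)
            for x in neg:
                labels.append(0)
                scores.append(scores_by_drug[d].get(str(x), 0.0))
        if len(set(scores)) == 1:  # all tied: AUC is 0.5 by convention
            fold_aucs.append(0.5)
        else:
            fold_aucs.append(float(roc_auc_score(labels, scores)))
    return CVReport(scheme=scheme, fold_aucs=fold_aucs, seed=seed, n_edges=len(edges))
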