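"""Compound-target interaction (CTI) bipartite networks.

The screened compounds and their predicted targets form a bipartite
graph: a compound links to a target iff the target appears in the
compound's prediction list (optionally tissue-filtered upstream).
The graph is held in networkx with a ``kind`` attribute ('compound' or
'target') per node, exported for visualization tools as SIF or GraphML.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .sdtnbi import TargetPrediction

logger = logging.getLogger(__name__)


class CTINetwork:
    """Strictly bipartite compound-target graph with node annotations."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        for u, v in self.graph.edges:
            ku, kv = self.graph.nodes[u].get("kind"), self.graph.nodes[v].get("kind")
            if {ku, kv} != {"compound", "target"}:
                raise ValidationError(f"non-bipartite edge ({u}, {v}): kinds ({ku}, {kv})")

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "compound")

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "target")

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges oriented compound -> target."""
        out = set()
        for u, v in self.graph.edges:
            if self.graph.nodes[u]["kind"] == "compound":
                out.add((u, v))
            else:
                out.add((v, u))
        return frozenset(out)

    def targets_of(self, compound_id: str) -> frozenset[str]:
        if compound_id not in self.compounds:
            raise ValidationError(f"unknown compound id {compound_id!r}")
        return frozenset(self.graph.neighbors(compound_id))

    def annotate(self, annotations: Mapping[str, Mapping[str, str]]) -> None:
        """Left-outer join of node annotations; unknown node ids are flagged."""
        for node, attrs in annotations.items():
            if node not in self.graph:
                logger.warning("annotation for unknown node %r ignored", node)
                continue
            self.graph.nodes[node].update(attrs)


def build_cti(predictions: Iterable[TargetPrediction | tuple[str, str]]) -> CTINetwork:
    """Union the per-compound prediction lists into one bipartite graph.

    Accepts :class:`TargetPrediction` objects or raw ``(compound,
    target)`` pairs; duplicate pairs collapse to a single edge with the
    multiplicity logged.
    """
    pairs: list[tuple[str, str]] = []
    for p in predictions:
        if isinstance(p, TargetPrediction):
            pairs.extend((p.query_id, t) for t, _ in p.ranked_targets)
        else:
            pairs.append(tuple(p))
    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        logger.info("collapsed %d duplicate compound-target pair(s)", n_dup)
    g = nx.Graph()
    for c, t in pairs:
        g.add_node(c, kind="compound")
        g.add_node(t, kind="target")
        g.add_edge(c, t)
    return CTINetwork(g)


def common_targets(network: CTINetwork, compounds: Iterable[str]) -> frozenset[str]:
    """Targets shared by every compound in the selection."""
    compounds = sorted(set(compounds))
    if not compounds:
        return frozenset()
    neighborhoods = [network.targets_of(c) for c in compounds]
    return frozenset.intersection(*neighborhoods)


def coverage_fraction(network: CTINetwork, target_subset: Iterable[str]) -> float:
    """Fraction of the network's targets contained in the given subset."""
    targets = network.targets
    if not targets:
        return 0.0
    subset = set(target_subset)
    unknown = subset - targets
    if unknown:
        raise ValidationError(f"subset contains non-network target(s): {sorted(unknown)}")
    return len(subset) / len(targets)


def export_network(network: CTINetwork, fmt: str, path: str | Path) -> None:
    """Write the network for Cytoscape-style tools.

    SIF: one ``compound <tab> cti <tab> target`` line per edge.
    GraphML: carries node kind and any annotations ('NA' for missing
    attribute values so every node has the full attribute set).
    """
    if fmt == "sif":
        with open(path, "w") as fh:
            for c, t in sorted(network.edges):
                fh.write(f"{c}\tcti\t{t}\n")
    elif fmt == "graphml":
        g = network.graph.copy()
        keys = set().union(*(d.keys() for _, d in g.nodes(data=True))) if g.nodes else set()
        for n, d in g.nodes(data=True):
            for k in keys:
                d.setdefault(k, "NA")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected 'sif' or 'graphml')")


def import_network(fmt: str, path: str | Path) -> CTINetwork:
    """Read back a network written by :func:`export_network`."""
    if fmt == "sif":
        pairs = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    c, _, t = line.rstrip("\n").split("\t")
                    pairs.append((c, t))
        return build_cti(pairs)
    if fmt == "graphml":
        return CTINetwork(nx.read_graphml(path))
    raise ValueError(f"unknown import format {fmt!r} (expected 'sif' or 'graphml')")


def export_node_attributes(network: CTINetwork, path: str | Path) -> None:
    """Node-attribute TSV companion for the SIF export."""
    rows = []
    for n, d in sorted(network.graph.nodes(data=True)):
        rows.append({"node_id": n, **{k: v for k, v in d.items()}})
    pd.DataFrame(rows).fillna("NA").to_csv(path, sep="\t", index=False)
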