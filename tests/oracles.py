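"""Independent brute-force oracles, kept free of the implementation code paths."""

from __future__ import annotations

import math
from itertools import product


def diffusion_by_path_enumeration(
    sub_drug: list[tuple[str, str]],
    drug_target: list[tuple[str, str]],
    query_subs: list[str],
) -> tuple[dict[str, float], float]:
    """Sum over explicit paths of products of inverse out-degrees.

    Unit mass over the query's in-network substructures; every
    substructure->drug->target path contributes
    (1/n_subs) * (1/deg(sub)) * (1/deg(drug)). Paths dying at a
    target-less drug contribute to the leak.
    """
    sub_deg: dict[str, int] = {}
    drug_deg: dict[str, int] = {}
    for s, d in sub_drug:
        sub_deg[s] = sub_deg.get(s, 0) + 1
    for d, t in drug_target:
        drug_deg[d] = drug_deg.get(d, 0) + 1
    present = [s for s in sorted(set(query_subs)) if s in sub_deg]
    if not present:
        return {}, 1.0
    resource: dict[str, float] = {}
    leaked = 0.0
    start = 1.0 / len(present)
    for s in present:
        for s2, d in sub_drug:
            if s2 != s:
                continue
            mass_at_drug = start / sub_deg[s]
            if d not in drug_deg:
                leaked += mass_at_drug
                continue
            for d2, t in drug_target:
                if d2 == d:
                    resource[t] = resource.get(t, 0.0) + mass_at_drug / drug_deg[d]
    return resource, leaked


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation over outcomes."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Textbook step-up BH: m*p/i then running minimum from the largest p."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, pvalues[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def enumerate_small_networks(max_nodes: int = 2):
    """Every nonempty tripartite incidence pattern up to max_nodes per class."""
    for ns, nd, nt in product(range(1, max_nodes + 1), repeat=3):
        subs = [f"s{i}" for i in range(ns)]
        drugs = [f"d{i}" for i in range(nd)]
        targets = [f"t{i}" for i in range(nt)]
        sd_pairs = [(s, d) for s in subs for d in drugs]
        dt_pairs = [(d, t) for d in drugs for t in targets]
        for sd_mask in range(1, 2 ** len(sd_pairs)):
            sd = [p for i, p in enumerate(sd_pairs) if sd_mask >> i & 1]
            for dt_mask in range(1, 2 ** len(dt_pairs)):
                dt = [p for i, p in enumerate(dt_pairs) if dt_mask >> i & 1]
                yield sd, dt, subs
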