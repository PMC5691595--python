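"""Diffusion kernel, top-k prediction and cross-validation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnetpharm.compound_library import FingerprintMatrix
from herbnetpharm.errors import ValidationError
from herbnetpharm.sdtnbi import (
    DiffusionParams,
    SDTNetwork,
    build_sdt_network,
    cross_validate,
    diffuse,
    predict_targets,
)
from herbnetpharm.synthetic import SynthConfig, gen_dti_with_signal, permute_dti_targets

from oracles import diffusion_by_path_enumeration, enumerate_small_networks


class TestBuild:
    def test_toy_degrees(self, toy_network):
        net = toy_network
        assert net.sub_to_drugs["s1"] == {"d1", "d2"}
        assert net.sub_to_drugs["s2"] == {"d1"}
        assert net.drug_to_targets["d1"] == {"t1", "t2"}
        assert net.drug_to_targets["d2"] == {"t2"}
        assert net.dangling_drugs == frozenset()

    def test_missing_fingerprint_row_named(self):
        fp = FingerprintMatrix(pd.DataFrame([[1]], index=["d1"], columns=["s1"]))
        with pytest.raises(ValidationError, match="d2"):
            build_sdt_network([("d1", "t1"), ("d2", "t1")], fp)

    def test_duplicate_edges_deduplicated(self):
        fp = FingerprintMatrix(pd.DataFrame([[1]], index=["d1"], columns=["s1"]))
        net = build_sdt_network([("d1", "t1"), ("d1", "t1")], fp)
        assert len(net.drug_target_edges) == 1

    def test_empty_dti_rejected(self):
        with pytest.raises(ValidationError):
            SDTNetwork([], [("s1", "d1")])

    def test_shared_ids_across_classes_rejected(self):
        with pytest.raises(ValidationError):
            SDTNetwork([("x", "t1")], [("x", "d1")])  # x is both drug and substructure


class TestDiffuse:
    def test_worked_example(self, toy_network):
        """Path enumeration gives t1 = 0.375, t2 = 0.625 for query {s1, s2}."""
        res = diffuse(toy_network, {"s1", "s2"})
        assert res.resource["t1"] == pytest.approx(0.375, abs=1e-12)
        assert res.resource["t2"] == pytest.approx(0.625, abs=1e-12)
        assert res.leaked_mass == 0.0

    def test_single_chain_conserves_mass(self):
        net = SDTNetwork([("d1", "t1")], [("s1", "d1")])
        res = diffuse(net, {"s1"})
        assert res.resource == {"t1": pytest.approx(1.0)}

    def test_targetless_drug_leaks_everything(self):
        net = SDTNetwork([("d1", "t1")], [("s1", "d1"), ("s2", "d2")])
        res = diffuse(net, {"s2"})
        assert res.resource == {}
        assert res.leaked_mass == pytest.approx(1.0)

    def test_unknown_substructures_dropped(self, toy_network):
        res = diffuse(toy_network, {"s1", "nope"})
        assert res.total_mass == pytest.approx(1.0, abs=1e-12)

    def test_no_known_substructure_leaks_all(self, toy_network):
        res = diffuse(toy_network, {"nope"})
        assert res.resource == {} and res.leaked_mass == 1.0

    def test_oracle_equivalence_exhaustive_small(self):
        """Matches brute-force path enumeration on every tiny incidence pattern."""
        n = 0
        for sd, dt, subs in enumerate_small_networks(max_nodes=2):
            net = SDTNetwork(dt, sd)
            expected, expected_leak = diffusion_by_path_enumeration(sd, dt, subs)
            res = diffuse(net, subs)
            assert res.leaked_mass == pytest.approx(expected_leak, abs=1e-12)
            assert set(res.resource) == set(expected)
            for t, v in expected.items():
                assert res.resource[t] == pytest.approx(v, abs=1e-12)
            n += 1
        assert n > 300

    def test_oracle_equivalence_random_medium(self):
        """Matches path enumeration on random networks up to 6 nodes per class."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            ns, nd, nt = rng.integers(1, 7, size=3)
            sd = [(f"s{i}", f"d{j}") for i in range(ns) for j in range(nd) if rng.random() < 0.5]
            dt = [(f"d{j}", f"t{k}") for j in range(nd) for k in range(nt) if rng.random() < 0.5]
            if not dt:
                continue
            net = SDTNetwork(dt, sd)
            q = [f"s{i}" for i in range(ns)]
            expected, expected_leak = diffusion_by_path_enumeration(sd, dt, q)
            res = diffuse(net, q)
            assert res.leaked_mass == pytest.approx(expected_leak, abs=1e-12)
            for t in set(expected) | set(res.resource):
                assert res.resource.get(t, 0.0) == pytest.approx(expected.get(t, 0.0), abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_mass_conservation_random_queries(self, seed):
        """Resource total plus leak is exactly the injected unit mass."""
        rng = np.random.default_rng(seed)
        cfg = SynthConfig(seed=int(seed) % 1000)
        synth = gen_dti_with_signal(cfg)
        net = build_sdt_network(synth.dti, synth.fingerprints)
        subs = list(net.substructures)
        query = set(rng.choice(subs, size=rng.integers(1, 6), replace=False))
        res = diffuse(net, query)
        assert res.total_mass == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self, toy_network):
        """Relabeling every node id permutes the result identically."""
        relabel = {"s1": "sA", "s2": "sB", "d1": "dA", "d2": "dB", "t1": "tA", "t2": "tB"}
        net2 = SDTNetwork(
            [(relabel[d], relabel[t]) for d, t in toy_network.drug_target_edges],
            [(relabel[s], relabel[d]) for s, d in toy_network.substructure_drug_edges],
        )
        res1 = diffuse(toy_network, {"s1", "s2"})
        res2 = diffuse(net2, {"sA", "sB"})
        assert {relabel[t]: v for t, v in res1.resource.items()} == pytest.approx(res2.resource)

    def test_duplicate_drug_does_not_change_rank_order(self, toy_network):
        """Cloning a drug (same substructures, same targets) preserves target ranks."""
        net2 = SDTNetwork(
            list(toy_network.drug_target_edges) + [("d1x", "t1"), ("d1x", "t2")],
            list(toy_network.substructure_drug_edges) + [("s1", "d1x"), ("s2", "d1x")],
        )
        order1 = [t for t, _ in predict_targets(toy_network, {"s1", "s2"}, k=10).ranked_targets]
        order2 = [t for t, _ in predict_targets(net2, {"s1", "s2"}, k=10).ranked_targets]
        assert order1 == order2

    def test_hop_exponents_conserve_mass(self, toy_network):
        res = diffuse(toy_network, {"s1", "s2"},
                      params=DiffusionParams(drug_degree_exponent=0.5, target_degree_exponent=1.0))
        assert res.total_mass == pytest.approx(1.0, abs=1e-12)


class TestPredict:
    def test_toy_top1(self, toy_network):
        pred = predict_targets(toy_network, {"s1", "s2"}, k=1)
        assert [t for t, _ in pred.ranked_targets] == ["t2"]

    def test_k_larger_than_reached(self, toy_network):
        pred = predict_targets(toy_network, {"s1", "s2"}, k=50)
        assert len(pred.ranked_targets) == 2

    def test_tie_broken_by_id(self):
        net = SDTNetwork([("d1", "t1"), ("d1", "t2")], [("s1", "d1")])
        pred = predict_targets(net, {"s1"}, k=2)
        assert [t for t, _ in pred.ranked_targets] == ["t1", "t2"]

    def test_scores_non_increasing(self, toy_network):
        scores = [s for _, s in predict_targets(toy_network, {"s1", "s2"}, k=5).ranked_targets]
        assert scores == sorted(scores, reverse=True)


class TestCrossValidate:
    def test_planted_signal_recovered(self):
        """Substructure-driven networks are predictable: mean AUC >= 0.9."""
        cfg = SynthConfig(seed=11)
        synth = gen_dti_with_signal(cfg)
        net = build_sdt_network(synth.dti, synth.fingerprints)
        report = cross_validate(net, scheme="kfold:10", seed=11)
        assert len(report.fold_aucs) == 10
        assert report.mean_auc >= 0.9

    def test_permuted_labels_near_chance(self):
        cfg = SynthConfig(seed=11)
        synth = gen_dti_with_signal(cfg)
        permuted = permute_dti_targets(synth.dti, seed=11)
        net = build_sdt_network(permuted, synth.fingerprints)
        report = cross_validate(net, scheme="kfold:10", seed=11)
        assert 0.4 <= report.mean_auc <= 0.6

    def test_no_leakage_fold_edges_absent(self, toy_network):
        """Removing a fold's edges really changes the degree structure used for scoring."""
        reduced = toy_network.without_edges([("d1", "t1")])
        assert ("d1", "t1") not in reduced.drug_target_edges
        assert reduced.drug_to_targets["d1"] == {"t2"}
        assert reduced.substructure_drug_edges == toy_network.substructure_drug_edges

    def test_reproducible_from_seed(self):
        cfg = SynthConfig(seed=3, n_drugs=30)
        synth = gen_dti_with_signal(cfg)
        net = build_sdt_network(synth.dti, synth.fingerprints)
        r1 = cross_validate(net, scheme="kfold:10", seed=5)
        r2 = cross_validate(net, scheme="kfold:10", seed=5)
        assert r1.fold_aucs == r2.fold_aucs

    def test_too_few_edges_rejected(self, toy_network):
        with pytest.raises(ValidationError):
            cross_validate(toy_network, scheme="kfold:10")

    def test_unknown_scheme_rejected(self, toy_network):
        with pytest.raises(ValueError):
            cross_validate(toy_network, scheme="bootstrap")
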