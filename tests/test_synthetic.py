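"""Ground-truth guarantees and determinism of the synthetic generators."""

import pathlib

import pytest

from herbnetpharm.admet_screen import absorption_filter
from herbnetpharm.errors import ValidationError
from herbnetpharm.sdtnbi import build_sdt_network, predict_targets
from herbnetpharm.synthetic import (
    SynthConfig,
    gen_admet_table,
    gen_compound_library,
    gen_dti_with_signal,
    gen_expression_table,
    gen_gene_sets,
    permute_dti_targets,
    write_all,
)
from herbnetpharm.tissue_filter import classify_targets


class TestConfig:
    def test_class_mix_must_sum(self):
        with pytest.raises(ValidationError):
            SynthConfig(class_mix=(10, 10, 10, 10, 10))

    def test_pass_count_bounded(self):
        with pytest.raises(ValidationError):
            SynthConfig(admet_pass_count=49)


class TestLibrary:
    def test_default_mix_mirrors_study(self):
        lib = gen_compound_library(SynthConfig(seed=0))
        classes = [r.structural_class for r in lib]
        assert len(lib) == 48
        assert (classes.count("steroid"), classes.count("terpene"),
                classes.count("flavonoid"), classes.count("fatty_acid"),
                classes.count("other")) == (18, 13, 11, 3, 3)


class TestAdmet:
    def test_planted_pass_count_matches_filter(self):
        """The absorption filter recovers exactly the planted double-positives."""
        synth = gen_admet_table(SynthConfig(seed=1))
        kept = absorption_filter(synth.records)
        assert len(kept) == 37
        assert sorted(r.compound_id for r in kept) == synth.pass_ids

    def test_zero_pass_count(self):
        synth = gen_admet_table(SynthConfig(seed=1, admet_pass_count=0))
        assert absorption_filter(synth.records) == []

    def test_failing_records_fail_at_least_one_gate(self):
        synth = gen_admet_table(SynthConfig(seed=4))
        failing = [r for r in synth.records if r.compound_id not in synth.pass_ids]
        assert all(r.hia < 0 or r.caco2 < 0 for r in failing)


class TestDtiSignal:
    def test_planted_target_in_top3_for_most_queries(self):
        """Strength-0.95 planting: the associated target ranks top-3 for >=90% of queries."""
        cfg = SynthConfig(seed=2, n_drugs=50)
        synth = gen_dti_with_signal(cfg)
        net = build_sdt_network(synth.dti, synth.fingerprints)
        hits = 0
        for row in synth.truth.itertuples(index=False):
            pred = predict_targets(net, synth.query_fingerprints.substructures_of(row.query_id), k=3)
            hits += row.expected_target in [t for t, _ in pred.ranked_targets]
        assert hits >= 0.9 * len(synth.truth)

    def test_zero_strength_no_planted_advantage(self):
        """With strength 0 the planted target's rank is driven by chance alone."""
        import numpy as np

        cfg = SynthConfig(seed=2, planted_strength=0.0)
        synth = gen_dti_with_signal(cfg)
        net = build_sdt_network(synth.dti, synth.fingerprints)
        ranks = []
        for row in synth.truth.itertuples(index=False):
            pred = predict_targets(net, synth.query_fingerprints.substructures_of(row.query_id),
                                   k=cfg.n_targets)
            order = [t for t, _ in pred.ranked_targets]
            ranks.append(order.index(row.expected_target) + 1 if row.expected_target in order
                         else cfg.n_targets)
        # median rank near the middle of 20 targets, not pinned to the top
        assert np.median(ranks) > 3

    def test_same_seed_identical_network(self):
        a = gen_dti_with_signal(SynthConfig(seed=9))
        b = gen_dti_with_signal(SynthConfig(seed=9))
        assert a.dti == b.dti
        assert a.fingerprints == b.fingerprints
        assert a.truth.equals(b.truth)

    def test_permutation_keeps_node_sets(self):
        synth = gen_dti_with_signal(SynthConfig(seed=3))
        permuted = permute_dti_targets(synth.dti, seed=3)
        assert {d for d, _ in permuted} == {d for d, _ in synth.dti}
        assert {t for _, t in permuted} <= {t for _, t in synth.dti}
        assert len(permuted) <= len(synth.dti)


class TestExpressionAndSets:
    def test_full_detection_puts_all_in_both(self):
        cfg = SynthConfig(seed=1, detection_rate_keratinocyte=1.0, detection_rate_melanocyte=1.0)
        targets = [f"T{i:02d}" for i in range(15)]
        synth = gen_expression_table(targets, cfg)
        cls = classify_targets(targets, synth.table)
        assert cls.both == frozenset(targets)

    def test_zero_detection_all_neither(self):
        cfg = SynthConfig(seed=1, detection_rate_keratinocyte=0.0, detection_rate_melanocyte=0.0)
        targets = [f"T{i:02d}" for i in range(15)]
        synth = gen_expression_table(targets, cfg)
        cls = classify_targets(targets, synth.table)
        assert cls.neither == frozenset(targets)

    def test_truth_sidecar_matches_table(self):
        cfg = SynthConfig(seed=6)
        targets = [f"T{i:02d}" for i in range(20)]
        synth = gen_expression_table(targets, cfg)
        for row in synth.truth.itertuples(index=False):
            assert (synth.table.level(row.target_id, "keratinocyte") != "not_detected") == row.in_keratinocyte

    def test_gene_sets_cover_universe(self):
        universe = [f"T{i:02d}" for i in range(40)]
        gs = gen_gene_sets(universe, SynthConfig(seed=2))
        assert all(set(m) <= set(universe) for m in gs.sets.values())
        assert gs.enriched_set_name in gs.sets


class TestBundle:
    def test_byte_identical_per_seed_and_parses_clean(self, tmp_path, caplog):
        import logging

        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_all(SynthConfig(seed=7), d1)
        p2 = write_all(SynthConfig(seed=7), d2)
        for key in p1:
            assert pathlib.Path(p1[key]).read_bytes() == pathlib.Path(p2[key]).read_bytes(), key

        # every generated file parses through its consuming module without warnings
        from herbnetpharm.admet_screen import read_admet_table
        from herbnetpharm.compound_library import FingerprintMatrix, load_compounds
        from herbnetpharm.enrichment import GeneSetCollection
        from herbnetpharm.sdtnbi import read_dti
        from herbnetpharm.tissue_filter import ExpressionTable

        logging.disable(logging.NOTSET)
        with caplog.at_level(logging.WARNING, logger="herbnetpharm"):
            assert len(load_compounds(p1["library"])) == 48
            assert len(read_admet_table(p1["admet"])) == 48
            assert len(read_dti(p1["dti"])) > 0
            FingerprintMatrix.from_tsv(p1["fingerprints"])
            ExpressionTable.from_tsv(p1["expression"])
            GeneSetCollection.from_gmt(p1["gene_sets"])
        assert [r for r in caplog.records if r.levelno >= logging.WARNING] == []
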