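"""Synthetic benchmark generator: determinism, planted truth, detection."""

import math

import numpy as np
import pytest

import circbench as cb
from circbench.synthetic_data import linear_site_coverage, make_benchmark
from circbench.truth_eval import filter_min_junction_reads, label_candidates


class TestTranscriptome:
    def test_same_seed_identical(self, small_config):
        a = cb.simulate_transcriptome(small_config)
        b = cb.simulate_transcriptome(small_config)
        assert a.genome == b.genome
        assert [t.key for t in a.circs] == [t.key for t in b.circs]
        assert [d.key for d in a.decoys] == [d.key for d in b.decoys]

    def test_planted_keys_unique_and_inside_genome(self, small_world):
        tx = small_world["tx"]
        cfg = small_world["config"]
        keys = [t.key for t in tx.circs]
        assert len(keys) == len(set(keys)) == cfg.n_circ
        for t in tx.circs + tx.linears:
            assert 1 <= t.start <= t.end <= cfg.genome_length
            if t.is_circ:
                assert t.length >= 2 * cfg.read_length

    def test_no_circs_config(self):
        cfg = cb.SimConfig(
            n_circ=0, n_linear=10, genome_length=100_000, depth=500, n_decoys=0, seed=1
        )
        tx = cb.simulate_transcriptome(cfg)
        assert tx.circs == []
        m1, m2, _ = cb.simulate_reads(tx, cfg, "total")
        assert len(cb.pseudo_predict((m1, m2), tx, cfg)) == 0

    def test_junction_probe_is_suffix_plus_prefix(self, small_world):
        tx = small_world["tx"]
        cfg = small_world["config"]
        t = tx.circs[0]
        seq = tx.sequence(t)
        probe = tx.junction_probe(t, cfg.probe_flank)
        assert probe == seq[-cfg.probe_flank :] + seq[: cfg.probe_flank]

    def test_decoy_probes_are_contiguous_genome(self, small_world):
        tx = small_world["tx"]
        for d in tx.decoys:
            assert d.probe in tx.genome

    def test_genome_too_short_rejected(self):
        cfg = cb.SimConfig(genome_length=1000, seed=1)
        with pytest.raises(ValueError):
            cb.simulate_transcriptome(cfg)


class TestSimulateReads:
    def test_deterministic_under_seed(self, small_config):
        tx = cb.simulate_transcriptome(small_config)
        a1, a2, _ = cb.simulate_reads(tx, small_config, "total")
        b1, b2, _ = cb.simulate_reads(tx, small_config, "total")
        assert a1 == b1 and a2 == b2

    def test_depth_and_read_structure(self, small_world):
        cfg = small_world["config"]
        m1, m2 = small_world["total"]
        assert len(m1) == len(m2) == cfg.depth
        for rec in (m1[0], m2[-1]):
            rec.validate()
            assert len(rec) == cfg.read_length

    def test_rnaser_enriches_circular_fraction(self, small_world):
        frac_total = small_world["truth_total"].is_circ.mean()
        frac_rnaser = small_world["truth_rnaser"].is_circ.mean()
        assert frac_rnaser > 5 * frac_total > 0

    def test_zero_linear_survival_removes_linear_reads(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, rnaser_linear_survival=0.0)
        tx = cb.simulate_transcriptome(cfg)
        _, _, truth = cb.simulate_reads(tx, cfg, "rnaser")
        assert truth.is_circ.all()

    def test_bsj_spanning_rate_matches_closed_form(self):
        # One circle, fragment length pinned to the read length: each mate
        # interval equals the fragment, so a pair spans the junction iff its
        # start falls in the L-1 positions wrapping the origin.  Check the
        # realized count against this expectation within 4 binomial SDs.
        cfg = cb.SimConfig(
            n_circ=1,
            n_linear=1,
            genome_length=100_000,
            depth=4000,
            fragment_mean=100.0,
            fragment_sd=0.0,
            n_decoys=0,
            circ_abundance=5.0,  # make circular reads plentiful for the check
            seed=3,
        )
        tx = cb.simulate_transcriptome(cfg)
        _, _, truth = cb.simulate_reads(tx, cfg, "total")
        circ = tx.circs[0]
        n_circ_pairs = int(truth.is_circ.sum())
        L = cfg.read_length
        p_span = (L - 1) / circ.length
        expected = n_circ_pairs * p_span
        sd = math.sqrt(n_circ_pairs * p_span * (1 - p_span))
        assert abs(int(truth.spans_bsj.sum()) - expected) <= 4 * sd

    def test_qualifying_overlap_never_exceeds_half_read(self, small_world):
        ov = small_world["truth_total"].bsj_overlap
        assert ov.min() >= 0
        assert ov.max() <= small_world["config"].read_length // 2


class TestPseudoPredict:
    def test_high_expression_circ_detected_and_counts_match_truth(self, small_world):
        cfg = small_world["config"]
        tx = small_world["tx"]
        truth = small_world["truth_rnaser"]
        preds = cb.pseudo_predict(small_world["rnaser"], tx, cfg)
        # per-circ qualifying pairs straight from provenance
        qual = truth.bsj_overlap >= cfg.min_overlap
        for t in tx.circs:
            expected = int(np.sum(qual & (truth.source_tid == t.tid)))
            got = preds.get(t.key)
            if expected >= 2:
                assert got is not None, f"{t.tid} with {expected} spanning pairs missed"
            if got is not None and t.key not in tx.decoy_keys():
                assert got.junction_reads == expected

    def test_error_injection_reduces_detections(self, small_world):
        cfg = small_world["config"]
        tx = small_world["tx"]
        m1, m2 = small_world["rnaser"]
        clean = filter_min_junction_reads(cb.pseudo_predict((m1, m2), tx, cfg), 2)
        e1, e2 = cb.inject_errors(m1, m2, 20, seed=cfg.seed)
        noisy = filter_min_junction_reads(cb.pseudo_predict((e1, e2), tx, cfg), 2)
        assert len(noisy) < len(clean)

    def test_no_reads_gives_empty_set(self, small_world):
        assert len(cb.pseudo_predict([], small_world["tx"], small_world["config"])) == 0

    def test_single_end_input_accepted(self, small_world):
        cfg = small_world["config"]
        tx = small_world["tx"]
        m1, m2 = small_world["rnaser"]
        se = cb.split_single_end(m1, m2, 1)
        pe = cb.pseudo_predict((m1, m2), tx, cfg)
        se_preds = cb.pseudo_predict(se, tx, cfg)
        for cand in se_preds:
            pe_cand = pe.get(cand.key)
            assert pe_cand is not None
            assert cand.junction_reads <= pe_cand.junction_reads

    def test_mismatch_tolerance_boundary(self, small_world):
        # A read built from a probe core with exactly max_mismatch errors is
        # found; one more mismatch and it is not.
        cfg = small_world["config"]
        tx = small_world["tx"]
        t = tx.circs[0]
        core = tx.junction_probe(t, cfg.probe_flank)[
            cfg.probe_flank - cfg.min_overlap : cfg.probe_flank + cfg.min_overlap
        ]

        def flip(base):
            return "A" if base != "A" else "C"

        pad = "G" * 40
        for n_err, should_find in ((cfg.max_mismatch, True), (cfg.max_mismatch + 1, False)):
            mutated = list(core)
            for i in range(n_err):
                mutated[2 * i] = flip(mutated[2 * i])
            read = cb.FastqRecord("probe_read", 1, pad + "".join(mutated) + pad, "I" * (80 + len(core)))
            preds = cb.pseudo_predict([read], tx, cfg)
            assert (t.key in preds) == should_find


class TestTruthLabelingEndToEnd:
    def test_labels_on_small_world(self, small_world):
        cfg = small_world["config"]
        tx = small_world["tx"]
        pt = filter_min_junction_reads(
            cb.pseudo_predict(small_world["total"], tx, cfg), 2
        )
        pr = filter_min_junction_reads(
            cb.pseudo_predict(small_world["rnaser"], tx, cfg), 2
        )
        labeled = label_candidates(pt, pr)
        assert {c.key for c in labeled} <= tx.circ_keys() | tx.decoy_keys()
        detected_circs = [c for c in labeled if c.key in tx.circ_keys()]
        # planted circles are strongly RNase-R enriched at any abundance
        for c in detected_circs:
            assert c.m > c.n

    def test_linear_site_coverage_counts_overlapping_pairs(self, small_world):
        truth = small_world["truth_total"]
        tx = small_world["tx"]
        keys = [t.key for t in tx.circs[:3]]
        cov = linear_site_coverage(truth, keys)
        lin = ~truth.is_circ
        for key in keys:
            _, s, e = key
            manual = int(
                np.sum(
                    lin
                    & (
                        ((truth.frag_start <= s) & (truth.frag_end >= s))
                        | ((truth.frag_start <= e) & (truth.frag_end >= e))
                    )
                )
            )
            assert cov[key] == manual


class TestMakeBenchmark:
    def test_file_inventory_and_determinism(self, tmp_path):
        cfg = cb.SimConfig(
            n_circ=4, n_linear=15, genome_length=100_000, depth=1500, n_decoys=2, seed=5
        )
        m1 = make_benchmark(cfg, tmp_path / "a")
        m2 = make_benchmark(cfg, tmp_path / "b")
        for name in (
            "total_1.fastq", "total_2.fastq", "rnaser_1.fastq", "rnaser_2.fastq",
            "total_preds.tsv", "rnaser_preds.tsv", "total_truth.tsv", "manifest.json",
        ):
            assert (tmp_path / "a" / name).exists()
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert m1["realized"] == m2["realized"]
        assert len(m1["planted_circs"]) == 4

    def test_no_circs_empty_prediction_tables(self, tmp_path):
        cfg = cb.SimConfig(
            n_circ=0, n_linear=10, genome_length=100_000, depth=500, n_decoys=0, seed=2
        )
        make_benchmark(cfg, tmp_path)
        assert (tmp_path / "total_preds.tsv").read_text() == ""
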