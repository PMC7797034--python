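"""Generator contracts: determinism, planting exactness, noise models."""

import numpy as np
import pytest

from mirclip.registers import SiteClass, all_patterns
from mirclip.scanner import scan
from mirclip.simulate import (
    DEFAULT_RESPONSE_EFFECTS,
    default_registers,
    generate_counts,
    generate_response,
    generate_small_rna,
    generate_transcriptome,
    make_site_plan,
    minimal_truth,
    synthetic_hairpin,
)


class TestTranscriptome:
    def test_seed_reproducibility(self):
        plan = make_site_plan(30, 0.2)
        a, truth_a = generate_transcriptome(30, site_plan=plan, seed=5)
        b, truth_b = generate_transcriptome(30, site_plan=plan, seed=5)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert truth_a.to_json() == truth_b.to_json()

    def test_scan_recall_and_precision_exactly_one(self, register_pair):
        base, ext = register_pair
        plan = make_site_plan(60, 1 / 6, SiteClass.SEVENMER_M8, region="utr3")
        recs, truth = generate_transcriptome(60, site_plan=plan, seed=8)
        patterns = [p for r in (base, ext) for p in all_patterns(r)]
        got = {
            (m.transcript_id, m.mirna_name, m.site_class, m.start, m.end, m.region)
            for m in scan(recs, patterns, region="whole")
        }
        exp = {
            (m.transcript_id, m.mirna_name, m.site_class, m.start, m.end, m.region)
            for m in truth.expected_matches
        }
        assert got == exp  # precision and recall both exactly 1 vs truth
        planted = {(s.transcript_id, s.mirna_name, s.site_class, s.start) for s in truth.sites}
        found = {(m[0], m[1], m[2], m[3]) for m in got}
        assert planted <= found

    def test_empty_plan_yields_clean_background(self, register_pair):
        base, ext = register_pair
        recs, truth = generate_transcriptome(20, seed=2)
        patterns = [p for r in (base, ext) for p in all_patterns(r)]
        assert scan(recs, patterns) == []
        assert truth.sites == [] and truth.expected_matches == []

    def test_planted_region_respected(self):
        plan = {0: [(None, SiteClass.EIGHTMER, "utr3")], 1: [(None, SiteClass.EIGHTMER, "non_utr3")]}
        recs, truth = generate_transcriptome(4, site_plan=plan, seed=3)
        by_tid = truth.sites_by_transcript()
        utr = recs[0].utr3
        s0 = by_tid[recs[0].transcript_id][0]
        assert utr[0] <= s0.start < utr[1]
        s1 = by_tid[recs[1].transcript_id][0]
        assert s1.start < recs[1].utr3[0]

    def test_infeasible_plan_rejected(self):
        plan = {0: [(None, SiteClass.EIGHTMER, "utr3")]}
        with pytest.raises((ValueError, RuntimeError)):
            generate_transcriptome(1, length_range=(30, 30), utr_fraction=0.1, site_plan=plan, seed=0)

    def test_enrichment_factors_follow_sites(self):
        plan = make_site_plan(10, 0.3)
        _, truth = generate_transcriptome(10, site_plan=plan, clip_enrichment=2.5, seed=4)
        planted_ids = {s.transcript_id for s in truth.sites}
        for tid in truth.transcript_ids:
            assert truth.enrichment_factors[tid] == (2.5 if tid in planted_ids else 1.0)


class TestCounts:
    def test_poisson_limit_variance_matches_mean(self):
        ids = ["A", "B", "C"]
        truth = minimal_truth(ids)
        cm = generate_counts(truth, n_input_reps=300, n_clip_reps=0, dispersion=0.0,
                             baseline_log_sd=0.0, seed=6)
        values = cm.counts.to_numpy(float)
        m = values.mean(axis=1)
        v = values.var(axis=1, ddof=1)
        assert np.allclose(v / m, 1.0, atol=0.25)

    def test_nb_overdispersion(self):
        truth = minimal_truth(["A"])
        cm = generate_counts(truth, n_input_reps=500, n_clip_reps=0, dispersion=0.2,
                             baseline_log_sd=0.0, seed=6)
        x = cm.counts.to_numpy(float)[0]
        phi_hat = (x.var(ddof=1) - x.mean()) / x.mean() ** 2
        assert phi_hat == pytest.approx(0.2, abs=0.06)

    def test_clip_samples_enriched(self):
        ids = [f"T{i}" for i in range(4)]
        truth = minimal_truth(ids, enrichment_factors={"T0": 4.0})
        cm = generate_counts(truth, n_input_reps=50, n_clip_reps=50, dispersion=0.0,
                             baseline_log_sd=0.0, seed=13)
        inp = cm.counts[[c for c in cm.counts if c.startswith("input")]].mean(axis=1)
        clip = cm.counts[[c for c in cm.counts if c.startswith("mir_clip")]].mean(axis=1)
        assert clip["T0"] / inp["T0"] == pytest.approx(4.0, rel=0.15)
        assert clip["T1"] / inp["T1"] == pytest.approx(1.0, rel=0.15)

    def test_bad_library_size_rejected(self):
        truth = minimal_truth(["A"])
        with pytest.raises(ValueError):
            generate_counts(truth, lib_sizes={"input_1": 0.0})


class TestResponse:
    def test_zero_effects_give_zero_truth(self):
        plan = make_site_plan(20, 0.5)
        _, truth = generate_transcriptome(20, site_plan=plan, seed=1)
        logfc = generate_response(truth, effect_by_class={c: 0.0 for c in DEFAULT_RESPONSE_EFFECTS},
                                  noise_sd=0.1, seed=1)
        assert all(v == 0.0 for v in truth.true_logfc.values())
        assert abs(logfc.median()) < 0.1

    def test_additive_effects_across_sites(self):
        plan = {0: [(None, SiteClass.SEVENMER_M8, "utr3"), ("mir-ext", SiteClass.SIXMER, "utr3")]}
        _, truth = generate_transcriptome(2, site_plan=plan, seed=11)
        generate_response(truth, seed=0)
        expected = (
            DEFAULT_RESPONSE_EFFECTS[SiteClass.SEVENMER_M8]
            + DEFAULT_RESPONSE_EFFECTS[SiteClass.SIXMER]
        )
        assert truth.true_logfc[truth.transcript_ids[0]] == pytest.approx(expected)
        assert truth.true_logfc[truth.transcript_ids[1]] == 0.0


class TestSmallRna:
    def test_balanced_mixture_within_binomial_interval(self):
        _, hp, ext_s, base_s = synthetic_hairpin()
        reads = generate_small_rna(hp, base_s, ext_s, ratio=1.0, n_reads=10_000, seed=14)
        n_b = sum(1 for r in reads if hp.startswith(r, ext_s))
        # 99% binomial interval around 5000 at p = 0.5
        assert abs(n_b - 5000) < 2.58 * np.sqrt(10_000 * 0.25)

    def test_reads_are_exact_substrings(self):
        _, hp, ext_s, base_s = synthetic_hairpin()
        reads = generate_small_rna(hp, base_s, ext_s, ratio=3.4, n_reads=500, seed=15)
        assert all(r in hp for r in reads)
        assert {len(r) for r in reads} <= {20, 21, 22, 23}

    def test_zero_reads_valid(self):
        _, hp, ext_s, base_s = synthetic_hairpin()
        assert generate_small_rna(hp, base_s, ext_s, 1.0, 0, seed=0) == []

    def test_offset_validation(self):
        _, hp, *_ = synthetic_hairpin()
        with pytest.raises(ValueError):
            generate_small_rna(hp, 0, len(hp) - 2, 1.0, 10, seed=0)
        with pytest.raises(ValueError):
            generate_small_rna(hp, 0, 1, 0.0, 10, seed=0)
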