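import io
from collections import Counter

import numpy as np
import pytest

from selexg4.reads import filter_and_extract, parse_fastq
from selexg4.simulate import (
    PlantedMotif,
    SelexSimConfig,
    g2_study_config,
    generate_initial_pool,
    run_selex,
    selection_recursion,
    selection_round,
    sequence_pool,
    simulate_competition,
    simulate_gene_lists,
)


def small_config(**kw):
    defaults = dict(pool_size=5000, reads_per_round=5000, rounds=2, seed=3)
    defaults.update(kw)
    return g2_study_config(**defaults)


class TestInitialPool:
    def test_deterministic_given_seed(self):
        cfg = small_config()
        a, _ = generate_initial_pool(cfg)
        b, _ = generate_initial_pool(cfg)
        assert a == b

    def test_unplanted_pool_is_near_uniform(self):
        cfg = SelexSimConfig(pool_size=20_000, reads_per_round=1000, rounds=1, seed=1)
        pool, founders = generate_initial_pool(cfg)
        assert founders == []
        tally = Counter("".join(pool))
        total = sum(tally.values())
        se = np.sqrt(0.25 * 0.75 / total)
        for base in "ACGT":
            assert abs(tally[base] / total - 0.25) < 3 * se + 1e-12

    def test_planted_fraction_one_all_match(self):
        motif = PlantedMotif(pattern="GGGGGGGG", initial_fraction=1.0, n_founders=50)
        cfg = SelexSimConfig(pool_size=500, reads_per_round=100, rounds=1, planted=(motif,), seed=2)
        pool, _ = generate_initial_pool(cfg)
        assert all("GGGGGGGG" in s for s in pool)

    def test_motif_longer_than_core_errors(self):
        motif = PlantedMotif(pattern="G" * 60)
        with pytest.raises(ValueError):
            SelexSimConfig(planted=(motif,))


class TestSelectionRound:
    def test_neutral_weights_preserve_expected_frequency(self, rng):
        cfg = SelexSimConfig(pool_size=20_000, reads_per_round=100, rounds=1, seed=4)
        pool, _ = generate_initial_pool(cfg)
        marker = pool[0]
        pool = [marker] * 2000 + pool[2000:]
        out = selection_round(pool, cfg, rng)
        f0, f1 = 0.1, Counter(out)[marker] / len(out)
        # two resampling stages; allow 4 binomial SEs of the dominant one
        se = np.sqrt(f0 * (1 - f0) / (cfg.pool_size * cfg.nonspecific_retention))
        assert abs(f1 - f0) < 4 * se

    def test_recursion_closed_form(self):
        assert selection_recursion(0.001, 10) == pytest.approx(0.0099108, abs=1e-6)
        freqs = [selection_recursion(0.001, 10, r) for r in range(7)]
        assert all(b > a for a, b in zip(freqs, freqs[1:]))

    def test_one_round_enrichment_matches_recursion(self, rng):
        cfg = small_config(pool_size=100_000)
        pool, (founders,) = generate_initial_pool(cfg, np.random.default_rng(cfg.seed))
        match = cfg.planted[0].matcher()
        f0 = sum(1 for s in pool if match(s)) / len(pool)
        out = selection_round(pool, cfg, rng)
        f1 = sum(1 for s in out if match(s)) / len(out)
        expected = selection_recursion(f0, 10)
        retained = cfg.pool_size * cfg.nonspecific_retention
        se = np.sqrt(expected * (1 - expected) / retained)
        assert abs(f1 - expected) < 4 * se

    def test_empty_pool_errors(self, rng):
        with pytest.raises(ValueError):
            selection_round([], small_config(), rng)


class TestSequencing:
    def test_errorfree_roundtrip_recovers_sampled_multiset(self, rng):
        cfg = small_config(per_base_error=0.0, quality_fail_fraction=0.0)
        pool, _ = generate_initial_pool(cfg, np.random.default_rng(cfg.seed))
        fastq, sampled = sequence_pool(pool, cfg, rng)
        regions = list(filter_and_extract(parse_fastq(io.StringIO(fastq)), cfg.design))
        assert Counter(regions) == sampled

    def test_fail_fraction_within_binomial_error(self, rng):
        cfg = small_config(reads_per_round=20_000, per_base_error=0.0, quality_fail_fraction=0.1)
        pool, _ = generate_initial_pool(cfg, np.random.default_rng(cfg.seed))
        fastq, _ = sequence_pool(pool, cfg, rng)
        reads = list(parse_fastq(io.StringIO(fastq)))
        failed = sum(1 for r in reads if any(q < 30 for q in r.quals))
        n = len(reads)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(failed / n - 0.1) < 3 * se

    def test_fixed_seed_byte_identical_fastq(self):
        cfg = small_config()
        a = sequence_pool(["ACGT" * 12 + "AC"] * 10, cfg, np.random.default_rng(9))
        b = sequence_pool(["ACGT" * 12 + "AC"] * 10, cfg, np.random.default_rng(9))
        assert a[0] == b[0]


class TestRunSelex:
    def test_full_run_deterministic_and_trajectory_increases(self):
        cfg = small_config(rounds=3)
        run1 = run_selex(cfg)
        run2 = run_selex(cfg)
        assert run1.fastq_by_round == run2.fastq_by_round
        traj = [m[0] for m in run1.ledger.planted_freq_by_round]
        assert traj[0] == pytest.approx(1e-3, abs=5e-4)
        assert traj[-1] > traj[0]

    def test_ledger_tracks_recursion_within_sampling_error(self):
        run = run_selex(small_config(pool_size=50_000, rounds=4))
        traj = [m[0] for m in run.ledger.planted_freq_by_round]
        for r, f in enumerate(traj):
            expected = selection_recursion(traj[0], 10, r)
            se = np.sqrt(max(expected * (1 - expected), 1e-9) / 2500) * (r + 1)
            assert abs(f - expected) < 5 * se + 1e-3


class TestCompetitionSim:
    def test_uniform_retention_fe_near_one(self):
        tables, true_fe = simulate_competition(
            {"RF001": 1.0, "scr50": 1.0}, replicates=5, depth=100_000, seed=6
        )
        assert true_fe == {"RF001": 1.0, "scr50": 1.0}
        for t in tables:
            assert t.counts["RF001"] / t.counts["scr50"] == pytest.approx(1.0, rel=0.05)

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            simulate_competition({"a": 1.0}, replicates=0, depth=10)

    def test_nonpositive_retention_error(self):
        with pytest.raises(ValueError):
            simulate_competition({"a": 0.0, "b": 1.0}, replicates=1, depth=10)


class TestGeneLists:
    def test_disjoint_when_k_zero(self):
        a, b = simulate_gene_lists(100, 10, 10, 0, seed=1)
        assert not set(a) & set(b)

    def test_identical_when_k_equals_sizes(self):
        a, b = simulate_gene_lists(100, 7, 7, 7, seed=1)
        assert a == b

    def test_exact_overlap(self):
        a, b = simulate_gene_lists(1000, 50, 80, 13, seed=2)
        assert len(set(a) & set(b)) == 13
        assert len(a) == 50 and len(b) == 80

    def test_infeasible_parameters_error(self):
        with pytest.raises(ValueError):
            simulate_gene_lists(10, 8, 8, 2, seed=0)
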