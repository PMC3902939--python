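import math

import numpy as np
import pytest

from selexevo.classify import DASE_SCAFFOLD
from selexevo.diversity import summarize_pool
from selexevo.pool_io_qc import phred_filter
from selexevo.selexsim import (
    PhredModel,
    PocketActivityModel,
    PopulationExtinctError,
    RoundSpec,
    SimulationConfig,
    default_barcodes,
    default_rounds,
    init_library,
    run_round,
    sample_pool_table,
    sequence_pool,
    simulate_experiment,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestInitLibrary:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(
            random_region_length=8, library_size=10, planted=(), seed=5,
            rounds=(RoundSpec(1.0, 10),),
        )
        pop1, _ = init_library(cfg)
        pop2, _ = init_library(cfg)
        assert pop1 == pop2
        assert sum(pop1.values()) == 10

    def test_planted_fraction_binomial_expectation(self):
        cfg = SimulationConfig(library_size=100_000, seed=3)
        pop, _ = init_library(cfg)
        carriers = pop.get(cfg.planted[0][0], 0)
        # Binomial(1e5, 1e-3): mean 100, sd ~10; 3 sigma band
        assert 70 <= carriers <= 130

    def test_all_sequences_are_round0_ancestors(self):
        cfg = SimulationConfig(
            random_region_length=8, library_size=20, planted=(), seed=1,
        )
        pop, truth = init_library(cfg)
        assert truth.parentage == []
        for seq in pop:
            assert truth.ancestor_of(seq) == seq


class TestRunRound:
    def test_zero_error_rate_introduces_no_new_sequences(self):
        cfg = SimulationConfig(
            random_region_length=10, library_size=500, planted=(),
            error_rate=0.0, seed=2,
        )
        pop, truth = init_library(cfg)
        nxt = run_round(pop, 1.0, cfg, _rng(3), truth)
        assert set(nxt) <= set(pop)
        assert sum(nxt.values()) == 500

    def test_mutated_fraction_matches_closed_form(self):
        """With eps=1e-3, L=100, g=10 the fraction of copies carrying at
        least one substitution is 1-(1-eps)^(L*g) ~= 0.632."""
        cfg = SimulationConfig(
            random_region_length=100, library_size=10_000, planted=(),
            error_rate=1e-3, copyings_per_round=10, seed=4,
            background_survival=1.0,
        )
        pop, truth = init_library(cfg)
        run_round(pop, 1.0, cfg, _rng(5), truth)
        frac = len(truth.parentage) / 10_000
        expected = 1 - (1 - 1e-3) ** 1000
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(frac - expected) <= 3 * se

    def test_mean_mutations_per_copy(self):
        cfg = SimulationConfig(
            random_region_length=40, library_size=50_000, planted=(),
            error_rate=1e-3, copyings_per_round=10, seed=6,
            background_survival=1.0,
        )
        pop, truth = init_library(cfg)
        run_round(pop, 1.0, cfg, _rng(7), truth)
        mean_muts = sum(len(e.positions) for e in truth.parentage) / 50_000
        mu = 1e-3 * 40 * 10
        se = math.sqrt(mu / 50_000)
        assert abs(mean_muts - mu) <= 3 * se

    def test_high_pressure_fixes_the_only_active_lineage(self):
        model = PocketActivityModel()
        cfg = SimulationConfig(
            library_size=2_000, planted=((DASE_SCAFFOLD, 0.005),),
            background_survival=0.0, activity_model=model, seed=8,
            error_rate=0.0,
        )
        pop, truth = init_library(cfg)
        nxt = run_round(pop, 50.0, cfg, _rng(9), truth)
        assert set(nxt) == {DASE_SCAFFOLD}

    def test_extinction_raises_with_round_number(self):
        cfg = SimulationConfig(
            random_region_length=10, library_size=50, planted=(),
            background_survival=0.0, seed=10,
        )
        pop, truth = init_library(cfg)
        with pytest.raises(PopulationExtinctError) as err:
            run_round(pop, 5.0, cfg, _rng(11), truth, round_index=4)
        assert err.value.round_index == 4

    def test_parentage_records_real_substitutions(self):
        cfg = SimulationConfig(
            random_region_length=20, library_size=5_000, planted=(),
            error_rate=1e-3, seed=12, background_survival=1.0,
        )
        pop, truth = init_library(cfg)
        run_round(pop, 1.0, cfg, _rng(13), truth)
        assert truth.parentage
        for e in truth.parentage[:50]:
            diff = [i for i, (a, b) in enumerate(zip(e.parent, e.child)) if a != b]
            assert diff == list(e.positions)


class TestSequencePool:
    def test_depth_zero_empty(self):
        spec = default_barcodes(1)[0]
        assert sequence_pool({"ACGT": 5}, 0, spec, PhredModel(), _rng()) == []

    def test_uniform_population_multinomial_counts(self):
        spec = default_barcodes(1)[0]
        pop = {("ACGT" * 5) + b * 4: 100 for b in "ACGT"}
        model = PhredModel(frac_low=0.0, apply_errors=False)
        reads = sequence_pool(pop, 4000, spec, model, _rng(21))
        from collections import Counter

        counts = Counter(r.bases for r in reads)
        sigma = math.sqrt(4000 * 0.25 * 0.75)
        for c in counts.values():
            assert abs(c - 1000) <= 3 * sigma

    def test_all_q40_survives_phred_filter(self):
        spec = default_barcodes(1)[0]
        model = PhredModel(q_high=40, frac_low=0.0, apply_errors=False)
        reads = sequence_pool({"ACGTACGTAC": 10}, 200, spec, model, _rng(22))
        kept, rejected = phred_filter(reads, min_q=20)
        assert rejected == 0 and len(kept) == 200

    def test_low_quality_positions_marked_and_errorprone(self):
        spec = default_barcodes(1)[0]
        model = PhredModel(q_high=40, q_low=15, frac_low=0.3, apply_errors=True)
        reads = sequence_pool({"ACGTACGTAC": 10}, 300, spec, model, _rng(23))
        some_low = sum(1 for r in reads if min(r.quals) < 20)
        assert some_low > 250  # nearly every read has a low-Q position


class TestSimulateExperiment:
    def test_same_seed_byte_identical_fastq(self, tmp_path):
        cfg = SimulationConfig(
            library_size=500, rounds=default_rounds(n_rounds=2, depth=200), seed=30,
        )
        simulate_experiment(cfg, outdir=tmp_path / "a")
        simulate_experiment(cfg, outdir=tmp_path / "b")
        for name in ("r1.fastq", "r2.fastq", "manifest.tsv", "truth_parentage.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_manifest_links_rounds_and_pressures(self, tmp_path):
        cfg = SimulationConfig(
            library_size=300, rounds=default_rounds(n_rounds=3, depth=100), seed=31,
        )
        result = simulate_experiment(cfg, outdir=tmp_path)
        lines = (tmp_path / "manifest.tsv").read_text().splitlines()
        assert len(lines) == 4
        assert lines[1].startswith("r1\tr1.fastq\t1.0\t100")
        assert len(result.truth.populations) == 4  # round 0 + 3 rounds

    def test_no_selection_run_preserves_diversity(self):
        """With pressure 0 and full background survival the final pool is
        as diverse as the first at depth far below library complexity."""
        cfg = SimulationConfig(
            library_size=50_000,
            rounds=tuple(RoundSpec(0.0, 1_000) for _ in range(3)),
            background_survival=1.0,
            planted=(),
            seed=32,
        )
        result = simulate_experiment(cfg)
        pools = [
            sample_pool_table(p, 1_000, f"r{i}", _rng(100 + i))
            for i, p in enumerate(result.truth.populations[1:], 1)
        ]
        first, last = summarize_pool(pools[0]), summarize_pool(pools[-1])
        assert first.frac_reads_in_gt2 <= 0.02
        assert last.frac_reads_in_gt2 <= 0.02
        assert abs(last.n_distinct - first.n_distinct) / first.n_distinct < 0.1

    def test_population_size_restored_every_round(self, sim_replicates):
        result, _ = sim_replicates[0]
        for pop in result.truth.populations[1:]:
            assert sum(pop.values()) == result.config.library_size
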