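"""Spatial Wright-Fisher dynamics: selection proportionality, fixation,
neutral drift, lineage reconstruction, coalescence truncation, determinism."""

import numpy as np
import pytest
from scipy import stats

from bitevol.chemistry import FitnessParams, build_target
from bitevol.genome import Genome, MutationRates
from bitevol.population import (
    LineageRecord,
    NotCoalescedWarning,
    PopulationGrid,
    Simulation,
    analysis_horizon,
    coalescence_truncation,
    reconstruct_line_of_descent,
    select_parent,
    step_generation,
)

TARGET = build_target(grid=128)  # decoding never matters in these tests
PARAMS = FitnessParams()
ZERO = MutationRates()


def make_grid(width, height, fitness):
    n = width * height
    bits = np.zeros(8, dtype=np.uint8)
    return PopulationGrid(
        width=width,
        height=height,
        genomes=[bits] * n,
        metabolic_error=np.zeros(n),
        fitness=np.asarray(fitness, dtype=float),
        coding=np.zeros(n, dtype=np.int64),
    )


class TestSelectParent:
    def test_uniform_fitness_uniform_choice(self, rng):
        grid = make_grid(4, 4, np.ones(16))
        draws = select_parent(grid, (1, 1), rng, size=100_000)
        _, counts = np.unique(draws, return_counts=True)
        assert counts.size == 9
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_dominant_neighbor_always_chosen(self, rng):
        fit = np.full(16, 1e-12)
        fit[5] = 1.0
        grid = make_grid(4, 4, fit)
        draws = select_parent(grid, (1, 1), rng, size=20_000)
        assert (draws == 5).mean() > 0.999

    def test_proportionality_three_to_one(self, rng):
        # centre cell has fitness 3, the 8 neighbours 1: P(centre) = 3/11
        fit = np.ones(9)
        fit[4] = 3.0
        grid = make_grid(3, 3, fit)
        draws = select_parent(grid, (1, 1), rng, size=100_000)
        p_hat = (draws == 4).mean()
        p = 3 / 11
        se = np.sqrt(p * (1 - p) / draws.size)
        assert abs(p_hat - p) < 3 * se


class TestStepGeneration:
    def test_clonal_zero_rates_unchanged(self, rng):
        founder = Genome.random(64, rng)
        grid = PopulationGrid.clonal(4, 4, founder, TARGET, PARAMS)
        new, parents, events = step_generation(grid, ZERO, PARAMS, TARGET, rng)
        assert events == {}
        assert new.size == 16 and new.generation == 1
        assert all(np.array_equal(g, founder.bits) for g in new.genomes)
        assert np.array_equal(new.fitness, grid.fitness)

    def test_population_size_constant(self, rng):
        founder = Genome.random(32, rng)
        sim = Simulation(
            founder, 4, 4, MutationRates.uniform(1e-3), PARAMS, TARGET, seed=3
        )
        for _ in range(20):
            sim.step()
            assert sim.grid.size == 16

    def test_fitter_clone_fixes(self):
        # two clones, fitness ratio 100: the fitter one fixes almost surely
        # on a 4x4 torus within 200 generations
        fixed = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            fit = np.where(np.arange(16) < 8, 1.0, 0.01)
            grid = make_grid(4, 4, fit)
            for _ in range(200):
                grid, _, _ = step_generation(grid, ZERO, PARAMS, TARGET, rng)
                if (grid.fitness == 1.0).all() or (grid.fitness == 0.01).all():
                    break
            if (grid.fitness == 1.0).all():
                fixed += 1
        assert fixed >= 95

    def test_neutral_fixation_probability_matches_frequency(self):
        # equal fitness: a neutral label starting at frequency 1/4 fixes
        # with probability ~ 1/4 on an 8x8 torus
        reps = 400
        wins = 0
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            labels = np.zeros(64)
            labels[:16] = 1.0
            rng.shuffle(labels)
            # encode the label in the metabolic_error channel (fitness equal)
            grid = make_grid(8, 8, np.ones(64))
            grid.metabolic_error = labels.copy()
            for _ in range(5000):
                grid, parents, _ = step_generation(grid, ZERO, PARAMS, TARGET, rng)
                if grid.metabolic_error.min() == grid.metabolic_error.max():
                    break
            wins += int(grid.metabolic_error[0] == 1.0)
        p = 16 / 64
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(wins / reps - p) < 3 * se

    def test_parent_locality(self, rng):
        founder = Genome.random(32, rng)
        sim = Simulation(
            founder, 6, 5, MutationRates.uniform(1e-3), PARAMS, TARGET, seed=9
        )
        sim.run(30)
        rec = sim.record
        for parents in rec.parents:
            for child, parent in enumerate(parents):
                cy, cx = divmod(child, 6)
                py, px = divmod(int(parent), 6)
                dy = min((cy - py) % 5, (py - cy) % 5)
                dx = min((cx - px) % 6, (px - cx) % 6)
                assert dy <= 1 and dx <= 1


class TestLineage:
    def test_hand_built_parent_table(self):
        rec = LineageRecord(
            width=2, height=1, initial_genomes=[np.zeros(4, np.uint8)] * 2
        )
        rec.append(np.array([1, 1]), {})
        rec.append(np.array([0, 0]), {})
        rec.append(np.array([1, 0]), {})
        path = reconstruct_line_of_descent(rec, 0)
        assert path.cells.tolist() == [1, 0, 1, 0]

    def test_clonal_run_ancestors_are_founder(self, rng):
        founder = Genome.random(40, rng)
        sim = Simulation(founder, 4, 4, ZERO, PARAMS, TARGET, seed=4)
        sim.run(25)
        path = reconstruct_line_of_descent(sim.record, 7)
        genomes = list(path.genomes())
        assert len(genomes) == 26
        assert all(np.array_equal(g, founder.bits) for g in genomes)

    def test_paths_share_all_ancestors_before_coalescence(self, rng):
        founder = Genome.random(60, rng)
        sim = Simulation(
            founder, 5, 5, MutationRates.uniform(2e-3), PARAMS, TARGET, seed=11
        )
        sim.run(50)
        a = reconstruct_line_of_descent(sim.record, 0).cells
        b = reconstruct_line_of_descent(sim.record, 24).cells
        eq = (a == b).tolist()
        # once the two paths have merged (walking backward) they never split:
        # forward in time, equality is monotone non-increasing
        assert eq == sorted(eq, reverse=True)

    def test_missing_generation_is_an_error(self):
        rec = LineageRecord(width=2, height=1, initial_genomes=[np.zeros(4, np.uint8)] * 2)
        rec.append(np.array([0, 0]), {})
        with pytest.raises(KeyError):
            reconstruct_line_of_descent(rec, 0, end_generation=5)


class TestCoalescenceTruncation:
    def test_horizon_arithmetic(self):
        assert analysis_horizon(2_100_000, 100_000) == 2_000_000
        assert analysis_horizon(1_100, 100) == 1_000
        with pytest.raises(ValueError):
            analysis_horizon(100, 100)

    def test_coalesced_run_no_warning(self, rng, recwarn):
        founder = Genome.random(40, rng)
        sim = Simulation(founder, 3, 3, ZERO, PARAMS, TARGET, seed=21)
        sim.run(300)
        coalescence_truncation(sim.record, 300, 100)
        assert not any(
            isinstance(w.message, NotCoalescedWarning) for w in recwarn.list
        )

    def test_zero_margin_triggers_warning(self, rng):
        founder = Genome.random(40, rng)
        sim = Simulation(founder, 4, 4, ZERO, PARAMS, TARGET, seed=22)
        sim.run(3)  # far too short for 16 cells to coalesce
        with pytest.warns(NotCoalescedWarning):
            coalescence_truncation(sim.record, 3, 0)


class TestDeterminism:
    def test_same_seed_same_trajectory(self, rng):
        founder = Genome.random(120, rng)
        runs = []
        for _ in range(2):
            sim = Simulation(
                founder, 4, 4, MutationRates.uniform(1e-3), PARAMS, TARGET, seed=77
            )
            sim.run(40)
            runs.append(sim)
        a, b = runs
        assert np.array_equal(a.grid.fitness, b.grid.fitness)
        assert all(
            np.array_equal(x, y) for x, y in zip(a.grid.genomes, b.grid.genomes)
        )

    def test_checkpoint_restart_bit_exact(self, rng):
        founder = Genome.random(120, rng)
        sim = Simulation(
            founder, 4, 4, MutationRates.uniform(1e-3), PARAMS, TARGET, seed=78
        )
        sim.run(20)
        snap = sim.snapshot()
        sim.run(20)
        final_a = [g.copy() for g in sim.grid.genomes]
        fit_a = sim.grid.fitness.copy()
        sim.restore(snap)
        assert sim.grid.generation == 20
        sim.run(20)
        assert np.array_equal(sim.grid.fitness, fit_a)
        assert all(np.array_equal(x, y) for x, y in zip(sim.grid.genomes, final_a))


class TestLineagePersistence:
    def test_save_load_replays_identically(self, tmp_path, rng):
        from bitevol.population import LineageRecord

        founder = Genome.random(150, rng)
        sim = Simulation(
            founder, 4, 4, MutationRates.uniform(2e-3), PARAMS, TARGET, seed=31
        )
        sim.run(40)
        sim.record.save(tmp_path / "lineage")
        back = LineageRecord.load(tmp_path / "lineage")
        assert back.width == 4 and back.height == 4
        assert back.last_generation == sim.record.last_generation
        a = reconstruct_line_of_descent(sim.record, 5)
        b = reconstruct_line_of_descent(back, 5)
        assert np.array_equal(a.cells, b.cells)
        for ga, gb in zip(a.genomes(), b.genomes()):
            assert np.array_equal(ga, gb)
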