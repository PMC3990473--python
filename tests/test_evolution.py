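"""Population loop, environment panel, lifetime fluctuation, protocol."""

import itertools
import math
import os
from math import comb

import numpy as np
import pytest

from virtualcell.dynamics import STANDARD_ENV, CHANGEABLE_PARAMS
from virtualcell.evolution import (Cell, ConfigError, FitnessEvaluator,
                                   Population, SimulationTrace,
                                   apply_environmental_change, evolve,
                                   init_population, lifetime_environments,
                                   load_trace, make_default_levels,
                                   make_environment_panel, run_experiment,
                                   run_generation, save_trace)
from virtualcell.fixtures import make_viable_genome, random_genome
from virtualcell.mutation import MutationRates, replay_events
from virtualcell.genome import stamp_ancestry


def zero_rates(**kw):
    base = dict(point_per_gene=0.0, dup_per_genome_ref=0.0,
                del_per_genome_ref=0.0, trans_per_genome_ref=0.0,
                wgd_per_cell=0.0)
    base.update(kw)
    return MutationRates(**base)


class TestEnvironmentPanel:
    def test_default_panel_has_80_environments(self):
        panel = make_environment_panel(STANDARD_ENV)
        assert len(panel) == 80
        assert len({env.label for env in panel.environments}) == 80

    def test_each_member_changes_exactly_three_parameters(self):
        panel = make_environment_panel(STANDARD_ENV)
        for env in panel.environments:
            changed = [p for p in CHANGEABLE_PARAMS
                       if getattr(env, p) != getattr(STANDARD_ENV, p)]
            assert len(changed) == 3

    def test_zero_changed_gives_standard_only(self):
        panel = make_environment_panel(STANDARD_ENV, n_changed=0)
        assert len(panel) == 1
        assert panel.environments[0].key() == STANDARD_ENV.key()

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4, 5])
    def test_size_is_choose_k_times_two_to_k(self, k):
        """Enumerated size matches C(5,k)*2^k for every subset size."""
        panel = make_environment_panel(STANDARD_ENV, n_changed=k)
        assert len(panel) == comb(5, k) * 2 ** k

    def test_missing_level_rejected(self):
        levels = make_default_levels(STANDARD_ENV)
        del levels["degradation"]
        with pytest.raises(ConfigError):
            make_environment_panel(STANDARD_ENV, levels)


class TestLifetimeEnvironments:
    def test_draw_count_in_one_to_three(self, rng):
        for _ in range(300):
            envs = lifetime_environments(STANDARD_ENV, rng)
            assert 1 <= len(envs) <= 3
            for env in envs:
                assert env.key()[1:] == STANDARD_ENV.key()[1:]  # only A_ext

    def test_collapsed_range_is_constant(self, rng):
        envs = lifetime_environments(STANDARD_ENV, rng, fluctuation=(1.0, 1.0))
        assert all(env.A_ext == pytest.approx(STANDARD_ENV.A_ext)
                   for env in envs)

    def test_continuous_log_mean_at_midpoint(self, rng):
        """Continuous mode: mean log A_ext equals the log-range midpoint."""
        draws = []
        for _ in range(4000):
            draws += [env.A_ext for env in lifetime_environments(
                STANDARD_ENV, rng, n_levels=None, n_draws=1)]
        mid = 0.5 * (math.log(0.1) + math.log(10.0))
        se = np.std(np.log(draws)) / math.sqrt(len(draws))
        assert abs(np.mean(np.log(draws)) - mid) < 4 * se

    def test_discrete_levels_symmetric(self, rng):
        draws = []
        for _ in range(4000):
            draws += [env.A_ext for env in lifetime_environments(
                STANDARD_ENV, rng, n_levels=5, n_draws=1)]
        mid = 0.5 * (math.log(0.1) + math.log(10.0))
        se = np.std(np.log(draws)) / math.sqrt(len(draws))
        assert abs(np.mean(np.log(draws)) - mid) < 4 * se


class TestSelection:
    def _fixed_fitness_population(self, rng, fitnesses):
        cells = [Cell(cell_id=i, genome=random_genome(rng, n_genes=4),
                      parent_index=-1, fitness=f)
                 for i, f in enumerate(fitnesses)]
        return Population(cells=cells, generation=0)

    def test_single_fit_parent_takes_over(self, rng):
        pop = self._fixed_fitness_population(rng, [0.0, 1.0, 0.0, 0.0])
        ev = FitnessEvaluator(STANDARD_ENV)
        nxt = run_generation(pop, ev, zero_rates(), rng)
        assert all(c.parent_index == 1 for c in nxt.cells)
        assert nxt.size == pop.size and nxt.generation == 1

    def test_equal_fitness_sampling_is_uniform(self, rng):
        """Aggregate offspring counts over replicates are multinomial-flat:
        chi-square statistic within a generous bound."""
        n, reps = 8, 400
        counts = np.zeros(n)
        for _ in range(reps):
            pop = self._fixed_fitness_population(rng, [0.5] * n)
            nxt = run_generation(pop, FitnessEvaluator(STANDARD_ENV),
                                 zero_rates(), rng)
            for c in nxt.cells:
                counts[c.parent_index] += 1
        total = counts.sum()
        expected = total / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # df=7; P(chi2 > 24) ~ 0.001
        assert chi2 < 24

    def test_all_zero_fitness_falls_back_to_uniform(self, rng):
        pop = self._fixed_fitness_population(rng, [0.0] * 6)
        nxt = run_generation(pop, FitnessEvaluator(STANDARD_ENV),
                             zero_rates(), rng)
        assert nxt.size == 6

    def test_offspring_equal_replay_of_parent(self, rng):
        genome = stamp_ancestry(random_genome(rng, n_genes=10))
        cells = [Cell(cell_id=i, genome=genome, parent_index=-1, fitness=1.0)
                 for i in range(10)]
        pop = Population(cells=cells, generation=0)
        rates = MutationRates(point_per_gene=0.2, dup_per_genome_ref=0.5,
                              del_per_genome_ref=0.5)
        nxt = run_generation(pop, FitnessEvaluator(STANDARD_ENV), rates, rng)
        for child in nxt.cells:
            assert replay_events(genome, child.events) == child.genome


class TestExperimentProtocol:
    def _factory(self):
        return lambda r: make_viable_genome()

    def test_zero_generations_traces_initial_population_only(self, rng):
        trace = run_experiment(
            n_cells=5, rng=rng, genome_factory=self._factory(),
            rates=zero_rates(),
            protocol=__import__("virtualcell.evolution", fromlist=["ExperimentProtocol"]
                                ).ExperimentProtocol(max_generations=0))
        assert trace.n_generations == 0
        assert 0 in trace.snapshots

    def test_change_applied_exactly_after_delay(self, rng):
        """The environmental change lands post_cutoff_delay generations
        after the cutoff is first passed."""
        from virtualcell.evolution import ExperimentProtocol
        protocol = ExperimentProtocol(high_fitness_cutoff=0.05,
                                      post_cutoff_delay=4, max_generations=30)
        change = STANDARD_ENV.replace(degradation=1.0, label="changed")
        trace = run_experiment(
            n_cells=5, rng=rng, genome_factory=self._factory(),
            rates=zero_rates(), protocol=protocol, change_env=change,
            post_change_generations=3)
        # viable fixture passes the tiny cutoff immediately (generation 1)
        assert trace.change_generation == 1 + 4
        assert trace.n_generations == trace.change_generation + 3

    def test_population_size_constant(self, rng):
        trace = run_experiment(
            n_cells=7, rng=rng, genome_factory=self._factory(),
            rates=MutationRates(),
            protocol=__import__("virtualcell.evolution", fromlist=["x"]
                                ).ExperimentProtocol(max_generations=6))
        for arr in trace.parents:
            assert len(arr) == 7

    def test_force_wgd_doubles_every_cell(self, rng):
        pop = init_population(4, rng, lambda r: random_genome(r, n_genes=6))
        sizes = [len(c.genome) for c in pop.cells]
        pop = apply_environmental_change(pop, None, force_wgd=True)
        assert [len(c.genome) for c in pop.cells] == [2 * s for s in sizes]
        assert all(g.wgd_tag is not None
                   for c in pop.cells for g in c.genome)


class TestDeterminismAndPersistence:
    def _run(self, seed, outdir):
        rng = np.random.default_rng(seed)
        pop = init_population(6, rng, lambda r: random_genome(r, n_genes=8))
        trace = SimulationTrace(snapshot_interval=2)
        ev = FitnessEvaluator(STANDARD_ENV)
        rates = MutationRates(point_per_gene=0.05, dup_per_genome_ref=0.2,
                              del_per_genome_ref=0.2)
        evolve(pop, ev, rates, rng, 5, trace)
        save_trace(trace, outdir)
        return trace

    def test_identical_seeds_give_byte_identical_traces(self, rng, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        self._run(123, str(a))
        self._run(123, str(b))
        for sub in sorted(os.listdir(a)):
            pa, pb = a / sub, b / sub
            if pa.is_dir():
                for f in sorted(os.listdir(pa)):
                    assert (pa / f).read_bytes() == (pb / f).read_bytes()
            else:
                assert pa.read_bytes() == pb.read_bytes()

    def test_trace_round_trip(self, tmp_path):
        trace = self._run(7, str(tmp_path / "t"))
        loaded = load_trace(str(tmp_path / "t"))
        assert loaded.n_generations == trace.n_generations
        assert loaded.change_generation == trace.change_generation
        for g in range(trace.n_generations + 1):
            assert np.array_equal(loaded.parents[g], trace.parents[g])
            assert set(loaded.events[g]) == set(trace.events[g])
        for g, genomes in trace.snapshots.items():
            assert loaded.snapshots[g] == genomes

    def test_lod_identical_from_loaded_trace(self, tmp_path):
        from virtualcell.lineage import trace_line_of_descent
        trace = self._run(11, str(tmp_path / "t"))
        loaded = load_trace(str(tmp_path / "t"))
        lod1 = trace_line_of_descent(trace, final_cell_index=3)
        lod2 = trace_line_of_descent(loaded, final_cell_index=3)
        assert [s.genome for s in lod1.steps] == [s.genome for s in lod2.steps]
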