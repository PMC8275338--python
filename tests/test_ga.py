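"""The constrained genetic algorithm: selection, mutation operators,
feasibility enforcement, convergence heuristics and the generational loop."""

from __future__ import annotations

import numpy as np
import pytest

from cgabni.constraints import ConstraintParams, ConstraintSet, PathConstraint, derive_constraints, satisfies
from cgabni.core import BooleanNetwork, NCFRule, edges_of, tuple_sign
from cgabni.ga import (
    Chromosome,
    GAConfig,
    GeneHistory,
    KindInapplicable,
    _FitnessEvaluator,
    choose_mutation_gene,
    evolve,
    initialize_population,
    mutate_rule,
    propose_offspring,
    roulette_select,
)
from cgabni.scoring import dynamics_accuracy
from cgabni.synthetic import BenchmarkSpec, generate_benchmark

from conftest import random_network


def small_benchmark(seed=0, n=6):
    spec = BenchmarkSpec(n_genes=n, n_initial_states=300, seed=seed)
    return generate_benchmark(spec)


def chromosome_for(net, gene_sim=None, window=5):
    c = Chromosome(net, GeneHistory(window, net.n_genes))
    c.gene_sim = gene_sim
    return c


NO_CORR = np.ones((20, 20))
PARAMS = ConstraintParams()
EMPTY = ConstraintSet(())


class TestFitnessEvaluator:
    def test_kernel_matches_pure_python_scoring(self, rng):
        """The jitted batch evaluator and the reference implementation give
        identical fitness and per-gene similarities."""
        _, ds = small_benchmark(seed=3, n=7)
        ev = _FitnessEvaluator(ds, max_steps=2000)
        for _ in range(15):
            net = random_network(rng, 7)
            fit, sims = ev(net)
            rep = dynamics_accuracy(net, ds)
            assert fit == pytest.approx(rep.dynamics_accuracy, abs=1e-12)
            assert np.allclose(sims, rep.per_gene, atol=1e-12)


class TestRouletteSelect:
    def test_proportional_to_fitness(self, rng):
        net = random_network(rng, 4)
        pop = [chromosome_for(net) for _ in range(2)]
        pop[0].fitness, pop[1].fitness = 0.2, 0.8
        picks = sum(roulette_select(pop, rng) is pop[1] for _ in range(4000))
        assert abs(picks / 4000 - 0.8) < 0.03

    def test_all_zero_fitness_falls_back_to_uniform(self, rng):
        net = random_network(rng, 4)
        pop = [chromosome_for(net) for _ in range(4)]
        for c in pop:
            c.fitness = 0.0
        counts = np.zeros(4)
        for _ in range(2000):
            chosen = roulette_select(pop, rng)
            counts[pop.index(chosen)] += 1
        assert (counts > 0).all()


class TestChooseMutationGene:
    def test_single_imperfect_gene_is_chosen(self, rng):
        net = random_network(rng, 5)
        c = chromosome_for(net, gene_sim=np.array([1, 1, 0.7, 1, 1.0]))
        assert all(
            choose_mutation_gene(c, GAConfig(population_size=10), rng) == 2
            for _ in range(10)
        )

    def test_all_perfect_falls_back_to_any_gene(self, rng):
        net = random_network(rng, 5)
        c = chromosome_for(net, gene_sim=np.ones(5))
        picks = {choose_mutation_gene(c, GAConfig(population_size=10), rng) for _ in range(60)}
        assert len(picks) > 1

    def test_flat_history_excludes_gene_from_first_tier(self, rng):
        net = random_network(rng, 3)
        cfg = GAConfig(population_size=10, gene_convergence_window=4,
                       gene_convergence_tolerance=0.02)
        c = chromosome_for(net, gene_sim=np.array([0.7, 0.5, 1.0]), window=4)
        for _ in range(4):  # gene 0 flat (range 0 <= 2%), gene 1 moving
            c.history.push(np.array([0.7, 0.5, 1.0]))
        c.history.values[:, 1] = [0.3, 0.4, 0.5, 0.6]
        assert all(choose_mutation_gene(c, cfg, rng) == 1 for _ in range(10))

    def test_all_flat_and_imperfect_falls_back_to_imperfect_tier(self, rng):
        net = random_network(rng, 3)
        cfg = GAConfig(population_size=10, gene_convergence_window=2)
        c = chromosome_for(net, gene_sim=np.array([0.7, 1.0, 1.0]), window=2)
        for _ in range(2):
            c.history.push(np.array([0.7, 1.0, 1.0]))
        assert all(choose_mutation_gene(c, cfg, rng) == 0 for _ in range(10))


class TestMutateRule:
    """Each operator on a fixed 3-gene chromosome.

    Rule of v1: (v2,1,1)(v3,0,1):0 — tuple 0 activating, tuple 1 inhibiting.
    """

    def fixed(self):
        net = BooleanNetwork(
            ("v1", "v2", "v3"),
            (
                NCFRule(0, ((1, 1, 1), (2, 0, 1))),
                NCFRule(1, ((0, 1, 1),)),
                NCFRule(2, ((0, 1, 1),)),
            ),
        )
        return chromosome_for(net)

    def test_canalyzing_flip_switches_sign(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 0, "canalyzing_flip", NO_CORR, PARAMS, EMPTY, rng)
        old = dict(((v, tuple_sign(i, o)) for v, i, o in c.network.rules[0].tuples))
        new = dict(((v, tuple_sign(i, o)) for v, i, o in out.rules[0].tuples))
        flipped = [v for v in old if old[v] != new[v]]
        assert len(flipped) == 1

    def test_both_flip_preserves_sign_and_toggles_bits(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 0, "both_flip", NO_CORR, PARAMS, EMPTY, rng)
        assert sorted(edges_of(out)) == sorted(edges_of(c.network))
        changed = [
            (a, b)
            for a, b in zip(c.network.rules[0].tuples, out.rules[0].tuples)
            if a != b
        ]
        (old, new), = changed
        assert new == (old[0], 1 - old[1], 1 - old[2])

    def test_swap_exchanges_positions(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 0, "swap", NO_CORR, PARAMS, EMPTY, rng)
        assert out.rules[0].tuples == (c.network.rules[0].tuples[1], c.network.rules[0].tuples[0])

    def test_removal_deletes_one_tuple_and_keeps_rule_nonempty(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 0, "removal", NO_CORR, PARAMS, EMPTY, rng)
        assert out.rules[0].k == 1

    def test_removal_inapplicable_on_single_tuple_rule(self, rng):
        c = self.fixed()
        with pytest.raises(KindInapplicable):
            mutate_rule(c, 1, "removal", NO_CORR, PARAMS, EMPTY, rng)

    def test_swap_inapplicable_without_two_tuples_in_a_subgroup(self, rng):
        c = self.fixed()
        with pytest.raises(KindInapplicable):
            mutate_rule(c, 1, "swap", NO_CORR, PARAMS, EMPTY, rng)

    def test_insertion_adds_correlated_regulator_at_vps_head(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 1, "insertion", NO_CORR, PARAMS, EMPTY, rng)
        assert out.rules[1].k == 2
        assert out.rules[1].tuples[0][0] == 2  # only v3 is eligible

    def test_insertion_blocked_below_alpha_correlation(self, rng):
        c = self.fixed()
        with pytest.raises(KindInapplicable):
            mutate_rule(c, 1, "insertion", np.zeros((3, 3)), PARAMS, EMPTY, rng)

    def test_default_output_rederived_after_mutation(self, rng):
        c = self.fixed()
        out = mutate_rule(c, 0, "removal", NO_CORR, PARAMS, EMPTY, rng)
        assert out.rules[0].default_out == 1 - out.rules[0].tuples[-1][2]

    def test_fps_tuples_protected_from_sign_changing_kinds(self, rng):
        cs = ConstraintSet((PathConstraint(1, 0, 1, "direct"),))
        c = self.fixed()  # (v2,1,1) embodies the direct constraint -> FPS
        for _ in range(20):
            out = mutate_rule(c, 0, "canalyzing_flip", NO_CORR, PARAMS, cs, rng)
            assert (1, 0, 1) in edges_of(out)  # constrained edge untouched
            out = mutate_rule(c, 0, "removal", NO_CORR, PARAMS, cs, rng)
            assert (1, 0, 1) in edges_of(out)


class TestInitializePopulation:
    def test_unconstrained_population_has_ba_edge_count(self, rng):
        cfg = GAConfig(population_size=20)
        pop = initialize_population(EMPTY, 10, cfg, rng)
        assert len(pop) == 20
        for c in pop:
            assert len(edges_of(c.network)) == 17
            assert all(rule.k >= 1 for rule in c.network.rules)

    def test_direct_constraints_seeded_in_every_chromosome(self, rng):
        cs = ConstraintSet(
            (PathConstraint(0, 4, 1, "direct"), PathConstraint(2, 1, -1, "direct"))
        )
        pop = initialize_population(cs, 8, GAConfig(population_size=15), rng)
        for c in pop:
            assert satisfies(c.network, cs)[0]
            edges = edges_of(c.network)
            assert (0, 4, 1) in edges and (2, 1, -1) in edges

    def test_indirect_constraints_hold_after_greedy_repair(self, rng):
        cs = ConstraintSet(
            (PathConstraint(0, 5, 1, "indirect"), PathConstraint(3, 1, -1, "indirect"))
        )
        pop = initialize_population(cs, 8, GAConfig(population_size=15), rng)
        assert all(satisfies(c.network, cs)[0] for c in pop)

    def test_structure_fixed_clones_signed_edges(self, rng):
        net = random_network(rng, 6)
        cfg = GAConfig(population_size=10, structure_fixed=True)
        pop = initialize_population(EMPTY, 6, cfg, rng, initial_network=net)
        ref = sorted(edges_of(net))
        assert all(sorted(edges_of(c.network)) == ref for c in pop)


class TestProposeOffspring:
    def test_offspring_always_feasible(self, rng):
        net, ds = small_benchmark(seed=1)
        cs = derive_constraints(ds)
        cfg = GAConfig(population_size=10)
        pop = initialize_population(cs, ds.n_genes, cfg, rng, gene_names=ds.gene_names)
        corr = np.ones((ds.n_genes, ds.n_genes))
        for parent in pop:
            child, gave_up = propose_offspring(parent, cs, corr, cfg, PARAMS, rng)
            assert satisfies(child.network, cs)[0]
            assert not gave_up

    def test_retry_cap_returns_parent_copy(self, rng):
        parent = chromosome_for(random_network(rng, 4))
        cfg = GAConfig(population_size=10, mutation_retry_cap=0)
        child, gave_up = propose_offspring(parent, EMPTY, NO_CORR, cfg, PARAMS, rng)
        assert gave_up and child.network == parent.network


class TestEvolve:
    CFG = dict(population_size=24, n_elites=2, stop_stagnant_generations=15,
               max_generations=60)

    def run(self, seed=0, **kwargs):
        net, ds = small_benchmark(seed=seed)
        cs = derive_constraints(ds)
        cfg = GAConfig(seed=seed + 1, **{**self.CFG, **kwargs})
        return net, ds, cs, evolve(ds, cs, cfg)

    def test_best_fitness_monotone_and_feasibility_total(self):
        _, _, _, res = self.run()
        best = [r["best_fitness"] for r in res.generations]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert all(r["feasibility_rate"] == 1.0 for r in res.generations)

    def test_identical_seed_reproduces_identical_result(self):
        _, _, _, res1 = self.run(seed=2)
        _, _, _, res2 = self.run(seed=2)
        assert res1.best.network == res2.best.network
        assert res1.generations == res2.generations

    def test_parallel_equals_sequential(self):
        _, _, _, res1 = self.run(seed=3, n_workers=1)
        _, _, _, res2 = self.run(seed=3, n_workers=2)
        assert res1.best.network == res2.best.network
        assert res1.generations == res2.generations

    def test_stops_on_stagnation_or_perfection(self):
        _, _, _, res = self.run(seed=4)
        assert res.stop_reason in ("stagnation", "perfect_fitness", "max_generations")
        if res.stop_reason == "perfect_fitness":
            assert res.best.fitness == 1.0
        elif res.stop_reason == "stagnation":
            tail = [r["best_fitness"] for r in res.generations][-15:]
            assert max(tail) <= res.best.fitness

    def test_structure_fixed_conserves_edge_set_exactly(self, rng):
        net, ds = small_benchmark(seed=5)
        cfg = GAConfig(seed=9, structure_fixed=True, **self.CFG)
        res = evolve(ds, EMPTY, cfg, initial_network=net)
        assert sorted(edges_of(res.best.network)) == sorted(edges_of(net))

    def test_improves_over_initial_population(self):
        _, _, _, res = self.run(seed=6)
        first, last = res.generations[0], res.generations[-1]
        assert res.best.fitness >= first["best_fitness"]
        assert res.best.fitness > 0.5


class TestGeneHistory:
    def test_short_history_counts_as_not_converged(self):
        h = GeneHistory(window=3, n_genes=2)
        h.push(np.array([0.5, 0.5]))
        assert h.not_converged(0.02).all()

    def test_range_vs_tolerance_after_window_filled(self):
        h = GeneHistory(window=3, n_genes=2)
        for v in ([0.5, 0.5], [0.5, 0.6], [0.51, 0.7]):
            h.push(np.array(v))
        assert list(h.not_converged(0.02)) == [False, True]

    def test_copy_is_independent(self):
        h = GeneHistory(window=2, n_genes=1)
        h.push(np.array([0.1]))
        c = h.copy()
        c.push(np.array([0.9]))
        assert h.count == 1 and c.count == 2
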