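"""Evolutionary minimiser: operators, sorting, and oracle equivalence."""

import math

import numpy as np
import pytest

from minnet.errors import ContractError, InfeasibleError
from minnet.evaluate import GrowthEvaluator
from minnet.evolve import (
    CandidateSolution,
    MinimiserConfig,
    backtrack,
    candidate_budget,
    discard_probability,
    dominates,
    genetic_operator,
    minimise,
    sort_population,
    verify_minimality,
)
from minnet.gpr import DeletionState
from minnet.synthetic import brute_force_mmns, make_fixture


def cand(model, genes, growth=10.0):
    return CandidateSolution(DeletionState.from_genes(model, genes),
                             growth=growth)


CFG = MinimiserConfig(population_size=10, max_generations=30,
                      growth_threshold_fraction=0.99, seed=0)


class TestDomination:
    def test_one_extra_knockout_dominates(self, toy1):
        p = cand(toy1, ["g1", "g2"])
        q = cand(toy1, ["g1"])
        assert dominates(p, q)
        assert not dominates(q, p)

    def test_distant_states_do_not_dominate(self, toy1):
        p = cand(toy1, ["g1", "g2"])
        r = cand(toy1, ["g3", "g4"])
        assert not dominates(p, r) and not dominates(r, p)


class TestSortPopulation:
    def test_fronts_on_toy1(self, toy1):
        wt = cand(toy1, [])
        a = cand(toy1, ["g1"])
        b = cand(toy1, ["g2"])
        ordered = sort_population([wt, a, b], CFG)
        fronts = {tuple(c.state.deleted_genes(toy1)): c.front
                  for c in ordered}
        assert fronts[("g1",)] == 1 and fronts[("g2",)] == 1
        assert fronts[()] == 2  # wild type dominated by both
        assert [c.front for c in ordered] == [1, 1, 2]

    def test_single_point(self, toy1):
        out = sort_population([cand(toy1, [])], CFG)
        assert out[0].front == 1 and out[0].diversity == 0.0

    def test_identical_points_deterministic(self, toy1):
        pop = [cand(toy1, ["g1"]) for _ in range(3)]
        out = sort_population(pop, CFG)
        assert all(c.front == 1 and c.diversity == 0.0 for c in out)

    def test_empty_population_rejected(self):
        with pytest.raises(ContractError):
            sort_population([], CFG)


class TestDiscardProbability:
    def test_midpoint_is_half(self):
        assert discard_probability(20, CFG) == pytest.approx(0.5)

    def test_age_zero_default_parameters(self):
        assert discard_probability(0, CFG) == pytest.approx(
            1.0 / (1.0 + math.exp(4.0)), rel=1e-12)

    def test_strictly_increasing(self):
        probs = [discard_probability(a, CFG) for a in range(0, 60, 5)]
        assert all(p1 < p2 for p1, p2 in zip(probs, probs[1:]))
        assert all(0.0 < p < 1.0 for p in probs)

    def test_negative_age_rejected(self):
        with pytest.raises(ContractError):
            discard_probability(-1, CFG)


class TestGeneticOperator:
    def test_wild_type_gains_one_feasible_knockout(self, toy1, shared_evaluator):
        # brute force over TOY1's five single knockouts: only g1 or g2
        # keeps growth at >= 99% of wild type
        thr = shared_evaluator.threshold(0.99)
        rng = np.random.default_rng(4)
        sol = genetic_operator(cand(toy1, []), toy1, CFG, rng,
                               shared_evaluator, thr)
        assert sol.n_ko == 1
        assert sol.state.deleted_genes(toy1) in (["g1"], ["g2"])

    def test_exhausted_solution_unchanged(self, toy1, shared_evaluator):
        thr = shared_evaluator.threshold(0.99)
        start = cand(toy1, ["g1"])
        rng = np.random.default_rng(0)
        out = genetic_operator(start, toy1, CFG, rng, shared_evaluator, thr)
        assert out is start

    def test_seeded_reproducibility(self, toy1, shared_evaluator):
        thr = shared_evaluator.threshold(0.99)
        outs = [
            genetic_operator(cand(toy1, []), toy1, CFG,
                             np.random.default_rng(9), shared_evaluator, thr)
            for _ in range(2)
        ]
        assert outs[0].state == outs[1].state

    def test_essential_genes_never_picked(self, toy1):
        from minnet.model import attach_essentials
        model, _ = attach_essentials(toy1, ["g1", "g2"])
        ev = GrowthEvaluator(model)
        thr = ev.threshold(0.99)
        rng = np.random.default_rng(0)
        # with g1/g2 off-limits no feasible knockout remains at all
        out = genetic_operator(cand(model, []), model, CFG, rng, ev, thr)
        assert out.n_ko == 0


class TestBacktrack:
    def test_reactivation_keeps_feasibility(self, toy1, shared_evaluator):
        thr = shared_evaluator.threshold(0.99)
        sol = cand(toy1, ["g1"])
        out = backtrack(sol, toy1, CFG, np.random.default_rng(1),
                        shared_evaluator, thr)
        assert out.growth >= thr
        assert out.n_ko < sol.n_ko or sol.n_ko == 0

    def test_seeded_reproducibility(self, toy1, shared_evaluator):
        thr = shared_evaluator.threshold(0.99)
        sol = cand(toy1, ["g1"])
        a = backtrack(sol, toy1, CFG, np.random.default_rng(5),
                      shared_evaluator, thr)
        b = backtrack(sol, toy1, CFG, np.random.default_rng(5),
                      shared_evaluator, thr)
        assert a.state == b.state


class TestVerifyMinimality:
    def test_toy1_certificates(self, toy1):
        assert verify_minimality(
            toy1, DeletionState.from_genes(toy1, ["g1"]), CFG)
        assert not verify_minimality(
            toy1, DeletionState.wild_type(5), CFG)

    def test_infeasible_state_rejected(self, toy1):
        with pytest.raises(ContractError):
            verify_minimality(
                toy1, DeletionState.from_genes(toy1, ["gT"]), CFG)

    def test_no_deletable_genes_vacuously_minimal(self, toy1):
        from minnet.model import attach_essentials
        model, _ = attach_essentials(toy1, list(toy1.gene_ids))
        assert verify_minimality(model, DeletionState.wild_type(5), CFG)


class TestMinimise:
    def test_toy1_exact_solution_set(self, toy1, toy1_collection):
        found = {tuple(r.deleted_genes) for r in toy1_collection.records}
        assert found == {("g1",), ("g2",)}
        oracle = brute_force_mmns(toy1, 0.99)
        assert toy1_collection.deletion_state_set() == {
            s.key() for s in oracle}

    def test_growth_constraint_satisfied_by_all_records(self, toy1_collection):
        thr = 0.99 * toy1_collection.wt_growth * (1 - 1e-6)
        assert all(r.growth >= thr for r in toy1_collection.records)

    def test_fluxes_attached(self, toy1, toy1_collection):
        for r in toy1_collection.records:
            assert r.fluxes["BIOMASS"] == pytest.approx(10.0, abs=1e-5)
            assert set(r.active_reactions) <= set(toy1.reaction_ids)

    def test_deterministic_for_fixed_seed(self, toy1):
        cfg = MinimiserConfig(population_size=8, max_generations=15, seed=3)
        a = minimise(toy1, cfg, attach_fluxes=False)
        b = minimise(toy1, cfg, attach_fluxes=False)
        assert a.deletion_state_set() == b.deletion_state_set()
        assert a.n_states_explored == b.n_states_explored
        assert [r.deleted_genes for r in a.records] == [
            r.deleted_genes for r in b.records]

    def test_nothing_deletable_returns_certified_wild_type(self, toy1):
        from minnet.model import attach_essentials
        model, _ = attach_essentials(toy1, list(toy1.gene_ids))
        col = minimise(model, MinimiserConfig(
            population_size=4, max_generations=5, seed=0))
        assert len(col) == 1
        assert col.records[0].deleted_genes == []

    def test_infeasible_wild_type_rejected(self, toy1):
        dead = toy1.copy()
        dead.lower_bound[dead.reaction_index("EX_A")] = 0.0
        with pytest.raises(InfeasibleError):
            minimise(dead, MinimiserConfig(
                population_size=4, max_generations=5, seed=0))

    def test_budget_accounting(self):
        assert candidate_budget(MinimiserConfig()) == 500_000
        assert candidate_budget(MinimiserConfig(
            population_size=20, max_generations=50)) == 1000

    def test_outputs_serialise(self, toy1_collection, tmp_path):
        toy1_collection.to_json(tmp_path / "mmns.json")
        toy1_collection.retention_csv(tmp_path / "retention.csv")
        import json
        doc = json.loads((tmp_path / "mmns.json").read_text())
        assert len(doc["mmns"]) == 2
        assert doc["seed"] == doc["config"]["seed"]
        lines = (tmp_path / "retention.csv").read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 MMNs
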