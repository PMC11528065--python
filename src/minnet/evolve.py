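"""Evolutionary search for minimal metabolic networks (MMNs).

The search works over gene-deletion states (logical arrays, True =
knocked out) and maximises the number of knockouts subject to a growth
constraint: FBA growth must stay at or above a fraction (default 99%)
of the wild-type optimum.  The population starts as wild types; each
generation a genetic operator tries to add one feasible knockout per
parent, the combined parent/offspring pool is sorted by Hamming-distance
domination fronts with a diversity tie-break, and stagnating solutions
are probabilistically discarded (a logistic function of their age) and
replaced by backtracked ancestors so that other branches of the search
tree can be explored.  A post-processing pass takes every
constraint-satisfying state encountered, keeps the non-dominated ones,
certifies each by exhaustively testing all single-knockout extensions,
and attaches a parsimonious flux distribution.

Domination is the paper-thin relation p dominates q iff their Hamming
distance is 1 and nKO(p) = nKO(q) + 1: p is q plus one more viable
knockout, so q cannot itself be minimal.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ContractError, InfeasibleError
from .evaluate import GrowthEvaluator
from .gpr import DeletionState, hamming_distance
from .model import MetabolicModel
from .solvers import pfba

__all__ = [
    "CandidateSolution",
    "MinimiserConfig",
    "MMNCollection",
    "dominates",
    "sort_population",
    "discard_probability",
    "genetic_operator",
    "backtrack",
    "verify_minimality",
    "minimise",
    "candidate_budget",
]


@dataclass
class CandidateSolution:
    """A deletion state with its search metadata."""

    state: DeletionState
    growth: float
    age: int = 0
    front: int | None = None
    diversity: float | None = None

    @property
    def n_ko(self) -> int:
        return self.state.n_ko


@dataclass(frozen=True)
class MinimiserConfig:
    """Tunable parameters of the evolutionary search.

    The production-scale defaults are a population of 100 evolved for up
    to 5000 generations with a 99% growth threshold; toy-model runs use
    far smaller budgets.
    """

    population_size: int = 100
    max_generations: int = 5000
    growth_threshold_fraction: float = 0.99
    max_operator_trials: int = 10
    diversity_neighbours: int = 10
    sigmoid_midpoint: float = 20.0
    sigmoid_scale: float = 5.0
    backtrack_max_fraction: float = 1.0
    backtrack_max_retries: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ContractError("population_size must be >= 2")
        if not 0.0 < self.growth_threshold_fraction <= 1.0:
            raise ContractError("growth_threshold_fraction must be in (0, 1]")
        if not 0.0 < self.backtrack_max_fraction <= 1.0:
            raise ContractError("backtrack_max_fraction must be in (0, 1]")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def candidate_budget(config: MinimiserConfig) -> int:
    """Theoretical maximum number of candidate solutions explored:
    one offspring per population slot per generation."""
    return config.population_size * config.max_generations


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def dominates(p: CandidateSolution, q: CandidateSolution) -> bool:
    """True iff p is q plus exactly one additional knockout."""
    return (p.n_ko == q.n_ko + 1
            and hamming_distance(p.state, q.state) == 1)


def discard_probability(age: int, config: MinimiserConfig) -> float:
    """Logistic probability of discarding a solution of the given age."""
    if age < 0:
        raise ContractError("age must be >= 0")
    z = (age - config.sigmoid_midpoint) / config.sigmoid_scale
    return 1.0 / (1.0 + math.exp(-z))


def sort_population(pop: list[CandidateSolution],
                    config: MinimiserConfig) -> list[CandidateSolution]:
    """Assign domination fronts and diversity, then order the population.

    Fronts are peeled iteratively: the non-dominated points (within the
    not-yet-labelled remainder) receive front 1, then 2, and so on.
    Diversity is the mean Hamming distance to the
    ``diversity_neighbours`` closest other points.  Ordering is by
    ascending front, then descending diversity, then lexicographic bit
    pattern for determinism.
    """
    if not pop:
        raise ContractError("population must be nonempty")
    n = len(pop)
    bits = np.array([c.state.bits for c in pop], dtype=bool)
    dist = (bits[:, None, :] ^ bits[None, :, :]).sum(axis=2)
    nko = bits.sum(axis=1)

    # diversity: mean distance to the k closest neighbours
    k = min(config.diversity_neighbours, n - 1)
    for i, cand in enumerate(pop):
        if k == 0:
            cand.diversity = 0.0
        else:
            others = np.delete(dist[i], i)
            cand.diversity = float(np.sort(others)[:k].mean())

    # iterative front peeling under the distance-1 domination relation
    unlabelled = set(range(n))
    front = 1
    while unlabelled:
        idx = sorted(unlabelled)
        current = []
        for q in idx:
            dominated = any(
                p != q and dist[p, q] == 1 and nko[p] == nko[q] + 1
                for p in idx)
            if not dominated:
                current.append(q)
        for q in current:
            pop[q].front = front
            unlabelled.discard(q)
        front += 1

    return sorted(pop, key=lambda c: (c.front, -c.diversity, c.state.key()))


def genetic_operator(sol: CandidateSolution, model: MetabolicModel,
                     config: MinimiserConfig, rng: np.random.Generator,
                     evaluator: GrowthEvaluator,
                     threshold_abs: float) -> CandidateSolution:
    """Try to add one feasible knockout to a solution.

    Candidate genes (active and non-essential) are tried in a seeded
    random order; after ``max_operator_trials`` failures the solution is
    returned unchanged.  Essential genes are never candidates.
    """
    active = np.flatnonzero(~sol.state.bits & ~model.essential_flags)
    if active.size == 0:
        return sol
    order = rng.permutation(active)[:config.max_operator_trials]
    for gi in order:
        new_state = sol.state.with_knockout(int(gi))
        g = evaluator.growth(new_state)
        if g >= threshold_abs:
            return CandidateSolution(new_state, growth=g, age=0)
    return sol


def backtrack(sol: CandidateSolution, model: MetabolicModel,
              config: MinimiserConfig, rng: np.random.Generator,
              evaluator: GrowthEvaluator,
              threshold_abs: float) -> CandidateSolution:
    """Re-activate a random nonempty subset of a solution's knockouts.

    Because re-activating genes can only shrink the disabled reaction
    set, the result of any subset choice satisfies the growth constraint
    whenever the input did; the feasibility check is retained as a
    safeguard.  Falls back to the wild type if no feasible backtrack is
    found within the retry budget.
    """
    ko = np.flatnonzero(sol.state.bits)
    if ko.size == 0:
        return CandidateSolution(sol.state, growth=sol.growth, age=0)
    max_size = max(1, math.ceil(config.backtrack_max_fraction * ko.size))
    for _ in range(config.backtrack_max_retries):
        size = int(rng.integers(1, max_size + 1))
        subset = rng.choice(ko, size=size, replace=False)
        new_state = sol.state.without_knockouts(int(i) for i in subset)
        g = evaluator.growth(new_state)
        if g >= threshold_abs:
            return CandidateSolution(new_state, growth=g, age=0)
    wt = DeletionState.wild_type(model.n_genes)
    return CandidateSolution(wt, growth=evaluator.wt_growth, age=0)


def verify_minimality(model: MetabolicModel, state: DeletionState,
                      config: MinimiserConfig,
                      evaluator: GrowthEvaluator | None = None) -> bool:
    """True iff no single further knockout of an active non-essential
    gene keeps growth at or above the threshold."""
    ev = evaluator or GrowthEvaluator(model)
    threshold_abs = ev.threshold(config.growth_threshold_fraction)
    if ev.growth(state) < threshold_abs:
        raise ContractError("state does not satisfy the growth constraint")
    active = np.flatnonzero(~state.bits & ~model.essential_flags)
    return all(ev.growth(state.with_knockout(int(gi))) < threshold_abs
               for gi in active)


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class MMNRecord:
    state: DeletionState
    deleted_genes: list[str]
    retained_genes: list[str]
    active_reactions: list[str]
    growth: float
    fluxes: dict[str, float]


@dataclass
class MMNCollection:
    """Deduplicated, minimality-certified solutions of one run."""

    model: MetabolicModel
    records: list[MMNRecord]
    config: MinimiserConfig
    wt_growth: float
    generations_run: int = 0
    n_states_explored: int = 0
    log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def states(self) -> list[DeletionState]:
        return [r.state for r in self.records]

    def deletion_state_set(self) -> set[bytes]:
        return {r.state.key() for r in self.records}

    def retention_matrix(self) -> np.ndarray:
        """(n_MMN x n_gene) 0/1 matrix, 1 = gene retained."""
        return np.array([~r.state.bits for r in self.records], dtype=int)

    def to_json(self, path) -> None:
        doc = {
            "model_id": self.model.model_id,
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "wild_type_growth": self.wt_growth,
            "generations_run": self.generations_run,
            "n_states_explored": self.n_states_explored,
            "mmns": [
                {
                    "deleted_genes": r.deleted_genes,
                    "retained_genes": r.retained_genes,
                    "active_reactions": r.active_reactions,
                    "growth": r.growth,
                    "pfba_fluxes": r.fluxes,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def retention_csv(self, path) -> None:
        mat = self.retention_matrix()
        lines = ["mmn," + ",".join(self.model.gene_ids)]
        for i, row in enumerate(mat):
            lines.append(f"MMN{i}," + ",".join(str(int(x)) for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def minimise(model: MetabolicModel, config: MinimiserConfig,
             attach_fluxes: bool = True,
             evaluator: GrowthEvaluator | None = None) -> MMNCollection:
    """Run the full evolutionary minimisation and certify the MMNs.

    Deterministic for fixed (model, config): all randomness flows from
    ``config.seed``.  The post-processing non-dominated filter is applied
    to the archive of every constraint-satisfying state encountered, not
    just the final population, and every survivor is certified by
    exhaustive single-knockout testing before inclusion.
    """
    rng = np.random.default_rng(config.seed)
    ev = evaluator or GrowthEvaluator(model)
    if ev.wt_growth <= 0:
        raise InfeasibleError("wild-type growth is zero; nothing to minimise")
    threshold_abs = ev.threshold(config.growth_threshold_fraction)

    wt = DeletionState.wild_type(model.n_genes)
    pop = [CandidateSolution(wt, growth=ev.wt_growth, age=0)
           for _ in range(config.population_size)]
    archive: dict[bytes, DeletionState] = {wt.key(): wt}
    log: list[dict] = []
    gen = 0
    for gen in range(1, config.max_generations + 1):
        offspring = []
        for parent in pop:
            child = genetic_operator(parent, model, config, rng, ev,
                                     threshold_abs)
            if child is parent:
                # stagnation: the parent ages, no new point enters
                parent.age += 1
            else:
                archive[child.state.key()] = child.state
                offspring.append(child)
        pool = sort_population(pop + offspring, config)
        pop = pool[:config.population_size]

        replacements = 0
        for i, cand in enumerate(pop):
            if rng.random() < discard_probability(cand.age, config):
                pop[i] = backtrack(cand, model, config, rng, ev,
                                   threshold_abs)
                archive[pop[i].state.key()] = pop[i].state
                replacements += 1
        log.append({
            "generation": gen,
            "best_n_ko": max(c.n_ko for c in pop),
            "mean_diversity": float(np.mean([c.diversity or 0.0
                                             for c in pop])),
            "replacements": replacements,
            "population": len(pop),
            "archive": len(archive),
        })

    # ---- post-processing: non-dominated filter + minimality certificate
    gene_pool = model.deletable_gene_indices
    records = []
    for key in sorted(archive):
        state = archive[key]
        dominated = any(
            not state.bits[gi]
            and state.with_knockout(int(gi)).key() in archive
            for gi in gene_pool)
        if dominated:
            continue
        if not verify_minimality(model, state, config, ev):
            continue
        mask = model.disabled_reaction_mask(state)
        growth = ev.growth(state)
        fluxes: dict[str, float] = {}
        active = [model.reaction_ids[j] for j in np.flatnonzero(~mask)]
        if attach_fluxes:
            dist = pfba(model, state, growth_fraction=1.0)
            fluxes = {r: v for r, v in dist.as_dict(model).items()
                      if abs(v) > 1e-9}
        records.append(MMNRecord(
            state=state,
            deleted_genes=state.deleted_genes(model),
            retained_genes=state.retained_genes(model),
            active_reactions=active,
            growth=growth,
            fluxes=fluxes,
        ))
    records.sort(key=lambda r: r.state.key())
    return MMNCollection(model=model, records=records, config=config,
                         wt_growth=ev.wt_growth, generations_run=gen,
                         n_states_explored=len(archive), log=log)
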