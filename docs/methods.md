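# Methods

## Problem statement

Given a genome-scale constraint-based metabolic model — stoichiometric
matrix *S* (metabolites × reactions), per-reaction flux bounds in
mmol/gDW/h, a Boolean gene–protein–reaction (GPR) rule per reaction and
a biomass pseudo-reaction whose flux is the growth rate — the pipeline
searches for **minimal metabolic networks (MMNs)**: gene-deletion sets
from which no further non-essential gene can be removed without
dropping the FBA growth rate below a threshold fraction (default 99%,
90% supported) of the wild-type optimum.  Collections of MMNs are then
analysed for per-gene retention ("NED degree"), and the impact of gene
removal on the network is quantified by the global efficiency of the
bipartite metabolite–reaction graph.

## Constraint-based core

**FBA.** maximise `v_bio` subject to `S·v = 0`, `lb ≤ v ≤ ub`.  Solved
as an LP with HiGHS (scipy.optimize.linprog).  Infeasible knockout LPs
are reported with growth 0: every caller only asks whether growth
clears a threshold, and an infeasible deletion strain is simply
non-viable.

**Gene deletions.** A deletion state is a logical array over the gene
list, `True` = knocked out; the wild type is all-`False`.  Each
reaction's GPR is evaluated with leaf value "gene not deleted"
(`and` = complex, `or` = isoenzymes); reactions whose rule evaluates
`False` have both bounds clamped to zero.  Clamping rather than column
removal keeps matrix indices stable across the ~10⁴–10⁵ evaluations of
a search run.  Reactions without a GPR (exchanges, spontaneous steps,
the biomass pseudo-reaction) can never be gene-disabled.

**pFBA.** Among near-optimal flux states (`v_bio ≥ f·v*`, default
`f = 1`), the flux vector minimising `Σ v_r²` is selected — a strictly
convex QP with a unique solution, solved with OSQP (absolute/relative
tolerance 1e-9, solution polishing on).  The common L1 variant
(minimise `Σ|v_r|`, an LP, not necessarily unique) is available behind
`variant="l1"` for comparison.

**FVA.** Per-reaction flux minima/maxima subject to
`v_bio ≥ f·v*`, implemented as 2 LPs per reaction with the biomass
lower bound tightened; `f` is exposed (`growth_fraction`, default 1.0).

**Tolerances.** LP/QP feasibility and optimality 1e-9.  Growth-threshold
comparisons use a relative slack of 1e-6 on `fraction × v*_wt` so that
knockouts sitting numerically on the threshold are not rejected by
solver round-off.  Growth-fraction constraints are imposed as
`lb_bio = target·(1 − 1e-9)` for the same reason.

## Minimal-medium design

All non-fixed exchange lower bounds are opened at the conventional
"unconstrained" magnitude 1000 mmol/gDW/h.  Nutrients are then removed
(lower bound set to 0) one at a time in seeded random order; a removal
is kept when FBA growth stays **well above** the requested minimum,
implemented as `growth ≥ min_growth·(1 + margin)` with `margin = 0.01`
(configurable — the qualitative phrase needed a number; 1% mirrors the
default growth-threshold granularity).  After `tol` consecutive failed
random picks (default 20; the parameter is named in the source
procedure without a value) an exhaustive pass tests every residual
removal; the procedure ends when none passes, and a final exhaustive
sweep certifies removal-minimality regardless of the random phase's
trajectory.  Removal is strictly sequential: a removed exchange is
never re-opened.  Glucose/oxygen/water exchanges (matched by name, or
any user-supplied fixed set) are never touched.  Anaerobic variants
(extra exchanges to open, biomass stoichiometry edits) are user
configuration, not hard-coded lists.

A second step narrows each remaining uptake bound to the
minimum-magnitude uptake compatible with the medium's FBA optimum
(an FVA maximisation of the exchange flux at fixed growth).  The step
never loosens a bound, preserves the optimum within relative 1e-6, and
is idempotent (sub-tolerance drift is clamped to the previous bound).

## Evolutionary minimisation

Population of `population_size` candidates (default 100), all wild
type initially, evolved for `max_generations` (default 5000; the
theoretical candidate-evaluation budget is the product, 500,000 at the
defaults).  Per generation:

1. **Genetic operator** — for each parent, candidate genes (active,
   non-essential) are tried in seeded random order, at most
   `max_operator_trials = 10`; the first knockout that keeps growth
   above threshold yields the offspring (age 0).  If none does, the
   parent ages by one and contributes no offspring.
2. **Sorting** — parents and offspring are pooled and sorted by
   domination fronts: *p dominates q* iff Hamming(p, q) = 1 and
   nKO(p) = nKO(q) + 1.  Non-dominated points get front 1, the
   relation is peeled iteratively for fronts 2, 3, …  Within a front,
   points with higher diversity — mean Hamming distance to their 10
   closest neighbours — are preferred; remaining ties break on the
   lexicographic bit pattern so runs are reproducible.  The best
   `population_size` points survive; duplicates are allowed (the
   population keeps its fixed size, which sustains parallel descent —
   an earlier deduplicating variant stalled exploration on toys).
3. **Ageing and backtracking** — each survivor is discarded with
   probability `1/(1 + exp(−(age − 20)/5))`, a logistic in its age
   (midpoint and scale configurable; the exact sigmoid is not pinned
   down by the source description, and the defaults keep solutions
   safe for ~2 idle rounds of 10 generations).  A discarded point is
   replaced by a backtracked ancestor: a uniformly-sized random
   nonempty subset of its knockouts is re-activated (any size up to
   the full set — capping the subset traps the search in one basin of
   the deletion lattice).  Re-activation can only shrink the disabled
   reaction set, so the replacement always satisfies the constraint;
   the wild type is the fallback.

"Age" is generations since the candidate last gained a knockout, reset
to 0 on improvement and on replacement.  The literal source definition
("the number of the last generation in which the point has been
present") is circular; improvement-based ageing matches its stated use
— stagnating candidates are probably minimal and should make room.

**Post-processing.** The archive of *every* constraint-satisfying
state encountered (not just the final population) is filtered to
non-dominated states, and each survivor is certified by exhaustively
testing all single-knockout extensions of active non-essential genes
(`verify_minimality`).  Certified states are deduplicated by bit
pattern, annotated with their pFBA flux distribution, and returned
sorted by bit pattern.  Soundness is therefore unconditional; only
completeness (finding *all* MMNs) depends on the search budget.

## MMN analytics

Retention fraction (NED degree) = share of MMNs retaining the gene;
essential genes are reported with fraction 1 and class
`essential_excluded`.  **NED genes** are non-essential genes with
retention strictly above the threshold (default 0.95; the defining
rule is a strict ">95%").  `always_active` (fraction exactly 1) is a
labelled subclass of the NED flag; `always_KO` is fraction 0; the rest
are `variable`.  Cross-condition aggregation intersects the
fraction-1 sets of several collections.  Pairwise MMN similarity is
the Jaccard index of active-reaction sets (a min-denominator variant
is selectable; the quantity "fraction of shared reactions" does not
fix the denominator).  Search-space accounting:
`n_deletable = n_genes − n_essential`, `log10(2^n) = n·log10 2` —
976 deletable genes give ~10²⁹³ states, the figure that rules out
exhaustive search at genome scale.

## Network metrics

The bipartite digraph has a node per metabolite and per (active)
reaction; a reagent of r contributes an edge m→r, a product r→m.
Structural mode keeps all GPR-active reactions at unit weight with
reversible reactions in forward orientation; flux mode drops
zero-flux reactions (|v| ≤ 1e-9), orients edges by flux sign, and sets
weight |v·coefficient|.

Global efficiency `E(G) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij` uses unweighted
hop-count distances by default (the defining formula does not define
weighted path lengths); a weighted mode with edge length 1/weight is
available, in which efficiencies are no longer bounded by 1 when
weights exceed 1.  Unreachable pairs contribute 0; graphs with < 2
nodes have efficiency 0.  Betweenness is the raw count of shortest
paths (over ordered pairs) through a node as an intermediate,
accumulated from per-source BFS path counts in O(N³) — fine for the
graph sizes here, and equal to networkx's unnormalised betweenness
exactly when shortest paths are unique.  Degree-distribution tails are
fitted with the continuous ML estimator
`γ = 1 + n / Σ ln(k_i/(k_min − ½))` (naive `k_ref = k_min` variant
selectable).

Monte-Carlo removal draws `n_samples` (default 1000) seeded k-subsets
from a gene pool, evaluates each subset's removal efficiency
(structural, or flux with pFBA recomputed and efficiency 0 when no
growth-positive state exists), and summarises with Q1/median/Q3 and
Q1−1.5·IQR / Q3+1.5·IQR whiskers.  Pool comparisons use the
Mann-Whitney U test (scipy).

## Synthetic models and the oracle

`TOY1`: chain `A_e → A → B → C → biomass`, uptake and transport capped
at 10 mmol/gDW/h, parallel isoenzymes g1/g2 on A→B, complex
"g3 and g4" on B→C, transporter gT.  Every LP/QP value used in tests
is hand-solvable: wild-type growth 10, pFBA split 5/5, FVA `R1, R2 ∈
[0,10]`, `R3 = [10,10]`, MMNs exactly {KO g1} and {KO g2}.  The
transport cap matters for medium narrowing: with the exchange opened
at 1000 the optimum stays 10, so the bound narrows 1000 → 10.
`TOY2` adds a second carbon source behind its own transporter, so its
minimal medium retains exactly one of the two exchanges.  The random
generator produces layered chains with 1..`redundancy` isoenzyme paths
per layer, AND-complexes of 1..`complex_size` subunits, and
1..`n_exchanges` carbon routes, all drawn from a seeded generator —
deterministic per (spec, seed), always viable, uptake 10 per exchange.

`brute_force_mmns` enumerates all `2^n_deletable` states (guarded at
n ≤ 20), marks feasibility by cached FBA, and returns the feasible
states with no feasible single-knockout extension.  Growth values are
memoised on the disabled-**reaction** mask, which many gene states
share, cutting LP solves by roughly an order of magnitude for both the
oracle and the search.

What the toys do *not* emulate: compartments, cofactor coupling,
by-product secretion, realistic biomass composition, reversible
internal fluxes, or genome-scale degeneracy.  Agreement with the
oracle on these models validates the search and certification logic,
not predictions about any real organism's metabolism.

## Problem sizes used in the shipped checks

The oracle-equivalence battery runs TOY1 plus 20 random toys (≤ 10
deletable genes each) at thresholds 0.99 and 0.90, with search budget
population 16 × 120 generations — enough that runs agreed with the
oracle across all tested master seeds, with margin.  Media checks use
toys with up to 8 non-fixed exchanges; Monte-Carlo comparisons use
k = 2 and 1000 structural samples on an 8-gene toy with one mandatory
and two redundant layers.  Production-scale defaults (population 100,
5000 generations) are untouched by these choices.

## Known limitations

- Completeness of the MMN collection is empirical (budget-dependent);
  only minimality of each returned solution is certified.
- Quadratic pFBA at genome scale is governed by OSQP's scaling; the
  pipeline has been exercised at toy scale here.
- The raw-count betweenness is cubic in node count and intended for
  the analysis-sized graphs of this pipeline, not for very large
  networks.
- The media designer treats "nutrient" as "exchange lower bound";
  models encoding uptake via separate transport constraints need those
  expressed as exchanges.
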