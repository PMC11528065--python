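"""Constraint-based flux solvers: FBA, parsimonious FBA, and FVA.

All three operate on the steady-state polytope ``{v : S v = 0,
lb <= v <= ub}``.  FBA maximises flux through the biomass
pseudo-reaction (an LP, solved with HiGHS through scipy); parsimonious
FBA then selects, among near-optimal flux vectors, the unique minimiser
of the sum of squared fluxes (a strictly convex QP, solved with OSQP);
FVA reports each reaction's attainable flux range at near-optimal
growth.

Gene deletions enter through the GPR logic: a disabled reaction has
both bounds clamped to zero, keeping matrix indices stable across the
thousands of evaluations performed by the minimiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import ContractError, InfeasibleError, SolverError
from .gpr import DeletionState
from .model import MetabolicModel

__all__ = ["FluxDistribution", "FluxRange", "fba", "pfba", "fva"]

#: Feasibility / optimality tolerance for the LP and QP solves.
FEASIBILITY_TOL = 1e-9


@dataclass
class FluxDistribution:
    """A flux vector (mmol/gDW/h) with its biomass flux and solve status."""

    fluxes: np.ndarray | None
    growth: float
    status: str  # "optimal" | "infeasible"
    objective_value: float = 0.0

    @property
    def v_bio(self) -> float:
        return self.growth

    def as_dict(self, model: MetabolicModel) -> dict[str, float]:
        if self.fluxes is None:
            return {}
        return {r: float(v) for r, v in zip(model.reaction_ids, self.fluxes)}

    def to_tsv(self, model: MetabolicModel, path) -> None:
        lines = ["reaction_id\tflux"]
        lines += [f"{r}\t{v:.10g}"
                  for r, v in self.as_dict(model).items()]
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux compatible with near-optimal growth."""

    min_flux: np.ndarray
    max_flux: np.ndarray

    def for_reaction(self, model: MetabolicModel, rxn: str) -> tuple[float, float]:
        j = model.reaction_index(rxn)
        return float(self.min_flux[j]), float(self.max_flux[j])


def _effective_bounds(model: MetabolicModel,
                      state: DeletionState | None) -> tuple[np.ndarray, np.ndarray]:
    lb = model.lower_bound.copy()
    ub = model.upper_bound.copy()
    if state is not None:
        mask = model.disabled_reaction_mask(state)
        lb[mask] = 0.0
        ub[mask] = 0.0
    return lb, ub


def _solve_lp(model: MetabolicModel, c: np.ndarray,
              lb: np.ndarray, ub: np.ndarray):
    """Minimise c.v over the steady-state polytope. Returns (x, fun) or None."""
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status == 0:
        return res.x, res.fun
    if res.status == 2:  # infeasible
        return None
    raise SolverError(f"LP solver failed (status {res.status}): {res.message}")


def fba(model: MetabolicModel,
        state: DeletionState | None = None) -> FluxDistribution:
    """Maximise biomass flux subject to S v = 0 and the flux bounds.

    Infeasible problems (possible when a knockout clamps an exchange or a
    forced-flux reaction to zero) are reported with status ``infeasible``
    and growth 0, since downstream callers only ask whether growth clears
    a threshold.
    """
    lb, ub = _effective_bounds(model, state)
    out = _solve_lp(model, -model.objective_coefficients, lb, ub)
    if out is None:
        return FluxDistribution(None, 0.0, "infeasible")
    x, fun = out
    growth = float(x[model.biomass_index])
    if abs(growth) < FEASIBILITY_TOL:
        growth = 0.0
    return FluxDistribution(x, growth, "optimal", objective_value=-fun)


def pfba(model: MetabolicModel, state: DeletionState | None = None,
         growth_fraction: float = 1.0, variant: str = "quadratic") -> FluxDistribution:
    """Parsimonious FBA: minimal-flux distribution at near-optimal growth.

    The default ``quadratic`` variant minimises the sum of squared fluxes
    subject to ``v_bio >= growth_fraction * v*`` where ``v*`` is the FBA
    optimum; its solution is unique by strict convexity.  The common L1
    variant (minimise the sum of absolute fluxes) is available as
    ``variant="l1"`` for comparison; it need not be unique.
    """
    if not 0.0 < growth_fraction <= 1.0:
        raise ContractError("growth_fraction must lie in (0, 1]")
    base = fba(model, state)
    if base.status != "optimal" or base.growth <= 0.0:
        raise InfeasibleError(
            "pFBA requires a strictly positive FBA optimum "
            f"(status={base.status}, growth={base.growth})")
    lb, ub = _effective_bounds(model, state)
    bio = model.biomass_index
    # requiring a fraction of the optimum is a tightened biomass lower bound
    target = growth_fraction * base.growth
    lb[bio] = max(lb[bio], target * (1.0 - 1e-9))
    if variant == "quadratic":
        v = _solve_qp_min_norm(model, lb, ub)
        obj = float(v @ v)
    elif variant == "l1":
        v = _solve_l1_min(model, lb, ub)
        obj = float(np.abs(v).sum())
    else:
        raise ContractError(f"unknown pFBA variant {variant!r}")
    growth = float(v[bio])
    return FluxDistribution(v, growth, "optimal", objective_value=obj)


def _solve_qp_min_norm(model: MetabolicModel, lb: np.ndarray,
                       ub: np.ndarray) -> np.ndarray:
    """min ||v||^2 s.t. S v = 0, lb <= v <= ub, via OSQP with polishing."""
    import osqp

    n = model.n_reactions
    A = sp.vstack([sp.csc_matrix(model.S), sp.eye(n)], format="csc")
    l = np.concatenate([np.zeros(model.n_metabolites), lb])
    u = np.concatenate([np.zeros(model.n_metabolites), ub])
    prob = osqp.OSQP()
    prob.setup(P=sp.eye(n, format="csc") * 2.0, q=np.zeros(n), A=A, l=l, u=u,
               eps_abs=FEASIBILITY_TOL, eps_rel=FEASIBILITY_TOL,
               max_iter=200_000, polishing=True, verbose=False)
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "solved" not in status:
        raise SolverError(f"QP solver failed: {status}")
    return np.asarray(res.x, dtype=float)


def _solve_l1_min(model: MetabolicModel, lb: np.ndarray,
                  ub: np.ndarray) -> np.ndarray:
    """min sum |v| via the standard split v = p - q with p, q >= 0."""
    n = model.n_reactions
    S = sp.csr_matrix(model.S)
    A_eq = sp.hstack([S, -S], format="csr")
    c = np.ones(2 * n)
    bounds = np.concatenate([
        np.column_stack([np.maximum(lb, 0.0), np.maximum(ub, 0.0)]),
        np.column_stack([np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)]),
    ])
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("L1 pFBA problem infeasible")
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}")
    return res.x[:n] - res.x[n:]


def fva(model: MetabolicModel, growth_fraction: float = 1.0,
        state: DeletionState | None = None,
        reactions: list[str] | None = None) -> FluxRange:
    """Per-reaction flux ranges at ``v_bio >= growth_fraction * v*``.

    Reactions outside ``reactions`` (when given) keep (nan, nan).
    """
    if not 0.0 < growth_fraction <= 1.0:
        raise ContractError("growth_fraction must lie in (0, 1]")
    base = fba(model, state)
    if base.status != "optimal":
        raise InfeasibleError("FVA requires a feasible FBA problem")
    lb, ub = _effective_bounds(model, state)
    bio = model.biomass_index
    lb[bio] = max(lb[bio], growth_fraction * base.growth * (1.0 - 1e-9))
    n = model.n_reactions
    idxs = (range(n) if reactions is None
            else [model.reaction_index(r) for r in reactions])
    vmin = np.full(n, np.nan)
    vmax = np.full(n, np.nan)
    for j in idxs:
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve_lp(model, c, lb, ub)
        hi = _solve_lp(model, -c, lb, ub)
        if lo is None or hi is None:
            raise InfeasibleError("FVA subproblem infeasible")
        vmin[j] = lo[1]
        vmax[j] = -hi[1]
    return FluxRange(vmin, vmax)
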