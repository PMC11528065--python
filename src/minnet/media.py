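"""Automatic minimal-medium design and uptake-bound narrowing.

The designer opens every non-fixed exchange at the unconstrained
magnitude (1000 mmol/gDW/h), then removes nutrients one at a time in
random order, keeping a removal only if the FBA growth rate stays well
above the requested minimum.  After a run of failed random picks an
exhaustive pass tests every residual removal; the medium returned is
removal-minimal with respect to that test.  A second step narrows each
remaining uptake bound to the minimum magnitude compatible with the FBA
optimum, in the manner of a flux-variability minimisation.

Glucose, oxygen and water exchanges (or any user-supplied fixed set)
are never touched by either step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ContractError, InfeasibleError, ValidationError
from .model import UNCONSTRAINED_BOUND, MetabolicModel
from .solvers import fba, fva

__all__ = [
    "MediumDefinition",
    "apply_medium",
    "design_minimal_medium",
    "narrow_uptake_bounds",
    "read_medium_tsv",
    "write_medium_tsv",
]

#: Common names of exchanges held fixed by default when present.
DEFAULT_FIXED_PATTERNS = ("glc", "glucose", "o2", "oxygen", "h2o", "water")


@dataclass(frozen=True)
class MediumDefinition:
    """Uptake (lower) bounds for a model's exchange reactions.

    Exchanges absent from ``uptake_bounds`` and not in ``fixed_exchanges``
    are closed (lower bound 0) when the medium is applied; fixed
    exchanges keep whatever bound the model already carries.
    """

    uptake_bounds: dict[str, float] = field(default_factory=dict)
    fixed_exchanges: frozenset[str] = frozenset()
    unconstrained_value: float = UNCONSTRAINED_BOUND

    def __post_init__(self):
        bad = {r: b for r, b in self.uptake_bounds.items() if b > 0}
        if bad:
            raise ValidationError(f"uptake bounds must be <= 0: {bad}")
        object.__setattr__(self, "fixed_exchanges",
                           frozenset(self.fixed_exchanges))

    @property
    def open_exchanges(self) -> list[str]:
        return [r for r, b in sorted(self.uptake_bounds.items()) if b < 0]


def _check_exchanges(model: MetabolicModel, names) -> None:
    bad = set(names) - model.exchange_reactions
    if bad:
        raise ValidationError(
            f"not exchange reactions of this model: {sorted(bad)}")


def apply_medium(model: MetabolicModel,
                 medium: MediumDefinition) -> MetabolicModel:
    """Return a copy of the model with exchange lower bounds set.

    Secretion (upper) bounds are untouched; exchanges neither mapped nor
    fixed are closed.
    """
    _check_exchanges(model, medium.uptake_bounds)
    _check_exchanges(model, medium.fixed_exchanges)
    out = model.copy()
    for rid in model.exchange_reactions:
        if rid in medium.fixed_exchanges:
            continue
        out.lower_bound[out.reaction_index(rid)] = medium.uptake_bounds.get(
            rid, 0.0)
    return out


def default_fixed_exchanges(model: MetabolicModel) -> frozenset[str]:
    """Exchanges matching the conventional glucose/oxygen/water names."""
    fixed = set()
    for rid in model.exchange_reactions:
        low = rid.lower()
        if any(p in low for p in DEFAULT_FIXED_PATTERNS):
            fixed.add(rid)
    return frozenset(fixed)


def design_minimal_medium(model: MetabolicModel, min_growth: float,
                          tol_attempts: int = 20, seed: int = 0,
                          fixed_exchanges=None,
                          margin: float = 0.01) -> MediumDefinition:
    """Randomised sequential nutrient removal with exhaustive fallback.

    A removal is accepted when FBA growth stays at or above
    ``min_growth * (1 + margin)`` ("well above" the minimum).  After
    ``tol_attempts`` consecutive failed random picks, every residual
    removal is tested exhaustively; the procedure ends when none passes.
    The result is reproducible for a fixed seed.
    """
    if min_growth <= 0:
        raise ContractError("min_growth must be > 0")
    fixed = frozenset(fixed_exchanges if fixed_exchanges is not None
                      else default_fixed_exchanges(model))
    _check_exchanges(model, fixed)
    rng = np.random.default_rng(seed)
    accept = min_growth * (1.0 + margin)

    open_set = sorted(model.exchange_reactions - fixed)
    medium = MediumDefinition(
        uptake_bounds={r: -UNCONSTRAINED_BOUND for r in open_set},
        fixed_exchanges=fixed)
    work = apply_medium(model, medium)

    def growth_without(rid: str) -> float:
        j = work.reaction_index(rid)
        saved = work.lower_bound[j]
        work.lower_bound[j] = 0.0
        g = fba(work).growth
        work.lower_bound[j] = saved
        return g

    if fba(work).growth < accept:
        raise InfeasibleError(
            f"model cannot reach growth {accept} even with all non-fixed "
            "exchanges open")

    open_set = list(open_set)
    failures = 0
    while open_set:
        if failures < tol_attempts:
            rid = open_set[int(rng.integers(len(open_set)))]
            if growth_without(rid) >= accept:
                work.lower_bound[work.reaction_index(rid)] = 0.0
                open_set.remove(rid)
                failures = 0
            else:
                failures += 1
        else:
            # exhaustive fallback: test every residual removal
            removed = None
            for rid in list(open_set):
                if growth_without(rid) >= accept:
                    removed = rid
                    break
            if removed is None:
                break
            work.lower_bound[work.reaction_index(removed)] = 0.0
            open_set.remove(removed)
            failures = 0
    # final certification sweep so the random phase cannot terminate early
    for rid in list(open_set):
        if growth_without(rid) >= accept:
            work.lower_bound[work.reaction_index(rid)] = 0.0
            open_set.remove(rid)
    return MediumDefinition(
        uptake_bounds={r: -UNCONSTRAINED_BOUND for r in open_set},
        fixed_exchanges=fixed)


def narrow_uptake_bounds(model: MetabolicModel,
                         medium: MediumDefinition) -> MediumDefinition:
    """Tighten each open uptake bound to the minimum magnitude that still
    supports the FBA optimum of the applied medium.

    For each non-fixed open exchange the least-negative flux compatible
    with optimal growth (an FVA maximisation of the exchange flux at
    fixed growth) becomes the new lower bound.  Fixed exchanges are left
    unconstrained.  The operation preserves the optimum to within
    relative 1e-6 and is idempotent.
    """
    work = apply_medium(model, medium)
    open_ids = [r for r in medium.open_exchanges
                if r not in medium.fixed_exchanges]
    if not open_ids:
        return medium
    ranges = fva(work, growth_fraction=1.0, reactions=open_ids)
    new_bounds = dict(medium.uptake_bounds)
    for rid in open_ids:
        _, vmax = ranges.for_reaction(work, rid)
        # snap to 1e-6 precision, ceiling the magnitude so the narrowed
        # bound still admits the required uptake
        new = -math.ceil(max(0.0, -vmax) * 1e6 - 1e-9) / 1e6
        old = medium.uptake_bounds[rid]
        # never loosen, and ignore sub-tolerance drift for idempotence
        if new < old or abs(new - old) <= 1e-9 * max(1.0, abs(old)):
            new = old
        new_bounds[rid] = 0.0 if abs(new) < 1e-9 else new
    return replace(medium, uptake_bounds=new_bounds)


def write_medium_tsv(medium: MediumDefinition, path) -> None:
    lines = ["exchange_id\tlower_bound"]
    lines += [f"{r}\t{b:.10g}" for r, b in sorted(medium.uptake_bounds.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_medium_tsv(path, fixed_exchanges=()) -> MediumDefinition:
    bounds = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("exchange_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"malformed medium row at line {ln}: {line!r}")
        try:
            bounds[parts[0]] = float(parts[1])
        except ValueError:
            raise ValidationError(
                f"non-numeric bound at line {ln}: {parts[1]!r}")
    return MediumDefinition(uptake_bounds=bounds,
                            fixed_exchanges=frozenset(fixed_exchanges))
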