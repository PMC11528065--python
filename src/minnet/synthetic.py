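"""Deterministic toy metabolic models with known minimal networks.

These generators supply every test input in the package: two fixed
fixtures (TOY1, TOY2) whose linear-programming solutions are known in
closed form, a seeded random generator producing layered models with a
controllable amount of isoenzyme redundancy, and an exhaustive
brute-force oracle that enumerates every deletion state to obtain the
exact set of minimal metabolic networks (MMNs).

TOY1 is a linear chain  A_e -> A -> B -> C -> biomass  with a carbon
uptake capped at 10 mmol/gDW/h, two isoenzyme-catalysed parallel
reactions R1/R2 (genes g1, g2) for A -> B, a two-subunit complex
("g3 and g4") for B -> C, and a transporter gene gT.  Its only MMNs at
any growth threshold above zero are the single knockouts of g1 and g2.
TOY2 adds a second, redundant carbon source (F_e via gene gF), so its
minimal medium retains exactly one of the two carbon exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ContractError
from .evaluate import GrowthEvaluator
from .gpr import DeletionState
from .model import MetabolicModel

__all__ = ["ToySpec", "make_fixture", "make_random_toy", "brute_force_mmns"]


def _build(metabolites, reactions, genes, biomass, model_id) -> MetabolicModel:
    """Assemble a MetabolicModel from a reaction table.

    ``reactions`` maps reaction id -> (stoich dict, lb, ub, gpr text).
    """
    met_index = {m: i for i, m in enumerate(metabolites)}
    rids = list(reactions)
    rows, cols, vals = [], [], []
    lb, ub, gpr = [], [], []
    for j, rid in enumerate(rids):
        stoich, lo, hi, rule = reactions[rid]
        for m, c in stoich.items():
            rows.append(met_index[m])
            cols.append(j)
            vals.append(float(c))
        lb.append(lo)
        ub.append(hi)
        gpr.append(rule)
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(metabolites), len(rids)))
    return MetabolicModel(
        metabolite_ids=list(metabolites), reaction_ids=rids, S=S,
        lower_bound=np.array(lb), upper_bound=np.array(ub),
        gpr_text=gpr, gene_ids=list(genes), biomass_reaction=biomass,
        model_id=model_id)


def make_fixture(name: str) -> MetabolicModel:
    """Return one of the fixed fixtures TOY1 or TOY2 (see module docstring)."""
    U = 1000.0
    if name == "TOY1":
        reactions = {
            "EX_A": ({"A_e": -1}, -10.0, U, ""),
            "T_A": ({"A_e": -1, "A": 1}, 0.0, 10.0, "gT"),
            "R1": ({"A": -1, "B": 1}, 0.0, U, "g1"),
            "R2": ({"A": -1, "B": 1}, 0.0, U, "g2"),
            "R3": ({"B": -1, "C": 1}, 0.0, U, "g3 and g4"),
            "BIOMASS": ({"C": -1}, 0.0, U, ""),
        }
        return _build(["A_e", "A", "B", "C"], reactions,
                      ["gT", "g1", "g2", "g3", "g4"], "BIOMASS", "TOY1")
    if name == "TOY2":
        reactions = {
            "EX_A": ({"A_e": -1}, -10.0, U, ""),
            "EX_F": ({"F_e": -1}, -10.0, U, ""),
            "T_A": ({"A_e": -1, "A": 1}, 0.0, 10.0, "gT"),
            "T_F": ({"F_e": -1, "A": 1}, 0.0, 10.0, "gF"),
            "R1": ({"A": -1, "B": 1}, 0.0, U, "g1"),
            "R2": ({"A": -1, "B": 1}, 0.0, U, "g2"),
            "R3": ({"B": -1, "C": 1}, 0.0, U, "g3 and g4"),
            "BIOMASS": ({"C": -1}, 0.0, U, ""),
        }
        return _build(["A_e", "F_e", "A", "B", "C"], reactions,
                      ["gT", "gF", "g1", "g2", "g3", "g4"], "BIOMASS", "TOY2")
    raise ContractError(f"unknown fixture {name!r}")


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a random layered toy model.

    ``n_layers`` chained conversion steps; each layer carries between 1
    and ``redundancy`` parallel isoenzyme paths, each gated by an AND
    complex of up to ``complex_size`` genes; ``n_exchanges`` independent
    carbon sources each behind its own transporter gene.  Uptake is
    capped at 10 mmol/gDW/h per exchange, so the wild-type growth rate
    is 10 * n_exchanges and, at thresholds near 1, every transporter is
    retained in every MMN while each layer retains exactly one path.
    """

    n_layers: int = 2
    redundancy: int = 2
    complex_size: int = 1
    n_exchanges: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_layers, self.redundancy,
               self.complex_size, self.n_exchanges) < 1:
            raise ContractError("all ToySpec counts must be >= 1")


def make_random_toy(spec: ToySpec) -> MetabolicModel:
    """Deterministically generate a feasible layered toy model."""
    rng = np.random.default_rng(spec.seed)
    U = 1000.0
    metabolites: list[str] = []
    reactions: dict = {}
    genes: list[str] = []
    for e in range(spec.n_exchanges):
        src = f"S{e}_e"
        metabolites.append(src)
        tr_gene = f"tr{e}"
        genes.append(tr_gene)
        reactions[f"EX_S{e}"] = ({src: -1}, -10.0, U, "")
        reactions[f"T{e}"] = ({src: -1, "M0": 1}, 0.0, U, tr_gene)
    metabolites += [f"M{i}" for i in range(spec.n_layers + 1)]
    for layer in range(spec.n_layers):
        n_paths = int(rng.integers(1, spec.redundancy + 1))
        for p in range(n_paths):
            n_sub = int(rng.integers(1, spec.complex_size + 1))
            subunits = [f"L{layer}P{p}G{k}" for k in range(n_sub)]
            genes += subunits
            rule = " and ".join(subunits)
            reactions[f"L{layer}P{p}"] = (
                {f"M{layer}": -1, f"M{layer + 1}": 1}, 0.0, U, rule)
    reactions["BIOMASS"] = ({f"M{spec.n_layers}": -1}, 0.0, U, "")
    return _build(metabolites, reactions, genes, "BIOMASS",
                  f"toy_seed{spec.seed}")


def brute_force_mmns(model: MetabolicModel, threshold_fraction: float,
                     evaluator: GrowthEvaluator | None = None,
                     max_deletable: int = 20) -> list[DeletionState]:
    """Exhaustively enumerate all deletion states and return the MMNs.

    An MMN is a state meeting the growth threshold from which no further
    single knockout of a non-essential gene stays feasible.  Enumeration
    covers all 2**n_deletable states and is guarded against exponential
    blow-up.  With ``threshold_fraction`` 0 every state (even zero
    growth) is feasible and the single all-deleted state is returned.
    """
    ev = evaluator or GrowthEvaluator(model)
    deletable = model.deletable_gene_indices
    n = deletable.size
    if n > max_deletable:
        raise ContractError(
            f"{n} deletable genes exceed the exhaustive-enumeration limit "
            f"of {max_deletable}")
    threshold_abs = ev.threshold(threshold_fraction)
    n_genes = model.n_genes
    feasible = np.zeros(1 << n, dtype=bool)
    for mask in range(1 << n):
        bits = np.zeros(n_genes, dtype=bool)
        for i in range(n):
            if mask >> i & 1:
                bits[deletable[i]] = True
        feasible[mask] = ev.feasible(DeletionState(bits), threshold_abs)
    mmns = []
    for mask in range(1 << n):
        if not feasible[mask]:
            continue
        if any(not mask >> i & 1 and feasible[mask | (1 << i)]
               for i in range(n)):
            continue
        bits = np.zeros(n_genes, dtype=bool)
        for i in range(n):
            if mask >> i & 1:
                bits[deletable[i]] = True
        mmns.append(DeletionState(bits))
    return sorted(mmns, key=lambda s: s.key())
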