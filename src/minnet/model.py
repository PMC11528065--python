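"""Canonical in-memory representation of constraint-based metabolic models.

The container mirrors the standard constraint-based formulation: a sparse
stoichiometric matrix ``S`` (metabolites x reactions), per-reaction flux
bounds in mmol/gDW/h, a gene-reaction rule per reaction, and a biomass
pseudo-reaction acting as the growth objective.  Models are loaded from
SBML Level 3 + FBC or COBRA-style JSON via cobrapy, then flattened to
plain numpy/scipy arrays so that the thousands of knockout evaluations
performed by the minimiser touch no heavyweight objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, ContractError, ModelFormatError, ValidationError
from .gpr import DeletionState, GprRule, parse_gpr

__all__ = [
    "MetabolicModel",
    "ModelSummary",
    "load_model",
    "write_json",
    "attach_essentials",
    "summarise",
    "read_gene_list",
]

#: Magnitude used for "unconstrained" flux bounds, following the common
#: convention of treating 1000 mmol/gDW/h as effectively infinite.
UNCONSTRAINED_BOUND = 1000.0


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model flattened to array form."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csr_matrix
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    gpr_text: list[str]
    gene_ids: list[str]
    biomass_reaction: str
    essential_flags: np.ndarray = None
    exchange_reactions: set[str] = None
    objective_coefficients: np.ndarray = None
    model_id: str = "model"

    # caches, built lazily
    _gene_index: dict = field(default=None, repr=False)
    _rxn_index: dict = field(default=None, repr=False)
    _gpr_rules: list = field(default=None, repr=False)
    _gpr_evaluators: list = field(default=None, repr=False)

    def __post_init__(self):
        n_r = len(self.reaction_ids)
        self.S = sp.csr_matrix(self.S)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        if self.essential_flags is None:
            self.essential_flags = np.zeros(len(self.gene_ids), dtype=bool)
        self.essential_flags = np.asarray(self.essential_flags, dtype=bool)
        if self.objective_coefficients is None:
            obj = np.zeros(n_r)
            if self.biomass_reaction is not None:
                obj[self.reaction_ids.index(self.biomass_reaction)] = 1.0
            self.objective_coefficients = obj
        self.objective_coefficients = np.asarray(
            self.objective_coefficients, dtype=float)
        if self.exchange_reactions is None:
            self.exchange_reactions = detect_exchanges(self)
        self.validate()

    # -- indices ----------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_essential(self) -> int:
        return int(self.essential_flags.sum())

    @property
    def biomass_index(self) -> int:
        return self.reaction_index(self.biomass_reaction)

    def gene_index(self, gene: str) -> int:
        if self._gene_index is None:
            self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return self._gene_index[gene]
        except KeyError:
            raise ContractError(f"unknown gene {gene!r}")

    def reaction_index(self, rxn: str) -> int:
        if self._rxn_index is None:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        try:
            return self._rxn_index[rxn]
        except KeyError:
            raise ContractError(f"unknown reaction {rxn!r}")

    @property
    def gpr(self) -> list[GprRule]:
        if self._gpr_rules is None:
            self._gpr_rules = [parse_gpr(t) for t in self.gpr_text]
        return self._gpr_rules

    # -- GPR evaluation ----------------------------------------------------
    def _compile_rule(self, rule: GprRule):
        """Compile a rule tree into a closure over the deleted-bits array."""
        if rule.is_empty:
            return None  # never disabled
        if rule.op == "gene":
            i = self.gene_index(rule.gene)
            return lambda bits: not bits[i]
        subs = [self._compile_rule(c) for c in rule.children]
        if rule.op == "and":
            return lambda bits: all(f(bits) for f in subs)
        return lambda bits: any(f(bits) for f in subs)

    def disabled_reaction_mask(self, state: DeletionState) -> np.ndarray:
        """Boolean mask over reactions disabled by the deletion state."""
        if len(state) != self.n_genes:
            raise ContractError(
                f"deletion state length {len(state)} != n_genes {self.n_genes}")
        if self._gpr_evaluators is None:
            self._gpr_evaluators = [self._compile_rule(r) for r in self.gpr]
        bits = state.bits
        mask = np.zeros(self.n_reactions, dtype=bool)
        if not bits.any():
            return mask
        for j, fn in enumerate(self._gpr_evaluators):
            if fn is not None and not fn(bits):
                mask[j] = True
        return mask

    # -- misc --------------------------------------------------------------
    @property
    def deletable_gene_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.essential_flags)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            gpr_text=list(self.gpr_text),
            gene_ids=list(self.gene_ids),
            biomass_reaction=self.biomass_reaction,
            essential_flags=self.essential_flags.copy(),
            exchange_reactions=set(self.exchange_reactions),
            objective_coefficients=self.objective_coefficients.copy(),
            model_id=self.model_id,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on breach."""
        n_m, n_r = self.S.shape
        if n_m != self.n_metabolites:
            raise ValidationError(
                f"S has {n_m} rows but model lists {self.n_metabolites} metabolites")
        if n_r != self.n_reactions:
            raise ValidationError(
                f"S has {n_r} columns but model lists {self.n_reactions} reactions")
        if len(self.gpr_text) != n_r:
            raise ValidationError("one GPR entry required per reaction")
        if np.any(self.lower_bound > self.upper_bound + 1e-12):
            bad = np.flatnonzero(self.lower_bound > self.upper_bound)
            raise ValidationError(
                f"lower bound exceeds upper bound for reactions {bad.tolist()}")
        if (self.biomass_reaction is not None
                and self.biomass_reaction not in self.reaction_ids):
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model")
        known = set(self.gene_ids)
        offenders = []
        for rid, rule in zip(self.reaction_ids, self.gpr):
            missing = rule.genes() - known
            if missing:
                offenders.append((rid, sorted(missing)))
        if offenders:
            raise ValidationError(
                f"GPR rules reference undeclared genes: {offenders}")
        unknown_ex = self.exchange_reactions - set(self.reaction_ids)
        if unknown_ex:
            raise ValidationError(
                f"exchange set names unknown reactions: {sorted(unknown_ex)}")


def detect_exchanges(model: MetabolicModel) -> set[str]:
    """Auto-detect exchange reactions as single-metabolite columns of S.

    The biomass/objective pseudo-reaction is never classed as an
    exchange, even when it drains a single pooled metabolite.
    """
    csc = sp.csc_matrix(model.S)
    nnz_per_col = np.diff(csc.indptr)
    objective = set(np.flatnonzero(model.objective_coefficients))
    return {model.reaction_ids[j] for j in np.flatnonzero(nnz_per_col == 1)
            if j not in objective}


@dataclass(frozen=True)
class ModelSummary:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_essential: int
    n_deletable: int


def summarise(model: MetabolicModel) -> ModelSummary:
    """Headline counts for a model; pure function of the model."""
    return ModelSummary(
        n_reactions=model.n_reactions,
        n_metabolites=model.n_metabolites,
        n_genes=model.n_genes,
        n_essential=model.n_essential,
        n_deletable=model.n_genes - model.n_essential,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_cobra(cm, objective: str | None) -> MetabolicModel:
    metabolite_ids = [m.id for m in cm.metabolites]
    reaction_ids = [r.id for r in cm.reactions]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    rows, cols, vals = [], [], []
    lb, ub, gprs, obj = [], [], [], []
    for j, rxn in enumerate(cm.reactions):
        for met, coeff in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(coeff))
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        gprs.append(rxn.gene_reaction_rule or "")
        obj.append(rxn.objective_coefficient)
    S = sp.csr_matrix((vals, (rows, cols)),
                      shape=(len(metabolite_ids), len(reaction_ids)))
    obj = np.asarray(obj, dtype=float)
    nonzero = np.flatnonzero(obj)
    if objective is not None:
        if objective not in reaction_ids:
            raise ConfigurationError(
                f"objective override {objective!r} not in model")
        biomass = objective
        obj = np.zeros_like(obj)
        obj[reaction_ids.index(biomass)] = 1.0
    elif nonzero.size == 1:
        biomass = reaction_ids[nonzero[0]]
    elif nonzero.size == 0:
        raise ConfigurationError(
            "model declares no objective reaction; pass objective=...")
    else:
        names = [reaction_ids[j] for j in nonzero]
        raise ConfigurationError(
            f"model declares multiple objective reactions {names}; "
            "pass objective=... to choose the biomass pseudo-reaction")
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bound=np.asarray(lb, dtype=float),
        upper_bound=np.asarray(ub, dtype=float),
        gpr_text=gprs,
        gene_ids=[g.id for g in cm.genes],
        biomass_reaction=biomass,
        objective_coefficients=obj,
        model_id=cm.id or "model",
    )


def load_model(path: str | Path, format: str | None = None,
               objective: str | None = None) -> MetabolicModel:
    """Load an SBML (Level 3 + FBC) or COBRA-style JSON model.

    ``format`` is inferred from the file extension when omitted.  Exactly
    one objective reaction must be declared unless ``objective`` names the
    biomass pseudo-reaction explicitly.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format not in ("sbml", "json"):
        raise ConfigurationError(f"unknown model format {format!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "json":
                cm = cobra.io.load_json_model(str(path))
            else:
                cm = cobra.io.read_sbml_model(str(path))
    except ConfigurationError:
        raise
    except Exception as exc:
        raise ModelFormatError(
            f"could not parse {path} as {format}: {exc}") from exc
    return _from_cobra(cm, objective)


def write_json(model: MetabolicModel, path: str | Path) -> None:
    """Write the model in the COBRA JSON dialect (readable by cobrapy)."""
    csc = sp.csc_matrix(model.S)
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = csc.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v)
                for i, v in zip(col.row, col.data)}
        reactions.append({
            "id": rid,
            "name": rid,
            "metabolites": mets,
            "lower_bound": float(model.lower_bound[j]),
            "upper_bound": float(model.upper_bound[j]),
            "gene_reaction_rule": model.gpr_text[j],
            "objective_coefficient": float(model.objective_coefficients[j]),
        })
    doc = {
        "id": model.model_id,
        "version": "1",
        "metabolites": [
            {"id": m, "name": m, "compartment": ""}
            for m in model.metabolite_ids
        ],
        "reactions": reactions,
        "genes": [{"id": g, "name": g} for g in model.gene_ids],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line, '#' comments."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def attach_essentials(model: MetabolicModel,
                      gene_list: list[str]) -> tuple[MetabolicModel, int]:
    """Flag listed genes as essential (excluded from deletion).

    Genes absent from the model are reported via a warning and ignored.
    Returns the updated model and the number of genes flagged.  Identifier
    matching is case-sensitive and exact.
    """
    flags = model.essential_flags.copy()
    missing = []
    n_flagged = 0
    for g in gene_list:
        try:
            idx = model.gene_index(g)
        except ContractError:
            missing.append(g)
            continue
        if not flags[idx]:
            n_flagged += 1
        flags[idx] = True
    if missing:
        warnings.warn(
            f"essential-gene list names {len(missing)} gene(s) absent from "
            f"the model (ignored): {missing}", stacklevel=2)
    out = model.copy()
    out.essential_flags = flags
    return out, n_flagged
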