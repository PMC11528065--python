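"""Gene-protein-reaction (GPR) logic and simulated gene deletions.

A GPR rule is a Boolean expression over gene identifiers in which ``and``
encodes a protein complex (every subunit required) and ``or`` encodes
isoenzymes (any one suffices).  Deleting a gene sets its leaf to False;
a reaction whose rule evaluates False is disabled.  Reactions without a
rule (spontaneous transport, the biomass pseudo-reaction, exchanges)
can never be gene-disabled.

Deletion states are logical arrays aligned with the model's gene list,
with ``True`` meaning *knocked out*.  The wild type is the all-False
array; every single mutation flips one bit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .errors import ContractError, GprParseError

if TYPE_CHECKING:  # pragma: no cover
    from .model import MetabolicModel

__all__ = [
    "GprRule",
    "DeletionState",
    "parse_gpr",
    "evaluate_gpr",
    "disabled_reactions",
]


# ---------------------------------------------------------------------------
# Rule tree
# ---------------------------------------------------------------------------

class GprRule:
    """Expression tree for a gene-reaction rule.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.
    Leaves carry the gene identifier in ``gene``; internal nodes carry
    two or more children.
    """

    __slots__ = ("op", "gene", "children")

    def __init__(self, op: str, gene: str | None = None,
                 children: list["GprRule"] | None = None):
        self.op = op
        self.gene = gene
        self.children = children or []

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        """All gene identifiers referenced by the rule."""
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        """Infix rendering, logically equivalent to the parsed input."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GprRule({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, GprRule):
            return NotImplemented
        return self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[^\s()]+))")


def _tokenise(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break  # trailing whitespace only
            raise GprParseError("unrecognised character", pos)
        if m.lastgroup == "lpar":
            tokens.append(("(", "(", m.start("lpar")))
        elif m.lastgroup == "rpar":
            tokens.append((")", ")", m.start("rpar")))
        else:
            word = m.group("word")
            low = word.lower()
            if low in ("and", "&", "&&"):
                tokens.append(("and", word, m.start("word")))
            elif low in ("or", "|", "||"):
                tokens.append(("or", word, m.start("word")))
            else:
                tokens.append(("gene", word, m.start("word")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the COBRA gene_reaction_rule grammar.

    Grammar (``or`` binds loosest, per SBML-FBC convention)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := "(" expr ")" | GENE
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenise(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _eof_pos(self) -> int:
        return len(self.text)

    def parse(self) -> GprRule:
        if not self.tokens:
            return GprRule("empty")
        rule = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return rule

    def _expr(self) -> GprRule:
        terms = [self._term()]
        while (tok := self._peek()) is not None and tok[0] == "or":
            self.i += 1
            terms.append(self._term())
        if len(terms) == 1:
            return terms[0]
        return GprRule("or", children=terms)

    def _term(self) -> GprRule:
        factors = [self._factor()]
        while (tok := self._peek()) is not None and tok[0] == "and":
            self.i += 1
            factors.append(self._factor())
        if len(factors) == 1:
            return factors[0]
        return GprRule("and", children=factors)

    def _factor(self) -> GprRule:
        tok = self._peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", self._eof_pos())
        kind, raw, pos = tok
        if kind == "(":
            self.i += 1
            inner = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                at = closing[2] if closing is not None else self._eof_pos()
                raise GprParseError("unbalanced parenthesis", at)
            self.i += 1
            return inner
        if kind == "gene":
            self.i += 1
            return GprRule("gene", gene=raw)
        raise GprParseError(f"unexpected token {raw!r}", pos)


def parse_gpr(text: str) -> GprRule:
    """Parse a gene-reaction rule string into an expression tree.

    Empty (or whitespace-only) text yields the empty rule, which always
    evaluates True: the reaction cannot be disabled by gene deletion.
    """
    return _Parser(text or "").parse()


# ---------------------------------------------------------------------------
# Deletion states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeletionState:
    """Logical array over a model's genes; True = knocked out."""

    bits: np.ndarray = field()

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=bool)
        b.setflags(write=False)
        object.__setattr__(self, "bits", b)

    @classmethod
    def wild_type(cls, n_genes: int) -> "DeletionState":
        return cls(np.zeros(n_genes, dtype=bool))

    @classmethod
    def from_genes(cls, model: "MetabolicModel",
                   genes: Iterable[str]) -> "DeletionState":
        bits = np.zeros(model.n_genes, dtype=bool)
        for g in genes:
            bits[model.gene_index(g)] = True
        return cls(bits)

    @property
    def n_ko(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        """Hashable canonical encoding of the bit pattern."""
        return np.packbits(self.bits).tobytes()

    def deleted_genes(self, model: "MetabolicModel") -> list[str]:
        return [model.gene_ids[i] for i in np.flatnonzero(self.bits)]

    def retained_genes(self, model: "MetabolicModel") -> list[str]:
        return [model.gene_ids[i] for i in np.flatnonzero(~self.bits)]

    def with_knockout(self, idx: int) -> "DeletionState":
        bits = self.bits.copy()
        bits[idx] = True
        return DeletionState(bits)

    def without_knockouts(self, idxs: Iterable[int]) -> "DeletionState":
        bits = self.bits.copy()
        bits[list(idxs)] = False
        return DeletionState(bits)

    def __len__(self) -> int:
        return self.bits.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, DeletionState):
            return NotImplemented
        return np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.key())


def hamming_distance(a: DeletionState, b: DeletionState) -> int:
    """Number of bit positions in which two deletion states differ."""
    if len(a) != len(b):
        raise ContractError(
            f"deletion states have different lengths ({len(a)} vs {len(b)})")
    return int(np.count_nonzero(a.bits ^ b.bits))


# ---------------------------------------------------------------------------
# Evaluation under deletions
# ---------------------------------------------------------------------------

def evaluate_gpr(rule: GprRule, state: DeletionState,
                 gene_index: dict[str, int]) -> bool:
    """Evaluate a rule under a deletion state.

    Leaf value is ``not deleted``; ``and``/``or`` follow Boolean logic;
    the empty rule is True.
    """
    if rule.is_empty:
        return True
    if rule.op == "gene":
        try:
            return not bool(state.bits[gene_index[rule.gene]])
        except KeyError:
            raise ContractError(
                f"gene {rule.gene!r} not present in the deletion state")
    if rule.op == "and":
        return all(evaluate_gpr(c, state, gene_index) for c in rule.children)
    if rule.op == "or":
        return any(evaluate_gpr(c, state, gene_index) for c in rule.children)
    raise ContractError(f"malformed rule node {rule.op!r}")


def disabled_reactions(model: "MetabolicModel",
                       state: DeletionState) -> set[str]:
    """Reaction identifiers whose GPR evaluates False under ``state``.

    Reactions with empty rules are never included.
    """
    mask = model.disabled_reaction_mask(state)
    return {model.reaction_ids[i] for i in np.flatnonzero(mask)}
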