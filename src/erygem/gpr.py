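"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` joins subunits of one enzyme complex, ``or`` joins isozymes.
A reaction with the empty rule has no gene association and is never
disabled by a knockout.

Grammar (keywords case-insensitive, gene ids case-sensitive)::

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := GENE | "(" expr ")"

so ``and`` binds tighter than ``or``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Tuple, Union


class GPRSyntaxError(ValueError):
    """Raised on malformed GPR text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneRef:
    gene_id: str

    def evaluate(self, knocked_out: FrozenSet[str]) -> bool:
        return self.gene_id not in knocked_out

    def genes(self) -> FrozenSet[str]:
        return frozenset({self.gene_id})

    def to_string(self) -> str:
        return self.gene_id


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: Tuple["GPRNode", ...]

    def evaluate(self, knocked_out: FrozenSet[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    def genes(self) -> FrozenSet[str]:
        out: set = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesise an OR nested under an AND to preserve precedence
            if self.op == "and" and isinstance(c, BoolOp) and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


GPRNode = Union[GeneRef, BoolOp]


@dataclass(frozen=True)
class GPRRule:
    """Boolean gene association of a reaction; ``root is None`` = empty rule."""

    root: Optional[GPRNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """Can the reaction still be catalysed with *knocked_out* genes removed?

        The empty rule always evaluates True (no gene association).
        """
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(knocked_out))

    def genes(self) -> FrozenSet[str]:
        return frozenset() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_RULE = GPRRule(None)

_KEYWORDS = {"and", "or"}


def _tokenize(text: str):
    """Yield (kind, value, pos) with kind in {'and','or','gene','(',')'}."""
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, ch, i))
            i += 1
            continue
        if ch == "&" or ch == "|":  # accept COBRA-style operators
            tokens.append(("and" if ch == "&" else "or", ch, i))
            i += 1 + (i + 1 < n and text[i + 1] == ch)
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()&|":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            tokens.append((low, word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(text: str) -> GPRRule:
    """Parse GPR text into a :class:`GPRRule`.

    ``and`` binds tighter than ``or``; parentheses override. Empty or
    whitespace-only text yields the empty rule. Raises
    :class:`GPRSyntaxError` with the offending position on malformed input.
    """
    if text is None or not text.strip():
        return EMPTY_RULE
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(text))

    def expect_factor() -> GPRNode:
        nonlocal pos
        kind, value, at = peek()
        if kind == "(":
            pos += 1
            node = expr()
            kind2, _, at2 = peek()
            if kind2 != ")":
                raise GPRSyntaxError("unbalanced parenthesis: expected ')'", at2)
            pos += 1
            return node
        if kind == "gene":
            pos += 1
            return GeneRef(value)
        raise GPRSyntaxError(
            f"expected gene id or '(' but found {value!r}" if kind else "unexpected end of input",
            at,
        )

    def term() -> GPRNode:
        nonlocal pos
        children = [expect_factor()]
        while peek()[0] == "and":
            pos += 1
            children.append(expect_factor())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def expr() -> GPRNode:
        nonlocal pos
        children = [term()]
        while peek()[0] == "or":
            pos += 1
            children.append(term())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    root = expr()
    kind, value, at = peek()
    if kind is not None:
        raise GPRSyntaxError(f"unexpected token {value!r}", at)
    return GPRRule(root)


def evaluate_gpr(rule: GPRRule, knocked_out: Iterable[str] = ()) -> bool:
    """Functional form of :meth:`GPRRule.evaluate`."""
    return rule.evaluate(knocked_out)
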