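"""Gene-protein-reaction (GPR) boolean rules.

A rule is stored in a two-level normal form ``OR(AND(OR(genes)))``:

* the outer OR ranges over alternative enzyme *complexes* (isozymes),
* each complex is an AND over its *subunits*,
* each subunit is an OR over the redundant genes able to encode it.

Arbitrary nesting in the input string is flattened into this form at
parse time.  The form is what the expression-scoring machinery walks
(max over complexes of min over subunits of max over genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

__all__ = [
    "GPRSyntaxError",
    "Subunit",
    "Complex",
    "GeneAssociation",
    "parse_gpr",
]


class GPRSyntaxError(ValueError):
    """Raised for malformed GPR strings."""


@dataclass(frozen=True)
class Subunit:
    """One protein subunit; any one of ``genes`` suffices to encode it."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("subunit must reference at least one gene")

    def score(self, gene_scores: Mapping[str, float]) -> Optional[float]:
        vals = [gene_scores[g] for g in self.genes if g in gene_scores]
        return max(vals) if vals else None

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return any(present.get(g, False) for g in self.genes)


@dataclass(frozen=True)
class Complex:
    """An enzyme complex; every subunit is required."""

    subunits: tuple[Subunit, ...]

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("complex must contain at least one subunit")

    def score(self, gene_scores: Mapping[str, float]) -> Optional[float]:
        vals = []
        for su in self.subunits:
            s = su.score(gene_scores)
            if s is None:  # a subunit with no scorable gene poisons the complex
                return None
            vals.append(s)
        return min(vals)

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return all(su.evaluate(present) for su in self.subunits)


@dataclass(frozen=True)
class GeneAssociation:
    """Normal-form GPR rule: OR over complexes."""

    complexes: tuple[Complex, ...]
    text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.complexes:
            raise ValueError("gene association must contain at least one complex")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(
            g for cx in self.complexes for su in cx.subunits for g in su.genes
        )

    def score(self, gene_scores: Mapping[str, float]) -> Optional[float]:
        """Expression score: max over complexes of min over subunits of
        max over genes.  ``None`` when no complex is fully scorable."""
        vals = [s for cx in self.complexes if (s := cx.score(gene_scores)) is not None]
        return max(vals) if vals else None

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return any(cx.evaluate(present) for cx in self.complexes)

    def to_string(self) -> str:
        parts = []
        for cx in self.complexes:
            sub_parts = []
            for su in cx.subunits:
                if len(su.genes) == 1:
                    sub_parts.append(su.genes[0])
                else:
                    sub_parts.append("(" + " or ".join(su.genes) + ")")
            body = " and ".join(sub_parts)
            if len(cx.subunits) > 1 and len(self.complexes) > 1:
                body = "(" + body + ")"
            parts.append(body)
        return " or ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# --- parsing -----------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive-descent parser for ``gene | expr and expr | expr or expr``."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise GPRSyntaxError(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        children = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and(self):
        children = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom(self):
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GPRSyntaxError("unbalanced parentheses in GPR")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r}")
        return ("gene", tok)


def _as_gene_disjunction(complexes: list[list[frozenset[str]]]) -> Optional[frozenset[str]]:
    """If a complex list encodes a plain disjunction of genes, return the gene
    set; otherwise None.  Such a node collapses to a single subunit inside an
    AND instead of being distributed."""
    genes: set[str] = set()
    for cx in complexes:
        if len(cx) != 1:
            return None
        genes.update(cx[0])
    return frozenset(genes)


def _normalize(node) -> list[list[frozenset[str]]]:
    """Return a list of complexes, each a list of gene-set subunits."""
    kind = node[0]
    if kind == "gene":
        return [[frozenset([node[1]])]]
    children = [_normalize(ch) for ch in node[1]]
    if kind == "or":
        out: list[list[frozenset[str]]] = []
        for ch in children:
            out.extend(ch)
        return out
    # AND: pure gene-disjunction children become subunits; anything richer is
    # distributed (cross product of complex alternatives).
    subunits: list[frozenset[str]] = []
    rich: list[list[list[frozenset[str]]]] = []
    for ch in children:
        dis = _as_gene_disjunction(ch)
        if dis is not None:
            subunits.append(dis)
        else:
            rich.append(ch)
    combos: list[list[frozenset[str]]] = [list(subunits)]
    for ch in rich:
        combos = [base + cx for base in combos for cx in ch]
    return combos


def parse_gpr(text: str) -> Optional[GeneAssociation]:
    """Parse a boolean GPR string into normal form.

    Returns ``None`` for empty/blank input.  ``and``/``or`` are
    case-insensitive; parentheses group arbitrarily deep.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    ast = _Parser(tokens).parse()
    complexes = _normalize(ast)
    # dedupe identical complexes while preserving order
    seen: set[tuple[frozenset[str], ...]] = set()
    out: list[Complex] = []
    for cx in complexes:
        key = tuple(cx)
        if key in seen:
            continue
        seen.add(key)
        out.append(Complex(tuple(Subunit(tuple(sorted(su))) for su in cx)))
    return GeneAssociation(tuple(out), text=text.strip())
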