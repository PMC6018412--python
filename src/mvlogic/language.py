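"""Text format for logical regulatory graphs, and graph exports.

The model format is line-oriented (``.lrg``, UTF-8)::

    # optional comment lines; a block directly above a declaration is
    # attached to that element, a leading block to the model itself
    node p53 max=2
    node Signal max=1 input
    edge p53 -> Mdm2nuc t=1 sign=-
    rule Mdm2nuc:=1 <- Mdm2cyt:2 | (Mdm2cyt:1 & !p53 & !DNAdam)

Formulas use ``!`` (NOT), ``&`` (AND) and ``|`` (inclusive OR) with the
usual precedence NOT > AND > OR, parentheses, and literals that are a
bare node id or ``id:threshold``.  Node declaration order is the
semantic node order of the model.

EBNF of the formula grammar::

    formula  = term , { "|" , term } ;
    term     = factor , { "&" , factor } ;
    factor   = "!" , factor | "(" , formula , ")" | literal ;
    literal  = identifier , [ ":" , integer ] ;
"""

from __future__ import annotations

import re
from typing import TYPE_CHECKING

from .model import (
    And,
    Const,
    Formula,
    Interaction,
    Literal,
    LogicalModel,
    ModelError,
    NodeSpec,
    Not,
    Or,
    RuleEntry,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import TransitionGraph

__all__ = [
    "parse_formula",
    "format_formula",
    "parse_model",
    "write_model",
    "export_dot",
    "export_tsv",
    "ParseError",
]


class ParseError(ModelError):
    """Syntax error with position information."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" at line {line}"
            if column is not None:
                where += f", column {column}"
        super().__init__(f"{message}{where}")


# --------------------------------------------------------------------------
# Formula parsing (recursive descent)

_TOKEN = re.compile(
    r"\s*(?:(?P<lit>[A-Za-z_]\w*(?::\d+)?)|(?P<op>[!&|()])|(?P<bad>\S))"
)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    for m in _TOKEN.finditer(text):
        if m.lastgroup == "bad":
            raise ParseError(
                f"unexpected character {m.group('bad')!r} in formula",
                column=m.start("bad") + 1,
            )
        tokens.append((m.group(m.lastgroup), m.start(m.lastgroup)))
    return tokens


class _FormulaParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise ParseError("unexpected end of formula", column=len(self.text) + 1)
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Formula:
        formula = self.or_expr()
        if self.pos < len(self.tokens):
            tok, col = self.tokens[self.pos]
            raise ParseError(f"unexpected token {tok!r}", column=col + 1)
        return formula

    def or_expr(self) -> Formula:
        operands = [self.and_expr()]
        while self.peek() == "|":
            self.next()
            operands.append(self.and_expr())
        return operands[0] if len(operands) == 1 else Or(*operands)

    def and_expr(self) -> Formula:
        operands = [self.factor()]
        while self.peek() == "&":
            self.next()
            operands.append(self.factor())
        return operands[0] if len(operands) == 1 else And(*operands)

    def factor(self) -> Formula:
        tok, col = self.next()
        if tok == "!":
            return Not(self.factor())
        if tok == "(":
            inner = self.or_expr()
            closing, ccol = self.next()
            if closing != ")":
                raise ParseError("expected ')'", column=ccol + 1)
            return inner
        if tok in {"&", "|", ")"}:
            raise ParseError(f"unexpected token {tok!r}", column=col + 1)
        if ":" in tok:
            name, th = tok.split(":")
            return Literal(name, int(th))
        if tok in ("true", "false"):
            return Const(tok == "true")
        return Literal(tok)


def parse_formula(
    text: str, context: tuple[LogicalModel, str] | None = None
) -> Formula:
    """Parse a rule formula; with ``context=(model, target)``, check that
    every literal resolves to a declared interaction toward the target."""
    formula = _FormulaParser(text).parse()
    if context is not None:
        model, target = context
        for lit in formula.literals():
            model.literal_window(target, (lit.node, lit.threshold))
    return formula


def format_formula(formula: Formula) -> str:
    return str(formula)


# --------------------------------------------------------------------------
# Model documents

_NODE_RE = re.compile(
    r"^node\s+(?P<id>[A-Za-z_]\w*)\s+max=(?P<max>\d+)(?P<input>\s+input)?\s*$"
)
_EDGE_RE = re.compile(
    r"^edge\s+(?P<src>[A-Za-z_]\w*)\s*->\s*(?P<tgt>[A-Za-z_]\w*)"
    r"\s+t=(?P<t>\d+)\s+sign=(?P<sign>[+\-?]|dual)\s*$"
)
_RULE_RE = re.compile(
    r"^rule\s+(?P<tgt>[A-Za-z_]\w*)\s*:=\s*(?P<val>\d+)\s*<-\s*(?P<formula>.+)$"
)


def parse_model(text: str) -> LogicalModel:
    """Parse a model document; the resulting model is validated."""
    nodes: list[NodeSpec] = []
    node_ids: set[str] = set()
    interactions: list[Interaction] = []
    raw_rules: list[tuple[str, int, str, int]] = []  # target, value, formula, line
    comments: dict[str, str] = {}
    pending_comment: list[str] = []
    model_comment: list[str] = []
    seen_declaration = False

    def attach(key: str) -> None:
        # a comment block at the very top of the file documents the
        # model itself; later blocks document the declaration below them
        nonlocal pending_comment, seen_declaration
        if pending_comment and not seen_declaration:
            model_comment.extend(pending_comment)
            pending_comment = []
        elif pending_comment:
            comments[key] = "\n".join(pending_comment)
            pending_comment = []
        seen_declaration = True

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            if pending_comment and not seen_declaration:
                model_comment.extend(pending_comment)
                pending_comment = []
            continue
        if line.startswith("#"):
            pending_comment.append(line[1:].strip())
            continue
        if m := _NODE_RE.match(line):
            node_id = m.group("id")
            if node_id in node_ids:
                raise ParseError(f"duplicate node {node_id!r}", line=lineno)
            node_ids.add(node_id)
            try:
                nodes.append(
                    NodeSpec(node_id, int(m.group("max")), bool(m.group("input")))
                )
            except ModelError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            attach(node_id)
        elif m := _EDGE_RE.match(line):
            src, tgt = m.group("src"), m.group("tgt")
            for g in (src, tgt):
                if g not in node_ids:
                    raise ParseError(
                        f"edge references undeclared node {g!r}", line=lineno
                    )
            interactions.append(
                Interaction(src, tgt, int(m.group("t")), m.group("sign"))
            )
            attach(f"{src}->{tgt}")
        elif m := _RULE_RE.match(line):
            tgt = m.group("tgt")
            if tgt not in node_ids:
                raise ParseError(
                    f"rule for undeclared node {tgt!r} (declare nodes first)",
                    line=lineno,
                )
            val = int(m.group("val"))
            raw_rules.append((tgt, val, m.group("formula").strip(), lineno))
            attach(f"{tgt}:={val}")
        else:
            raise ParseError(f"cannot parse line {line!r}", line=lineno)

    if not nodes:
        raise ParseError("empty model: no node declarations")
    if model_comment:
        comments[""] = "\n".join(model_comment)
    if pending_comment:  # trailing comment block
        comments.setdefault("", "\n".join(pending_comment))

    # group formulas per (target, value); repeated lines OR together
    grouped: dict[str, dict[int, list[str]]] = {}
    lines_of: dict[tuple[str, int], int] = {}
    for tgt, val, ftext, lineno in raw_rules:
        grouped.setdefault(tgt, {}).setdefault(val, []).append(ftext)
        lines_of.setdefault((tgt, val), lineno)

    skeleton = LogicalModel(nodes, interactions)
    rules: dict[str, list[RuleEntry]] = {}
    for tgt, by_value in grouped.items():
        entries = []
        for val, ftexts in by_value.items():
            formulas = []
            for ftext in ftexts:
                try:
                    formulas.append(parse_formula(ftext, (skeleton, tgt)))
                except ModelError as exc:
                    raise ParseError(str(exc), line=lines_of[(tgt, val)]) from exc
            entries.append(RuleEntry(val, formulas))
        rules[tgt] = entries

    model = LogicalModel(nodes, interactions, rules, comments)
    report = model.validate()
    if not report.ok:
        raise ModelError(f"invalid model:\n{report}")
    return model


def write_model(model: LogicalModel) -> str:
    """Canonical serialization; re-parsing yields a structurally equal model."""
    out: list[str] = []

    def comment_block(key: str) -> None:
        if key in model.comments:
            for line in model.comments[key].splitlines():
                out.append(f"# {line}".rstrip())

    if "" in model.comments:
        comment_block("")
        out.append("")
    for spec in model.nodes:
        comment_block(spec.id)
        suffix = " input" if spec.is_input else ""
        out.append(f"node {spec.id} max={spec.max_level}{suffix}")
    for it in model.interactions:
        comment_block(f"{it.source}->{it.target}")
        out.append(f"edge {it.source} -> {it.target} t={it.threshold} sign={it.sign}")
    for g in model.node_ids:
        for entry in model.rules.get(g, ()):
            comment_block(f"{g}:={entry.target_value}")
            for formula in entry.formulas:
                out.append(f"rule {g}:={entry.target_value} <- {formula}")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Graph exports

# always quote digit strings: DOT numerals would drop leading zeros
_DOT_ID = re.compile(r"^[A-Za-z_]\w*$")


def _dot_quote(s: str) -> str:
    if _DOT_ID.match(s):
        return s
    return '"' + s.replace('"', '\\"') + '"'


def export_dot(graph) -> str:
    """Render a transition graph, hierarchical graph or regulatory graph
    as DOT text.  States with no outgoing transition (stable states) and
    attractor classes are drawn with a distinctive box shape."""
    # late imports avoid a dependency cycle
    from .compression import HierarchicalGraph
    from .dynamics import TransitionGraph

    lines = ["digraph {"]
    if isinstance(graph, TransitionGraph):
        for state in graph.states():
            code = state.code()
            attrs = ""
            if graph.out_degree(state) == 0:
                attrs = " [shape=box, style=filled, fillcolor=salmon]"
            lines.append(f"  {_dot_quote(code)}{attrs};")
        for a, b in graph.transitions():
            lines.append(f"  {_dot_quote(a.code())} -> {_dot_quote(b.code())};")
    elif isinstance(graph, HierarchicalGraph):
        shapes = {
            "stable": "box, style=filled, fillcolor=salmon",
            "cyclic_attractor": "ellipse, style=filled, fillcolor=lightblue",
            "cyclic_transient": "ellipse, style=filled, fillcolor=lightcyan",
            "transient_chain": "ellipse",
        }
        for node in graph.nodes:
            lines.append(
                f"  {_dot_quote(node.label)} [shape={shapes[node.kind]}];"
            )
        for a, b in graph.edges:
            lines.append(f"  {_dot_quote(a.label)} -> {_dot_quote(b.label)};")
    elif isinstance(graph, LogicalModel):
        arrow = {"+": "normal", "-": "tee", "dual": "diamond", "?": "vee"}
        for spec in graph.nodes:
            shape = "box" if spec.is_input else "ellipse"
            lines.append(
                f"  {_dot_quote(spec.id)} "
                f'[shape={shape}, label="{spec.id} (max {spec.max_level})"];'
            )
        for it in graph.interactions:
            lines.append(
                f"  {_dot_quote(it.source)} -> {_dot_quote(it.target)} "
                f'[arrowhead={arrow[it.sign]}, label="{it.threshold}"];'
            )
    else:  # pragma: no cover
        raise TypeError(f"cannot export {type(graph).__name__} as DOT")
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_tsv(graph: "TransitionGraph") -> str:
    """Transition edge list as TSV with a header line."""
    lines = ["source_code\ttarget_code"]
    for a, b in graph.transitions():
        lines.append(f"{a.code()}\t{b.code()}")
    return "\n".join(lines) + "\n"
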