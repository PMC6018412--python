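"""Core domain types and evaluation semantics for multi-valued logical
regulatory graphs.

A model is a set of regulatory components (*nodes*), each carrying a
discrete activity level between 0 and an individual maximum, a set of
signed threshold *interactions* between them, and per-node logical
*rules* mapping each state of the regulators to a target level.

Threshold semantics follow the multi-valued logical formalism of
R. Thomas: a single regulatory arc from a multi-valued source may carry
several interactions at increasing thresholds, and an interaction with
threshold ``t`` is active exactly when the source level lies in the
window ``[t, t' - 1]``, where ``t'`` is the next-higher threshold
declared on the same arc (or ``[t, max]`` when there is none).  Formula
literals therefore denote *activity windows*, not plain ``>=``
comparisons, and negation of a literal means "outside the window".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Sign",
    "NodeSpec",
    "Interaction",
    "Formula",
    "Const",
    "Literal",
    "Not",
    "And",
    "Or",
    "RuleEntry",
    "LogicalModel",
    "State",
    "ModelError",
    "LiteralResolutionError",
    "RuleConflictError",
    "ValidationIssue",
    "ValidationReport",
]


class ModelError(ValueError):
    """A structural problem in a logical model."""


class LiteralResolutionError(ModelError):
    """A formula literal does not resolve to a declared interaction."""


class RuleConflictError(ModelError):
    """Two rule entries of one node are satisfied in the same state.

    Carries the offending node and a witness state.
    """

    def __init__(self, node: str, values: tuple[int, int], witness: "State"):
        self.node = node
        self.values = values
        self.witness = witness
        super().__init__(
            f"rules for target values {values[0]} and {values[1]} of node "
            f"{node!r} are both satisfied in state {witness.code()}"
        )


# --------------------------------------------------------------------------
# Structure


@dataclass(frozen=True)
class NodeSpec:
    """A regulatory component with levels ``0 .. max_level``.

    Input nodes are unregulated environmental signals: they carry no
    incoming interactions and no rules, and implicitly maintain their
    current level.
    """

    id: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self) -> None:
        if not self.id.isidentifier():
            raise ModelError(f"node id {self.id!r} is not an identifier")
        if not 1 <= self.max_level <= 9:
            # single decimal digit per node keeps state codes unambiguous
            raise ModelError(
                f"max_level of {self.id!r} must be in [1, 9], got {self.max_level}"
            )


#: Interaction signs: activation, inhibition, dual (both, level-dependent)
#: or unknown/unspecified.
Sign = str
SIGNS = ("+", "-", "dual", "?")


@dataclass(frozen=True)
class Interaction:
    """One threshold interaction of a regulatory arc.

    A multi-valued source may act on the same target through several
    interactions at distinct thresholds; together they partition the
    source's positive levels into activity windows.
    """

    source: str
    target: str
    threshold: int = 1
    sign: Sign = "?"

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ModelError(
                f"threshold of {self.source}->{self.target} must be >= 1"
            )
        if self.sign not in SIGNS:
            raise ModelError(f"invalid sign {self.sign!r} (use one of {SIGNS})")


# --------------------------------------------------------------------------
# Formulas


class Formula:
    """Base class of the rule-formula AST."""

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        raise NotImplementedError

    def literals(self) -> Iterator["Literal"]:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Formula):
    """A boolean constant (``true`` / ``false`` in the text format)."""

    value: bool

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return self.value

    def literals(self) -> Iterator["Literal"]:
        return iter(())

    def __str__(self) -> str:
        return "true" if self.value else "false"


@dataclass(frozen=True)
class Literal(Formula):
    """A regulator reference, optionally with an explicit threshold.

    A bare literal (``threshold is None``) is only legal when its arc
    toward the formula's target carries exactly one interaction.
    """

    node: str
    threshold: int | None = None

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return model.eval_literal(target, (self.node, self.threshold), state)

    def literals(self) -> Iterator["Literal"]:
        yield self

    def __str__(self) -> str:
        return self.node if self.threshold is None else f"{self.node}:{self.threshold}"


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return not self.operand.eval(model, target, state)

    def literals(self) -> Iterator[Literal]:
        yield from self.operand.literals()

    def __str__(self) -> str:
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(Formula):
    """N-ary conjunction; nested conjunctions are flattened, so the AST
    is canonical under associativity."""

    operands: tuple[Formula, ...]

    def __init__(self, *operands: Formula):
        flat: list[Formula] = []
        for op in operands:
            flat.extend(op.operands if isinstance(op, And) else (op,))
        object.__setattr__(self, "operands", tuple(flat))

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return all(op.eval(model, target, state) for op in self.operands)

    def literals(self) -> Iterator[Literal]:
        for op in self.operands:
            yield from op.literals()

    def __str__(self) -> str:
        parts = [
            f"({op})" if isinstance(op, Or) else str(op) for op in self.operands
        ]
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Formula):
    """N-ary disjunction; nested disjunctions are flattened."""

    operands: tuple[Formula, ...]

    def __init__(self, *operands: Formula):
        flat: list[Formula] = []
        for op in operands:
            flat.extend(op.operands if isinstance(op, Or) else (op,))
        object.__setattr__(self, "operands", tuple(flat))

    def eval(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return any(op.eval(model, target, state) for op in self.operands)

    def literals(self) -> Iterator[Literal]:
        for op in self.operands:
            yield from op.literals()

    def __str__(self) -> str:
        return " | ".join(str(op) for op in self.operands)


@dataclass(frozen=True)
class RuleEntry:
    """Formulas calling a node toward one target value.

    Several formulas under one target value are combined with OR.
    """

    target_value: int
    formulas: tuple[Formula, ...]

    def __init__(self, target_value: int, formulas: Iterable[Formula]):
        object.__setattr__(self, "target_value", target_value)
        object.__setattr__(self, "formulas", tuple(formulas))
        if self.target_value < 1:
            raise ModelError("rule target values must be >= 1 (0 is the default)")

    def satisfied(self, model: "LogicalModel", target: str, state: "State") -> bool:
        return any(f.eval(model, target, state) for f in self.formulas)


# --------------------------------------------------------------------------
# States


@dataclass(frozen=True, order=True)
class State:
    """An activity-level vector, one level per node in declared order."""

    levels: tuple[int, ...]

    def __init__(self, levels: Iterable[int]):
        object.__setattr__(self, "levels", tuple(levels))

    def code(self) -> str:
        """Digit-string rendering in node order, e.g. ``'0110'``."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "State":
        return cls(int(c) for c in code)

    def replace(self, index: int, level: int) -> "State":
        levels = list(self.levels)
        levels[index] = level
        return State(levels)

    def __getitem__(self, index: int) -> int:
        return self.levels[index]

    def __iter__(self) -> Iterator[int]:
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __str__(self) -> str:
        return self.code()


# --------------------------------------------------------------------------
# The model


@dataclass
class ValidationIssue:
    kind: str
    message: str
    witness: State | None = None

    def __str__(self) -> str:
        if self.witness is not None:
            return f"[{self.kind}] {self.message} (witness state {self.witness})"
        return f"[{self.kind}] {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "model is valid"
        return "\n".join(str(i) for i in self.issues)


class LogicalModel:
    """A multi-valued logical regulatory graph.

    Node order is part of the semantics: states render as digit strings
    in declared order, and the sequential updating scheme sweeps nodes
    in this order.

    Parameters
    ----------
    nodes:
        Ordered node declarations.
    interactions:
        Threshold interactions; thresholds on a shared (source, target)
        arc must be distinct and are kept sorted.
    rules:
        Mapping from node id to its rule entries (one per target value).
        Nodes without rules default to target level 0.
    comments:
        Optional free-text comment per element: keys are ``""`` for the
        model itself, a node id, ``"src->tgt"`` for an arc, or
        ``"id:=v"`` for a rule entry.
    """

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        interactions: Iterable[Interaction] = (),
        rules: Mapping[str, Sequence[RuleEntry]] | None = None,
        comments: Mapping[str, str] | None = None,
    ):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.interactions: tuple[Interaction, ...] = tuple(interactions)
        self.rules: dict[str, tuple[RuleEntry, ...]] = {
            g: tuple(entries) for g, entries in (rules or {}).items()
        }
        self.comments: dict[str, str] = dict(comments or {})

        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate node ids")
        self._index = {n.id: i for i, n in enumerate(self.nodes)}
        self._by_id = {n.id: n for n in self.nodes}

        # thresholds per arc, sorted ascending
        self._arc_thresholds: dict[tuple[str, str], list[int]] = {}
        for it in self.interactions:
            if it.source not in self._by_id or it.target not in self._by_id:
                raise ModelError(
                    f"interaction {it.source}->{it.target} references an "
                    "undeclared node"
                )
            self._arc_thresholds.setdefault((it.source, it.target), []).append(
                it.threshold
            )
        for arc, ths in self._arc_thresholds.items():
            if len(set(ths)) != len(ths):
                raise ModelError(f"duplicate threshold on arc {arc[0]}->{arc[1]}")
            ths.sort()

        for g in self.rules:
            if g not in self._by_id:
                raise ModelError(f"rule for undeclared node {g!r}")
        for g, entries in self.rules.items():
            values = [e.target_value for e in entries]
            if len(set(values)) != len(values):
                raise ModelError(f"two rule entries for one target value of {g!r}")

    # -- basic queries ------------------------------------------------------

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise ModelError(f"unknown node {node_id!r}") from None

    def index(self, node_id: str) -> int:
        self.node(node_id)
        return self._index[node_id]

    def regulators(self, node_id: str) -> tuple[str, ...]:
        """Sources of the declared interactions toward ``node_id``."""
        seen: dict[str, None] = {}
        for it in self.interactions:
            if it.target == node_id:
                seen.setdefault(it.source, None)
        return tuple(seen)

    def targets(self, node_id: str) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.interactions:
            if it.source == node_id:
                seen.setdefault(it.target, None)
        return tuple(seen)

    def arc_thresholds(self, source: str, target: str) -> tuple[int, ...]:
        return tuple(self._arc_thresholds.get((source, target), ()))

    def state_count(self) -> int:
        n = 1
        for spec in self.nodes:
            n *= spec.max_level + 1
        return n

    def states(self) -> Iterator[State]:
        """Enumerate the full product state space in lexicographic order."""
        ranges = [range(spec.max_level + 1) for spec in self.nodes]
        for levels in itertools.product(*ranges):
            yield State(levels)

    # -- evaluation semantics ----------------------------------------------

    def literal_window(
        self, target: str, literal: tuple[str, int | None]
    ) -> tuple[str, int, int]:
        """Resolve a literal to ``(source, lo, hi)`` — its activity window.

        The window of an interaction at threshold ``t`` runs up to the
        next-higher threshold on the same arc (exclusive), or to the
        source's maximal level.
        """
        source, threshold = literal
        ths = self._arc_thresholds.get((source, target))
        if not ths:
            raise LiteralResolutionError(
                f"literal {source!r} in the rule of {target!r} matches no "
                f"declared interaction {source}->{target}"
            )
        if threshold is None:
            if len(ths) > 1:
                raise LiteralResolutionError(
                    f"bare literal {source!r} in the rule of {target!r} is "
                    f"ambiguous: the arc carries thresholds {ths}; write "
                    f"{source}:t explicitly"
                )
            threshold = ths[0]
        if threshold not in ths:
            raise LiteralResolutionError(
                f"literal {source}:{threshold} in the rule of {target!r}: no "
                f"interaction at this threshold (declared: {ths})"
            )
        pos = ths.index(threshold)
        hi = ths[pos + 1] - 1 if pos + 1 < len(ths) else self.node(source).max_level
        return source, threshold, hi

    def eval_literal(
        self, target: str, literal: tuple[str, int | None], state: State
    ) -> bool:
        """True iff the source level lies inside the literal's window."""
        source, lo, hi = self.literal_window(target, literal)
        level = state[self._index[source]]
        return lo <= level <= hi

    def target_level(self, state: State, node_id: str) -> int:
        """The level the rules call ``node_id`` toward in ``state``.

        Input nodes maintain their current level.  A node whose entries
        are all unsatisfied (or that has no rule) has target level 0.
        Two simultaneously satisfied entries raise
        :class:`RuleConflictError` with the state as witness.
        """
        spec = self.node(node_id)
        if spec.is_input:
            return state[self._index[node_id]]
        satisfied = [
            e
            for e in self.rules.get(node_id, ())
            if e.satisfied(self, node_id, state)
        ]
        if len(satisfied) > 1:
            raise RuleConflictError(
                node_id,
                (satisfied[0].target_value, satisfied[1].target_value),
                state,
            )
        return satisfied[0].target_value if satisfied else 0

    def targets_vector(self, state: State) -> tuple[int, ...]:
        return tuple(self.target_level(state, g) for g in self.node_ids)

    def called_nodes(self, state: State) -> set[tuple[str, int]]:
        """Nodes whose target differs from their level, with direction ±1.

        Updates are unitary: a node called from 0 toward 2 moves by +1.
        """
        calls: set[tuple[str, int]] = set()
        for i, spec in enumerate(self.nodes):
            target = self.target_level(state, spec.id)
            current = state[i]
            if target > current:
                calls.add((spec.id, +1))
            elif target < current:
                calls.add((spec.id, -1))
        return calls

    def is_stable(self, state: State) -> bool:
        return all(
            self.target_level(state, spec.id) == state[i]
            for i, spec in enumerate(self.nodes)
        )

    # -- regulator-space enumeration (shared by validation & analyses) ------

    def regulator_states(
        self, node_id: str, fixed: Mapping[str, int] | None = None
    ) -> Iterator[State]:
        """All states varying the regulators of ``node_id`` (others at 0).

        Sufficient for evaluating the node's rules, which only read
        regulator levels.  ``fixed`` pins chosen nodes to given levels.
        """
        fixed = dict(fixed or {})
        regs = self.regulators(node_id)
        free = [r for r in regs if r not in fixed]
        ranges = [range(self.node(r).max_level + 1) for r in free]
        base = [0] * len(self.nodes)
        for g, v in fixed.items():
            base[self.index(g)] = v
        for combo in itertools.product(*ranges):
            levels = list(base)
            for r, v in zip(free, combo):
                levels[self._index[r]] = v
            yield State(levels)

    # -- validation ---------------------------------------------------------

    def validate(self) -> ValidationReport:
        """Structural and semantic checks; failures are reported, not raised.

        Covers threshold bounds, literal resolvability, input-node
        constraints, and pairwise mutual exclusion of each node's rule
        entries (exhaustively over regulator level combinations).
        """
        report = ValidationReport()
        add = report.issues.append

        for it in self.interactions:
            max_src = self.node(it.source).max_level
            if it.threshold > max_src:
                add(
                    ValidationIssue(
                        "threshold-bound",
                        f"interaction {it.source}->{it.target} has threshold "
                        f"{it.threshold} above source max level {max_src}",
                    )
                )

        for spec in self.nodes:
            if spec.is_input:
                if self.regulators(spec.id):
                    add(
                        ValidationIssue(
                            "input-node",
                            f"input node {spec.id!r} has incoming interactions",
                        )
                    )
                if self.rules.get(spec.id):
                    add(
                        ValidationIssue(
                            "input-node",
                            f"input node {spec.id!r} has explicit rules",
                        )
                    )

        for g, entries in self.rules.items():
            spec = self.node(g)
            for entry in entries:
                if entry.target_value > spec.max_level:
                    add(
                        ValidationIssue(
                            "target-value",
                            f"rule of {g!r} targets value {entry.target_value} "
                            f"above max level {spec.max_level}",
                        )
                    )
                for formula in entry.formulas:
                    for lit in formula.literals():
                        try:
                            self.literal_window(g, (lit.node, lit.threshold))
                        except LiteralResolutionError as exc:
                            add(ValidationIssue("literal", str(exc)))

        # mutual exclusion of entries for distinct target values
        for g, entries in self.rules.items():
            if len(entries) < 2:
                continue
            if any(
                issue.kind == "literal" for issue in report.issues
            ):  # unresolvable literals would raise during evaluation
                continue
            for a, b in itertools.combinations(entries, 2):
                witness = next(
                    (
                        s
                        for s in self.regulator_states(g)
                        if a.satisfied(self, g, s) and b.satisfied(self, g, s)
                    ),
                    None,
                )
                if witness is not None:
                    add(
                        ValidationIssue(
                            "rule-conflict",
                            f"rules for values {a.target_value} and "
                            f"{b.target_value} of {g!r} overlap",
                            witness,
                        )
                    )
        return report

    # -- misc ----------------------------------------------------------------

    def replace_rules(
        self, node_id: str, entries: Sequence[RuleEntry]
    ) -> "LogicalModel":
        rules = dict(self.rules)
        rules[node_id] = tuple(entries)
        return LogicalModel(self.nodes, self.interactions, rules, self.comments)

    def __repr__(self) -> str:
        return (
            f"LogicalModel({len(self.nodes)} nodes, "
            f"{len(self.interactions)} interactions, "
            f"{sum(len(e) for e in self.rules.values())} rule entries)"
        )
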