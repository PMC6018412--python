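"""State transition graphs under the classical updating schemes.

Given a state, the rules call every node whose target level differs
from its current level; updates are always unitary (one level up or
down).  The updating scheme decides which calls fire in one transition:

asynchronous
    one successor per called node — interleaving semantics;
synchronous
    a single successor stepping every called node at once;
complete
    one successor per non-empty subset of the called nodes (the
    synchronous and asynchronous relations are both sub-relations);
sequential
    one sweep over the nodes in declared order, each step recomputed
    against the partially updated state;
priority
    nodes are grouped in ranked classes; only calls in the
    highest-priority class(es) containing a call fire, each class under
    its own inner (synchronous or asynchronous) assumption, equal-rank
    classes combined asynchronously.

Stability (no call at all) does not depend on the scheme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .model import LogicalModel, ModelError, NodeSpec, State

__all__ = [
    "UpdatingScheme",
    "PriorityClass",
    "Perturbation",
    "InitialPattern",
    "TransitionGraph",
    "CapExceededError",
    "apply_perturbation",
    "successors",
    "build_stg",
    "MAX_STATES_DEFAULT",
]

#: Guard against accidental full enumeration of huge state spaces.
MAX_STATES_DEFAULT = 2**20


class CapExceededError(RuntimeError):
    """The state cap was reached while building a transition graph."""


@dataclass(frozen=True)
class PriorityClass:
    """A group of nodes sharing a priority rank.

    Lower ``rank`` means higher priority (rank 0 fires before rank 1).
    ``mode`` is the updating assumption applied *inside* the class.
    """

    members: frozenset[str]
    rank: int = 0
    mode: str = "asynchronous"

    def __init__(self, members: Iterable[str], rank: int = 0, mode: str = "asynchronous"):
        object.__setattr__(self, "members", frozenset(members))
        object.__setattr__(self, "rank", rank)
        object.__setattr__(self, "mode", mode)
        if mode not in ("asynchronous", "synchronous"):
            raise ModelError(f"priority class mode must be (a)synchronous, got {mode!r}")


@dataclass(frozen=True)
class UpdatingScheme:
    """An updating policy; use the classmethod constructors."""

    mode: str
    classes: tuple[PriorityClass, ...] = ()

    MODES = ("asynchronous", "synchronous", "complete", "sequential", "priority")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ModelError(f"unknown updating mode {self.mode!r}")

    @classmethod
    def asynchronous(cls) -> "UpdatingScheme":
        return cls("asynchronous")

    @classmethod
    def synchronous(cls) -> "UpdatingScheme":
        return cls("synchronous")

    @classmethod
    def complete(cls) -> "UpdatingScheme":
        return cls("complete")

    @classmethod
    def sequential(cls) -> "UpdatingScheme":
        return cls("sequential")

    @classmethod
    def priority(cls, classes: Iterable[PriorityClass]) -> "UpdatingScheme":
        return cls("priority", tuple(classes))

    def check(self, model: LogicalModel) -> None:
        if self.mode != "priority":
            return
        covered: set[str] = set()
        for c in self.classes:
            unknown = c.members - set(model.node_ids)
            if unknown:
                raise ModelError(f"priority class references unknown nodes {unknown}")
            overlap = covered & c.members
            if overlap:
                raise ModelError(f"nodes {overlap} appear in several priority classes")
            covered |= c.members
        missing = set(model.node_ids) - covered
        if missing:
            raise ModelError(f"priority classes do not cover nodes {missing}")


# --------------------------------------------------------------------------
# Perturbations


@dataclass(frozen=True)
class Perturbation:
    """Level clamps: each entry drives a node's target into ``[low, high]``.

    A knock-down is the clamp ``[0, 0]``; an ectopic expression clamps
    to the maximal level (or any range above zero).
    """

    clamps: tuple[tuple[str, int, int], ...]

    def __init__(self, clamps: Iterable[tuple[str, int, int]]):
        object.__setattr__(self, "clamps", tuple(clamps))
        seen = set()
        for node, low, high in self.clamps:
            if not 0 <= low <= high:
                raise ModelError(f"invalid clamp [{low}, {high}] on {node!r}")
            if node in seen:
                raise ModelError(f"several clamps on node {node!r}")
            seen.add(node)

    @classmethod
    def knockdown(cls, node: str) -> "Perturbation":
        return cls([(node, 0, 0)])

    @classmethod
    def ectopic(cls, node: str, level: int) -> "Perturbation":
        return cls([(node, level, level)])

    def describe(self) -> str:
        return ", ".join(f"{g}@[{lo},{hi}]" for g, lo, hi in self.clamps)


class PerturbedModel(LogicalModel):
    """A model whose target levels are clamped node-wise.

    Shares structure with the original; only :meth:`target_level` (and
    hence everything derived from it) differs.
    """

    def __init__(self, base: LogicalModel, perturbation: Perturbation):
        super().__init__(base.nodes, base.interactions, base.rules, base.comments)
        self.base = base
        self.perturbation = perturbation
        self._clamp: dict[str, tuple[int, int]] = {}
        for node, low, high in perturbation.clamps:
            spec = self.node(node)  # raises on unknown node
            if high > spec.max_level:
                raise ModelError(
                    f"clamp [{low}, {high}] on {node!r} exceeds max level "
                    f"{spec.max_level}"
                )
            self._clamp[node] = (low, high)

    def target_level(self, state: State, node_id: str) -> int:
        target = super().target_level(state, node_id)
        if node_id in self._clamp:
            low, high = self._clamp[node_id]
            target = min(max(target, low), high)
        return target


def apply_perturbation(model: LogicalModel, p: Perturbation) -> LogicalModel:
    """Return the perturbed model (the original is untouched)."""
    if isinstance(model, PerturbedModel):
        # compose: later clamps may not re-clamp the same node
        merged = Perturbation(model.perturbation.clamps + p.clamps)
        return PerturbedModel(model.base, merged)
    return PerturbedModel(model, p)


# --------------------------------------------------------------------------
# Initial patterns


@dataclass(frozen=True)
class InitialPattern:
    """A state pattern: fixed level per node, or ``None`` for a wildcard."""

    entries: tuple[int | None, ...]

    def __init__(self, entries: Iterable[int | None]):
        object.__setattr__(self, "entries", tuple(entries))

    @classmethod
    def from_string(cls, pattern: str) -> "InitialPattern":
        """Parse a digit/star string such as ``'0*1*'``."""
        return cls(None if c == "*" else int(c) for c in pattern)

    @classmethod
    def from_levels(
        cls, model: LogicalModel, levels: Mapping[str, int]
    ) -> "InitialPattern":
        entries: list[int | None] = [None] * len(model.nodes)
        for g, v in levels.items():
            entries[model.index(g)] = v
        return cls(entries)

    def expand(self, model: LogicalModel) -> Iterator[State]:
        if len(self.entries) != len(model.nodes):
            raise ModelError(
                f"pattern has {len(self.entries)} entries for "
                f"{len(model.nodes)} nodes"
            )
        ranges = []
        for entry, spec in zip(self.entries, model.nodes):
            if entry is None:
                ranges.append(range(spec.max_level + 1))
            else:
                if not 0 <= entry <= spec.max_level:
                    raise ModelError(
                        f"pattern level {entry} out of range for {spec.id!r}"
                    )
                ranges.append(range(entry, entry + 1))
        for levels in itertools.product(*ranges):
            yield State(levels)

    def __str__(self) -> str:
        return "".join("*" if e is None else str(e) for e in self.entries)


# --------------------------------------------------------------------------
# Successor computation


def _step(state: State, model: LogicalModel, calls: Iterable[tuple[str, int]]) -> State:
    levels = list(state.levels)
    for g, d in calls:
        levels[model.index(g)] += d
    return State(levels)


def _ordered_calls(
    model: LogicalModel, calls: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    return sorted(calls, key=lambda c: model.index(c[0]))


def successors(
    model: LogicalModel, state: State, scheme: UpdatingScheme
) -> list[State]:
    """Successor states of ``state`` under ``scheme``, in deterministic
    order (node order, then subset order).  Stable states have none."""
    scheme.check(model)
    mode = scheme.mode

    if mode == "sequential":
        current = state
        for i, spec in enumerate(model.nodes):
            target = model.target_level(current, spec.id)
            if target > current[i]:
                current = current.replace(i, current[i] + 1)
            elif target < current[i]:
                current = current.replace(i, current[i] - 1)
        return [current] if current != state else []

    calls = _ordered_calls(model, model.called_nodes(state))
    if not calls:
        return []

    if mode == "asynchronous":
        return [_step(state, model, [c]) for c in calls]
    if mode == "synchronous":
        return [_step(state, model, calls)]
    if mode == "complete":
        out = []
        for r in range(1, len(calls) + 1):
            for subset in itertools.combinations(calls, r):
                out.append(_step(state, model, subset))
        return out

    # priority
    by_class = [
        (c, [call for call in calls if call[0] in c.members]) for c in scheme.classes
    ]
    active = [(c, cc) for c, cc in by_class if cc]
    top_rank = min(c.rank for c, _ in active)
    out = []
    for c, class_calls in active:
        if c.rank != top_rank:
            continue
        if c.mode == "synchronous":
            out.append(_step(state, model, class_calls))
        else:
            out.extend(_step(state, model, [call]) for call in class_calls)
    # deduplicate while preserving order (classes may collide)
    seen: set[State] = set()
    unique = []
    for s in out:
        if s not in seen:
            seen.add(s)
            unique.append(s)
    return unique


# --------------------------------------------------------------------------
# Transition graphs


@dataclass
class TransitionGraph:
    """States and transitions of a model under one updating scheme.

    Thin wrapper around a :class:`networkx.DiGraph` whose nodes are
    :class:`~mvlogic.model.State` objects, carrying provenance.
    """

    model: LogicalModel
    scheme: UpdatingScheme
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    initial: tuple[InitialPattern, ...] | None = None

    def states(self) -> list[State]:
        return sorted(self.graph.nodes)

    def transitions(self) -> list[tuple[State, State]]:
        return sorted(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, state: State) -> bool:
        return state in self.graph

    def out_degree(self, state: State) -> int:
        return self.graph.out_degree(state)

    def successors(self, state: State) -> list[State]:
        return sorted(self.graph.successors(state))

    def stable_states(self) -> list[State]:
        """States with no outgoing transition."""
        return sorted(s for s in self.graph.nodes if self.graph.out_degree(s) == 0)

    def predecessors_of(self, states: Iterable[State]) -> set[State]:
        """All states from which some state in ``states`` is reachable
        (including the given states themselves)."""
        targets = set(states)
        reversed_view = self.graph.reverse(copy=False)
        reached = set(targets)
        for s in targets:
            reached |= nx.descendants(reversed_view, s)
        return reached


def build_stg(
    model: LogicalModel,
    scheme: UpdatingScheme | None = None,
    initial: Sequence[InitialPattern] | None = None,
    perturbation: Perturbation | None = None,
    max_states: int = MAX_STATES_DEFAULT,
) -> TransitionGraph:
    """Build the state transition graph.

    Without ``initial`` the full product state space is enumerated; with
    initial patterns, only the states reachable from their expansion
    (plus the traversed transitions) are kept.
    """
    scheme = scheme or UpdatingScheme.asynchronous()
    if perturbation is not None:
        model = apply_perturbation(model, perturbation)
    scheme.check(model)

    graph = nx.DiGraph()
    if initial is None:
        if model.state_count() > max_states:
            raise CapExceededError(
                f"full state space has {model.state_count()} states, "
                f"above the cap of {max_states}"
            )
        for state in model.states():
            graph.add_node(state)
            for succ in successors(model, state, scheme):
                graph.add_edge(state, succ)
    else:
        frontier: list[State] = []
        for pattern in initial:
            for state in pattern.expand(model):
                if state not in graph:
                    graph.add_node(state)
                    frontier.append(state)
        while frontier:
            state = frontier.pop()
            for succ in successors(model, state, scheme):
                if succ not in graph:
                    if graph.number_of_nodes() >= max_states:
                        raise CapExceededError(
                            f"reached the cap of {max_states} states"
                        )
                    graph.add_node(succ)
                    frontier.append(succ)
                graph.add_edge(state, succ)

    return TransitionGraph(
        model=model,
        scheme=scheme,
        graph=graph,
        initial=tuple(initial) if initial is not None else None,
    )
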