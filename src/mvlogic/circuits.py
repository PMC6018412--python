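"""Regulatory circuit enumeration, signs and functionality analysis.

A regulatory circuit is a simple closed directed path of interactions.
Its sign is the product of its interaction signs: positive with an even
number of inhibitions, negative otherwise.  Positive circuits are
necessary for multistationarity, negative ones for sustained
oscillations; whether a circuit actually generates its characteristic
dynamics depends on the levels of its external regulators — the
*functionality context*.

Functionality is assessed window-wise: choosing one threshold per
circuit arc confines each circuit node to the two levels around its
outgoing threshold, and a context (levels of the external regulators)
is admissible when every circuit interaction then switches its
target's rule, for every placement of the remaining circuit nodes
inside their windows.  A circuit is functional iff some threshold
choice admits a non-empty context.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .model import Interaction, LogicalModel, State

__all__ = [
    "Circuit",
    "FunctionalityContext",
    "InteractionReport",
    "enumerate_circuits",
    "circuit_sign",
    "functionality_context",
    "interaction_functionality",
]


@dataclass(frozen=True)
class Circuit:
    """A simple directed cycle of regulatory arcs.

    ``arcs`` are (source, target) pairs in cyclic order, canonically
    rotated to start at the smallest node id.  ``arc_signs`` are the
    per-arc signs ('+', '-', 'dual' or '?'), where an arc bundling
    several interactions of differing signs counts as dual.
    """

    arcs: tuple[tuple[str, str], ...]
    arc_signs: tuple[str, ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(src for src, _ in self.arcs)

    def __len__(self) -> int:
        return len(self.arcs)

    def __str__(self) -> str:
        return " -> ".join(self.nodes + (self.nodes[0],))


@dataclass(frozen=True)
class FunctionalityContext:
    """Admissible levels of a circuit's external regulators.

    ``externals`` lists the external regulator ids (in model node
    order); ``assignments`` the admissible level combinations.  An
    empty set of assignments means the circuit is non-functional.  A
    circuit without external regulators is functional in the single,
    empty context.
    """

    externals: tuple[str, ...]
    assignments: frozenset[tuple[int, ...]]

    @property
    def empty(self) -> bool:
        return not self.assignments

    def clauses(self) -> list[dict[str, tuple[int, int]]]:
        """Context as per-node level intervals.

        When the assignment set is a product of per-node level ranges a
        single clause is returned; otherwise one clause per assignment.
        Unconstrained externals are omitted from clauses.
        """
        if not self.assignments:
            return []
        if not self.externals:
            return [{}]
        per_node = [sorted({a[i] for a in self.assignments}) for i in
                    range(len(self.externals))]
        product = set(itertools.product(*per_node))
        contiguous = all(vs == list(range(vs[0], vs[-1] + 1)) for vs in per_node)
        if contiguous and product == set(self.assignments):
            return [
                {
                    g: (vs[0], vs[-1])
                    for g, vs in zip(self.externals, per_node)
                }
            ]
        return [
            {g: (v, v) for g, v in zip(self.externals, a)}
            for a in sorted(self.assignments)
        ]

    def describe(self, model: LogicalModel) -> str:
        if self.empty:
            return "non-functional (empty context)"
        parts = []
        for clause in self.clauses():
            constrained = []
            for g, (lo, hi) in clause.items():
                if (lo, hi) == (0, model.node(g).max_level):
                    continue  # unconstrained
                constrained.append(
                    f"{g}={lo}" if lo == hi else f"{g} in [{lo},{hi}]"
                )
            parts.append(" & ".join(constrained) if constrained else "any level")
        return " | ".join(parts) if parts else "functional in every context"


@dataclass(frozen=True)
class InteractionReport:
    """Observed effect of one declared interaction on its target's rule."""

    interaction: Interaction
    observed: str | None  # '+', '-', 'dual', or None when never effective
    status: str  # 'consistent', 'inconsistent' or 'non-functional'

    def __str__(self) -> str:
        it = self.interaction
        obs = self.observed or "none"
        return (
            f"{it.source} -> {it.target} (t={it.threshold}, declared "
            f"{it.sign}): observed {obs} -> {self.status}"
        )


# --------------------------------------------------------------------------
# Enumeration and signs


def _arc_sign(model: LogicalModel, source: str, target: str) -> str:
    signs = {it.sign for it in model.interactions
             if (it.source, it.target) == (source, target)}
    if signs == {"+"}:
        return "+"
    if signs == {"-"}:
        return "-"
    if "?" in signs and len(signs) == 1:
        return "?"
    return "dual"


def _canonical(cycle: list[str]) -> tuple[str, ...]:
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def enumerate_circuits(
    model: LogicalModel,
    max_length: int | None = None,
    include: set[str] | None = None,
    exclude: set[str] | None = None,
) -> list[Circuit]:
    """All simple directed cycles of the regulatory graph, at arc level
    (thresholds are not distinguished), deduplicated up to rotation."""
    digraph = nx.DiGraph()
    digraph.add_nodes_from(model.node_ids)
    for it in model.interactions:
        digraph.add_edge(it.source, it.target)
    if exclude:
        digraph.remove_nodes_from(exclude)

    circuits = []
    for cycle in nx.simple_cycles(digraph):
        if max_length is not None and len(cycle) > max_length:
            continue
        if include and not include.issubset(cycle):
            continue
        nodes = _canonical(cycle)
        arcs = tuple(
            (nodes[i], nodes[(i + 1) % len(nodes)]) for i in range(len(nodes))
        )
        signs = tuple(_arc_sign(model, s, t) for s, t in arcs)
        circuits.append(Circuit(arcs, signs))
    return sorted(circuits, key=lambda c: (len(c), c.nodes))


def circuit_sign(circuit: Circuit) -> str | None:
    """'+' or '-' by sign parity; None when a member arc is dual or
    unsigned, leaving the circuit sign undetermined."""
    if any(s not in ("+", "-") for s in circuit.arc_signs):
        return None
    negatives = sum(1 for s in circuit.arc_signs if s == "-")
    return "+" if negatives % 2 == 0 else "-"


# --------------------------------------------------------------------------
# Functionality

def functionality_context(
    model: LogicalModel, circuit: Circuit
) -> tuple[FunctionalityContext, dict[tuple[str, str], int] | None]:
    """Functionality context of a circuit and a witness threshold choice.

    Returns the union of admissible contexts over all per-arc threshold
    assignments, together with the assignment admitting the most
    contexts (None when the circuit is non-functional).
    """
    circuit_nodes = set(circuit.nodes)
    out_arc = {src: (src, tgt) for src, tgt in circuit.arcs}

    externals = tuple(
        g
        for g in model.node_ids
        if g not in circuit_nodes
        and any(g in model.regulators(tgt) for _, tgt in circuit.arcs)
    )
    ext_ranges = [range(model.node(g).max_level + 1) for g in externals]
    all_contexts = list(itertools.product(*ext_ranges))

    threshold_options = [
        model.arc_thresholds(src, tgt) for src, tgt in circuit.arcs
    ]
    admissible: set[tuple[int, ...]] = set()
    best_choice: dict[tuple[str, str], int] | None = None
    best_count = 0
    for thresholds in itertools.product(*threshold_options):
        window = {
            src: (thresholds[i] - 1, thresholds[i])
            for i, (src, _) in enumerate(circuit.arcs)
        }
        found = {
            ctx
            for ctx in all_contexts
            if _context_admissible(model, circuit, thresholds, window, externals, ctx)
        }
        admissible |= found
        if len(found) > best_count:
            best_count = len(found)
            best_choice = {
                arc: th for arc, th in zip(circuit.arcs, thresholds)
            }
    return (
        FunctionalityContext(externals, frozenset(admissible)),
        best_choice,
    )


def _context_admissible(
    model: LogicalModel,
    circuit: Circuit,
    thresholds: tuple[int, ...],
    window: dict[str, tuple[int, int]],
    externals: tuple[str, ...],
    context: tuple[int, ...],
) -> bool:
    base = [0] * len(model.nodes)
    for g, v in zip(externals, context):
        base[model.index(g)] = v

    for i, (src, tgt) in enumerate(circuit.arcs):
        theta = thresholds[i]
        others = [g for g in circuit.nodes if g != src]
        placements = itertools.product(*(window[g] for g in others))
        for placement in placements:
            levels = list(base)
            for g, v in zip(others, placement):
                levels[model.index(g)] = v
            levels[model.index(src)] = theta - 1
            below = model.target_level(State(levels), tgt)
            levels[model.index(src)] = theta
            above = model.target_level(State(levels), tgt)
            if below == above:
                return False
    return True


# --------------------------------------------------------------------------
# Declared-sign consistency


def interaction_functionality(model: LogicalModel) -> list[InteractionReport]:
    """Check every declared interaction against the target's rules.

    For interaction s -> g at threshold t, the observed effect is the
    sign of the change of g's target level as s steps from t-1 to t,
    over all level combinations of g's other regulators.
    """
    reports = []
    for it in model.interactions:
        others = [r for r in model.regulators(it.target) if r != it.source]
        deltas: set[int] = set()
        ranges = [range(model.node(r).max_level + 1) for r in others]
        for combo in itertools.product(*ranges):
            levels = [0] * len(model.nodes)
            for r, v in zip(others, combo):
                levels[model.index(r)] = v
            levels[model.index(it.source)] = it.threshold - 1
            below = model.target_level(State(levels), it.target)
            levels[model.index(it.source)] = it.threshold
            above = model.target_level(State(levels), it.target)
            if above != below:
                deltas.add(1 if above > below else -1)

        if not deltas:
            observed = None
            status = "non-functional"
        else:
            observed = (
                "dual" if deltas == {1, -1} else ("+" if 1 in deltas else "-")
            )
            if it.sign == "?" or it.sign == observed or it.sign == "dual":
                status = "consistent"
            else:
                status = "inconsistent"
        reports.append(InteractionReport(it, observed, status))
    return reports
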