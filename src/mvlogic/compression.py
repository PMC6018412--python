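"""Compression of state transition graphs.

Two acyclic compressions of an STG are provided.  The *SCC quotient*
lumps every strongly connected component into one node and preserves
reachability between components.  The *hierarchical transition graph*
(HTG) starts from the SCC quotient and additionally absorbs linear
chains of transient states into single nodes; it preserves the
attractors (terminal components) exactly, but not all reachability
relations.

Attractors are the terminal strongly connected components of the STG:
singletons are stable states, larger ones cyclic attractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .dynamics import TransitionGraph
from .model import LogicalModel, State

__all__ = [
    "HierarchicalNode",
    "HierarchicalGraph",
    "scc_quotient",
    "attractors",
    "build_htg",
    "states_to_patterns",
]


# --------------------------------------------------------------------------
# SCC quotient and attractors


def scc_quotient(stg: TransitionGraph) -> nx.DiGraph:
    """Quotient of the STG by strongly connected components.

    Nodes of the result are frozensets of member states; the graph is
    acyclic and preserves reachability between components.
    """
    quotient = nx.DiGraph()
    comp_of: dict[State, frozenset[State]] = {}
    for comp in nx.strongly_connected_components(stg.graph):
        members = frozenset(comp)
        quotient.add_node(members)
        for s in members:
            comp_of[s] = members
    for a, b in stg.graph.edges:
        ca, cb = comp_of[a], comp_of[b]
        if ca is not cb:
            quotient.add_edge(ca, cb)
    return quotient


def attractors(stg: TransitionGraph) -> list[tuple[str, frozenset[State]]]:
    """Terminal SCCs of the STG as ``(kind, member states)`` pairs,
    with kind ``'stable'`` for singletons and ``'cyclic'`` otherwise."""
    quotient = scc_quotient(stg)
    out = []
    for members in quotient.nodes:
        if quotient.out_degree(members) == 0:
            kind = "stable" if len(members) == 1 else "cyclic"
            out.append((kind, members))
    return sorted(out, key=lambda kv: min(kv[1]))


# --------------------------------------------------------------------------
# Hierarchical transition graph


@dataclass(frozen=True)
class HierarchicalNode:
    """One class of states of the hierarchical transition graph.

    ``kind`` is one of ``stable``, ``cyclic_attractor``,
    ``cyclic_transient`` or ``transient_chain``.  Labels follow the
    convention: the state code for stable states, ``ca#N`` / ``ct#N``
    for cyclic (attractor / transient) components of N states, ``i#N``
    for merged transient chains.
    """

    kind: str
    members: frozenset[State]
    label: str

    def patterns(self, model: LogicalModel) -> list[str]:
        return states_to_patterns(model, self.members)


@dataclass
class HierarchicalGraph:
    """Acyclic graph of hierarchical nodes; members partition the STG."""

    model: LogicalModel
    nodes: list[HierarchicalNode]
    edges: list[tuple[HierarchicalNode, HierarchicalNode]]

    def __len__(self) -> int:
        return len(self.nodes)

    def by_kind(self, kind: str) -> list[HierarchicalNode]:
        return [n for n in self.nodes if n.kind == kind]

    def terminal_nodes(self) -> list[HierarchicalNode]:
        with_out = {a for a, _ in self.edges}
        return [n for n in self.nodes if n not in with_out]

    def node_of(self, state: State) -> HierarchicalNode:
        for node in self.nodes:
            if state in node.members:
                return node
        raise KeyError(state)


def build_htg(stg: TransitionGraph) -> HierarchicalGraph:
    """Build the hierarchical transition graph of an STG.

    Starting from the SCC quotient, the *anchor* classes — cyclic
    components and stable states — are kept as they are, while the
    remaining transient singleton classes are grouped by their
    downstream behavior: two transient states land in the same
    hierarchical node exactly when the sets of anchors reachable from
    them coincide.  A linear chain of states running into a stable
    state thus collapses into a single node, and more generally the
    transient part of the dynamics is stratified by which cyclic
    components and attractors remain reachable.  The result is acyclic
    (along any transition the reachable-anchor set can only shrink, and
    classes where it is equal are merged) and preserves the attractors
    exactly.
    """
    quotient = scc_quotient(stg)
    anchors = {
        c for c in quotient.nodes if len(c) > 1 or quotient.out_degree(c) == 0
    }

    signature: dict[frozenset[State], frozenset] = {}
    for c in reversed(list(nx.topological_sort(quotient))):
        sig = frozenset().union(
            *(signature[s] for s in quotient.successors(c))
        ) if quotient.out_degree(c) else frozenset()
        if c in anchors:
            sig |= {c}
        signature[c] = sig

    groups: dict[frozenset, set[frozenset[State]]] = {}
    for c in quotient.nodes:
        if c not in anchors:
            groups.setdefault(signature[c], set()).add(c)

    # hierarchical node membership: anchors stay, transient groups fuse
    member_sets: list[frozenset[State]] = [frozenset(a) for a in anchors]
    fused: dict[frozenset[State], frozenset[State]] = {a: a for a in anchors}
    for classes in groups.values():
        merged = frozenset().union(*classes)
        member_sets.append(merged)
        for c in classes:
            fused[c] = merged

    terminal = {c for c in quotient.nodes if quotient.out_degree(c) == 0}
    nodes: list[HierarchicalNode] = []
    for members in sorted(member_sets, key=min):
        if members in anchors and len(members) > 1:
            kind = (
                "cyclic_attractor" if members in terminal else "cyclic_transient"
            )
            label = ("ca#" if members in terminal else "ct#") + str(len(members))
        elif members in anchors:
            kind = "stable"
            label = next(iter(members)).code()
        else:
            kind = "transient_chain"
            label = f"i#{len(members)}"
        nodes.append(HierarchicalNode(kind, members, label))

    # disambiguate duplicate labels deterministically
    seen: dict[str, int] = {}
    final_nodes = []
    for node in nodes:
        count = seen.get(node.label, 0)
        seen[node.label] = count + 1
        if count:
            node = HierarchicalNode(node.kind, node.members, f"{node.label}.{count}")
        final_nodes.append(node)
    node_for = {n.members: n for n in final_nodes}

    edge_set = {
        (node_for[fused[a]], node_for[fused[b]])
        for a, b in quotient.edges
        if fused[a] is not fused[b]
    }
    edges = sorted(
        edge_set, key=lambda ab: (min(ab[0].members), min(ab[1].members))
    )
    return HierarchicalGraph(stg.model, final_nodes, edges)


# --------------------------------------------------------------------------
# Wildcard pattern rendering


def states_to_patterns(model: LogicalModel, states: frozenset[State]) -> list[str]:
    """Render a state set as digit/star patterns covering it exactly.

    Greedy: repeatedly pick the pattern obtained by freeing maximal
    subsets of coordinates around a remaining state, provided all
    covered states belong to the set.
    """
    remaining = set(states)
    patterns: list[str] = []
    while remaining:
        seed = min(remaining)
        best = tuple(seed.levels)
        # grow wildcards greedily, in node order
        entries: list[int | None] = list(seed.levels)
        for i, spec in enumerate(model.nodes):
            trial = list(entries)
            trial[i] = None
            if _covered(model, trial, states):
                entries = trial
        covered = set(_expand(model, entries))
        patterns.append("".join("*" if e is None else str(e) for e in entries))
        remaining -= covered
    return sorted(patterns)


def _expand(model: LogicalModel, entries: list[int | None]) -> list[State]:
    import itertools

    ranges = [
        range(spec.max_level + 1) if e is None else range(e, e + 1)
        for e, spec in zip(entries, model.nodes)
    ]
    return [State(levels) for levels in itertools.product(*ranges)]


def _covered(
    model: LogicalModel, entries: list[int | None], states: frozenset[State]
) -> bool:
    return all(s in states for s in _expand(model, entries))
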