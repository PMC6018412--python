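"""Model reduction by node elimination.

Eliminating a node rewrites the rules of its targets so that the
removed regulator's level is replaced by its own target-level function:
the indirect effects of the removed node's regulators are absorbed into
its targets.  The rewritten functions are re-expressed as ordinary
rules and signed threshold interactions by exact synthesis.

The construction preserves the stable states exactly (they project
one-to-one onto the kept nodes) and, more generally, the attractors of
the asynchronous dynamics.  A node may not be eliminated while it is
self-regulated (its own function would have to be substituted into
itself); input nodes maintain their own level and are self-regulated in
this sense.
"""

from __future__ import annotations

from typing import Sequence

from .model import LogicalModel, ModelError, State
from .synthesis import TabulatedFunction, derive_interactions, synthesize_rules

__all__ = ["reduce_model", "SelfRegulationError"]


class SelfRegulationError(ModelError):
    """Raised when eliminating a self-regulated (or input) node."""


def reduce_model(model: LogicalModel, remove: Sequence[str]) -> LogicalModel:
    """Eliminate the given nodes, sequentially in the given order."""
    for node_id in remove:
        model = _eliminate(model, node_id)
    return model


def _tabulate_node(
    model: LogicalModel, node_id: str, sources: Sequence[str]
) -> TabulatedFunction:
    pairs = [(s, model.node(s).max_level) for s in sources]

    def evaluate(combo: tuple[int, ...]) -> int:
        levels = [0] * len(model.nodes)
        for s, v in zip(sources, combo):
            levels[model.index(s)] = v
        return model.target_level(State(levels), node_id)

    return TabulatedFunction.from_callable(pairs, evaluate)


def _eliminate(model: LogicalModel, node_id: str) -> LogicalModel:
    spec = model.node(node_id)  # raises on unknown node
    if spec.is_input:
        raise SelfRegulationError(
            f"input node {node_id!r} maintains its own level and cannot be "
            "eliminated"
        )
    if node_id in model.regulators(node_id):
        raise SelfRegulationError(
            f"node {node_id!r} is self-regulated and cannot be eliminated"
        )

    removed_regs = list(model.regulators(node_id))
    targets = [g for g in model.targets(node_id) if g != node_id]

    kept_nodes = [n for n in model.nodes if n.id != node_id]
    kept_ids = {n.id for n in kept_nodes}
    new_rules = {
        g: entries for g, entries in model.rules.items() if g != node_id
    }
    new_interactions = [
        it
        for it in model.interactions
        if it.source != node_id
        and it.target != node_id
        and it.target not in targets
    ]
    new_comments = {
        key: text
        for key, text in model.comments.items()
        if node_id not in key.replace("->", " ").replace(":=", " ").split()
        or key == ""
    }

    # order sources of the rewritten functions by the original node order
    for g in targets:
        sources = [
            s
            for s in model.node_ids
            if s in kept_ids
            and (s in model.regulators(g) or s in removed_regs)
        ]

        def evaluate(combo: tuple[int, ...], g=g, sources=sources) -> int:
            levels = [0] * len(model.nodes)
            for s, v in zip(sources, combo):
                levels[model.index(s)] = v
            # substitute the removed node's own target-level function
            levels[model.index(node_id)] = model.target_level(
                State(levels), node_id
            )
            return model.target_level(State(levels), g)

        func = TabulatedFunction.from_callable(
            [(s, model.node(s).max_level) for s in sources], evaluate
        )
        derived = derive_interactions(func, g)
        new_interactions.extend(derived)
        new_rules[g] = tuple(synthesize_rules(func, g, derived))

    # keep the original arc ordering style: sort by (source, target, t)
    order = {n.id: i for i, n in enumerate(kept_nodes)}
    new_interactions.sort(
        key=lambda it: (order[it.source], order[it.target], it.threshold)
    )
    return LogicalModel(kept_nodes, new_interactions, new_rules, new_comments)
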