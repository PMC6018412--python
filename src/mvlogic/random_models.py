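"""Reproducible random logical models, for property testing.

Models are drawn structure-first: node maximal levels, then arcs with
the requested density (self-loops included at half density), then one
threshold set per arc.  Rules are drawn as a random target level per
combination of regulator activity windows, which makes the rule entries
of a node mutually exclusive by construction, and every literal
resolvable; interaction signs are derived from the drawn function, so
generated models always validate cleanly.
"""

from __future__ import annotations

import itertools
import random

from .model import LogicalModel, NodeSpec
from .synthesis import TabulatedFunction, derive_interactions, synthesize_rules

__all__ = ["random_model"]


def random_model(
    n_nodes: int,
    max_level_cap: int = 2,
    density: float = 0.3,
    seed: int = 0,
) -> LogicalModel:
    """Draw a random valid logical model.

    Parameters
    ----------
    n_nodes:
        Number of components (ids ``g0 .. g{n-1}``).
    max_level_cap:
        Maximal levels are drawn uniformly in ``[1, max_level_cap]``.
    density:
        Probability of an arc between an ordered pair of distinct
        nodes; self-loops appear with half this probability.
    seed:
        Same seed, same model.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if max_level_cap < 1:
        raise ValueError("max_level_cap must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = random.Random(seed)

    nodes = [
        NodeSpec(f"g{i}", rng.randint(1, max_level_cap)) for i in range(n_nodes)
    ]
    by_id = {n.id: n for n in nodes}

    arcs: dict[tuple[str, str], list[int]] = {}
    for src in nodes:
        for tgt in nodes:
            p = density / 2 if src.id == tgt.id else density
            if rng.random() < p:
                n_th = 1 + sum(
                    rng.random() < 0.3 for _ in range(src.max_level - 1)
                )
                arcs[(src.id, tgt.id)] = sorted(
                    rng.sample(range(1, src.max_level + 1), n_th)
                )

    interactions = []
    rules = {}
    for tgt in nodes:
        regulators = [n.id for n in nodes if (n.id, tgt.id) in arcs]
        if not regulators:
            continue
        # one random target level per combination of activity windows
        windows: dict[str, list[int]] = {}
        for src in regulators:
            ths = arcs[(src, tgt.id)]
            bounds = [0, *ths, by_id[src].max_level + 1]
            windows[src] = [bounds[i] for i in range(len(bounds) - 1)]

        choice: dict[tuple[int, ...], int] = {}
        for reps in itertools.product(*(windows[s] for s in regulators)):
            choice[reps] = rng.randint(0, tgt.max_level)

        def evaluate(combo: tuple[int, ...], tgt=tgt, regulators=regulators,
                     windows=windows) -> int:
            reps = []
            for src, level in zip(regulators, combo):
                starts = windows[src]
                rep = max(s for s in starts if s <= level)
                reps.append(rep)
            return choice[tuple(reps)]

        func = TabulatedFunction.from_callable(
            [(s, by_id[s].max_level) for s in regulators], evaluate
        )
        derived = derive_interactions(func, tgt.id)
        effective = {(it.source, it.threshold) for it in derived}
        # declare every drawn arc; thresholds without observable effect
        # keep sign '?' so that validation and sign checks stay clean
        for src in regulators:
            for th in arcs[(src, tgt.id)]:
                match = [
                    it for it in derived
                    if (it.source, it.threshold) == (src, th)
                ]
                interactions.append(
                    match[0] if match else
                    _unknown_interaction(src, tgt.id, th)
                )
        del effective
        entries = synthesize_rules(
            func,
            tgt.id,
            [it for it in interactions
             if it.target == tgt.id],
        )
        if entries:
            rules[tgt.id] = entries

    model = LogicalModel(nodes, interactions, rules)
    report = model.validate()
    assert report.ok, f"generator produced an invalid model:\n{report}"
    return model


def _unknown_interaction(src: str, tgt: str, threshold: int):
    from .model import Interaction

    return Interaction(src, tgt, threshold, "?")
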