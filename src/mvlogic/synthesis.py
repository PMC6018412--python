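"""Synthesis of interactions and rule formulas from tabulated functions.

Used by model reduction (rewritten target-level functions must be
re-expressed as ordinary rules and signed threshold interactions) and
by the random-model generator (functions drawn per window combination
are turned into formulas).

A *tabulated function* maps level combinations of an ordered list of
candidate regulators to a target level.  Thresholds are recovered as
the level crossings where the function changes for some context; the
function is then constant on each activity window, which makes exact
formula synthesis over window literals possible.  Terms are merged
greedily (a regulator whose every window class appears with otherwise
identical terms is dropped), yielding compact disjunctive normal forms.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Sequence

from .model import And, Const, Formula, Interaction, Literal, Not, RuleEntry

__all__ = ["TabulatedFunction", "derive_interactions", "synthesize_rules"]


class TabulatedFunction:
    """A target-level function tabulated over candidate regulators.

    Parameters
    ----------
    sources:
        Ordered (id, max_level) pairs of candidate regulators.
    table:
        Mapping from level tuples (one level per source, full product
        domain) to the target level.
    """

    def __init__(
        self,
        sources: Sequence[tuple[str, int]],
        table: Mapping[tuple[int, ...], int],
    ):
        self.sources = tuple(sources)
        self.table = dict(table)
        expected = 1
        for _, mx in self.sources:
            expected *= mx + 1
        if len(self.table) != expected:
            raise ValueError(
                f"table has {len(self.table)} entries, expected {expected}"
            )

    @classmethod
    def from_callable(
        cls,
        sources: Sequence[tuple[str, int]],
        func: Callable[[tuple[int, ...]], int],
    ) -> "TabulatedFunction":
        ranges = [range(mx + 1) for _, mx in sources]
        return cls(
            sources, {combo: func(combo) for combo in itertools.product(*ranges)}
        )

    def __call__(self, combo: tuple[int, ...]) -> int:
        return self.table[combo]


def derive_interactions(
    func: TabulatedFunction, target: str
) -> list[Interaction]:
    """Effective interactions of a tabulated function.

    A threshold t of source s is effective when the function changes as
    s steps from t-1 to t in some context of the other sources; the
    sign is '+', '-' or 'dual' according to the observed changes.
    """
    interactions = []
    for i, (source, max_level) in enumerate(func.sources):
        other_ranges = [
            range(mx + 1) for j, (_, mx) in enumerate(func.sources) if j != i
        ]
        for theta in range(1, max_level + 1):
            deltas: set[int] = set()
            for others in itertools.product(*other_ranges):
                combo_lo = list(others)
                combo_lo.insert(i, theta - 1)
                combo_hi = list(others)
                combo_hi.insert(i, theta)
                lo = func(tuple(combo_lo))
                hi = func(tuple(combo_hi))
                if lo != hi:
                    deltas.add(1 if hi > lo else -1)
            if deltas:
                sign = "dual" if deltas == {1, -1} else ("+" if 1 in deltas else "-")
                interactions.append(Interaction(source, target, theta, sign))
    return interactions


def _window_classes(max_level: int, thresholds: Sequence[int]) -> list[range]:
    """Partition of [0, max] into the below-zone and activity windows."""
    bounds = [0, *thresholds, max_level + 1]
    return [range(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def synthesize_rules(
    func: TabulatedFunction,
    target: str,
    interactions: Sequence[Interaction] | None = None,
) -> list[RuleEntry]:
    """Exact rule entries reproducing a tabulated function.

    ``interactions`` defaults to :func:`derive_interactions`; their
    thresholds define the window literals available to the formulas.
    The function must be constant on every window combination (always
    true when the interactions are the derived ones).
    """
    if interactions is None:
        interactions = derive_interactions(func, target)
    thresholds: dict[str, list[int]] = {s: [] for s, _ in func.sources}
    for it in interactions:
        thresholds[it.source].append(it.threshold)
    for ths in thresholds.values():
        ths.sort()

    classes = [
        _window_classes(mx, thresholds[s]) for s, mx in func.sources
    ]
    # terms by value: tuple of per-source class index (None = free)
    by_value: dict[int, list[tuple[int | None, ...]]] = {}
    for combo_classes in itertools.product(*(range(len(c)) for c in classes)):
        representative = tuple(
            classes[i][ci][0] for i, ci in enumerate(combo_classes)
        )
        value = func(representative)
        _check_constant(func, classes, combo_classes, value)
        if value >= 1:
            by_value.setdefault(value, []).append(combo_classes)

    entries = []
    for value in sorted(by_value):
        terms = _merge_terms(by_value[value], [len(c) for c in classes])
        formulas = [
            _term_formula(term, thresholds, func.sources) for term in terms
        ]
        entries.append(RuleEntry(value, formulas))
    return entries


def _check_constant(func, classes, combo_classes, value) -> None:
    for combo in itertools.product(
        *(classes[i][ci] for i, ci in enumerate(combo_classes))
    ):
        if func(combo) != value:
            raise ValueError(
                "function is not constant on a window combination; "
                "thresholds do not match the function"
            )


def _merge_terms(
    terms: list[tuple[int | None, ...]], n_classes: list[int]
) -> list[tuple[int | None, ...]]:
    """Greedy cube merging: free a coordinate whenever all its classes
    occur with otherwise identical terms."""
    current = set(terms)
    changed = True
    while changed:
        changed = False
        for i, n in enumerate(n_classes):
            if n <= 1:
                continue
            groups: dict[tuple, set[int | None]] = {}
            for term in current:
                key = term[:i] + term[i + 1:]
                groups.setdefault(key, set()).add(term[i])
            for key, vals in groups.items():
                if None in vals:
                    continue
                if vals == set(range(n)):
                    for v in vals:
                        current.discard(key[:i] + (v,) + key[i:])
                    current.add(key[:i] + (None,) + key[i:])
                    changed = True
    return sorted(current, key=lambda t: tuple(-1 if x is None else x for x in t))


def _term_formula(
    term: tuple[int | None, ...],
    thresholds: dict[str, list[int]],
    sources: Sequence[tuple[str, int]],
) -> Formula:
    literals: list[Formula] = []
    for (source, _), cls in zip(sources, term):
        if cls is None:
            continue
        ths = thresholds[source]
        if cls == 0:
            # below every threshold: outside all windows
            literals.extend(
                Not(_literal(source, t, ths)) for t in ths
            )
        else:
            literals.append(_literal(source, ths[cls - 1], ths))
    if not literals:
        # the target value holds unconditionally
        return Const(True)
    return literals[0] if len(literals) == 1 else And(*literals)


def _literal(source: str, threshold: int, declared: Sequence[int]) -> Literal:
    # bare literal when unambiguous, explicit threshold otherwise
    if len(declared) == 1:
        return Literal(source)
    return Literal(source, threshold)
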