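# Methods

## The formalism

A model is an ordered list of components (nodes), each with a maximal
level `max_g ≥ 1` (levels are non-negative integers; we require
`max_g ≤ 9` so that states render unambiguously as digit strings in
declared node order, e.g. `0110`).  Node order is semantic: it fixes
state codes, the sweep order of the sequential updating scheme, and all
deterministic output orderings.

Interactions carry a source, target, threshold and sign (`+`, `-`,
`dual`, `?`).  Several interactions may share a (source, target) arc at
strictly increasing thresholds; the interaction at threshold `t` is
active exactly when the source level lies in `[t, t′−1]`, where `t′` is
the next-higher threshold on the same arc, or `[t, max]` for the
highest.  Formula literals denote these *activity windows*, not `≥`
comparisons: in the p53-Mdm2 model the bare literal `p53` inside
Mdm2cyt's rule means `p53 = 2`, because the only declared p53→Mdm2cyt
interaction has threshold 2.  Negation is window complement
(`!p53` there means `p53 ≠ 2`, not `p53 = 0`).  A bare literal is an
error when its arc carries several thresholds — there is no unambiguous
reading — and must be written `source:t`.

Rules associate formulas with target values 1..max (several formulas
for one value are OR-ed).  The target level of a node in a state is the
value of its unique satisfied entry, 0 when none is satisfied (the
implicit default), and the current level for input nodes, which model
constant environmental signals.  Two simultaneously satisfied entries
raise an error carrying a witness state; validation detects such
overlaps ahead of time by exhaustive enumeration of regulator level
combinations.  We chose rejection over silent precedence because
overlapping entries almost always indicate a modeling mistake.  The
grammar also admits the constants `true`/`false`; they are needed to
express constant rules that model reduction can produce (see below).

## Updating schemes and transition graphs

In a state, every node whose target differs from its level is *called*,
always by a unit step.  Successor states per scheme:

- **asynchronous** — one successor per called node;
- **synchronous** — one successor stepping all called nodes;
- **complete** — one successor per non-empty subset of called nodes
  (both previous relations are sub-relations);
- **sequential** — one sweep over the nodes in declared order; each
  node's target is recomputed against the partially updated state, and
  each node moves at most one level per sweep.  (The alternative —
  evaluating all targets against the sweep's start state — is exactly
  the synchronous step, so the progressive reading is the one that
  makes the scheme distinct.)
- **priority classes** — nodes are partitioned into classes with an
  integer rank; numerically *smaller* rank means higher priority (rank
  0 fires first).  Only calls in the top-priority classes among those
  containing a call fire; each class applies its own inner synchronous
  or asynchronous assumption, and equal-rank classes combine
  asynchronously (no cross-class simultaneity).

`build_stg` either enumerates the full product state space (with a
default guard of 2²⁰ states, overridable, failing loudly rather than
exhausting memory) or explores forward from the expansion of initial
patterns (digit strings with `*` wildcards).  Successors are always
generated in node order, then subset order, so every output is
byte-reproducible.

Perturbations clamp a node's target level into `[lo, hi]`
(knock-down `[0,0]`, ectopic `[max,max]` or any positive range).  The
clamp applies to the *target*, so the dynamics still moves the node
stepwise into the clamped range.  Stability is scheme-independent, so
stable states, attractors and clamps compose predictably.

## Stable states

`compute_stable` performs backtracking search over node levels in
declared order, checking each node's stability constraint as soon as
its own level and those of its regulators are assigned.  On sparsely
regulated models this prunes most of the product space; it is exactly
equivalent to the brute-force definition (every node at its target),
which ships as `brute_force_stable` and serves as the normative
reference in the tests, alongside a second independent oracle — the
out-degree-0 states of the full asynchronous STG.

## Compression: SCC quotient and HTG

The SCC quotient lumps each strongly connected component of the STG
into one node; it is acyclic and preserves reachability between
components.  Attractors are the terminal components: singleton = stable
state, larger = cyclic attractor.

The hierarchical transition graph (HTG) compresses further.  We call
*anchors* the non-trivial SCCs and the stable states.  Transient
states are grouped by their *signature* — the set of anchors reachable
from them; each signature class forms one `transient_chain` node
(label `i#N`), while anchors keep their own nodes (`ct#N` cyclic
transient, `ca#N` cyclic attractor, state code for stable states).
Along any transition the signature can only shrink, and states with
equal signatures are merged, so the result is acyclic; terminal HTG
nodes are exactly the attractors, and member sets partition the STG
states.  This grouping is our operational definition of the published
HTG construction, which is specified elsewhere only by example; it
reproduces the published 6-node HTG of the p53-Mdm2 model (ct#9, ct#6,
the stable state, and transient groups of 10, 9 and 1 states), which
the test suite pins as the arbiter.  A simple single-successor chain
absorption was tried first and does not reproduce that graph.  Member
sets are rendered compactly as wildcard patterns by a greedy cover
(grow `*` coordinates around each remaining state while coverage stays
inside the set); patterns cover each member set exactly but are not
guaranteed minimal in number.

## Circuit functionality

Circuits are enumerated at arc level (a multi-threshold arc is one
edge), as simple directed cycles, deduplicated up to rotation.  The
circuit sign is the product of arc signs; an arc bundling interactions
of different signs makes the circuit sign undetermined.

Functionality is window-based.  For each choice of one threshold `t_i`
per circuit arc, each circuit node is confined to the two levels
`{t_i−1, t_i}` around its outgoing threshold.  A context — an
assignment of levels to the external regulators of the circuit's
targets — is admissible when, for every circuit arc `s → g`, the target
level of `g` differs between `s = t_i−1` and `s = t_i` for *every*
placement of the remaining circuit nodes inside their windows.  The
functionality context is the union over threshold choices; the circuit
is functional iff it is non-empty.  The universal (rather than
existential) quantification over co-circuit placements is a design
choice; it reproduces both the published context of the p53/Mdm2nuc
circuit ({Mdm2cyt = 1, DNAdam = 0}) and the 3-of-4 functional count on
the fixture, which the tests enforce.  Contexts are reported as
per-node intervals when they factor as a product, otherwise listed
assignment by assignment.

`interaction_functionality` checks each *declared* interaction the same
way: the observed effect of `s → g` at threshold `t` is the sign of the
change of `g`'s target as `s` steps from `t−1` to `t`, over all level
combinations of `g`'s other regulators — classified as non-functional
(no context changes anything), consistent, or inconsistent with the
declared sign (`dual` and `?` declarations are never inconsistent).

## Model reduction

Eliminating node `r` (not self-regulated, not an input — an input
effectively maintains itself) rewrites each of its targets `g`:
the new target-level function is `x ↦ T_g(x[r := T_r(x)])` over the
regulator set `(reg(g) ∖ {r}) ∪ reg(r)`.  Thresholds and signs of the
reduced interactions are re-derived from the rewritten functions
(a threshold is kept iff crossing it changes the function in some
context), and rules are re-synthesized exactly as disjunctive normal
forms over window literals, with greedy cube merging for readability.
Because non-effective thresholds are discarded, the function is
provably constant on every window combination, so the synthesis is
exact.  Multiple removals are sequential in the given order; a removal
may create new self-regulation on kept nodes (only the removed node
must be self-regulation-free at its own step).  Stable states project
bijectively onto the kept nodes; on the p53-Mdm2 model, removing
Mdm2cyt yields a 12-state model with stable state `010` and a dual
p53→Mdm2nuc arc (inhibiting at level 1, activating at level 2).

## Random models

`random_model(n_nodes, max_level_cap, density, seed)` supports the
property tests: maximal levels are uniform in `[1, cap]`, ordered node
pairs get an arc with probability `density` (self-loops at half that,
so that elimination-based properties usually have a removable node),
and each arc draws one or more thresholds.  Rules are drawn as one
random target value per combination of regulator *windows*, which
makes entries mutually exclusive by construction and every literal
resolvable; declared signs are then derived from the drawn function,
so generated models always validate and are sign-consistent.  The same
seed reproduces the same model exactly.

The generator emulates the structural features the engine cares about
(multi-valuedness, multi-threshold arcs, sparse regulation); it does
not attempt biological realism — no degree-distribution, motif or
sign-bias structure of real regulatory networks — so passing property
tests demonstrates the algebraic invariants of the engine, not
biological validity of any particular random model.

## Problem sizes and determinism

Everything in the test suite and the acceptance script runs on graphs
of at most a few hundred states (the 36-state fixture, random models
with ≤ 6 nodes and maximal level ≤ 3), chosen because every invariant
checked is size-independent and exhaustive oracles (full enumeration,
brute-force stability) stay exact at that scale.  There is no
stochastic step anywhere in the analysis pipeline: given a model file
and flags, every output is byte-identical across runs.

## Known limitations

- Full-space construction is exponential in node count; the state cap
  fails loudly, and no symbolic (decision-diagram) representation is
  provided.
- The HTG does not preserve full reachability (by design, as in the
  published construction); use the SCC quotient when reachability
  matters.
- Circuit functionality analysis enumerates external contexts
  exhaustively and is meant for small models.
- Formula synthesis after reduction produces exact but not guaranteed
  minimal formulas.
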