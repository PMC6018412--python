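# mvlogic

Multi-valued logical modeling of cellular regulatory networks: define a
regulatory graph with threshold interactions and logical rules, build
its discrete dynamics under several updating schemes, and analyse the
results — stable states, attractors, hierarchical compressions of the
state transition graph, regulatory-circuit functionality, perturbations
and model reduction.

The package is aimed at systems biologists who want a scriptable,
fully deterministic engine for the logical (Thomas) formalism, in which
each regulatory component *g* carries a discrete activity level
`x_g ∈ {0, …, max_g}` and each interaction `s → g` a threshold `t`: the
interaction is active when `x_s` lies in the window `[t, t′−1]` up to
the next threshold `t′` declared on the same arc.  Per-node rules map
every state to a *target level* `T_g(x)`; a node whose level differs
from its target is *called* to move one step toward it.  An updating
scheme (asynchronous, synchronous, complete, sequential, or ranked
priority classes) selects which calls fire in each transition, defining
a state transition graph (STG) whose sinks are the stable states and
whose terminal strongly connected components are the attractors.

The bundled example model is the four-node p53-Mdm2 network — p53,
cytoplasmic Mdm2, nuclear Mdm2, DNA damage — whose dynamics couple DNA
damage sensing to oscillatory p53 activity.

## A worked example

```python
from mvlogic import (build_htg, build_stg, compute_stable,
                     p53_mdm2_model, Perturbation)

model = p53_mdm2_model()
print([s.code() for s in compute_stable(model)])   # ['0110']

stg = build_stg(model)                             # asynchronous, full
print(len(stg), [s.code() for s in stg.stable_states()])  # 36 ['0110']

htg = build_htg(stg)
print([(n.label, len(n.members)) for n in htg.nodes])
# [('i#10', 10), ('i#9', 9), ('ct#9', 9), ('0110', 1), ('i#1', 1), ('ct#6', 6)]

print(compute_stable(model, Perturbation.ectopic("DNAdam", 1)))  # []
```

Read: the wild-type model has a unique stable state `0110` (digits are
p53, Mdm2cyt, Mdm2nuc, DNAdam) — the cellular rest state.  Its 36-state
asynchronous STG compresses into a 6-node hierarchical transition
graph in which `ct#9` is a 9-state transient cycle of large p53
oscillations under DNA damage and `ct#6` a 6-state cycle of smaller
post-repair oscillations.  Clamping DNAdam at 1 (sustained damage)
leaves no stable state at all: the system can only oscillate.

The `examples/` directory contains one short script per capability
(stable states, transition graphs, HTG compression, circuit analysis,
model reduction), each printing the numbers above with commentary.

## Command line

Models live in a small line-oriented text format (see
`mvlogic.models.P53_MDM2_SOURCE` for a complete document):

```
node p53 max=2
edge p53 -> Mdm2nuc t=1 sign=-
rule Mdm2nuc:=1 <- Mdm2cyt:2 | (Mdm2cyt:1 & !p53 & !DNAdam)
```

```
mvlogic stable model.lrg                   # stable states, one code per line
mvlogic stg model.lrg --updating sync --format dot
mvlogic htg model.lrg
mvlogic circuits model.lrg
mvlogic reduce model.lrg --reduce Mdm2cyt
mvlogic check-interactions model.lrg
```

All verbs accept `--perturb node@lo[:hi]` and `--reduce nodes`; graph
verbs accept `--initial <pattern>` (digits and `*` wildcards),
`--priority` class specifications and `--max-states`.  Exit codes:
0 success, 2 validation error, 3 state cap exceeded.

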