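"""State transition graphs under asynchronous and synchronous updating.

The asynchronous STG fires one called node per transition (all
interleavings); the synchronous STG fires all of them at once
(deterministic).  Stability does not depend on the scheme, but the
attractor structure does.
"""

from mvlogic import (
    State,
    UpdatingScheme,
    attractors,
    build_stg,
    p53_mdm2_model,
    successors,
)

model = p53_mdm2_model()

async_stg = build_stg(model)  # full state space, asynchronous
print("asynchronous STG:", len(async_stg), "states,",
      len(async_stg.transitions()), "transitions")
# -> 36 states (3*3*2*2): the whole product state space.

s = State.from_code("0200")
print("async successors of 0200:",
      [x.code() for x in successors(model, s, UpdatingScheme.asynchronous())])
# -> ['1200', '0100', '0210']: p53 up, Mdm2cyt down, Mdm2nuc up — three
# unitary alternatives from the same state.

print("async attractors:",
      [(kind, sorted(x.code() for x in ms)) for kind, ms in attractors(async_stg)])
# -> one attractor, the stable rest state 0110.

sync_stg = build_stg(model, UpdatingScheme.synchronous())
print("sync successor of 0010:",
      [x.code() for x in successors(model, State.from_code("0010"),
                                    UpdatingScheme.synchronous())])
# -> ['0100']: Mdm2cyt and Mdm2nuc switch in one simultaneous step.

for kind, members in attractors(sync_stg):
    basin = sync_stg.predecessors_of(members)
    print(f"sync attractor {sorted(x.code() for x in members)} ({kind}): "
          f"reachable from {len(basin) - len(members)} other states")
# -> the stable state (reached from 26 states) plus two 2-state cycles
# (reached from 3 and 2 states): synchronous updating adds spurious
# cyclic attractors that the asynchronous dynamics does not have.
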