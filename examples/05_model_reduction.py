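"""Eliminate cytoplasmic Mdm2 and compare the reduced dynamics.

Node elimination substitutes the removed node's own target-level
function into its targets' rules, so indirect effects survive: stable
states (and attractors) are preserved up to projection, at a third of
the state space.
"""

from mvlogic import (
    build_htg,
    build_stg,
    compute_stable,
    p53_mdm2_model,
    reduce_model,
    write_model,
)

model = p53_mdm2_model()
reduced = reduce_model(model, ["Mdm2cyt"])
print(write_model(reduced))
# -> three nodes remain; p53 now acts on Mdm2nuc through a dual arc:
# inhibiting at level 1 (it would shut cytoplasmic Mdm2 production
# down) and activating at level 2 (it boosts it).

stg = build_stg(reduced)
print("reduced async STG:", len(stg), "states (was 36)")
print("reduced stable states:", [s.code() for s in compute_stable(reduced)])
# -> 12 states; the stable state 010 is exactly the projection of 0110
# onto (p53, Mdm2nuc, DNAdam).

htg = build_htg(stg)
print("reduced HTG nodes:",
      [(n.label, n.kind) for n in htg.nodes])
# -> still two cyclic-transient components: both kinds of transient p53
# oscillation (with and without DNA damage) survive the reduction.
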