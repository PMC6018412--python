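"""Build the p53-Mdm2 model and find its stable states.

The four components are, in order: p53 (levels 0-2), cytoplasmic Mdm2
(0-2), nuclear Mdm2 (0-1) and DNA damage (0-1).  States print as digit
strings in that order.
"""

from mvlogic import Perturbation, compute_stable, p53_mdm2_model, write_model

model = p53_mdm2_model()
print(write_model(model))

stable = compute_stable(model)
print("stable states:", [s.code() for s in stable])
# -> ['0110']: the cell rest state — no p53, medium Mdm2 in both
# compartments' terms (cytoplasmic 1, nuclear 1), no DNA damage.

clamped = compute_stable(model, Perturbation.ectopic("DNAdam", 1))
print("stable states under sustained DNA damage:", [s.code() for s in clamped])
# -> []: clamping DNAdam at 1 destroys the rest state; the system can
# only oscillate (see the transition-graph example).
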