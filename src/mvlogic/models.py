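"""Bundled example models.

The four-node p53-Mdm2 network couples the tumor suppressor p53 with
its negative regulator Mdm2, split into a cytoplasmic and a nuclear
pool, and with DNA damage.  Nuclear Mdm2 degrades p53; p53 activates
Mdm2 transcription (raising the cytoplasmic pool) but blocks its
nuclear translocation; DNA damage promotes nuclear Mdm2 degradation and
is repaired under high p53.  p53 and cytoplasmic Mdm2 are ternary
(levels 0-2), the other two components Boolean.
"""

from __future__ import annotations

from .language import parse_model
from .model import LogicalModel

__all__ = ["p53_mdm2_model", "P53_MDM2_SOURCE"]

#: Model document for the p53-Mdm2 network (node order is semantic).
P53_MDM2_SOURCE = """\
# Four-node logical model of the mammalian p53-Mdm2 network.
node p53 max=2
node Mdm2cyt max=2
node Mdm2nuc max=1
node DNAdam max=1
edge p53 -> Mdm2nuc t=1 sign=-
edge p53 -> Mdm2cyt t=2 sign=+
edge p53 -> DNAdam t=2 sign=-
edge Mdm2cyt -> Mdm2nuc t=1 sign=+
edge Mdm2cyt -> Mdm2nuc t=2 sign=+
edge Mdm2nuc -> p53 t=1 sign=-
edge DNAdam -> DNAdam t=1 sign=+
edge DNAdam -> Mdm2nuc t=1 sign=-
rule p53:=2 <- !Mdm2nuc
rule Mdm2cyt:=2 <- p53
rule Mdm2cyt:=1 <- !p53
rule Mdm2nuc:=1 <- Mdm2cyt:2 | (Mdm2cyt:1 & !p53 & !DNAdam)
rule DNAdam:=1 <- DNAdam & !p53
"""


def p53_mdm2_model() -> LogicalModel:
    """The p53-Mdm2 logical model (4 nodes, 8 interactions, 5 rules)."""
    return parse_model(P53_MDM2_SOURCE)
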