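"""Map inverted-repeat presence onto the Euglenophyta tree and count losses.

Under Dollo parsimony with the root fixed to "present" (the plastid was
acquired from a prasinophyte-like alga with the canonical quadripartite
genome, and re-creating an IR de novo is far less likely than losing one),
the minimum number of irreversible IR losses explaining the tip states is
counted, and the stem edges carrying those losses are reported.  Fitch
parsimony is run as a sensitivity check.
"""

from plastocompare import count_losses
from plastocompare.datasets import euglenophyta_tree, ir_character

tree = euglenophyta_tree()
character = ir_character()

dollo = count_losses(tree, character, model="dollo", root_state="1")
print(f"Dollo minimum losses : {dollo.min_changes}")
print(f"loss edges           : {', '.join(dollo.loss_edges)}")

fitch = count_losses(tree, character, model="fitch", root_state="1")
print(f"Fitch minimum changes: {fitch.min_changes} "
      f"(gains: {fitch.gain_edges or 'none'})")
# Three losses: one on the Eutreptia lineage, one on the stem of the Phacus
# clade, one on the stem of the Euglenaceae clade.  Fitch agrees with three
# changes and needs no gains, so a loss-only history is also minimum-change.
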