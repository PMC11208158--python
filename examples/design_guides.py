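"""Design a bridge RNA against a target and a donor site.

Builds a placeholder 177-nt scaffold, reprograms its guide regions against two
14-bp windows with CT cores, and prints the per-region guide sequences plus
the pairing diagram.  Each guide is the Watson-Crick RNA complement of the DNA
strand it pairs (LTG/LDG: bottom strands; RTG/RDG: top strands; HSGs: the
*other* site's top strand at positions 7-6).
"""

import numpy as np

import bridgekit as bk

scaffold = bk.random_scaffold(np.random.default_rng(42))
target = bk.make_window("ACGTACGCTGACTA", role="target")
donor = bk.make_window("TTCAGATCTTGATT", role="donor")

brna, report = bk.design_bridge_rna(scaffold, target, donor)

for region in ("ltg", "rtg", "rtg-extension", "hsg-t", "ldg", "rdg", "hsg-d"):
    guide = "".join(brna.base(p) for p in brna.positions(region))
    print(f"{region:>14}: {guide}")
print()
print(report.format_table())
# "not locked" means no handshake guide can pair its own (cognate) site, so
# the simulated reaction will proceed through strand exchange to products.
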