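"""Scan a molecule for candidate cores and build a mismatch-trap construct.

Every 14-bp window placement with T at position 9 is a candidate site; CT
cores rank first (then GT, then AT/TT).  The trap construct complements top
positions 2-7, planting six duplex mismatches that stall the complex for
structural work while leaving the core untouched.
"""

import bridgekit as bk

mol = bk.SubstrateMolecule("AAGGCCAACTGGTTCAGATCTTGATTCCGG", "linear")
for hit in bk.scan_cores(mol):
    print(f"offset {hit.window_start:>2} strand {hit.strand} core {hit.core} "
          f"-> {hit.report.verdict.value}")

window = bk.make_window("ACGTACGCTGACTA")
trapped = bk.trap_mismatches(window)
print(f"\noriginal top: {window.top}")
print(f"trapped top:  {trapped.top}")
print(f"mismatched positions: {sorted(trapped.mismatches)} (core intact: "
      f"{trapped.core == window.core})")
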