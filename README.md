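# bridgekit

Bridge-RNA design and recombination simulation for IS110-family RNA-guided
DNA recombinases.

IS110 insertion sequences move as circular double-stranded DNA intermediates
and insert into specific genomic sites using a single small recombinase and a
single non-coding **bridge RNA** (bRNA).  The reference system modelled here
is the *E. coli* IS621 element: a 177-nt bRNA whose two internal loops — the
target-binding loop (TBL, nucleotides 34–98) and the donor-binding loop (DBL,
110–177) — are independently reprogrammable, making the system a general tool
for programmed insertion, excision and inversion.  `bridgekit` is for people
engineering or studying such systems: it designs guides, predicts whether a
design will recombine or stall, and simulates the reaction at single-
nucleotide resolution.

## What it models

* **Recognition sites.**  Each site is a 14-bp duplex window (top strand
  1..14, bottom strand starred 1\*..14\*, top *i* across from bottom
  15 − *i*) with a core dinucleotide at top positions 8–9.  Position 9 must
  be T; position 8 prefers C ≥ G > A ≈ T.  `scan_cores` enumerates candidate
  placements on both strands of a linear or circular molecule.
* **Guide design.**  `design_bridge_rna` rewrites only the programmable
  regions — LTG (50–58) against target bottom 14\*..6\*, RTG (77–80) against
  target top 11..8, the optional RTG extension (74–76) against top 14..12,
  LDG (123–130) against donor bottom 14\*..7\*, RDG (157–158, 161, 162–165)
  against donor top 14..8, and the two handshake guides HSG-T (81–82) and
  HSG-D (166–167) against the *non-cognate* site's top 7–6.  Eight
  family-conserved nucleotides (A43/A67/A116/A150, G48/G72/G121/G155) are
  refused as write targets.
* **The reaction.**  `form_synapse` → `run` walks an explicit state machine:
  top-strand cleavage between positions 9|10 (5′-phosphoserine intermediates
  S241.4↔target top 10, S241.2↔donor top 10), handshake-gated top-strand
  exchange and religation (Holliday junction), bottom-strand cleavage between
  9\*|10\* (S241.3↔target bottom 10\*, S241.1↔donor bottom 10\*), and bottom
  exchange/ligation.  Handshake guides programmed against the *cognate* site
  ("pre-HSB") trap the complex in an absorbing `locked` state with no
  products.  Two target halves refuse to synapse at all; two donor halves
  recombine.
* **Products.**  `recombine_molecules` splices full molecules topology-aware
  (insertion of a circular donor, two linear products, intramolecular
  excision/inversion), tracking per-position parent-of-origin and the
  junction heteroduplex at window positions 6–7 (6–9 if the cores differ),
  which `repair` can resolve.
* **Covariation.**  `signed_scores` computes, between every DNA-site column
  and every bRNA column of a paired alignment, a normalized covariation
  statistic (mutual information with average-product correction) multiplied
  by the sign of a base-pairing concordance, giving scores in [−1, +1]:
  −1 = top-strand pairing, +1 = bottom-strand pairing.
  `simulate_alignment` generates seeded synthetic alignments with planted
  covarying pairs.

## Worked example

```python
import numpy as np
import bridgekit as bk

scaffold = bk.random_scaffold(np.random.default_rng(42))
target = bk.make_window("ACGTACGCTGACTA", role="target")   # core CT at 8-9
donor  = bk.make_window("TTCAGATCTTGATT", role="donor")

brna, report = bk.design_bridge_rna(scaffold, target, donor)
# LTG ACGUACGCU  RTG UCAG  ext UAG  HSG-T AU
# LDG UUCAGAUC   RDG AAUCAAG        HSG-D CG     lock prediction: not locked

traj = bk.run(bk.form_synapse((brna, target), (brna, donor)))
# stages: synapsed -> top-cleaved -> hj-intermediate -> hj-resolved -> products
ja, jb = traj[-1].junctions()
print(ja.top, ja.bottom, sorted(ja.heteroduplex))
# ACGTACGCTTGATT AATCAAGATTACGT [6, 7]
```

Junction A carries the target's left half (top 1–9) joined to the donor's
right half (top 10–14); its bottom strand comes from the donor up to 9\* and
the target beyond, so positions 6–7 — where the two sites differ — are
heteroduplex until repaired.  `bk.repair(products, "top-wins")` resolves them
to the top strand.  The `examples/` directory holds one short script per
capability (design, simulation/insertion, scanning/trapping, covariation),
and the `bridgekit` console script exposes the same operations as
subcommands (`design`, `simulate`, `scan`, `trap`, `covary`, `covary-sim`,
`fixtures`).

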