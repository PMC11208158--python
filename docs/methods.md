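# Methods

## The model

`bridgekit` models bridge recombination — the reaction by which an
IS110-family recombinase, guided by its bispecific bridge RNA (bRNA), joins a
donor DNA (the element's circular form) to a target DNA (a genomic site) — as
a deterministic, sequence-level state machine.  The model is symbolic where
the chemistry is structural: protomers, composite active sites and
phosphoserine intermediates are bookkeeping labels attached to exact sequence
coordinates, never 3D geometry.  Kinetics, yields and efficiencies are out of
scope; the simulator answers *what products form and where every nucleotide
came from*, not *how fast* or *how often*.

### Coordinates and data model

All coordinates are 1-based closed intervals.  A recognition site is a 14-bp
duplex window: top strand positions 1..14 (5′→3′), bottom strand starred
1\*..14\* (5′→3′ on the complement), top *i* across from bottom 15 − *i*.
The core dinucleotide sits at top 8–9.  Flanking sequence belongs to
`SubstrateMolecule` (linear or circular; circularity is declared out-of-band
because FASTA cannot carry it), not to the window.

The reference bRNA scaffold is 177 nt.  Region coordinates (TBL 34–98, DBL
110–177, LTG 50–58, RTG 77–80, RTG-extension slots 74–76, HSG-T 81–82, LDG
123–130, RDG 157–158/161/162–165 with flipped-out spacers 159–160, HSG-D
166–167, linker blocks 47–49/59/72–73/83–86 and 121–122/131–132/155–156/168,
DBL stem loop 137–147) are shipped as the default region map and may be
replaced by a user map of matching shape.  The 5′ stem-loop boundary is fixed
at 1..31 — *inferred* from the two published lengths (full scaffold 177 nt,
stem-loop deletion mutant 146 nt); only the length difference, not the
boundary, is printed anywhere.  Internal stem registers of the TBL/DBL are
deliberately not modelled: design never rewrites them, so intervals suffice.
Eight family-conserved nucleotides (A43, A67, A116, A150; G48, G72, G121,
G155) are warnings on load (orthologue scaffolds may deviate) but hard errors
on write.

### Pairing policy

RNA:DNA Watson-Crick pairs are A:T, U:A, G:C, C:G.  G:T wobble is observed in
the functional wild-type guide/DNA duplexes, so the *permissive* policy (WC +
wobble) is the validation and gating default; U:G is included in the wobble
class for symmetry even though only G:T is evidenced — the pair class
distinguishes them so a caller can tighten this.  Guide *generation* is
always WC-only: wobble is accepted, never emitted.

### Design registers

Each guide is written as the WC RNA complement of the strand it physically
pairs, in antiparallel register (ascending scaffold position ↔ descending DNA
position).  LTG covers target bottom 14\*..6\* (9 nt) while LDG covers donor
bottom 14\*..7\* (8 nt); the asymmetry is implemented exactly as annotated.
Position 161 is treated as a programmable RDG position pairing donor top 12
(the wild type shows a non-canonical pair there and the productive engineered
variant makes it canonical), although the compact RDG interval notation omits
it.  A consequence worth knowing: for a WT-complementary target the emitted
LTG equals the RNA transliteration of target top 1–9 (complement of the
complement), which is also why *bottom-strand* concordance in the covariation
module means *identity* with the top strand.

### The handshake gate and the lock rule

The two handshake guides (HSG-T at 81–82, HSG-D at 166–167; registers 81↔7,
82↔6, 166↔7, 167↔6) pair the *non-cognate* site's top strand after top-strand
exchange; this is the productive "post-HSB" default.  Programming them
against the cognate site ("pre-HSB") stalls the reaction before exchange.
The lock predicate is: **any** HSG position that can pair its cognate top
strand under the permissive policy locks the complex.  The single-position
form is deliberate — a lone point change at position 166 that enables pairing
to donor top 7 is enough to collapse recombination, and the wild-type G at
166 can wobble-pair a T at donor 7, consistent with the wild type exchanging
strands less efficiently than the engineered post-HSB variant.  The rule is
aggressive by construction: roughly 85% of *unconstrained* random site pairs
yield a post-HSB design predicted to lock, because the WC complement of one
site's base at 6/7 frequently also pairs the other site's base there.  Sites
whose positions 6–7 coincide are therefore not productively designable in
this model, and the fixture generator (below) excludes them.

### Reaction state machine

Stages: `synapsed → top-cleaved → (locked | hj-intermediate) → hj-resolved →
products`; `locked` and `products` absorb.  Cleavage registers are fixed:
top strands cut 3′ of window position 9, bottom strands 3′ of 9\*; no
alternative registers are modelled.  Covalent bookkeeping follows the fixed
protomer assignment (dimer 1–2 binds the TBL/target half, 3–4 the DBL/donor
half; composite sites RuvC.1-Tnp.4 and RuvC.3-Tnp.2 cut the target and donor
top strands, RuvC.2-Tnp.3 and RuvC.4-Tnp.1 the bottoms; serine links S241.4↔
target top 10, S241.2↔donor top 10, S241.3↔target bottom 10\*, S241.1↔donor
bottom 10\*).  Two modelled simplifications are stamped into every
trajectory's notes: bottom-strand exchange and final ligation are
deterministic in-simulator steps (in vivo the hand-off to host processes is
plausible but unresolved), and the partially religated Holliday intermediate
is collapsed into a single stage with no occupancy fractions.  Observed but
functionally unimportant target–donor bottom-strand contacts at positions
3\*–5\* gate nothing.

Synapsis asymmetry is enforced structurally: only the DBL stem loop carries
the recombinase contact that licenses tetramer assembly, so two target/TBL
halves raise `SynapsisError` while two donor/DBL halves proceed (donor–donor
recombination), with a provenance note that the "target" slot holds a
donor-role window.

### Products, junctions, repair

Junction A joins target top 1–9 to donor top 10–14 over donor bottom 1\*–9\*
and target bottom 10\*–14\*; junction B is the mirror.  Because the top
crossover (9|10) and bottom crossover (9\*|10\*, i.e. between top coordinates
5 and 6) are offset by four positions, each junction has a four-position zone
(window 6–9) where the strands descend from different parents; with matching
cores only 6–7 can mismatch.  Full-molecule splicing handles linear × linear
(two products), linear × circular (insertion, either orientation of which
molecule is the backbone), circular × circular (fusion circle), and
intramolecular direct/inverted site pairs (excision to a circle + shortened
backbone, or in-place inversion of the intervening segment).  Nucleotide
conservation (top and bottom counted separately) holds for every case by
construction and is asserted in tests.  `repair` resolves heteroduplex
positions to the chosen strand (`top-wins` / `bottom-wins` / `leave`),
relabelling the losing strand's parent.

### Covariation scale

The covariation statistic between a DNA column and a bRNA column is mutual
information (bits) with average-product correction, floored at zero — a
self-contained substitute for external pseudo-likelihood coupling tools,
chosen for determinism and zero fitted parameters.  The signed scale on top
of it is the module's point: scores are normalized by the single matrix
maximum (so the bounds ±1 are attainable; the normalization method is a
design choice — alternatives such as per-row scaling would change magnitudes
but not signs or ranks) and multiplied by `sign(f_bottom − f_top)`, where
`f_bottom` is the fraction of records whose bRNA base equals the
transliterated top-strand base (bottom-strand pairing, see above) and `f_top`
the fraction equal to its RNA complement.  Ties give sign 0.  Concordance is
computed from the top-strand representation only, since the bottom strand is
its complement by construction.

## Synthetic data

The fixture generator (`generate_fixtures`) emulates reprogrammable
recombination jobs: WT-complementary 14-bp window pairs with the canonical CT
core planted at 8–9 and uniform random bases elsewhere, plus a 177-nt
placeholder scaffold with the eight conserved bases planted.  Donor positions
6–7 are resampled until the pair is handshake-compatible (a post-HSB design
is lock-free), reflecting the site-pair population a designer would actually
use; lock behaviour is exercised separately with pre-HSB designs and with
unconstrained random pairs.  The alignment simulator draws i.i.d. uniform
columns and plants covarying pairs with a per-record error rate.

What passing tests on this synthetic population do **not** show: behaviour on
real genomic composition (GC skew, repeats), off-target landscapes, core
variants beyond the ordinal C ≥ G > A ≈ T preference, cellular recombination
efficiencies, or the phylogenetic correlation structure of real orthologue
alignments (records here are exchangeable; real alignments are not).

## Numerical and interface choices

All randomness flows through numpy `Generator` objects seeded explicitly;
identical seeds give byte-identical outputs.  Scan ranking is ordinal (CT,
then GT, then AT/TT) with ties broken by ascending offset, forward strand
first; reverse-strand hits carry coordinates on the reverse-complemented
sequence.  Ambiguity codes are rejected, not expanded.  The mismatch-trap
construct substitutes the complement of each original top base at positions
2–7 (the published constructs' exact mismatch bases are not printed;
complementation guarantees a mismatch at all six positions).  Degenerate
covariation inputs (monomorphic alignments) return all-zero matrices with a
warning rather than NaNs.  CLI exit codes separate user errors (2) from
mechanism refusals (3: synapsis refusal or lock), which still write their
trajectory JSON.

Problem sizes used by the test suite and acceptance script — 1000-pair
splice-oracle and lock-agreement sweeps, 100-replicate sign-recovery at
n = 200 and 20% noise — were chosen as comfortably large for the properties
being estimated while keeping the whole suite in the seconds-to-minutes
range.

## Known limitations

* The wild-type scaffold's base identities at non-programmable positions are
  not bundled; `load_scaffold` accepts any user scaffold of matching length,
  and the generated placeholder scaffold is clearly synthetic (conserved
  bases planted, everything else random).
* The lock predicate is categorical; it cannot express the graded efficiency
  differences seen between handshake variants (e.g. the modest enhancement
  from reprogramming position 167).
* Excision/inversion support two non-overlapping sites on a linear molecule;
  multi-site and nested arrangements are not modelled.
* RNA secondary-structure prediction, covariance-model homology search and
  genome-wide specificity scoring are explicit non-goals.
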