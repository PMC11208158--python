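"""State-machine simulation of bridge recombination.

The reaction is modelled as an explicit four-step cycle over two 14-bp windows
held in a tetrameric synaptic complex (protomers 1-4: dimer 1-2 binds the
TBL/target half, dimer 3-4 the DBL/donor half; the TBL and DBL are contributed
by two bridge-RNA molecules):

1. top-strand cleavage between window positions 9|10 of both substrates at the
   composite RuvC-Tnp active sites, leaving covalent 5'-phosphoserine
   intermediates (S241.4 on target top 10, S241.2 on donor top 10);
2. handshake gate: if either handshake guide pairs its *cognate* top strand at
   positions 7/6 (permissive policy) the complex is trapped in an absorbing
   ``locked`` state; otherwise the top strands are exchanged and religated,
   forming a Holliday junction;
3. Holliday-junction resolution by bottom-strand cleavage between starred
   positions 9*|10* (S241.3 on target bottom 10*, S241.1 on donor bottom 10*);
4. bottom-strand exchange and ligation, yielding two recombinant junctions
   whose positions 6-7 (6-9 for differing cores) are heteroduplex until
   repaired.

Bottom-strand exchange and final ligation are modelled as deterministic steps
(recorded in the trajectory as a modelled assumption — in vivo the final
resolution and heteroduplex repair are host processes), and the partially
religated Holliday intermediate is collapsed into a single stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .nucleic import comp_dna, revcomp_dna
from .pairing import classify_pair
from .scaffold import BridgeRNA
from .substrate import DnaWindow, SubstrateMolecule, WINDOW_LENGTH, make_window, star

MODELLED_ASSUMPTIONS = (
    "bottom-strand exchange and ligation modelled as deterministic in-complex steps",
    "partial religation of the Holliday intermediate collapsed into one stage",
)

#: Fixed protomer/domain assignment of the four composite active sites.
ACTIVE_SITES = {
    ("target", "top"): "RuvC.1-Tnp.4",
    ("donor", "top"): "RuvC.3-Tnp.2",
    ("target", "bottom"): "RuvC.2-Tnp.3",
    ("donor", "bottom"): "RuvC.4-Tnp.1",
}

#: Serine (by protomer) forming the 5'-phosphoserine link on each strand.
SERINES = {
    ("target", "top"): 4,
    ("donor", "top"): 2,
    ("target", "bottom"): 3,
    ("donor", "bottom"): 1,
}

TOP_CUT_5P = 9  # cut between top 9 | 10
BOTTOM_CUT_5P = 9  # cut between bottom 9* | 10*


class Stage(str, Enum):
    APO = "apo"
    SYNAPSED = "synapsed"
    TOP_CLEAVED = "top-cleaved"
    LOCKED = "locked"
    HJ_INTERMEDIATE = "hj-intermediate"
    HJ_RESOLVED = "hj-resolved"
    PRODUCTS = "products"


class SynapsisError(ValueError):
    """Synapsis refused (two TBL/target halves lack the DBL-SL-RuvC contact)."""


class ProductsUnavailable(RuntimeError):
    """The reaction locked before strand exchange; carries the trajectory."""

    def __init__(self, message: str, trajectory: list["SynapticState"]):
        super().__init__(message)
        self.trajectory = trajectory


class StepWarning(UserWarning):
    """step() called on an absorbing state."""


@dataclass(frozen=True)
class CutRecord:
    """A strand cleavage between ``five_prime`` and ``three_prime`` (window coords)."""

    slot: str  # 'target' | 'donor'
    strand: str  # 'top' | 'bottom'
    five_prime: int
    three_prime: int
    starred: bool
    active_site: str


@dataclass(frozen=True)
class CovalentLink:
    """A 5'-phosphoserine link between a protomer's S241 and a DNA position."""

    serine: str  # e.g. 'S241.4'
    protomer: int
    slot: str
    strand: str
    position: int
    starred: bool


@dataclass(frozen=True)
class Half:
    """One dimeric half of the synaptic complex: a bRNA loop bound to a window."""

    brna: BridgeRNA
    window: DnaWindow
    loop: str  # 'tbl' | 'dbl'
    label: str  # parent-of-origin label


@dataclass(frozen=True)
class JunctionWindow:
    """A 14-position recombinant junction with parent-of-origin bookkeeping.

    ``top``/``bottom`` are both 5'->3' (bottom in starred numbering);
    ``parents_top[i-1]`` / ``parents_bottom[j-1]`` name the parent of top
    position i / bottom position j*.  ``heteroduplex`` lists top positions
    whose strands derive from different parents and are non-complementary.
    """

    name: str
    top: str
    bottom: str
    parents_top: tuple[str, ...]
    parents_bottom: tuple[str, ...]

    @property
    def heteroduplex(self) -> frozenset[int]:
        flags = set()
        for i in range(1, WINDOW_LENGTH + 1):
            j = star(i)
            if (
                self.parents_top[i - 1] != self.parents_bottom[j - 1]
                and self.bottom[j - 1] != comp_dna(self.top[i - 1])
            ):
                flags.add(i)
        return frozenset(flags)

    def as_window(self) -> DnaWindow:
        return DnaWindow(top=self.top, bottom=self.bottom, role="target")


@dataclass(frozen=True)
class SynapticState:
    """One state of the recombination reaction (immutable; step() returns a new one)."""

    stage: Stage
    halves: dict[str, Half]
    tops: dict[str, str]
    bottoms: dict[str, str]
    parents_top: dict[str, tuple[str, ...]]
    parents_bottom: dict[str, tuple[str, ...]]
    cuts: tuple[CutRecord, ...] = ()
    covalent_links: tuple[CovalentLink, ...] = ()
    lock_reason: str | None = None
    provenance: str | None = None
    notes: tuple[str, ...] = ()

    @property
    def protomers(self) -> dict[int, str]:
        """Symbolic protomer roles (no structural coordinates)."""
        return {
            1: "dimer 1-2, binds TBL half",
            2: "dimer 1-2, binds TBL half; Tnp.2 cuts donor top",
            3: "dimer 3-4, binds DBL half; Tnp.3 cuts target bottom",
            4: "dimer 3-4, binds DBL half; Tnp.4 cuts target top",
        }

    def junctions(self) -> tuple[JunctionWindow, JunctionWindow]:
        if self.stage is not Stage.PRODUCTS:
            raise ValueError("junctions available only at the products stage")
        ja = JunctionWindow(
            name="A",
            top=self.tops["target"],
            bottom=self.bottoms["target"],
            parents_top=self.parents_top["target"],
            parents_bottom=self.parents_bottom["target"],
        )
        jb = JunctionWindow(
            name="B",
            top=self.tops["donor"],
            bottom=self.bottoms["donor"],
            parents_top=self.parents_top["donor"],
            parents_bottom=self.parents_bottom["donor"],
        )
        return ja, jb

    def to_dict(self) -> dict:
        return {
            "stage": self.stage.value,
            "cuts": [
                {
                    "slot": c.slot,
                    "strand": c.strand,
                    "between": [c.five_prime, c.three_prime],
                    "starred": c.starred,
                    "active_site": c.active_site,
                }
                for c in self.cuts
            ],
            "covalent_links": [
                {
                    "serine": l.serine,
                    "slot": l.slot,
                    "strand": l.strand,
                    "position": l.position,
                    "starred": l.starred,
                }
                for l in self.covalent_links
            ],
            "lock_reason": self.lock_reason,
            "provenance": self.provenance,
            "notes": list(self.notes),
        }


def form_synapse(
    rnp_target: tuple[BridgeRNA, DnaWindow],
    rnp_donor: tuple[BridgeRNA, DnaWindow],
) -> SynapticState:
    """Assemble the tetrameric synaptic complex from two dimeric halves.

    A target-role window recruits a TBL half, a donor-role window a DBL half.
    Two TBL halves cannot synapse (no DBL stem-loop to contact RuvC); two DBL
    halves can (donor-donor recombination), noted in the provenance.
    """
    halves_in = [rnp_target, rnp_donor]
    roles = [w.role for _, w in halves_in]
    if roles == ["target", "target"]:
        raise SynapsisError(
            "two TBL/target halves cannot form a synaptic complex: the TBL stem "
            "loop lacks the DBL-SL contact with RuvC that licenses synapsis"
        )
    provenance = None
    if roles == ["donor", "donor"]:
        provenance = (
            "donor-donor synapsis: both halves are DBL/donor complexes; the "
            "'target' slot is occupied by a donor-role window"
        )
        labels = ("donor.1", "donor.2")
        loops = ("dbl", "dbl")
    else:
        # order-normalize so the target half sits in the target slot
        if roles == ["donor", "target"]:
            halves_in = [halves_in[1], halves_in[0]]
        labels = ("target", "donor")
        loops = ("tbl", "dbl")
    halves = {
        "target": Half(brna=halves_in[0][0], window=halves_in[0][1], loop=loops[0], label=labels[0]),
        "donor": Half(brna=halves_in[1][0], window=halves_in[1][1], loop=loops[1], label=labels[1]),
    }
    tops = {s: h.window.top for s, h in halves.items()}
    bottoms = {s: h.window.bottom for s, h in halves.items()}
    return SynapticState(
        stage=Stage.SYNAPSED,
        halves=halves,
        tops=tops,
        bottoms=bottoms,
        parents_top={s: (h.label,) * WINDOW_LENGTH for s, h in halves.items()},
        parents_bottom={s: (h.label,) * WINDOW_LENGTH for s, h in halves.items()},
        provenance=provenance,
        notes=MODELLED_ASSUMPTIONS,
    )


def _cognate_hsg_lock(halves: dict[str, Half]) -> str | None:
    """Return a lock description if any HSG position pairs its cognate top strand."""
    locked_pairs = []
    for slot, half in halves.items():
        region = "hsg-t" if half.loop == "tbl" else "hsg-d"
        guide_positions = half.brna.positions(region)
        for gp, dp in zip(guide_positions, (7, 6)):
            base = half.brna.base(gp)
            cls, paired = classify_pair(base, half.window.top_at(dp), "permissive")
            if paired:
                locked_pairs.append(
                    f"{region} {base}{gp}:{half.window.top_at(dp)}{dp} ({slot} top, {cls.value})"
                )
    if locked_pairs:
        return "cognate handshake pairing: " + "; ".join(locked_pairs)
    return None


def step(s: SynapticState) -> SynapticState:
    """Advance the reaction by one stage (no-op with a warning on absorbing states)."""
    import warnings

    if s.stage in (Stage.LOCKED, Stage.PRODUCTS):
        warnings.warn(f"step() on absorbing stage {s.stage.value}", StepWarning, stacklevel=2)
        return s
    if s.stage is Stage.SYNAPSED:
        cuts = tuple(
            CutRecord(
                slot=slot,
                strand="top",
                five_prime=TOP_CUT_5P,
                three_prime=TOP_CUT_5P + 1,
                starred=False,
                active_site=ACTIVE_SITES[(slot, "top")],
            )
            for slot in ("target", "donor")
        )
        links = tuple(
            CovalentLink(
                serine=f"S241.{SERINES[(slot, 'top')]}",
                protomer=SERINES[(slot, "top")],
                slot=slot,
                strand="top",
                position=TOP_CUT_5P + 1,
                starred=False,
            )
            for slot in ("target", "donor")
        )
        return replace(s, stage=Stage.TOP_CLEAVED, cuts=s.cuts + cuts, covalent_links=s.covalent_links + links)
    if s.stage is Stage.TOP_CLEAVED:
        reason = _cognate_hsg_lock(s.halves)
        if reason is not None:
            return replace(s, stage=Stage.LOCKED, lock_reason=reason)
        # exchange top strands at the 9|10 cut and religate both junctions;
        # serines are released
        t, d = s.tops["target"], s.tops["donor"]
        pt, pd = s.parents_top["target"], s.parents_top["donor"]
        tops = {"target": t[:9] + d[9:], "donor": d[:9] + t[9:]}
        parents_top = {"target": pt[:9] + pd[9:], "donor": pd[:9] + pt[9:]}
        links = tuple(l for l in s.covalent_links if l.strand != "top")
        return replace(
            s,
            stage=Stage.HJ_INTERMEDIATE,
            tops=tops,
            parents_top=parents_top,
            covalent_links=links,
            notes=s.notes + ("top strands exchanged and religated at both 9|10 junctions",),
        )
    if s.stage is Stage.HJ_INTERMEDIATE:
        cuts = tuple(
            CutRecord(
                slot=slot,
                strand="bottom",
                five_prime=BOTTOM_CUT_5P,
                three_prime=BOTTOM_CUT_5P + 1,
                starred=True,
                active_site=ACTIVE_SITES[(slot, "bottom")],
            )
            for slot in ("target", "donor")
        )
        links = tuple(
            CovalentLink(
                serine=f"S241.{SERINES[(slot, 'bottom')]}",
                protomer=SERINES[(slot, "bottom")],
                slot=slot,
                strand="bottom",
                position=BOTTOM_CUT_5P + 1,
                starred=True,
            )
            for slot in ("target", "donor")
        )
        return replace(s, stage=Stage.HJ_RESOLVED, cuts=s.cuts + cuts, covalent_links=s.covalent_links + links)
    if s.stage is Stage.HJ_RESOLVED:
        bt, bd = s.bottoms["target"], s.bottoms["donor"]
        pt, pd = s.parents_bottom["target"], s.parents_bottom["donor"]
        bottoms = {"target": bd[:9] + bt[9:], "donor": bt[:9] + bd[9:]}
        parents_bottom = {"target": pd[:9] + pt[9:], "donor": pt[:9] + pd[9:]}
        links = tuple(l for l in s.covalent_links if l.strand != "bottom")
        return replace(
            s,
            stage=Stage.PRODUCTS,
            bottoms=bottoms,
            parents_bottom=parents_bottom,
            covalent_links=links,
            notes=s.notes + ("bottom strands exchanged and ligated at both 9*|10* junctions",),
        )
    raise ValueError(f"cannot step from stage {s.stage}")


def run(s: SynapticState) -> list[SynapticState]:
    """Run to an absorbing state; returns the full trajectory (first = input)."""
    traj = [s]
    while traj[-1].stage not in (Stage.LOCKED, Stage.PRODUCTS):
        traj.append(step(traj[-1]))
    return traj


# ---------------------------------------------------------------------------
# Full-molecule products


@dataclass(frozen=True)
class ProductMolecule:
    """A recombinant molecule with per-position parent-of-origin bookkeeping.

    ``top`` is the top strand 5'->3'; ``bottom_aligned`` lists, left to right
    under each top position, the base of the bottom strand paired there (the
    bottom strand read 5'->3' is :attr:`bottom`).  ``heteroduplex`` holds
    1-based top coordinates where the duplex is non-complementary.
    """

    name: str
    top: str
    bottom_aligned: str
    topology: str
    parents_top: tuple[str, ...]
    parents_bottom_aligned: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.top)

    @property
    def bottom(self) -> str:
        return self.bottom_aligned[::-1]

    @property
    def heteroduplex(self) -> frozenset[int]:
        return frozenset(
            i + 1
            for i in range(len(self.top))
            if self.bottom_aligned[i] != comp_dna(self.top[i])
        )


@dataclass(frozen=True)
class RecombinationProducts:
    """Junction windows plus (optionally) full-length product molecules."""

    junction_a: JunctionWindow
    junction_b: JunctionWindow
    molecules: tuple[ProductMolecule, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def total_top_length(self) -> int:
        return sum(m.length for m in self.molecules)

    @property
    def total_bottom_length(self) -> int:
        return sum(len(m.bottom_aligned) for m in self.molecules)


def _normalized(mol: SubstrateMolecule) -> SubstrateMolecule:
    """Rotate a circular molecule so its window starts at position 1."""
    if mol.topology == "linear" or mol.window_start == 1:
        return mol
    k = mol.window_start - 1
    return SubstrateMolecule(
        sequence=mol.sequence[k:] + mol.sequence[:k],
        topology=mol.topology,
        window_start=1,
        role=mol.role,
    )


def _patch(ab: list[str], parents: list[str], coords: range, bases: str, label: str) -> None:
    for idx, base in zip(coords, bases):
        ab[idx] = base
        parents[idx] = label


def _junction_zone(w: DnaWindow) -> str:
    """Aligned bottom bases contributed across a junction (window pos 6..9)."""
    return "".join(comp_dna(w.top_at(k)) for k in (6, 7, 8, 9))


def _product(
    name: str,
    topology: str,
    pieces: list[tuple[str, str]],
    patches: list[tuple[int, str, str]],
) -> ProductMolecule:
    """Assemble a product from (top-segment, label) pieces plus AB patches.

    Each patch is (1-based coord of the first of 4 zone positions, bases, label).
    """
    top = "".join(seg for seg, _ in pieces)
    parents_top: list[str] = []
    for seg, label in pieces:
        parents_top.extend([label] * len(seg))
    ab = [comp_dna(c) for c in top]
    parents_ab = list(parents_top)
    for start, bases, label in patches:
        _patch(ab, parents_ab, range(start - 1, start + 3), bases, label)
    return ProductMolecule(
        name=name,
        top=top,
        bottom_aligned="".join(ab),
        topology=topology,
        parents_top=tuple(parents_top),
        parents_bottom_aligned=tuple(parents_ab),
    )


def recombine_molecules(
    target: SubstrateMolecule,
    donor: SubstrateMolecule,
    b: BridgeRNA,
) -> RecombinationProducts:
    """Run the reaction and splice full-length products, topology-aware.

    linear x linear -> two linear products; linear x circular -> one linear
    product with the circle integrated between the junctions (insertion);
    circular x circular -> one fused circle.  Raises
    :class:`ProductsUnavailable` (carrying the trajectory) if the reaction
    locks.
    """
    target = _normalized(target)
    donor = _normalized(donor)
    tw, dw = target.window(), donor.window()
    traj = run(form_synapse((b, tw), (b, dw)))
    final = traj[-1]
    if final.stage is Stage.LOCKED:
        raise ProductsUnavailable(
            f"reaction locked before strand exchange ({final.lock_reason})", traj
        )
    ja, jb = final.junctions()

    t_seq, d_seq = target.sequence, donor.sequence
    lt, ld = len(t_seq), len(d_seq)
    ct, cd = target.window_start + 8, donor.window_start + 8
    zone_from_donor = _junction_zone(dw)
    zone_from_target = _junction_zone(tw)

    if target.topology == "linear" and donor.topology == "linear":
        pa = _product(
            "junction-A-product",
            "linear",
            [(t_seq[:ct], "target"), (d_seq[cd:], "donor")],
            [(ct - 3, zone_from_donor, "donor")],
        )
        pb = _product(
            "junction-B-product",
            "linear",
            [(d_seq[:cd], "donor"), (t_seq[ct:], "target")],
            [(cd - 3, zone_from_target, "target")],
        )
        molecules = (pa, pb)
    elif target.topology == "linear" and donor.topology == "circular":
        rotated = d_seq[cd:] + d_seq[:cd]
        molecules = (
            _product(
                "insertion-product",
                "linear",
                [(t_seq[:ct], "target"), (rotated, "donor"), (t_seq[ct:], "target")],
                [
                    (ct - 3, zone_from_donor, "donor"),
                    (ct + ld - 3, zone_from_target, "target"),
                ],
            ),
        )
    elif target.topology == "circular" and donor.topology == "linear":
        rotated = t_seq[ct:] + t_seq[:ct]
        molecules = (
            _product(
                "insertion-product",
                "linear",
                [(d_seq[:cd], "donor"), (rotated, "target"), (d_seq[cd:], "donor")],
                [
                    (cd - 3, zone_from_target, "target"),
                    (cd + lt - 3, zone_from_donor, "donor"),
                ],
            ),
        )
    else:  # both circular: one fused circle
        molecules = (
            _product(
                "fusion-circle",
                "circular",
                [(t_seq[ct:] + t_seq[:ct], "target"), (d_seq[cd:] + d_seq[:cd], "donor")],
                [
                    (lt - 3, zone_from_donor, "donor"),
                    (lt + ld - 3, zone_from_target, "target"),
                ],
            ),
        )
    return RecombinationProducts(
        junction_a=ja, junction_b=jb, molecules=molecules, notes=final.notes
    )


def recombine_intramolecular(
    molecule: SubstrateMolecule,
    second_window_start: int,
    b: BridgeRNA,
    inverted: bool = False,
) -> RecombinationProducts:
    """Recombine two sites on one linear molecule: excision or inversion.

    The molecule's own window is the target site; ``second_window_start`` marks
    the donor site.  In direct orientation the intervening segment is excised
    as a circle; in inverted orientation (the second window read on the reverse
    strand) the segment is inverted in place.
    """
    if molecule.topology != "linear":
        raise ValueError("intramolecular recombination is modelled on linear molecules")
    pa, pb = molecule.window_start, second_window_start
    if pb < pa:
        raise ValueError("second window must lie downstream of the molecule's window")
    if pb < pa + WINDOW_LENGTH:
        raise ValueError("the two windows overlap")
    s_seq = molecule.sequence
    if pb + WINDOW_LENGTH - 1 > len(s_seq):
        raise ValueError("second window does not fit within the sequence")
    wa = make_window(s_seq[pa - 1 : pa + 13], role="target")
    wb_top = s_seq[pb - 1 : pb + 13]
    if inverted:
        wb_top = revcomp_dna(wb_top)
    wb = make_window(wb_top, role="donor")
    traj = run(form_synapse((b, wa), (b, wb)))
    final = traj[-1]
    if final.stage is Stage.LOCKED:
        raise ProductsUnavailable(
            f"reaction locked before strand exchange ({final.lock_reason})", traj
        )
    ja, jb = final.junctions()
    c1, c2 = pa + 8, pb + 8

    if not inverted:
        backbone = _product(
            "deletion-backbone",
            "linear",
            [(s_seq[:c1], "flank-5p"), (s_seq[c2:], "flank-3p")],
            [(c1 - 3, _junction_zone(wb), "flank-3p")],
        )
        circle = _product(
            "excised-circle",
            "circular",
            [(s_seq[c1:c2], "segment")],
            [(c2 - c1 - 3, _junction_zone(wa), "flank-5p")],
        )
        molecules = (backbone, circle)
    else:
        mid = revcomp_dna(s_seq[pa + 4 : pb + 4])  # coords pa+5 .. pb+4 inclusive
        molecules = (
            _product(
                "inversion-product",
                "linear",
                [
                    (s_seq[:c1], "flank-5p"),
                    (mid, "inverted-segment"),
                    (s_seq[pb + 8 :], "flank-3p"),
                ],
                [
                    (pa + 5, _junction_zone(wb), "inverted-segment"),
                    (pb + 5, "".join(comp_dna(c) for c in s_seq[pb + 4 : pb + 8]), "flank-3p"),
                ],
            ),
        )
    return RecombinationProducts(
        junction_a=ja, junction_b=jb, molecules=molecules, notes=final.notes
    )


def repair(p: RecombinationProducts, policy: str = "leave") -> RecombinationProducts:
    """Resolve heteroduplex positions to one strand's bases.

    ``top-wins`` rewrites the bottom strand to the complement of the top,
    ``bottom-wins`` the reverse, ``leave`` returns the input unchanged.
    Repaired positions inherit the winning strand's parent label.
    """
    if policy == "leave":
        return p
    if policy not in ("top-wins", "bottom-wins"):
        raise ValueError(f"unknown repair policy {policy!r}")

    def fix_junction(j: JunctionWindow) -> JunctionWindow:
        top = list(j.top)
        bottom = list(j.bottom)
        p_top = list(j.parents_top)
        p_bot = list(j.parents_bottom)
        for i in j.heteroduplex:
            jpos = star(i)
            if policy == "top-wins":
                bottom[jpos - 1] = comp_dna(top[i - 1])
                p_bot[jpos - 1] = p_top[i - 1]
            else:
                top[i - 1] = comp_dna(bottom[jpos - 1])
                p_top[i - 1] = p_bot[jpos - 1]
        return JunctionWindow(
            name=j.name,
            top="".join(top),
            bottom="".join(bottom),
            parents_top=tuple(p_top),
            parents_bottom=tuple(p_bot),
        )

    def fix_molecule(m: ProductMolecule) -> ProductMolecule:
        top = list(m.top)
        ab = list(m.bottom_aligned)
        p_top = list(m.parents_top)
        p_ab = list(m.parents_bottom_aligned)
        for pos in m.heteroduplex:
            i = pos - 1
            if policy == "top-wins":
                ab[i] = comp_dna(top[i])
                p_ab[i] = p_top[i]
            else:
                top[i] = comp_dna(ab[i])
                p_top[i] = p_ab[i]
        return ProductMolecule(
            name=m.name,
            top="".join(top),
            bottom_aligned="".join(ab),
            topology=m.topology,
            parents_top=tuple(p_top),
            parents_bottom_aligned=tuple(p_ab),
        )

    return RecombinationProducts(
        junction_a=fix_junction(p.junction_a),
        junction_b=fix_junction(p.junction_b),
        molecules=tuple(fix_molecule(m) for m in p.molecules),
        notes=p.notes + (f"heteroduplex repaired with policy {policy}",),
    )
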