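"""Reprogramming the bridge-RNA scaffold against a target and a donor window.

Each guide region is written as the Watson-Crick RNA complement of the DNA
strand it physically pairs, in antiparallel register:

* LTG (9 nt)  <-> target bottom 14*..6*      * LDG (8 nt)  <-> donor bottom 14*..7*
* RTG (4 nt)  <-> target top 11..8           * RDG (7 nt)  <-> donor top 14..8
* RTG extension (3 nt, optional) <-> target top 14..12  (skips 159-160 spacers)
* HSG-T (81-82) and HSG-D (166-167) <-> top positions 7, 6 of a window that
  depends on the handshake mode.

The handshake guides (HSGs) gate strand exchange: programmed against the
*non-cognate* DNA ("post-HSB", the productive default) they pair only after
top-strand exchange and pull the reaction forward; programmed against the
*cognate* DNA ("pre-HSB") they pair before exchange and trap the synaptic
complex in a locked, non-productive state.  The lock prediction flags a design
whenever any HSG position can pair its cognate top strand under the permissive
policy — the single-point behaviour seen when position 166 is mutated to pair
the donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .nucleic import guide_base_for
from .pairing import PairClass, classify_pair
from .scaffold import BridgeRNA
from .substrate import CoreReport, DnaWindow, Verdict, validate_core

HSG_MODES = ("post-hsb", "pre-hsb", "keep-scaffold")

#: region -> (window slot, DNA strand, DNA positions faced by the region's
#: guide positions in ascending scaffold order).  Bottom positions are starred.
GUIDE_REGISTERS: dict[str, tuple[str, str, tuple[int, ...]]] = {
    "ltg": ("target", "bottom", (14, 13, 12, 11, 10, 9, 8, 7, 6)),
    "rtg": ("target", "top", (11, 10, 9, 8)),
    "rtg-extension": ("target", "top", (14, 13, 12)),
    "ldg": ("donor", "bottom", (14, 13, 12, 11, 10, 9, 8, 7)),
    "rdg": ("donor", "top", (14, 13, 12, 11, 10, 9, 8)),
}

#: HSG guide regions face top positions 7, 6; the window depends on the mode.
HSG_REGISTER = (7, 6)


class DesignError(ValueError):
    """The design inputs are unusable (bad core, missing region map, ...)."""


class CoreVerdictError(DesignError):
    """A window failed core validation (position 9 is not T)."""


class PreHsbWarning(UserWarning):
    """A pre-HSB design was requested: experimentally non-productive (locks)."""


class CoreMismatchWarning(UserWarning):
    """Target and donor cores differ: products will carry a junction heteroduplex at 8-9."""


@dataclass(frozen=True)
class DesignOptions:
    """Knobs for the design engine.

    ``rtg_extension`` additionally programs positions 74-76 against target top
    14..12 (stabilizes the synaptic complex).  ``hsg_mode`` picks the handshake
    programming; ``keep-scaffold`` leaves HSG bases untouched for orthologue
    scaffolds.  ``policy`` is the pairing policy used for *validation* only —
    generated guides are always Watson-Crick.
    """

    rtg_extension: bool = True
    hsg_mode: str = "post-hsb"
    policy: str = "permissive"

    def __post_init__(self) -> None:
        if self.hsg_mode not in HSG_MODES:
            raise DesignError(f"unknown hsg_mode {self.hsg_mode!r}")


@dataclass(frozen=True)
class DiagramEntry:
    """One row of the pairing diagram: guide position <-> DNA strand/position."""

    region: str
    guide_position: int
    guide_base: str
    window: str  # 'target' | 'donor'
    strand: str  # 'top' | 'bottom'
    dna_position: int  # starred numbering when strand == 'bottom'
    dna_base: str
    pair_class: PairClass
    paired: bool

    @property
    def dna_label(self) -> str:
        mol = "t" if self.window == "target" else "d"
        st = "*" if self.strand == "bottom" else ""
        return f"{mol}{self.dna_base}{self.dna_position}{st}"


@dataclass(frozen=True)
class DesignReport:
    """Full per-region pairing diagram plus core checks and the lock prediction."""

    diagram: tuple[DiagramEntry, ...]
    guide_mismatches: tuple[DiagramEntry, ...]
    core_target: CoreReport
    core_donor: CoreReport
    cores_match: bool
    locked: bool
    lock_pairs: tuple[DiagramEntry, ...]
    hsg_mode: str
    policy: str
    rewritten_positions: tuple[int, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "diagram": [
                {
                    "region": e.region,
                    "guide_position": e.guide_position,
                    "guide_base": e.guide_base,
                    "window": e.window,
                    "strand": e.strand,
                    "dna_position": e.dna_position,
                    "dna_base": e.dna_base,
                    "pair_class": e.pair_class.value,
                    "paired": e.paired,
                }
                for e in self.diagram
            ],
            "guide_mismatches": [
                [e.region, e.guide_position] for e in self.guide_mismatches
            ],
            "core_target": self.core_target.core,
            "core_donor": self.core_donor.core,
            "core_target_verdict": self.core_target.verdict.value,
            "core_donor_verdict": self.core_donor.verdict.value,
            "cores_match": self.cores_match,
            "locked": self.locked,
            "hsg_mode": self.hsg_mode,
            "policy": self.policy,
            "rewritten_positions": list(self.rewritten_positions),
        }

    def format_table(self) -> str:
        """Human-readable pairing diagram (one guide:DNA row per position)."""
        lines = [f"{'region':<14} {'bRNA':>8}  pair  DNA"]
        mark = {PairClass.WATSON_CRICK: "|", PairClass.WOBBLE: ":", PairClass.MISMATCH: "x"}
        for e in self.diagram:
            lines.append(
                f"{e.region:<14} {e.guide_base}{e.guide_position:<7} "
                f"  {mark[e.pair_class]}   {e.dna_label}"
            )
        lines.append(
            f"cores: target {self.core_target.core} / donor {self.core_donor.core}"
            f" ({'match' if self.cores_match else 'MISMATCH'})"
        )
        lines.append(f"lock prediction: {'LOCKED' if self.locked else 'not locked'}")
        return "\n".join(lines)


def _window_base(w: DnaWindow, strand: str, pos: int) -> str:
    return w.top_at(pos) if strand == "top" else w.bottom_at(pos)


def _region_entries(
    b: BridgeRNA,
    region: str,
    window_name: str,
    w: DnaWindow,
    strand: str,
    dna_positions: tuple[int, ...],
    policy: str,
) -> list[DiagramEntry]:
    try:
        guide_positions = b.positions(region)
    except KeyError as exc:
        raise DesignError(f"scaffold lacks region {region!r} in its region map") from exc
    if len(guide_positions) != len(dna_positions):
        raise DesignError(
            f"region {region!r} spans {len(guide_positions)} positions, "
            f"register expects {len(dna_positions)}"
        )
    entries = []
    for gp, dp in zip(guide_positions, dna_positions):
        base = _window_base(w, strand, dp)
        cls, paired = classify_pair(b.base(gp), base, policy)
        entries.append(
            DiagramEntry(
                region=region,
                guide_position=gp,
                guide_base=b.base(gp),
                window=window_name,
                strand=strand,
                dna_position=dp,
                dna_base=base,
                pair_class=cls,
                paired=paired,
            )
        )
    return entries


def _hsg_partners(hsg_mode: str) -> dict[str, str]:
    # post-HSB pairs the non-cognate window; pre-HSB the cognate one.
    if hsg_mode == "pre-hsb":
        return {"hsg-t": "target", "hsg-d": "donor"}
    return {"hsg-t": "donor", "hsg-d": "target"}


def cognate_hsg_entries(
    b: BridgeRNA, target: DnaWindow, donor: DnaWindow, policy: str = "permissive"
) -> list[DiagramEntry]:
    """HSG positions scored against their *cognate* top strands (the lock test)."""
    entries = []
    for region, w, name in (("hsg-t", target, "target"), ("hsg-d", donor, "donor")):
        entries.extend(
            _region_entries(b, region, name, w, "top", HSG_REGISTER, policy)
        )
    return entries


def validate_design(
    b: BridgeRNA,
    target: DnaWindow,
    donor: DnaWindow,
    opts: DesignOptions | None = None,
) -> DesignReport:
    """Evaluate every guide region of ``b`` against its assigned strand/positions.

    Nothing is modified.  The lock prediction is computed from the cognate HSG
    pairing under the permissive policy regardless of ``opts.policy``.
    """
    opts = opts or DesignOptions()
    windows = {"target": target, "donor": donor}
    diagram: list[DiagramEntry] = []
    core_regions = ["ltg", "rtg"] + (["rtg-extension"] if opts.rtg_extension else [])
    core_regions += ["ldg", "rdg"]
    for region in core_regions:
        slot, strand, dna_positions = GUIDE_REGISTERS[region]
        diagram.extend(
            _region_entries(b, region, slot, windows[slot], strand, dna_positions, opts.policy)
        )
    partners = _hsg_partners(opts.hsg_mode)
    hsg_entries: list[DiagramEntry] = []
    for region in ("hsg-t", "hsg-d"):
        slot = partners[region]
        hsg_entries.extend(
            _region_entries(b, region, slot, windows[slot], "top", HSG_REGISTER, opts.policy)
        )
    diagram.extend(hsg_entries)

    mismatch_pool = diagram if opts.hsg_mode != "keep-scaffold" else diagram[: -len(hsg_entries)]
    guide_mismatches = tuple(e for e in mismatch_pool if e.pair_class is PairClass.MISMATCH)

    lock_pairs = tuple(
        e for e in cognate_hsg_entries(b, target, donor, "permissive") if e.paired
    )
    return DesignReport(
        diagram=tuple(diagram),
        guide_mismatches=guide_mismatches,
        core_target=validate_core(target),
        core_donor=validate_core(donor),
        cores_match=target.core == donor.core,
        locked=bool(lock_pairs),
        lock_pairs=lock_pairs,
        hsg_mode=opts.hsg_mode,
        policy=opts.policy,
    )


def design_bridge_rna(
    scaffold: BridgeRNA,
    target: DnaWindow,
    donor: DnaWindow,
    opts: DesignOptions | None = None,
) -> tuple[BridgeRNA, DesignReport]:
    """Rewrite the scaffold's programmable positions against two windows.

    Both windows must pass core validation; differing cores are allowed but
    flagged (the recombination junction will carry a heteroduplex at positions
    8-9).  Emitted guides are Watson-Crick complements of the strand each guide
    physically pairs; all positions outside the programmable mask are returned
    byte-identical.
    """
    opts = opts or DesignOptions()
    for name, w in (("target", target), ("donor", donor)):
        if validate_core(w).verdict is Verdict.FAIL:
            raise CoreVerdictError(
                f"{name} window core {w.core!r} fails validation (position 9 must be T)"
            )
    if target.core != donor.core:
        warnings.warn(
            f"target core {target.core} != donor core {donor.core}: products will "
            "carry a junction heteroduplex at positions 8-9",
            CoreMismatchWarning,
            stacklevel=2,
        )
    if opts.hsg_mode == "pre-hsb":
        warnings.warn(
            "pre-HSB handshake programming pairs the cognate DNA before strand "
            "exchange: the synaptic complex will lock and recombination will not "
            "be productive",
            PreHsbWarning,
            stacklevel=2,
        )

    windows = {"target": target, "donor": donor}
    writes: dict[int, str] = {}
    regions = ["ltg", "rtg"] + (["rtg-extension"] if opts.rtg_extension else [])
    regions += ["ldg", "rdg"]
    for region in regions:
        slot, strand, dna_positions = GUIDE_REGISTERS[region]
        try:
            guide_positions = scaffold.positions(region)
        except KeyError as exc:
            raise DesignError(f"scaffold lacks region {region!r} in its region map") from exc
        if len(guide_positions) != len(dna_positions):
            raise DesignError(f"region {region!r} does not match its register length")
        for gp, dp in zip(guide_positions, dna_positions):
            writes[gp] = guide_base_for(_window_base(windows[slot], strand, dp))
    if opts.hsg_mode != "keep-scaffold":
        partners = _hsg_partners(opts.hsg_mode)
        for region in ("hsg-t", "hsg-d"):
            w = windows[partners[region]]
            for gp, dp in zip(scaffold.positions(region), HSG_REGISTER):
                writes[gp] = guide_base_for(w.top_at(dp))

    outside = set(writes) - set(scaffold.programmable_mask)
    if outside:
        raise DesignError(f"design would write outside the programmable mask: {sorted(outside)}")

    designed = scaffold.with_bases(writes)
    report = replace(
        validate_design(designed, target, donor, opts),
        rewritten_positions=tuple(sorted(writes)),
    )
    return designed, report
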