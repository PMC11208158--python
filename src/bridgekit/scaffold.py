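"""Bridge-RNA scaffold model: sequence, region annotation and engineered variants.

The reference scaffold is the 177-nt IS621 bridge RNA.  It carries a 5' stem
loop followed by two pseudo-symmetric modules: the target-binding loop (TBL,
positions 34-98) and the donor-binding loop (DBL, positions 110-177).  Each
module holds a left guide pairing the bottom strand of its DNA (LTG / LDG), a
right guide pairing the top strand (RTG / RDG), a short handshake guide (HSG)
that pairs the *other* DNA's top strand after strand exchange, and structural
stems/linkers that the design engine never rewrites.  Eight nucleotides
(flipped-out A's and syn-conformation G's) are conserved across the family and
are refused as write targets.

Coordinates are 1-based closed intervals throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from .nucleic import ensure_rna

logger = logging.getLogger(__name__)

REFERENCE_LENGTH = 177

#: Reference region map.  The 5' stem-loop boundary (1..31) is inferred from the
#: scaffold length (177 nt) and the length of the stem-loop deletion mutant
#: (146 nt); the internal stem registers of the TBL/DBL are deliberately not
#: modelled (intervals only) because design never rewrites them.
DEFAULT_REGIONS: dict[str, tuple[tuple[int, int], ...]] = {
    "5p-stem-loop": ((1, 31),),
    "tbl": ((34, 98),),
    "dbl": ((110, 177),),
    "ltg": ((50, 58),),
    "rtg": ((77, 80),),
    "rtg-extension": ((74, 76),),
    "hsg-t": ((81, 82),),
    "ldg": ((123, 130),),
    "rdg": ((157, 158), (161, 161), (162, 165)),
    "rdg-spacers": ((159, 160),),
    "hsg-d": ((166, 167),),
    "tbl-linkers": ((47, 49), (59, 59), (72, 73), (83, 86)),
    "dbl-linkers": ((121, 122), (131, 132), (155, 156), (168, 168)),
    "dbl-sl": ((137, 147),),
}

#: Conserved nucleotides (position -> required base): flipped-out adenosines and
#: syn-conformation guanosines shared across the IS110 family.
CONSERVED: dict[int, str] = {
    43: "A", 67: "A", 116: "A", 150: "A",
    48: "G", 72: "G", 121: "G", 155: "G",
}

#: Regions the design engine is allowed to rewrite.
PROGRAMMABLE_REGIONS = ("ltg", "rtg", "rtg-extension", "hsg-t", "ldg", "rdg", "hsg-d")

#: Top-level regions; every other region must nest inside one of these.
_CONTAINERS = ("5p-stem-loop", "tbl", "dbl")

#: One character per region for the flat annotation-string export.
_ANNOTATION_CHARS = {
    "5p-stem-loop": "s",
    "tbl": "t",
    "dbl": "d",
    "ltg": "L",
    "rtg": "R",
    "rtg-extension": "r",
    "hsg-t": "H",
    "ldg": "l",
    "rdg": "G",
    "rdg-spacers": "x",
    "hsg-d": "h",
    "tbl-linkers": "-",
    "dbl-linkers": "=",
    "dbl-sl": "S",
}

DELETE_5P_STEM_LOOP = "delete-5p-stem-loop"
DBLSL_GAAA_TETRALOOP = "dblsl-gaaa-tetraloop"
POINT_SUBSTITUTIONS = "point-substitutions"

VARIANT_KINDS = (DELETE_5P_STEM_LOOP, DBLSL_GAAA_TETRALOOP, POINT_SUBSTITUTIONS)


class ScaffoldError(ValueError):
    """Invalid scaffold sequence, region map or variant."""


class ConservedPositionError(ScaffoldError):
    """A write was attempted at a family-conserved scaffold position."""


class ConservationWarning(UserWarning):
    """A loaded scaffold deviates from a family-conserved base (orthologue?)."""


def _region_length(regions: dict[str, tuple[tuple[int, int], ...]]) -> int:
    return max(end for ivs in regions.values() for _, end in ivs)


def _positions(intervals: tuple[tuple[int, int], ...]) -> list[int]:
    out: list[int] = []
    for start, end in intervals:
        out.extend(range(start, end + 1))
    return out


def _validate_regions(regions: dict[str, tuple[tuple[int, int], ...]], length: int) -> None:
    for name, ivs in regions.items():
        for start, end in ivs:
            if not (1 <= start <= end <= length):
                raise ScaffoldError(
                    f"region {name!r} interval ({start}, {end}) outside 1..{length}"
                )
    containers = {n: set(_positions(regions[n])) for n in _CONTAINERS if n in regions}
    # containers must be pairwise disjoint
    names = list(containers)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if containers[a] & containers[b]:
                raise ScaffoldError(f"regions {a!r} and {b!r} overlap")
    # sub-regions nest inside a container and are pairwise disjoint
    subs = {n: set(_positions(ivs)) for n, ivs in regions.items() if n not in _CONTAINERS}
    for name, pos in subs.items():
        if containers and not any(pos <= cpos for cpos in containers.values()):
            raise ScaffoldError(f"region {name!r} does not nest inside a top-level region")
    sub_names = list(subs)
    for i, a in enumerate(sub_names):
        for b in sub_names[i + 1:]:
            if subs[a] & subs[b]:
                raise ScaffoldError(f"regions {a!r} and {b!r} overlap")


@dataclass(frozen=True)
class BridgeRNA:
    """An annotated bridge-RNA scaffold.

    ``sequence`` uses 1-based positions 1..L; ``regions`` maps region names to
    closed intervals; ``conserved`` maps positions to required bases;
    ``programmable_mask`` is the set of positions the design engine may rewrite.
    """

    sequence: str
    regions: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    conserved: dict[int, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def programmable_mask(self) -> frozenset[int]:
        mask: set[int] = set()
        for name in PROGRAMMABLE_REGIONS:
            if name in self.regions:
                mask.update(_positions(self.regions[name]))
        return frozenset(mask)

    def base(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def positions(self, region: str) -> list[int]:
        """All positions of a region, ascending."""
        if region not in self.regions:
            raise KeyError(f"no region {region!r} in this scaffold")
        return _positions(self.regions[region])

    def with_bases(self, writes: dict[int, str]) -> "BridgeRNA":
        """Return a copy with ``writes`` (position -> RNA base) applied.

        Writing a conserved position is an error naming the position.
        """
        seq = list(self.sequence)
        for pos, base in writes.items():
            if pos in self.conserved:
                raise ConservedPositionError(
                    f"position {pos} is conserved ({self.conserved[pos]}) and cannot be rewritten"
                )
            if not 1 <= pos <= self.length:
                raise IndexError(f"position {pos} outside 1..{self.length}")
            seq[pos - 1] = ensure_rna(base, f"base for position {pos}", length=1)
        return BridgeRNA(sequence="".join(seq), regions=self.regions, conserved=self.conserved)

    def annotation_string(self) -> str:
        """Flat per-position region annotation (documentation aid, not structure).

        Sub-regions override their container's character; unannotated positions
        are dots.
        """
        chars = ["."] * self.length
        order = [n for n in _CONTAINERS if n in self.regions] + [
            n for n in self.regions if n not in _CONTAINERS
        ]
        for name in order:
            c = _ANNOTATION_CHARS.get(name, "?")
            for pos in _positions(self.regions[name]):
                chars[pos - 1] = c
        return "".join(chars)


@dataclass(frozen=True)
class ScaffoldVariant:
    """An engineered scaffold variant.

    ``kind`` is one of :data:`VARIANT_KINDS`; ``substitutions`` is used only by
    the point-substitutions kind.
    """

    kind: str
    substitutions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ScaffoldError(f"unknown variant kind {self.kind!r}")


def load_scaffold(
    sequence: str,
    regions: dict[str, tuple[tuple[int, int], ...]] | None = None,
    conserved: dict[int, str] | None = None,
) -> BridgeRNA:
    """Annotate a scaffold sequence with a region map.

    ``T`` is silently converted to ``U`` (logged).  The sequence length must
    equal the region map's last coordinate.  Deviations from the conserved
    bases are reported as :class:`ConservationWarning` (user scaffolds may be
    orthologues); *writes* to conserved positions are errors.
    """
    regions = dict(DEFAULT_REGIONS) if regions is None else dict(regions)
    conserved = dict(CONSERVED) if conserved is None else dict(conserved)
    seq = sequence.upper()
    if "T" in seq:
        logger.info("converted %d T nucleotide(s) to U on scaffold load", seq.count("T"))
        seq = seq.replace("T", "U")
    seq = ensure_rna(seq, "scaffold")
    expected = _region_length(regions)
    if len(seq) != expected:
        raise ScaffoldError(
            f"scaffold length {len(seq)} does not match region map length {expected}"
        )
    _validate_regions(regions, len(seq))
    for pos, base in sorted(conserved.items()):
        if seq[pos - 1] != base:
            warnings.warn(
                f"conserved position {pos}: expected {base}, found {seq[pos - 1]}",
                ConservationWarning,
                stacklevel=2,
            )
    return BridgeRNA(sequence=seq, regions=regions, conserved=conserved)


def _shift_regions(
    regions: dict[str, tuple[tuple[int, int], ...]],
    block: tuple[int, int],
    replacement_len: int,
) -> dict[str, tuple[tuple[int, int], ...]]:
    bs, be = block
    delta = replacement_len - (be - bs + 1)
    out: dict[str, tuple[tuple[int, int], ...]] = {}
    for name, ivs in regions.items():
        new_ivs: list[tuple[int, int]] = []
        for s, e in ivs:
            if e < bs:
                new_ivs.append((s, e))
            elif s > be:
                new_ivs.append((s + delta, e + delta))
            elif s == bs and e == be:
                if replacement_len:
                    new_ivs.append((s, s + replacement_len - 1))
                # else: interval excised entirely
            elif s >= bs and e <= be:
                pass  # nested inside the edited block: dropped
            elif s <= bs and e >= be:
                new_ivs.append((s, e + delta))  # interval contains the edited block
            else:
                raise ScaffoldError(
                    f"region {name!r} interval ({s}, {e}) straddles edit block ({bs}, {be})"
                )
        if new_ivs:
            out[name] = tuple(new_ivs)
    return out


def _edit_block(b: BridgeRNA, block: tuple[int, int], replacement: str) -> BridgeRNA:
    bs, be = block
    seq = b.sequence[: bs - 1] + replacement + b.sequence[be:]
    regions = _shift_regions(b.regions, block, len(replacement))
    delta = len(replacement) - (be - bs + 1)
    conserved: dict[int, str] = {}
    for pos, base in b.conserved.items():
        if pos < bs:
            conserved[pos] = base
        elif pos > be:
            conserved[pos + delta] = base
        else:
            raise ConservedPositionError(
                f"variant would remove conserved position {pos} ({base})"
            )
    return BridgeRNA(sequence=seq, regions=regions, conserved=conserved)


def apply_variant(b: BridgeRNA, v: ScaffoldVariant) -> BridgeRNA:
    """Apply an engineered variant, re-indexing downstream annotation.

    * ``delete-5p-stem-loop`` removes the 5' stem loop (177 -> 146 nt on the
      reference map) and shifts all downstream coordinates.
    * ``dblsl-gaaa-tetraloop`` replaces the 11-nt DBL stem-loop block with a
      GAAA tetraloop (177 -> 170 nt), abolishing the synapsis-licensing contact.
    * ``point-substitutions`` rewrites individual bases; conserved positions
      are refused.
    """
    if v.kind == DELETE_5P_STEM_LOOP:
        if "5p-stem-loop" not in b.regions:
            raise ScaffoldError("scaffold has no annotated 5' stem loop")
        (block,) = b.regions["5p-stem-loop"]
        return _edit_block(b, block, "")
    if v.kind == DBLSL_GAAA_TETRALOOP:
        if "dbl-sl" not in b.regions:
            raise ScaffoldError("scaffold has no annotated DBL stem loop")
        (block,) = b.regions["dbl-sl"]
        return _edit_block(b, block, "GAAA")
    # point substitutions
    return b.with_bases({pos: base for pos, base in v.substitutions})


def regions_to_json(regions: dict[str, tuple[tuple[int, int], ...]]) -> str:
    """Serialize a region map deterministically (sorted keys, closed intervals)."""
    payload = {name: [list(iv) for iv in ivs] for name, ivs in regions.items()}
    return json.dumps(payload, sort_keys=True, indent=1)


def regions_from_json(text: str) -> dict[str, tuple[tuple[int, int], ...]]:
    payload = json.loads(text)
    return {
        name: tuple((int(s), int(e)) for s, e in ivs) for name, ivs in payload.items()
    }
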