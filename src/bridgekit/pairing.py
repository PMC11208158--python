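"""RNA-DNA base-pair classification and guide/segment evaluation.

Watson-Crick pairs (RNA base : DNA base) are A:T, U:A, G:C and C:G.  The
wobble class holds G:T (seen in the wild-type guide/DNA duplexes) and U:G
(included for policy symmetry; distinguishable via the pair class if a caller
wants to tighten it).  Everything else is a mismatch.

Two pairing policies are used throughout the toolkit: ``strict`` counts only
Watson-Crick pairs as paired; ``permissive`` additionally counts wobble pairs.
Validation defaults to permissive (the wild-type system functions with G.T
pairs); design generation always emits Watson-Crick-only guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .nucleic import ensure_dna, ensure_rna

WATSON_CRICK_PAIRS = frozenset({("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "T"), ("U", "G")})

POLICIES = ("strict", "permissive")


class PairClass(str, Enum):
    WATSON_CRICK = "watson-crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


class PairingError(ValueError):
    pass


def classify_pair(
    rna_base: str, dna_base: str, policy: str = "permissive"
) -> tuple[PairClass, bool]:
    """Classify one RNA:DNA pair and say whether it counts as paired."""
    if policy not in POLICIES:
        raise PairingError(f"unknown policy {policy!r}")
    r = ensure_rna(rna_base, "RNA base", length=1)
    d = ensure_dna(dna_base, "DNA base", length=1)
    if (r, d) in WATSON_CRICK_PAIRS:
        cls = PairClass.WATSON_CRICK
    elif (r, d) in WOBBLE_PAIRS:
        cls = PairClass.WOBBLE
    else:
        cls = PairClass.MISMATCH
    paired = cls is PairClass.WATSON_CRICK or (
        policy == "permissive" and cls is PairClass.WOBBLE
    )
    return cls, paired


@dataclass(frozen=True)
class PairingReport:
    """Position-by-position pair classes for a guide segment, in guide coordinates."""

    classes: tuple[PairClass, ...]
    paired: tuple[bool, ...]
    policy: str

    @property
    def counts(self) -> dict[PairClass, int]:
        return {cls: sum(1 for c in self.classes if c is cls) for cls in PairClass}

    @property
    def n_paired(self) -> int:
        return sum(self.paired)

    @property
    def all_paired(self) -> bool:
        return all(self.paired)


def evaluate_segment(
    guide: str, dna: str, antiparallel: bool = True, policy: str = "permissive"
) -> PairingReport:
    """Score a guide (5'->3') against a DNA segment (5'->3').

    With ``antiparallel=True`` the guide is scored against the DNA read
    3'->5', i.e. guide position k faces the DNA base ``dna[-k]``.
    """
    guide = ensure_rna(guide, "guide")
    dna = ensure_dna(dna, "dna")
    if len(guide) != len(dna):
        raise PairingError(
            f"guide length {len(guide)} != DNA length {len(dna)}"
        )
    faced = dna[::-1] if antiparallel else dna
    classes = []
    paired = []
    for r, d in zip(guide, faced):
        cls, ok = classify_pair(r, d, policy)
        classes.append(cls)
        paired.append(ok)
    return PairingReport(classes=tuple(classes), paired=tuple(paired), policy=policy)
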