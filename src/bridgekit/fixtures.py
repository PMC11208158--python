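"""Seeded synthetic fixtures: site pairs and placeholder scaffolds.

The generator emulates reprogrammable recombination jobs: each fixture is a
pair of WT-complementary 14-bp windows with the canonical CT core at positions
8-9 and random flanks, plus a 177-nt placeholder scaffold carrying the eight
family-conserved bases at their reference positions (everything else random).

Window positions 6-7 of the donor are resampled until the pair is
*handshake-compatible*: a post-HSB design against the pair must not be
predicted to lock (no guide written against one window's positions 6-7 may
also pair the other window's positions 6-7, wobble included).  Site pairs that
coincide there are not designable productively, so they are excluded from the
fixture population — lock behaviour itself is exercised with dedicated
constructs, not with these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nucleic import guide_base_for
from .pairing import classify_pair
from .scaffold import CONSERVED, REFERENCE_LENGTH, BridgeRNA, load_scaffold
from .substrate import DnaWindow, make_window

_BASES = np.array(list("ACGT"))
_RNA_BASES = np.array(list("ACGU"))


def handshake_compatible(target: DnaWindow, donor: DnaWindow) -> bool:
    """True if a post-HSB design against this pair is lock-free.

    Checks, for window positions 7 and 6, that the guide complementary to one
    window's base cannot pair (WC or wobble) the other window's base — in both
    directions, since HSG-T is written against the donor and HSG-D against the
    target.
    """
    for pos in (7, 6):
        t, d = target.top_at(pos), donor.top_at(pos)
        if classify_pair(guide_base_for(d), t, "permissive")[1]:
            return False
        if classify_pair(guide_base_for(t), d, "permissive")[1]:
            return False
    return True


def random_window(rng: np.random.Generator, role: str = "target", core: str = "CT") -> DnaWindow:
    """A WT-complementary window with the given core at positions 8-9."""
    top = rng.choice(_BASES, size=14)
    top[7] = core[0]
    top[8] = core[1]
    return make_window("".join(top), role=role)


def random_scaffold(rng: np.random.Generator) -> BridgeRNA:
    """A 177-nt placeholder scaffold: conserved bases planted, the rest random."""
    seq = rng.choice(_RNA_BASES, size=REFERENCE_LENGTH)
    for pos, base in CONSERVED.items():
        seq[pos - 1] = base
    return load_scaffold("".join(seq))


@dataclass(frozen=True)
class FixtureSet:
    pairs: tuple[tuple[DnaWindow, DnaWindow], ...]
    scaffold: BridgeRNA


def generate_fixtures(seed: int, n_pairs: int) -> FixtureSet:
    """``n_pairs`` handshake-compatible (target, donor) window pairs + a scaffold.

    Deterministic under ``seed``; identical seeds give identical fixtures.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        target = random_window(rng, "target")
        donor = random_window(rng, "donor")
        while not handshake_compatible(target, donor):
            top = list(donor.top)
            top[5] = rng.choice(_BASES)
            top[6] = rng.choice(_BASES)
            donor = make_window("".join(top), role="donor")
        pairs.append((target, donor))
    return FixtureSet(pairs=tuple(pairs), scaffold=random_scaffold(rng))
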