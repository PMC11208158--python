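"""DNA substrates: the 14-bp recognition window, core rules and genome scanning.

Each recombination site is a 14-position duplex window.  The top strand is
numbered 1..14 (5'->3'); the bottom strand carries its own starred numbering
1*..14* (5'->3' on the complementary strand), so top position ``i`` sits across
from bottom position ``15 - i``.  The core dinucleotide occupies top positions
8-9 (complement at bottom 6*-7*): the T at position 9 is read by the protein
backbone and is effectively invariant, while position 8 tolerates C > G > A/T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

from .nucleic import comp_dna, ensure_dna, revcomp_dna

WINDOW_LENGTH = 14
CORE_POSITIONS = (8, 9)
TRAP_POSITIONS = (2, 3, 4, 5, 6, 7)

#: Ordinal core preference at position 8 (no numeric weights are implied).
_POSITION8_RANK = {"C": 0, "G": 1, "A": 2, "T": 2}


class SubstrateError(ValueError):
    """Invalid substrate window or molecule."""


class DoubleTrapError(SubstrateError):
    """trap_mismatches applied to a window already mismatched at positions 2-7."""


class ScanWarning(UserWarning):
    """A scan was run on a sequence that cannot hold a full window."""


class Verdict(str, Enum):
    PASS = "pass"
    PASS_WITH_WARNING = "pass-with-warning"
    FAIL = "fail"


def star(i: int) -> int:
    """Bottom-strand (starred) position across from top position ``i``."""
    return 15 - i


@dataclass(frozen=True)
class DnaWindow:
    """A 14-position duplex recognition window.

    ``top`` and ``bottom`` are both stored 5'->3'; ``bottom`` defaults to the
    reverse complement of ``top`` (a "WT-complementary" window).  Windows may
    deliberately violate complementarity (mismatch-trap constructs); per-
    position duplex mismatches are exposed in top coordinates.
    """

    top: str
    bottom: str
    role: str = "target"

    def __post_init__(self) -> None:
        object.__setattr__(self, "top", ensure_dna(self.top, "top strand", WINDOW_LENGTH))
        object.__setattr__(
            self, "bottom", ensure_dna(self.bottom, "bottom strand", WINDOW_LENGTH)
        )
        if self.role not in ("target", "donor"):
            raise SubstrateError(f"role must be 'target' or 'donor', got {self.role!r}")

    def top_at(self, i: int) -> str:
        return self.top[i - 1]

    def bottom_at(self, j: int) -> str:
        """Base at starred bottom position ``j*``."""
        return self.bottom[j - 1]

    def paired_bottom(self, i: int) -> str:
        """The bottom base physically across from top position ``i``."""
        return self.bottom[star(i) - 1]

    @property
    def core(self) -> str:
        return self.top[7:9]

    @property
    def mismatches(self) -> frozenset[int]:
        """Top positions whose duplex partner is not the complement."""
        return frozenset(
            i
            for i in range(1, WINDOW_LENGTH + 1)
            if self.paired_bottom(i) != comp_dna(self.top_at(i))
        )

    def is_complementary(self) -> bool:
        return not self.mismatches


def make_window(top: str, bottom: str | None = None, role: str = "target") -> DnaWindow:
    """Build a window; ``bottom`` defaults to the reverse complement of ``top``."""
    top = ensure_dna(top, "top strand", WINDOW_LENGTH)
    if bottom is None:
        bottom = revcomp_dna(top)
    return DnaWindow(top=top, bottom=bottom, role=role)


@dataclass(frozen=True)
class CoreReport:
    """Verdict on a window's core dinucleotide (top positions 8-9)."""

    core: str
    position9_ok: bool
    position8_class: str
    verdict: Verdict

    @property
    def rank(self) -> int:
        """Sort key for scan ranking: CT before GT before AT/TT; fail last."""
        if not self.position9_ok:
            return 99
        return _POSITION8_RANK[self.position8_class]


def validate_core(w: DnaWindow) -> CoreReport:
    """Apply the core rules: position 9 must be T; position 8 prefers C/G.

    The report is identical for target and donor roles.
    """
    p8, p9 = w.top_at(8), w.top_at(9)
    ok9 = p9 == "T"
    if not ok9:
        verdict = Verdict.FAIL
    elif p8 == "C":
        verdict = Verdict.PASS
    else:
        verdict = Verdict.PASS_WITH_WARNING
    return CoreReport(core=p8 + p9, position9_ok=ok9, position8_class=p8, verdict=verdict)


@dataclass(frozen=True)
class SubstrateMolecule:
    """A full-length top-strand sequence, optionally carrying one recognition window.

    ``window_start`` is the 1-based offset of window position 1 (``None`` for a
    molecule that is only being scanned); the window may wrap the origin iff
    the molecule is circular.
    """

    sequence: str
    topology: str = "linear"
    window_start: int | None = None
    role: str = "target"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", ensure_dna(self.sequence, "sequence"))
        if self.topology not in ("linear", "circular"):
            raise SubstrateError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        if self.role not in ("target", "donor"):
            raise SubstrateError(f"role must be 'target' or 'donor', got {self.role!r}")
        if self.window_start is not None:
            n = len(self.sequence)
            if not 1 <= self.window_start <= n:
                raise SubstrateError(f"window_start {self.window_start} outside 1..{n}")
            if self.topology == "linear" and self.window_start + WINDOW_LENGTH - 1 > n:
                raise SubstrateError("window does not fit within the linear sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def top_slice(self, start: int, length: int) -> str:
        """``length`` top-strand bases from 1-based ``start``, wrapping iff circular."""
        n = self.length
        if self.topology == "linear":
            if start < 1 or start + length - 1 > n:
                raise SubstrateError("slice outside linear sequence")
            return self.sequence[start - 1 : start - 1 + length]
        return "".join(self.sequence[(start - 1 + k) % n] for k in range(length))

    def window(self) -> DnaWindow:
        if self.window_start is None:
            raise SubstrateError("molecule has no designated window (window_start is None)")
        top = self.top_slice(self.window_start, WINDOW_LENGTH)
        return make_window(top, role=self.role)


@dataclass(frozen=True)
class ScanHit:
    """One candidate core placement found by :func:`scan_cores`.

    ``strand`` is ``+`` or ``-``; reverse-strand hits carry the coordinates of
    their own window on the reverse-complemented sequence.
    """

    window_start: int
    strand: str
    core: str
    report: CoreReport = field(compare=False)


def _scan_strand(seq: str, circular: bool, strand: str) -> list[ScanHit]:
    n = len(seq)
    hits = []
    starts = range(1, n + 1) if circular else range(1, n - WINDOW_LENGTH + 2)
    for start in starts:
        if circular:
            top = "".join(seq[(start - 1 + k) % n] for k in range(WINDOW_LENGTH))
        else:
            top = seq[start - 1 : start - 1 + WINDOW_LENGTH]
        report = validate_core(make_window(top))
        if report.verdict is not Verdict.FAIL:
            hits.append(ScanHit(window_start=start, strand=strand, core=report.core, report=report))
    return hits


def scan_cores(molecule: SubstrateMolecule) -> list[ScanHit]:
    """All window placements with T at position 9, on both strands, ranked.

    Ranking: CT first, then GT, then AT/TT; ties broken by ascending offset
    with the forward strand first.  A linear sequence shorter than a window
    yields an empty result with a warning.
    """
    seq = molecule.sequence
    circular = molecule.topology == "circular"
    if not circular and len(seq) < WINDOW_LENGTH:
        warnings.warn(
            f"sequence of {len(seq)} nt is shorter than a {WINDOW_LENGTH}-nt window",
            ScanWarning,
            stacklevel=2,
        )
        return []
    hits = _scan_strand(seq, circular, "+") + _scan_strand(revcomp_dna(seq), circular, "-")
    hits.sort(key=lambda h: (h.report.rank, h.window_start, 0 if h.strand == "+" else 1))
    return hits


def trap_mismatches(w: DnaWindow) -> DnaWindow:
    """Build the structural mismatch-trapping construct.

    Top positions 2-7 are each replaced by the complement of the original top
    base, guaranteeing a duplex mismatch at all six positions; the bottom
    strand and the core (8-9) are untouched.  Re-trapping an already-trapped
    window is refused.
    """
    existing = w.mismatches & set(TRAP_POSITIONS)
    if existing:
        raise DoubleTrapError(
            f"window already carries mismatches at positions {sorted(existing)}"
        )
    top = list(w.top)
    for i in TRAP_POSITIONS:
        top[i - 1] = comp_dna(top[i - 1])
    return replace(w, top="".join(top))
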