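"""Heat shock element (HSE) recognition.

An HSE is a run of at least three contiguous pentanucleotide units, each
unit being 5'-nGAAn-3' or its reverse complement 5'-nTTCn-3'.  Positions
2-4 of a unit carry the fixed core (GAA or TTC); positions 1 and 5 are
free.  A run with zero core mismatches is a *typical* HSE; a run with
exactly one core mismatch is a *varied* HSE, with the restriction that in
a three-unit run the mismatch may not fall on the G of the GAA core (the
C of the TTC core) of the first or last unit.

Coordinates are 0-based half-open internally.  Reporting uses 3'-anchored
coordinates: the last nucleotide of the scanned sequence is -1 and
intervals are inclusive on both ends.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import accumulate
from typing import Optional

__all__ = [
    "Orientation",
    "HSEClass",
    "ReportOverlaps",
    "ScanConfig",
    "PentamerUnit",
    "MismatchAnnotation",
    "HSEMatch",
    "SequenceAlphabetError",
    "WindowLengthError",
    "CoordinateError",
    "score_unit",
    "classify_window",
    "scan_sequence",
    "brute_force_scan",
    "to_3prime_coords",
    "from_3prime_start",
    "reverse_complement",
]

UNIT_LENGTH = 5

# IUPAC nucleotide codes; anything outside this set is rejected outright.
_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")

_RC_TABLE = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""


class WindowLengthError(ValueError):
    """A window cannot be decomposed into whole pentamer units."""


class CoordinateError(ValueError):
    """A coordinate conversion was requested outside the sequence."""


class Orientation(enum.Enum):
    GAA_TYPE = "GAA"
    TTC_TYPE = "TTC"

    @property
    def core(self) -> str:
        return self.value

    @property
    def protected_offset(self) -> int:
        """1-based offset of the invariant core base: the G of nGAAn, the C of nTTCn."""
        return 2 if self is Orientation.GAA_TYPE else 4

    @property
    def flipped(self) -> "Orientation":
        return (
            Orientation.TTC_TYPE
            if self is Orientation.GAA_TYPE
            else Orientation.GAA_TYPE
        )


class HSEClass(enum.Enum):
    TYPICAL = "typical"
    VARIED = "varied"


class ReportOverlaps(enum.Enum):
    ALL = "all"
    MERGE_IDENTICAL = "merge_identical"


@dataclass(frozen=True)
class ScanConfig:
    """Scanning rules.

    The defaults encode the published HSE definition; the flags exist so
    the stricter variants discussed in the HSE literature (orientation
    alternation, terminal-core protection for runs longer than three) can
    be switched on without touching the scanner.
    """

    min_units: int = 3
    max_mismatches: int = 1
    require_alternation: bool = False
    protect_terminal_core_only_when_three: bool = True
    report_overlaps: ReportOverlaps = ReportOverlaps.ALL

    def __post_init__(self) -> None:
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")


DEFAULT_CONFIG = ScanConfig()


@dataclass(frozen=True)
class MismatchAnnotation:
    """One core mismatch inside an HSE.

    ``pair_code`` renders as the observed base followed by the expected
    consensus base, e.g. ``"CA"`` for an observed C where A was expected.
    """

    unit_index: int  # 1-based index of the unit within the HSE; 0 = standalone unit
    position_in_unit: int  # 1-based offset within the unit, always 2..4
    observed: str
    expected: str
    at_protected_position: bool

    def __post_init__(self) -> None:
        if self.observed == self.expected:
            raise ValueError("a mismatch requires observed != expected")
        if not 2 <= self.position_in_unit <= 4:
            raise ValueError("core mismatches occur only at offsets 2..4")

    @property
    def pair_code(self) -> str:
        return self.observed + self.expected


@dataclass(frozen=True)
class PentamerUnit:
    """A scored 5-nt unit: best orientation and the mismatches under it."""

    sequence: str
    orientation: Orientation
    mismatches: tuple[MismatchAnnotation, ...] = ()

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


@dataclass(frozen=True)
class HSEMatch:
    """An accepted HSE with 3'-anchored inclusive coordinates."""

    sequence_id: str
    start_3prime: int
    end_3prime: int
    hse_sequence: str
    units: tuple[PentamerUnit, ...]
    n_units: int
    hse_class: HSEClass
    mismatch: Optional[MismatchAnnotation] = None
    seq_length: Optional[int] = field(default=None, compare=False)

    @property
    def start_0based(self) -> int:
        if self.seq_length is None:
            raise ValueError("match carries no sequence-length context")
        return self.seq_length + self.start_3prime

    @property
    def length(self) -> int:
        return self.end_3prime - self.start_3prime + 1

    @property
    def mismatch_code(self) -> str:
        """Observed+expected pair for varied HSEs, empty for typical ones."""
        return self.mismatch.pair_code if self.mismatch is not None else ""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _fold(seq: str) -> str:
    folded = seq.upper()
    bad = set(folded) - _ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"illegal character(s) {sorted(bad)!r}; expected IUPAC nucleotide codes"
        )
    return folded


@lru_cache(maxsize=4096)
def _score_unit_cached(pentamer: str) -> PentamerUnit:
    best: Optional[tuple[int, Orientation, tuple[MismatchAnnotation, ...]]] = None
    for orientation in (Orientation.GAA_TYPE, Orientation.TTC_TYPE):
        core = orientation.core
        mism = []
        for offset in (2, 3, 4):
            observed = pentamer[offset - 1]
            expected = core[offset - 2]
            if observed != expected:
                mism.append(
                    MismatchAnnotation(
                        unit_index=0,
                        position_in_unit=offset,
                        observed=observed,
                        expected=expected,
                        at_protected_position=(offset == orientation.protected_offset),
                    )
                )
        # GAA_TYPE is tried first, so it wins ties deterministically; ties
        # only arise with >=2 mismatches and are rejected downstream anyway.
        if best is None or len(mism) < best[0]:
            best = (len(mism), orientation, tuple(mism))
    assert best is not None
    return PentamerUnit(sequence=pentamer, orientation=best[1], mismatches=best[2])


def score_unit(pentamer: str) -> PentamerUnit:
    """Score a 5-nt unit against both nGAAn and nTTCn.

    Returns the orientation with the fewer core mismatches together with
    the mismatch annotations under that orientation.  Free positions
    (offsets 1 and 5) never contribute mismatches; N or any ambiguity
    code at a core position counts as a mismatch.
    """
    if len(pentamer) != UNIT_LENGTH:
        raise WindowLengthError(
            f"a unit is exactly {UNIT_LENGTH} nt, got {len(pentamer)}"
        )
    return _score_unit_cached(_fold(pentamer))


def to_3prime_coords(
    start_0based: int, length: int, seq_length: int
) -> tuple[int, int]:
    """Convert a 0-based interval to 3'-anchored inclusive coordinates.

    The last nucleotide of the sequence is -1, so a window of ``length``
    starting at ``start_0based`` spans ``(start_0based - seq_length,
    start_0based - seq_length + length - 1)``.
    """
    if length < 1:
        raise CoordinateError("length must be >= 1")
    if start_0based < 0 or start_0based + length > seq_length:
        raise CoordinateError(
            f"interval [{start_0based}, {start_0based + length}) outside "
            f"sequence of length {seq_length}"
        )
    start = start_0based - seq_length
    return start, start + length - 1


def from_3prime_start(start_3prime: int, seq_length: int) -> int:
    """Inverse of :func:`to_3prime_coords` for the start coordinate."""
    if not -seq_length <= start_3prime <= -1:
        raise CoordinateError(
            f"3'-anchored start {start_3prime} outside [-{seq_length}, -1]"
        )
    return seq_length + start_3prime


def _window_units(window: str) -> list[PentamerUnit]:
    units = []
    for i, off in enumerate(range(0, len(window), UNIT_LENGTH)):
        scored = _score_unit_cached(window[off : off + UNIT_LENGTH])
        if scored.mismatches:
            scored = replace(
                scored,
                mismatches=tuple(
                    replace(m, unit_index=i + 1) for m in scored.mismatches
                ),
            )
        units.append(scored)
    return units


def _protection_violated(units: list[PentamerUnit], config: ScanConfig) -> bool:
    """Terminal-core protection: no mismatch on the invariant G/C of the
    first or last unit.  By default only enforced for three-unit runs."""
    n = len(units)
    if config.protect_terminal_core_only_when_three and n != 3:
        return False
    for unit in (units[0], units[-1]):
        if any(m.at_protected_position for m in unit.mismatches):
            return True
    return False


def _alternation_violated(units: list[PentamerUnit]) -> bool:
    return any(
        a.orientation is b.orientation for a, b in zip(units, units[1:])
    )


def classify_window(
    window: str,
    config: ScanConfig = DEFAULT_CONFIG,
    sequence_id: str = "window",
) -> Optional[HSEMatch]:
    """Classify one candidate window as a typical/varied HSE, or reject.

    The window is decomposed into contiguous, non-overlapping pentamer
    units left to right.  Acceptance requires a total core-mismatch count
    within budget and, for three-unit runs, no mismatch at the protected
    terminal core positions.  Returns ``None`` on rejection.
    """
    folded = _fold(window)
    if len(folded) % UNIT_LENGTH != 0 or len(folded) < UNIT_LENGTH * config.min_units:
        raise WindowLengthError(
            f"window length {len(folded)} is not a multiple of {UNIT_LENGTH} "
            f">= {UNIT_LENGTH * config.min_units}"
        )
    units = _window_units(folded)
    total = sum(u.n_mismatches for u in units)
    if total > config.max_mismatches:
        return None
    if _protection_violated(units, config):
        return None
    if config.require_alternation and _alternation_violated(units):
        return None
    mismatches = [m for u in units for m in u.mismatches]
    start, end = to_3prime_coords(0, len(folded), len(folded))
    return HSEMatch(
        sequence_id=sequence_id,
        start_3prime=start,
        end_3prime=end,
        hse_sequence=folded,
        units=tuple(units),
        n_units=len(units),
        hse_class=HSEClass.TYPICAL if total == 0 else HSEClass.VARIED,
        mismatch=mismatches[0] if mismatches else None,
        seq_length=len(folded),
    )


def _build_match(
    seq: str,
    seq_id: str,
    frame: int,
    units: list[PentamerUnit],
    i: int,
    j: int,
) -> HSEMatch:
    start0 = frame + UNIT_LENGTH * i
    length = UNIT_LENGTH * (j - i + 1)
    run = [
        replace(
            u,
            mismatches=tuple(
                replace(m, unit_index=k + 1) for m in u.mismatches
            ),
        )
        if u.mismatches
        else u
        for k, u in enumerate(units[i : j + 1])
    ]
    mismatches = [m for u in run for m in u.mismatches]
    start3, end3 = to_3prime_coords(start0, length, len(seq))
    return HSEMatch(
        sequence_id=seq_id,
        start_3prime=start3,
        end_3prime=end3,
        hse_sequence=seq[start0 : start0 + length],
        units=tuple(run),
        n_units=j - i + 1,
        hse_class=HSEClass.TYPICAL if not mismatches else HSEClass.VARIED,
        mismatch=mismatches[0] if mismatches else None,
        seq_length=len(seq),
    )


def scan_sequence(
    seq: str,
    seq_id: str = "seq",
    config: ScanConfig = DEFAULT_CONFIG,
) -> list[HSEMatch]:
    """Report every maximal HSE run in ``seq`` on the given strand.

    All five pentamer frames are enumerated.  A run is maximal when
    extending it by one unit on either side would violate the mismatch
    budget, the terminal-protection rule or (if enabled) orientation
    alternation.  Because nGAAn and nTTCn are mutual reverse complements,
    a single-strand scan already captures both orientations.

    Matches are sorted by 3'-anchored start and identical intervals are
    reported once.
    """
    folded = _fold(seq)
    n = len(folded)
    min_len = UNIT_LENGTH * config.min_units
    if n < min_len:
        return []

    budget = config.max_mismatches
    collected: dict[tuple[int, int], HSEMatch] = {}

    for frame in range(UNIT_LENGTH):
        n_units = (n - frame) // UNIT_LENGTH
        if n_units < config.min_units:
            continue
        units = [
            _score_unit_cached(folded[frame + UNIT_LENGTH * k : frame + UNIT_LENGTH * (k + 1)])
            for k in range(n_units)
        ]
        m = [u.n_mismatches for u in units]
        csum = [0, *accumulate(m)]

        # alt_end[i]: last unit index of the alternating run starting at i
        if config.require_alternation:
            alt_end = [0] * n_units
            alt_end[-1] = n_units - 1
            for k in range(n_units - 2, -1, -1):
                alt_end[k] = (
                    alt_end[k + 1]
                    if units[k].orientation is not units[k + 1].orientation
                    else k
                )
        else:
            alt_end = None

        protected = [
            any(mm.at_protected_position for mm in u.mismatches) for u in units
        ]

        def accepted(i: int, j: int) -> bool:
            if i < 0 or j >= n_units or j - i + 1 < config.min_units:
                return False
            if csum[j + 1] - csum[i] > budget:
                return False
            if alt_end is not None and alt_end[i] < j:
                return False
            apply_protection = (
                (j - i + 1 == 3)
                if config.protect_terminal_core_only_when_three
                else True
            )
            if apply_protection and (protected[i] or protected[j]):
                return False
            return True

        # For each start i, the budget/alternation-feasible right edge is
        # monotone, so a two-pointer sweep finds it in O(n_units).
        j_edge = -1
        for i in range(n_units):
            if j_edge < i - 1:
                j_edge = i - 1
            while (
                j_edge + 1 < n_units
                and csum[j_edge + 2] - csum[i] <= budget
            ):
                j_edge += 1
            r = j_edge
            if alt_end is not None:
                r = min(r, alt_end[i])
            candidates = {r}
            if not config.protect_terminal_core_only_when_three:
                # a protected-core mismatch at unit q blocks windows ending
                # exactly at q, so the window ending at q-1 can be maximal
                for q in range(i, min(r + 1, n_units - 1) + 1):
                    if protected[q]:
                        candidates.add(q - 1)
            for j in candidates:
                if (
                    accepted(i, j)
                    and not accepted(i - 1, j)
                    and not accepted(i, j + 1)
                ):
                    match = _build_match(folded, seq_id, frame, units, i, j)
                    collected[(match.start_3prime, match.end_3prime)] = match

    return sorted(
        collected.values(), key=lambda h: (h.start_3prime, h.end_3prime)
    )


def brute_force_scan(
    seq: str,
    seq_id: str = "seq",
    config: ScanConfig = DEFAULT_CONFIG,
) -> list[HSEMatch]:
    """Exhaustive reference scanner (independent oracle for tests).

    Classifies every substring of length ``5*k`` for every feasible unit
    count ``k`` at every offset with :func:`classify_window`, then keeps
    only runs not extensible by one unit on either side.  Quadratic in
    sequence length; intended for sequences up to a few kilobases.
    """
    folded = _fold(seq)
    n = len(folded)
    accepted: set[tuple[int, int]] = set()
    # Enumerate windows per offset with unit count growing outward; once
    # the running mismatch total exceeds the budget every longer window at
    # this offset is rejected too, so the walk stops early.  Windows that
    # survive the budget walk are judged by classify_window itself.
    for off in range(0, n - UNIT_LENGTH * config.min_units + 1):
        total = 0
        k = 0
        while off + UNIT_LENGTH * (k + 1) <= n:
            unit = _score_unit_cached(
                folded[off + UNIT_LENGTH * k : off + UNIT_LENGTH * (k + 1)]
            )
            total += unit.n_mismatches
            if total > config.max_mismatches:
                break
            k += 1
            if k >= config.min_units:
                length = UNIT_LENGTH * k
                if classify_window(folded[off : off + length], config) is not None:
                    accepted.add((off, length))

    matches: dict[tuple[int, int], HSEMatch] = {}
    for off, length in sorted(accepted):
        left = (off - UNIT_LENGTH, length + UNIT_LENGTH)
        right = (off, length + UNIT_LENGTH)
        if left in accepted or right in accepted:
            continue
        window_match = classify_window(folded[off : off + length], config)
        assert window_match is not None
        start3, end3 = to_3prime_coords(off, length, n)
        match = HSEMatch(
            sequence_id=seq_id,
            start_3prime=start3,
            end_3prime=end3,
            hse_sequence=window_match.hse_sequence,
            units=window_match.units,
            n_units=window_match.n_units,
            hse_class=window_match.hse_class,
            mismatch=window_match.mismatch,
            seq_length=n,
        )
        matches[(start3, end3)] = match
    return sorted(matches.values(), key=lambda h: (h.start_3prime, h.end_3prime))
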