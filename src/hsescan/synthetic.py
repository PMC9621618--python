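"""Synthetic promoter backgrounds with planted HSEs, plus packaged fixtures.

The generator produces backgrounds that provably or verifiably contain no
HSE, then substitutes known typical/varied HSEs (or rejected decoys) at
chosen 3'-anchored positions, returning a ground-truth table.  This makes
every scanner behaviour testable without any genome download.

Two background modes:

* ``GC_ONLY`` — G/C-only sequence.  HSE-freeness is provable: every
  pentamer unit needs A or T at a fixed core position, so each unit costs
  at least one mismatch and three units always exceed the one-mismatch
  budget.
* ``RANDOM_REJECTED`` — i.i.d. A/C/G/T background at a configurable GC
  content, with any window the exhaustive oracle accepts redrawn until
  the sequence is oracle-empty.

The module also packages the two printed tables this package's tests are
anchored on: the 17-row HSE table and the gene x cis-element presence
table for the nine wheat Fes1 homoeologues.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    DEFAULT_CONFIG,
    HSEClass,
    ScanConfig,
    brute_force_scan,
    classify_window,
    from_3prime_start,
)

__all__ = [
    "BackgroundMode",
    "SyntheticSpec",
    "PlantSpec",
    "PlantedTruth",
    "PlantingError",
    "generate_background",
    "plant",
    "realize",
    "HSETableRow",
    "load_hse_table_fixture",
    "hse_table_to_tsv",
    "parse_hse_table_tsv",
    "load_cis_element_fixture",
]

MIN_BACKGROUND_LENGTH = 15


class PlantingError(ValueError):
    """A plant specification is infeasible or corrupts the background."""


class BackgroundMode(enum.Enum):
    GC_ONLY = "gc_only"
    RANDOM_REJECTED = "random_rejected"


class ExpectedClass(enum.Enum):
    TYPICAL = "typical"
    VARIED = "varied"
    DECOY = "decoy"


@dataclass(frozen=True)
class PlantSpec:
    """One motif to substitute into a background.

    ``start_3prime`` follows the reporting convention (last base = -1).
    ``expected_class`` DECOY marks a sequence that must be *rejected* by
    the classifier (e.g. two mismatches, or a protected-position
    mismatch in a three-unit window).
    """

    hse_sequence: str
    start_3prime: int
    expected_class: ExpectedClass

    @property
    def end_3prime(self) -> int:
        return self.start_3prime + len(self.hse_sequence) - 1


@dataclass(frozen=True)
class PlantedTruth:
    hse_sequence: str
    start_3prime: int
    end_3prime: int
    expected_class: ExpectedClass


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic promoter: background plus plants."""

    length: int
    background_mode: BackgroundMode = BackgroundMode.GC_ONLY
    gc_content: float = 0.5
    seed: int = 0
    plants: tuple[PlantSpec, ...] = field(default_factory=tuple)


def generate_background(
    length: int,
    mode: BackgroundMode = BackgroundMode.GC_ONLY,
    gc_content: float = 0.5,
    seed: int = 0,
    config: ScanConfig = DEFAULT_CONFIG,
    max_rounds: int = 200,
) -> str:
    """Generate an HSE-free background sequence, deterministic per seed."""
    if length < MIN_BACKGROUND_LENGTH:
        raise ValueError(
            f"background must be >= {MIN_BACKGROUND_LENGTH} nt (one "
            f"three-unit window), got {length}"
        )
    rng = np.random.default_rng(seed)
    if mode is BackgroundMode.GC_ONLY:
        return "".join(rng.choice(["G", "C"], size=length))

    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    probs = [
        (1 - gc_content) / 2,
        gc_content / 2,
        gc_content / 2,
        (1 - gc_content) / 2,
    ]
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=probs))
    for _ in range(max_rounds):
        hits = brute_force_scan("".join(seq), config=config)
        if not hits:
            return "".join(seq)
        for hit in hits:
            start = from_3prime_start(hit.start_3prime, length)
            redraw = rng.choice(bases, size=hit.length, p=probs)
            seq[start : start + hit.length] = list(redraw)
    raise RuntimeError(
        f"could not clear background of HSEs within {max_rounds} rounds "
        f"(gc_content={gc_content})"
    )


def _check_plants(background: str, plants: Sequence[PlantSpec]) -> None:
    n = len(background)
    intervals = []
    for spec in plants:
        if spec.end_3prime > -1 or spec.start_3prime < -n:
            raise PlantingError(
                f"plant at {spec.start_3prime} (len {len(spec.hse_sequence)}) "
                f"does not fit a {n}-nt background"
            )
        intervals.append((spec.start_3prime, spec.end_3prime))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise PlantingError(
                f"planted intervals overlap: ({s1},{e1}) and ({s2},{e2})"
            )


def plant(
    background: str,
    plants: Sequence[PlantSpec],
    config: ScanConfig = DEFAULT_CONFIG,
    verify: bool = True,
) -> tuple[str, list[PlantedTruth]]:
    """Substitute HSEs/decoys into a background at 3'-anchored positions.

    Each non-decoy plant must itself classify as its declared class, and
    each decoy must be rejected; violations raise :class:`PlantingError`.
    With ``verify=True`` the planted sequence is re-scanned with the
    exhaustive oracle and any accepted window other than the declared
    truth (an accidental HSE straddling a junction) raises.  On GC-only
    backgrounds such accidents cannot occur.
    """
    _check_plants(background, plants)
    n = len(background)
    seq = list(background)
    truth: list[PlantedTruth] = []
    for spec in plants:
        match = classify_window(spec.hse_sequence, config)
        if spec.expected_class is ExpectedClass.DECOY:
            if match is not None:
                raise PlantingError(
                    f"decoy {spec.hse_sequence!r} is accepted by the classifier"
                )
        else:
            if match is None:
                raise PlantingError(
                    f"plant {spec.hse_sequence!r} is rejected by the classifier"
                )
            got = (
                ExpectedClass.TYPICAL
                if match.hse_class is HSEClass.TYPICAL
                else ExpectedClass.VARIED
            )
            if got is not spec.expected_class:
                raise PlantingError(
                    f"plant {spec.hse_sequence!r} classifies as {got.value}, "
                    f"declared {spec.expected_class.value}"
                )
            truth.append(
                PlantedTruth(
                    hse_sequence=spec.hse_sequence.upper(),
                    start_3prime=spec.start_3prime,
                    end_3prime=spec.end_3prime,
                    expected_class=spec.expected_class,
                )
            )
        start0 = from_3prime_start(spec.start_3prime, n)
        seq[start0 : start0 + len(spec.hse_sequence)] = list(
            spec.hse_sequence.upper()
        )
    planted = "".join(seq)
    if verify:
        expected = {(t.start_3prime, t.end_3prime) for t in truth}
        found = {
            (m.start_3prime, m.end_3prime)
            for m in brute_force_scan(planted, config=config)
        }
        extra = found - expected
        missing = expected - found
        if extra or missing:
            raise PlantingError(
                f"planting corrupted the truth table: unexpected {sorted(extra)}, "
                f"missing {sorted(missing)}"
            )
    truth.sort(key=lambda t: (t.start_3prime, t.end_3prime))
    return planted, truth


def realize(
    spec: SyntheticSpec, config: ScanConfig = DEFAULT_CONFIG, verify: bool = True
) -> tuple[str, list[PlantedTruth]]:
    """Generate the background of a :class:`SyntheticSpec` and plant into it."""
    background = generate_background(
        spec.length,
        spec.background_mode,
        spec.gc_content,
        spec.seed,
        config=config,
    )
    return plant(background, spec.plants, config=config, verify=verify)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_ANALYZED_RE = re.compile(r"^(\d+)(?:\s*\((\d+)\))?$")


@dataclass(frozen=True)
class HSETableRow:
    """One row of the packaged HSE table.

    ``utr_length`` is ``None`` for rows from the plain 2-kb analysis and
    an integer (possibly 0) for rows from the extended analysis, where
    the analyzed length is upstream-window + 5' UTR.
    """

    row_no: int
    gene: str
    start_3prime: int
    end_3prime: int
    hse_seq: str
    mismatch: str
    analyzed_length: int
    utr_length: Optional[int]

    @property
    def analyzed_length_rendered(self) -> str:
        if self.utr_length is None:
            return str(self.analyzed_length)
        return f"{self.analyzed_length} ({self.utr_length})"


HSE_TABLE_COLUMNS = (
    "No.",
    "Gene",
    "Position Start",
    "Position End",
    "HSE_seq",
    "Mismatch",
    "Analyzed sequence length",
)


def parse_hse_table_tsv(text: str) -> list[HSETableRow]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = tuple(lines[0].split("\t"))
    if header != HSE_TABLE_COLUMNS:
        raise ValueError(f"unexpected header {header!r}")
    rows = []
    for line in lines[1:]:
        no, gene, start, end, seq, mismatch, analyzed = line.split("\t")
        m = _ANALYZED_RE.match(analyzed.strip())
        if m is None:
            raise ValueError(f"cannot parse analyzed length {analyzed!r}")
        rows.append(
            HSETableRow(
                row_no=int(no),
                gene=gene,
                start_3prime=int(start),
                end_3prime=int(end),
                hse_seq=seq,
                mismatch=mismatch,
                analyzed_length=int(m.group(1)),
                utr_length=int(m.group(2)) if m.group(2) is not None else None,
            )
        )
    return rows


def hse_table_to_tsv(rows: Sequence[HSETableRow]) -> str:
    lines = ["\t".join(HSE_TABLE_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    str(r.row_no),
                    r.gene,
                    str(r.start_3prime),
                    str(r.end_3prime),
                    r.hse_seq,
                    r.mismatch,
                    r.analyzed_length_rendered,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _fixture_text(name: str) -> str:
    return (resources.files("hsescan.data") / name).read_text()


def load_hse_table_fixture() -> list[HSETableRow]:
    """The 17 varied HSEs found in the wheat Fes1 promoters."""
    return parse_hse_table_tsv(_fixture_text("fes1_hse_table.tsv"))


def load_cis_element_fixture():
    """Gene x cis-element presence matrix for the nine Fes1 homoeologues."""
    from .catalog import ElementPresenceMatrix

    with resources.as_file(
        resources.files("hsescan.data") / "fes1_cis_elements.tsv"
    ) as path:
        return ElementPresenceMatrix.from_tsv(path)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (for CLI export)."""
    with resources.as_file(resources.files("hsescan.data") / name) as p:
        return Path(p)
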