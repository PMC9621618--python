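"""Deterministic writers: HSE-table TSV, GFF3, and run manifests.

The TSV layout mirrors the printed HSE table: running number, gene,
3'-anchored inclusive start/end, the matched sequence, the mismatch as
an observed+expected two-letter code (empty for typical HSEs, which
carry no mismatch), and the analyzed sequence length, rendered as
``total (utr)`` for extended promoters.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .core import HSEMatch, ScanConfig
from .synthetic import HSETableRow, hse_table_to_tsv

__all__ = [
    "matches_to_rows",
    "write_hse_table_report",
    "write_gff3",
    "write_run_manifest",
]


def matches_to_rows(
    matches: Sequence[HSEMatch],
    analyzed_lengths: Optional[dict[str, int]] = None,
    utr_lengths: Optional[dict[str, Optional[int]]] = None,
    first_row_no: int = 1,
) -> list[HSETableRow]:
    """Convert scanner matches to report rows.

    ``analyzed_lengths`` overrides the per-sequence analyzed length
    (defaults to the scanned sequence length); ``utr_lengths`` supplies
    the 5' UTR portion for extended promoters (``None`` = plain mode).
    """
    rows = []
    for i, m in enumerate(matches):
        analyzed = (
            analyzed_lengths.get(m.sequence_id)
            if analyzed_lengths is not None
            else None
        )
        if analyzed is None:
            if m.seq_length is None:
                raise ValueError(
                    f"match on {m.sequence_id!r} has no analyzed length"
                )
            analyzed = m.seq_length
        utr = (
            utr_lengths.get(m.sequence_id)
            if utr_lengths is not None
            else None
        )
        rows.append(
            HSETableRow(
                row_no=first_row_no + i,
                gene=m.sequence_id,
                start_3prime=m.start_3prime,
                end_3prime=m.end_3prime,
                hse_seq=m.hse_sequence,
                mismatch=m.mismatch_code,
                analyzed_length=analyzed,
                utr_length=utr,
            )
        )
    return rows


def write_hse_table_report(
    rows: Sequence[HSETableRow], destination: Union[str, Path, TextIO]
) -> None:
    text = hse_table_to_tsv(rows)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(
    matches: Iterable[HSEMatch],
    destination: Union[str, Path, TextIO],
    source: str = "hsescan",
) -> None:
    """Write matches as 1-based GFF3 ``nucleotide_motif`` features."""
    lines = ["##gff-version 3"]
    for i, m in enumerate(
        sorted(matches, key=lambda x: (x.sequence_id, x.start_3prime)), 1
    ):
        if m.seq_length is None:
            raise ValueError("GFF3 output needs sequence-length context")
        start_1based = m.start_0based + 1
        end_1based = m.start_0based + m.length
        attrs = [
            f"ID=hse{i:05d}",
            f"hse_class={m.hse_class.value}",
            f"n_units={m.n_units}",
        ]
        if m.mismatch is not None:
            attrs.append(f"mismatch={_gff3_escape(m.mismatch_code)}")
        lines.append(
            "\t".join(
                [
                    _gff3_escape(m.sequence_id),
                    source,
                    "nucleotide_motif",
                    str(start_1based),
                    str(end_1based),
                    ".",
                    "+",
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def write_run_manifest(
    path: Union[str, Path],
    subcommand: str,
    inputs: dict,
    config: Optional[ScanConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Record what produced a set of outputs, for reproducibility audits."""
    from . import __version__

    def _plain(obj):
        if is_dataclass(obj):
            return {k: _plain(v) for k, v in asdict(obj).items()}
        if hasattr(obj, "value"):
            return obj.value
        return obj

    manifest = {
        "tool": "hsescan",
        "version": __version__,
        "python": platform.python_version(),
        "subcommand": subcommand,
        "inputs": inputs,
        "scan_config": _plain(config) if config is not None else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
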