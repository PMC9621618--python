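"""Cis-element repertoire comparison across homoeologue triads.

Hexaploid wheat genes typically exist as a triad: one copy per A, B and
D subgenome.  Given a gene x element presence matrix (e.g. parsed from a
PlantCARE result table), this module partitions each triad's element
repertoires into a three-set Venn: elements shared by all three
homoeologues, elements shared by exactly one pair, and
homoeologue-specific elements.  Differences in these sets are a first
hint that the homoeologues are wired to different regulatory programs.

Element identity is exact string equality after whitespace trimming; no
fuzzy merging is attempted (e.g. "MYB" and "MYB recognition site" are
distinct elements).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = [
    "ElementPresenceMatrix",
    "TriadComparison",
    "compare_triad",
    "elements_in_all_genes",
    "infer_triads",
]


def infer_triads(genes) -> dict[str, str]:
    """Derive triad ids from wheat-style gene names.

    ``TaFes1A-5A`` -> triad ``Fes1A`` (clade name without the species
    prefix and chromosome suffix).  Names without a ``-`` are left
    unassigned.
    """
    triads = {}
    for gene in genes:
        stem = gene.split("-", 1)[0]
        if "-" in gene and stem:
            triads[gene] = stem[2:] if stem.startswith("Ta") else stem
    return triads


class ElementPresenceMatrix:
    """Boolean gene x element table with an optional triad assignment."""

    def __init__(
        self,
        presence: pd.DataFrame,
        triad_assignment: Optional[Mapping[str, str]] = None,
    ) -> None:
        presence = presence.astype(bool)
        presence.index = presence.index.astype(str).str.strip()
        presence.columns = presence.columns.astype(str).str.strip()
        if presence.columns.duplicated().any():
            dupes = presence.columns[presence.columns.duplicated()].tolist()
            raise ValueError(f"duplicate element names after trimming: {dupes}")
        if presence.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.presence = presence
        self.triad_assignment = dict(
            triad_assignment
            if triad_assignment is not None
            else infer_triads(presence.index)
        )

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def elements(self) -> list[str]:
        return list(self.presence.columns)

    def elements_of(self, gene: str) -> frozenset[str]:
        row = self.presence.loc[gene]
        return frozenset(row.index[row])

    def triad_genes(self, triad_id: str) -> list[str]:
        return [
            g for g in self.genes if self.triad_assignment.get(g) == triad_id
        ]

    @property
    def triads(self) -> list[str]:
        seen = []
        for g in self.genes:
            t = self.triad_assignment.get(g)
            if t is not None and t not in seen:
                seen.append(t)
        return seen

    @classmethod
    def from_tsv(
        cls,
        path: Union[str, Path],
        triad_assignment: Optional[Mapping[str, str]] = None,
    ) -> "ElementPresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.astype(int).astype(bool), triad_assignment)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.presence.astype(int).to_csv(path, sep="\t")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElementPresenceMatrix):
            return NotImplemented
        return (
            self.presence.equals(other.presence)
            and self.triad_assignment == other.triad_assignment
        )


@dataclass(frozen=True)
class TriadComparison:
    """Three-set Venn partition of a triad's element repertoires.

    For each gene: ``specific[gene]``, the pairwise shares it belongs
    to, and ``shared_all`` partition its element set (pairwise disjoint,
    jointly exhaustive).
    """

    triad_id: str
    genes: tuple[str, str, str]
    shared_all: frozenset[str]
    shared_pairwise: dict[tuple[str, str], frozenset[str]]
    specific: dict[str, frozenset[str]]


def compare_triad(
    matrix: ElementPresenceMatrix, triad_id: str
) -> TriadComparison:
    """Venn-partition the element sets of a triad's three homoeologues."""
    genes = sorted(matrix.triad_genes(triad_id))
    if len(genes) != 3:
        raise ValueError(
            f"triad {triad_id!r} has {len(genes)} genes in the matrix; need 3"
        )
    sets = {g: matrix.elements_of(g) for g in genes}
    shared_all = frozenset(sets[genes[0]] & sets[genes[1]] & sets[genes[2]])
    pairwise = {}
    for a, b in combinations(genes, 2):
        (c,) = (g for g in genes if g not in (a, b))
        pairwise[(a, b)] = frozenset((sets[a] & sets[b]) - sets[c])
    specific = {}
    for g in genes:
        others = [sets[o] for o in genes if o != g]
        specific[g] = frozenset(sets[g] - others[0] - others[1])
    return TriadComparison(
        triad_id=triad_id,
        genes=tuple(genes),
        shared_all=shared_all,
        shared_pairwise=pairwise,
        specific=specific,
    )


def elements_in_all_genes(matrix: ElementPresenceMatrix) -> frozenset[str]:
    """Elements present in every gene of the matrix."""
    if not matrix.genes:
        raise ValueError("empty matrix")
    present_everywhere = matrix.presence.all(axis=0)
    return frozenset(present_everywhere.index[present_everywhere])
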