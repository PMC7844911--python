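"""Coordinate atoms and interval arithmetic shared across the toolkit.

All in-memory coordinates are 0-based, half-open ``[start, end)`` — BED's
native convention. GFF3 input (1-based, closed) is converted at the parsing
boundary, never downstream. Two intervals overlap iff they are on the same
molecule and their half-open spans intersect; intervals that merely abut
(share one endpoint) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span on a named molecule (chromosome, arm, or scaffold)."""

    molecule: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.molecule:
            raise ValueError("molecule name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.molecule == other.molecule
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.molecule != other.molecule:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.molecule == other.molecule
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class Peak:
    """A named interval emitted by a peak caller (MACS2 or similar)."""

    interval: GenomicInterval
    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("peak name must be non-empty")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped alignment record, reduced to the fields the matcher needs.

    ``interval`` is the full aligned reference extent (first to last aligned
    base, half-open). Only mapped records are materialized; readers drop
    unmapped ones at the boundary.
    """

    read_id: str
    interval: GenomicInterval
    mapq: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand and a merged, non-overlapping exon chain."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got "
                f"{self.interval.strand!r}"
            )
        prev_end = None
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{exon.start}, {exon.end}) on "
                    f"{exon.molecule} lies outside the gene span"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be merged and sorted"
                )
            prev_end = exon.end


class MoleculeTable(dict):
    """Mapping of molecule name to length in bp; the genome universe."""

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(lengths)
        for name, length in self.items():
            if not name:
                raise ValueError("molecule name must be non-empty")
            if length <= 0:
                raise ValueError(f"molecule {name}: length must be > 0, got {length}")

    @property
    def genome_bp(self) -> int:
        return sum(self.values())


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id}: FPKM must be >= 0")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand is dropped).

    Abutting intervals are coalesced: the result is the minimal set of
    disjoint spans covering the same bases.
    """
    by_molecule: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_molecule.setdefault(iv.molecule, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for molecule in sorted(by_molecule):
        spans = sorted(by_molecule[molecule])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                merged.append(GenomicInterval(molecule, cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append(GenomicInterval(molecule, cur_start, cur_end))
    return merged


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersection_bp(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Bases covered by both unions (merged A intersected with merged B)."""
    merged_a = merge_intervals(a)
    merged_b = merge_intervals(b)
    b_by_molecule: dict[str, list[GenomicInterval]] = {}
    for iv in merged_b:
        b_by_molecule.setdefault(iv.molecule, []).append(iv)
    total = 0
    for iv_a in merged_a:
        for iv_b in b_by_molecule.get(iv_a.molecule, ()):
            total += iv_a.overlap_bp(iv_b)
    return total


def subtract_intervals(
    span: GenomicInterval, cuts: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set-difference ``span`` minus the union of ``cuts`` on its molecule."""
    remaining: list[GenomicInterval] = []
    cursor = span.start
    for cut in merge_intervals(iv for iv in cuts if iv.molecule == span.molecule):
        if cut.end <= span.start or cut.start >= span.end:
            continue
        clipped_start = max(cut.start, span.start)
        clipped_end = min(cut.end, span.end)
        if clipped_start > cursor:
            remaining.append(GenomicInterval(span.molecule, cursor, clipped_start))
        cursor = max(cursor, clipped_end)
    if cursor < span.end:
        remaining.append(GenomicInterval(span.molecule, cursor, span.end))
    return remaining


def iter_molecules(intervals: Iterable[GenomicInterval]) -> Iterator[str]:
    seen: set[str] = set()
    for iv in intervals:
        if iv.molecule not in seen:
            seen.add(iv.molecule)
            yield iv.molecule
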