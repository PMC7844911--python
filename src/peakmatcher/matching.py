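"""The read-mediated peak-matching algorithm.

Peaks called from the same sequencing data on two different assembly
versions cannot be compared by coordinates — the coordinate systems are
unrelated. Instead, each peak is associated with the names of the reads
aligned inside it, once per assembly, and the two read-to-peak assignments
are joined on read name. Any (source peak, target peak) pair sharing at
least ``min_reads`` distinct reads becomes a match; the output is
many-to-many, so split, merged, and collapsed-duplicate loci all surface
naturally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .core import AlignedRead, Peak
from .index import build_index


@dataclass(frozen=True, order=True)
class ReadPeakPair:
    """One read observed inside one peak; the join-key carrier."""

    read_id: str
    peak_name: str


@dataclass(frozen=True, order=True)
class PeakMatch:
    """A source/target peak correspondence backed by shared reads."""

    source_peak: str
    target_peak: str
    shared_reads: int

    def __post_init__(self) -> None:
        if self.shared_reads < 1:
            raise ValueError("shared_reads must be >= 1")

    def transpose(self) -> "PeakMatch":
        return PeakMatch(self.target_peak, self.source_peak, self.shared_reads)


@dataclass(frozen=True)
class MatchSummary:
    source_total: int
    source_matched: int
    target_total: int
    target_matched: int

    @property
    def source_fraction(self) -> float:
        return self.source_matched / self.source_total if self.source_total else 0.0

    @property
    def target_fraction(self) -> float:
        return self.target_matched / self.target_total if self.target_total else 0.0


@dataclass
class MatchResult:
    matches: list[PeakMatch]
    summary: MatchSummary


def assign_reads_to_peaks(
    reads: Iterable[AlignedRead], peaks: list[Peak]
) -> list[ReadPeakPair]:
    """Associate each read with every peak it overlaps by >= 1 bp.

    Pairs are deduplicated on (read_id, peak): mates and secondary hits of
    one read name falling in the same peak collapse to a single pair.
    """
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        raise ValueError("peak names must be unique within one peak list")
    index = build_index((p.interval, p.name) for p in peaks)
    pairs: set[tuple[str, str]] = set()
    for read in reads:
        for peak_name in index.query(read.interval):
            pairs.add((read.read_id, peak_name))
    return [ReadPeakPair(r, p) for r, p in sorted(pairs)]


def join_matches(
    source_pairs: Iterable[ReadPeakPair],
    target_pairs: Iterable[ReadPeakPair],
    min_reads: int = 1,
) -> list[PeakMatch]:
    """Join the two read-to-peak assignments on read name.

    Every (source peak, target peak) pair sharing at least ``min_reads``
    distinct read names yields one match carrying the shared-read count.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    source_by_read: dict[str, set[str]] = {}
    for pair in source_pairs:
        source_by_read.setdefault(pair.read_id, set()).add(pair.peak_name)
    target_by_read: dict[str, set[str]] = {}
    for pair in target_pairs:
        target_by_read.setdefault(pair.read_id, set()).add(pair.peak_name)

    counts: dict[tuple[str, str], int] = {}
    for read_id, source_peaks in source_by_read.items():
        target_peaks = target_by_read.get(read_id)
        if not target_peaks:
            continue
        for source_peak in source_peaks:
            for target_peak in target_peaks:
                key = (source_peak, target_peak)
                counts[key] = counts.get(key, 0) + 1
    return [
        PeakMatch(source, target, count)
        for (source, target), count in sorted(counts.items())
        if count >= min_reads
    ]


def match_peak_sets(
    source_reads: Iterable[AlignedRead],
    source_peaks: list[Peak],
    target_reads: Iterable[AlignedRead],
    target_peaks: list[Peak],
    min_reads: int = 1,
) -> MatchResult:
    """Run both assignment steps and the join on in-memory inputs."""
    source_reads = list(source_reads)
    target_reads = list(target_reads)
    source_names = {r.read_id for r in source_reads}
    target_names = {r.read_id for r in target_reads}
    if source_names and target_names and not (source_names & target_names):
        warnings.warn(
            "no read names are shared between the two alignment sets; "
            "the inputs probably do not derive from the same sequencing data"
        )
    source_pairs = assign_reads_to_peaks(source_reads, source_peaks)
    target_pairs = assign_reads_to_peaks(target_reads, target_peaks)
    matches = join_matches(source_pairs, target_pairs, min_reads=min_reads)
    summary = MatchSummary(
        source_total=len(source_peaks),
        source_matched=len({m.source_peak for m in matches}),
        target_total=len(target_peaks),
        target_matched=len({m.target_peak for m in matches}),
    )
    return MatchResult(matches, summary)


def match_peaks(
    source_alignments: str | Path,
    source_peaks: str | Path,
    target_alignments: str | Path,
    target_peaks: str | Path,
    min_reads: int = 1,
    min_mapq: int = 10,
    keep_secondary: bool = False,
    dialect: str = "BED",
) -> MatchResult:
    """File-level entry point: two SAM/BAMs plus two peak lists in, matches out."""
    from . import io

    return match_peak_sets(
        io.read_alignments(source_alignments, min_mapq=min_mapq, keep_secondary=keep_secondary),
        io.read_peaks(source_peaks, dialect=dialect),
        io.read_alignments(target_alignments, min_mapq=min_mapq, keep_secondary=keep_secondary),
        io.read_peaks(target_peaks, dialect=dialect),
        min_reads=min_reads,
    )
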