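"""Per-molecule interval index for read-versus-peak overlap queries.

One balanced interval tree (:mod:`intervaltree`) is kept per molecule, so a
query touches only entries on the probe's molecule and costs O(log n + k)
for n entries and k hits. Query semantics are strictly half-open: ``[a, b)``
and ``[c, d)`` intersect iff ``a < d and c < b``, so abutting intervals
never match. Results are materialized and sorted (by start, end, then
payload) so downstream output is deterministic and independent of insertion
order.
"""

from __future__ import annotations

from typing import Any, Iterable

from intervaltree import IntervalTree

from .core import GenomicInterval

Entry = tuple[GenomicInterval, Any]


class IntervalIndex:
    """Searchable multiset of (interval, payload) entries.

    Duplicate identical entries are retained: each insertion carries a
    unique token, so two entries with equal spans and equal payloads are
    both returned by a query that hits them.
    """

    def __init__(self, entries: Iterable[Entry] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._count = 0
        for interval, payload in entries:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: Any) -> None:
        tree = self._trees.setdefault(interval.molecule, IntervalTree())
        tree.addi(interval.start, interval.end, (self._count, payload))
        self._count += 1

    def __len__(self) -> int:
        return self._count

    @property
    def molecules(self) -> list[str]:
        return sorted(self._trees)

    def count_for(self, molecule: str) -> int:
        tree = self._trees.get(molecule)
        return 0 if tree is None else len(tree)

    def query(self, probe: GenomicInterval) -> list[Any]:
        """Payloads of all entries intersecting ``probe``, sorted."""
        tree = self._trees.get(probe.molecule)
        if tree is None:
            return []
        hits = tree.overlap(probe.start, probe.end)
        # sort on payload repr before the insertion token so that the order
        # visible to callers does not depend on insertion order
        ordered = sorted(
            hits, key=lambda h: (h.begin, h.end, repr(h.data[1]), h.data[0])
        )
        return [h.data[1] for h in ordered]


def build_index(entries: Iterable[Entry]) -> IntervalIndex:
    return IntervalIndex(entries)


def query_overlaps(index: IntervalIndex, probe: GenomicInterval) -> list[Any]:
    return index.query(probe)
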