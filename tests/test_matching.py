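"""Read-to-peak assignment and the read-name join."""

import numpy as np
import pytest

from peakmatcher import (
    AlignedRead,
    GenomicInterval,
    Peak,
    PeakMatch,
    ReadPeakPair,
    assign_reads_to_peaks,
    join_matches,
    match_peak_sets,
)


def read(read_id, mol, start, end):
    return AlignedRead(read_id, GenomicInterval(mol, start, end), mapq=60)


def peak(name, mol, start, end):
    return Peak(GenomicInterval(mol, start, end), name)


# ------------------------------------------------------------- assignment

def test_assignment_requires_one_bp_overlap():
    peaks = [peak("pk", "chr1", 140, 300)]
    assert assign_reads_to_peaks([read("r1", "chr1", 100, 150)], peaks) == [
        ReadPeakPair("r1", "pk")
    ]
    # half-open abutment: no pair
    assert assign_reads_to_peaks([read("r2", "chr1", 100, 140)], peaks) == []


def test_mates_in_same_peak_collapse_to_one_pair():
    peaks = [peak("pk", "chr1", 0, 500)]
    mates = [read("r1", "chr1", 100, 150), read("r1", "chr1", 250, 300)]
    assert assign_reads_to_peaks(mates, peaks) == [ReadPeakPair("r1", "pk")]


def test_read_spanning_two_peaks_yields_two_pairs():
    peaks = [peak("a", "chr1", 0, 120), peak("b", "chr1", 110, 300)]
    pairs = assign_reads_to_peaks([read("r1", "chr1", 100, 130)], peaks)
    assert pairs == [ReadPeakPair("r1", "a"), ReadPeakPair("r1", "b")]


def test_duplicate_peak_names_rejected():
    peaks = [peak("pk", "chr1", 0, 10), peak("pk", "chr1", 20, 30)]
    with pytest.raises(ValueError, match="unique"):
        assign_reads_to_peaks([], peaks)


# ------------------------------------------------------------------- join

def test_join_counts_shared_reads():
    source = [ReadPeakPair("r1", "P1"), ReadPeakPair("r2", "P1")]
    target = [
        ReadPeakPair("r1", "Q1"),
        ReadPeakPair("r2", "Q1"),
        ReadPeakPair("r3", "Q2"),
    ]
    assert join_matches(source, target, min_reads=1) == [PeakMatch("P1", "Q1", 2)]


def test_join_split_peak_many_to_many():
    source = [ReadPeakPair(r, "P1") for r in ("r1", "r2", "r3", "r4")]
    target = [
        ReadPeakPair("r1", "Q1"),
        ReadPeakPair("r2", "Q1"),
        ReadPeakPair("r3", "Q2"),
        ReadPeakPair("r4", "Q2"),
    ]
    assert join_matches(source, target) == [
        PeakMatch("P1", "Q1", 2),
        PeakMatch("P1", "Q2", 2),
    ]


def test_join_min_reads_prunes_monotonically():
    rng = np.random.default_rng(3)
    source = [ReadPeakPair(f"r{i}", f"P{int(rng.integers(0, 5))}") for i in range(60)]
    target = [ReadPeakPair(f"r{i}", f"Q{int(rng.integers(0, 5))}") for i in range(60)]
    previous = None
    for k in (1, 2, 5):
        matches = join_matches(source, target, min_reads=k)
        as_set = {(m.source_peak, m.target_peak, m.shared_reads) for m in matches}
        if previous is not None:
            assert as_set <= previous  # surviving counts unchanged, set shrinks
        previous = as_set


def brute_force_join(source, target, min_reads):
    """Independent oracle: nested loop over all read-pair combinations."""
    counts = {}
    source_set, target_set = set(source), set(target)
    for rs, ps in source_set:
        for rt, pt in target_set:
            if rs == rt:
                counts.setdefault((ps, pt), set()).add(rs)
    return sorted(
        PeakMatch(s, t, len(reads))
        for (s, t), reads in counts.items()
        if len(reads) >= min_reads
    )


@pytest.mark.parametrize("seed", range(5))
def test_join_agrees_with_nested_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    source = [
        (f"r{int(rng.integers(0, 30))}", f"P{int(rng.integers(0, 6))}")
        for _ in range(50)
    ]
    target = [
        (f"r{int(rng.integers(0, 30))}", f"Q{int(rng.integers(0, 6))}")
        for _ in range(50)
    ]
    source_pairs = [ReadPeakPair(r, p) for r, p in set(source)]
    target_pairs = [ReadPeakPair(r, p) for r, p in set(target)]
    for k in (1, 2, 3):
        assert join_matches(source_pairs, target_pairs, k) == brute_force_join(
            source, target, k
        )


def test_join_rejects_min_reads_below_one():
    with pytest.raises(ValueError):
        join_matches([], [], min_reads=0)


# ------------------------------------------------------------- composition

def test_identity_assemblies_match_themselves(clean_sim):
    result = match_peak_sets(
        clean_sim.source_reads,
        clean_sim.source_peaks,
        clean_sim.source_reads,
        clean_sim.source_peaks,
    )
    identity = {(p.name, p.name) for p in clean_sim.source_peaks}
    assert {(m.source_peak, m.target_peak) for m in result.matches} == identity
    assert result.summary.source_fraction == 1.0


def test_match_symmetry_is_exact_transpose(clean_sim):
    forward = match_peak_sets(
        clean_sim.source_reads, clean_sim.source_peaks,
        clean_sim.target_reads, clean_sim.target_peaks,
    )
    backward = match_peak_sets(
        clean_sim.target_reads, clean_sim.target_peaks,
        clean_sim.source_reads, clean_sim.source_peaks,
    )
    assert sorted(m.transpose() for m in forward.matches) == backward.matches


def test_shared_reads_bounded_by_per_peak_read_counts(clean_sim):
    source_pairs = assign_reads_to_peaks(clean_sim.source_reads, clean_sim.source_peaks)
    target_pairs = assign_reads_to_peaks(clean_sim.target_reads, clean_sim.target_peaks)
    source_counts = {}
    for pair in source_pairs:
        source_counts[pair.peak_name] = source_counts.get(pair.peak_name, 0) + 1
    target_counts = {}
    for pair in target_pairs:
        target_counts[pair.peak_name] = target_counts.get(pair.peak_name, 0) + 1
    for match in join_matches(source_pairs, target_pairs):
        assert match.shared_reads <= min(
            source_counts[match.source_peak], target_counts[match.target_peak]
        )


def test_disjoint_read_names_warn_and_yield_nothing():
    peaks_a = [peak("a", "chr1", 0, 100)]
    peaks_b = [peak("b", "chr1", 0, 100)]
    with pytest.warns(UserWarning, match="no read names are shared"):
        result = match_peak_sets(
            [read("x1", "chr1", 10, 60)], peaks_a,
            [read("y1", "chr1", 10, 60)], peaks_b,
        )
    assert result.matches == []
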