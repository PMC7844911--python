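"""Simulator invariants: determinism, truth consistency, read-name conservation."""

import pytest

from peakmatcher import (
    GenomicInterval,
    MoleculeTable,
    io,
    simulate_assembly_pair,
    simulate_gene_models,
)
from peakmatcher.simulate import BlockMapping


def test_block_mapping_forward_and_inverted():
    source = GenomicInterval("s", 100, 200)
    target = GenomicInterval("t", 1000, 1100)
    probe = GenomicInterval("s", 110, 130, "+")
    forward = BlockMapping(source, target, 1)
    assert forward.map_interval(probe) == GenomicInterval("t", 1010, 1030, "+")
    inverted = BlockMapping(source, target, -1)
    assert inverted.map_interval(probe) == GenomicInterval("t", 1070, 1090, "-")
    with pytest.raises(ValueError, match="not contained"):
        forward.map_interval(GenomicInterval("s", 90, 130))


def test_identical_seed_gives_byte_identical_files(tmp_path):
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    simulate_assembly_pair(seed=21, n_peaks=10, background_reads=50, out_dir=dir_a)
    simulate_assembly_pair(seed=21, n_peaks=10, background_reads=50, out_dir=dir_b)
    for name in ("truth.tsv", "source.sam", "target.sam", "source_peaks.bed",
                 "target_peaks.bed", "blocks.tsv"):
        assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()


def test_different_seeds_differ(tmp_path):
    sim_a = simulate_assembly_pair(seed=1, n_peaks=10, background_reads=50)
    sim_b = simulate_assembly_pair(seed=2, n_peaks=10, background_reads=50)
    assert [p.interval for p in sim_a.source_peaks] != [
        p.interval for p in sim_b.source_peaks
    ]


def test_read_name_sets_identical_across_assemblies(clean_sim):
    source_names = {r.read_id for r in clean_sim.source_reads}
    target_names = {r.read_id for r in clean_sim.target_reads}
    assert source_names == target_names
    assert len(clean_sim.source_reads) == len(clean_sim.target_reads)


def test_truth_pairs_consistent_with_block_map(collapse_sim):
    """Transforming each source peak through its block lands in the target peak."""
    source_by_name = {p.name: p.interval for p in collapse_sim.source_peaks}
    target_by_name = {p.name: p.interval for p in collapse_sim.target_peaks}
    for source_name, target_name in collapse_sim.truth.peak_pairs:
        source_iv = source_by_name[source_name]
        target_iv = target_by_name[target_name]
        block = next(
            b for b in collapse_sim.truth.blocks if b.source.contains(source_iv)
        )
        mapped = block.map_interval(source_iv)
        assert (mapped.molecule, mapped.start, mapped.end) == (
            target_iv.molecule, target_iv.start, target_iv.end,
        )


def test_collapse_produces_many_to_one_truth(collapse_sim):
    targets = [t for _, t in collapse_sim.truth.peak_pairs]
    assert len(targets) > len(set(targets))
    # target genome is smaller than the source genome, as collapse implies
    assert (collapse_sim.truth.target_molecules.genome_bp
            < collapse_sim.truth.source_molecules.genome_bp)


def test_identity_regime_no_rearrangement():
    sim = simulate_assembly_pair(
        seed=5, n_molecules=2, blocks_per_molecule=1, collapse_fraction=0.0,
        invert_prob=0.0, n_target_molecules=2, n_peaks=8, background_reads=20,
    )
    # every truth pair is 1-to-1
    sources = [s for s, _ in sim.truth.peak_pairs]
    targets = [t for _, t in sim.truth.peak_pairs]
    assert len(set(sources)) == len(sources)
    assert len(set(targets)) == len(targets)


def test_infeasible_peak_count_raises():
    with pytest.raises(ValueError, match="cannot fit"):
        simulate_assembly_pair(seed=1, n_molecules=1, molecule_bp=10_000,
                               blocks_per_molecule=1, n_peaks=500)


def test_written_files_load_back(sim_dir):
    sim, out = sim_dir
    molecules = io.read_molecule_table(out / "source_molecules.tsv")
    assert molecules == sim.truth.source_molecules
    peaks = io.read_peaks(out / "source_peaks.bed")
    assert peaks == sim.source_peaks
    reads = list(io.read_alignments(out / "source.sam", min_mapq=0))
    assert {r.read_id for r in reads} == {r.read_id for r in sim.source_reads}
    spans = {(r.read_id, r.interval.molecule, r.interval.start, r.interval.end)
             for r in reads}
    expected = {(r.read_id, r.interval.molecule, r.interval.start, r.interval.end)
                for r in sim.source_reads}
    assert spans == expected


# ---------------------------------------------------------------- gene models

def test_gene_models_nonoverlapping_and_within_bounds(molecules):
    genes, records = simulate_gene_models(seed=3, molecules=molecules, n_genes=20)
    assert len(genes) == 20
    assert len(records) == 20
    by_molecule = {}
    for g in genes:
        by_molecule.setdefault(g.interval.molecule, []).append(g.interval)
        assert g.interval.end <= molecules[g.interval.molecule]
    for ivs in by_molecule.values():
        ordered = sorted(ivs, key=lambda iv: iv.start)
        for left, right in zip(ordered, ordered[1:]):
            assert left.end <= right.start


def test_gene_models_single_gene_gff3_round_trip(tmp_path, molecules):
    gff3 = tmp_path / "one.gff3"
    genes, _ = simulate_gene_models(seed=4, molecules=molecules, n_genes=1,
                                    gff3_path=gff3)
    (loaded,) = io.read_gene_models(gff3)
    assert loaded.gene_id == genes[0].gene_id
    assert loaded.interval == genes[0].interval
    assert loaded.exons == tuple(genes[0].exons)


def test_gene_models_infeasible_raises():
    with pytest.raises(ValueError, match="could not fit"):
        simulate_gene_models(seed=1, molecules=MoleculeTable({"m": 30_000}),
                             n_genes=500)
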