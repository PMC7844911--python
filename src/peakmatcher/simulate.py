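"""Synthetic two-assembly fixtures with known cross-assembly truth.

The generator emulates the situation the matcher is built for: one
sequencing experiment, two genome assemblies of the same organism. A
source assembly is cut into equal-sized blocks; a target assembly is built
by shuffling those blocks (translocation), optionally inverting them,
concatenating them into fewer molecules (scaffold joins — the target is a
more contiguous assembly), and collapsing chosen duplicate block pairs
onto a single target block (so the target genome is smaller, as happens
when an assembler resolves artifactual duplications). Peaks are placed
inside blocks on the source, transformed through the block map to give the
target peak list, and reads are sampled inside each peak plus a uniform
background; both alignment sets carry the same read names. Every expected
source/target peak correspondence is recorded in a truth table, including
the many-to-one pairs forced by duplicate collapse.

Reads have a fixed length (default 100 bp, a typical short-read length
after trimming) and uniform placement; base content, sequencing error and
quality realism are deliberately out of scope — the fixture exercises
coordinates and read names, which is all the matcher consumes.

A companion generator lays non-overlapping gene models onto a molecule
table and draws FPKM values whose high/low status can be tied to whether
the gene's promoter window is covered by a peak, giving the
expression-association test a null (effect 0) and an alternative regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .core import AlignedRead, GeneModel, GenomicInterval, MoleculeTable, Peak
from .elements import tss_windows
from .index import build_index
from . import io


@dataclass(frozen=True)
class BlockMapping:
    """One rearrangement block: a source span, its target span, orientation."""

    source: GenomicInterval
    target: GenomicInterval
    orientation: int  # +1 colinear, -1 inverted

    def __post_init__(self) -> None:
        if len(self.source) != len(self.target):
            raise ValueError("block source and target spans must have equal length")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")

    def map_interval(self, iv: GenomicInterval) -> GenomicInterval:
        """Transform a source-assembly interval inside this block to target coords."""
        if not self.source.contains(iv):
            raise ValueError("interval is not contained in the source block")
        rel_start = iv.start - self.source.start
        rel_end = iv.end - self.source.start
        if self.orientation > 0:
            start = self.target.start + rel_start
            end = self.target.start + rel_end
            strand = iv.strand
        else:
            length = len(self.source)
            start = self.target.start + length - rel_end
            end = self.target.start + length - rel_start
            strand = {"+": "-", "-": "+", ".": "."}[iv.strand]
        return GenomicInterval(self.target.molecule, start, end, strand)


@dataclass
class AssemblyPairTruth:
    source_molecules: MoleculeTable
    target_molecules: MoleculeTable
    blocks: list[BlockMapping]
    peak_pairs: list[tuple[str, str]]
    seed: int


@dataclass
class SimulatedAssemblyPair:
    truth: AssemblyPairTruth
    source_peaks: list[Peak]
    target_peaks: list[Peak]
    source_reads: list[AlignedRead]
    target_reads: list[AlignedRead]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit all fixture files (molecule TSVs, SAMs, BEDs, truth TSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "source_molecules": out / "source_molecules.tsv",
            "target_molecules": out / "target_molecules.tsv",
            "source_alignments": out / "source.sam",
            "target_alignments": out / "target.sam",
            "source_peaks": out / "source_peaks.bed",
            "target_peaks": out / "target_peaks.bed",
            "truth": out / "truth.tsv",
            "blocks": out / "blocks.tsv",
        }
        io.write_molecule_table(self.truth.source_molecules, paths["source_molecules"])
        io.write_molecule_table(self.truth.target_molecules, paths["target_molecules"])
        _write_sam(paths["source_alignments"], self.truth.source_molecules, self.source_reads)
        _write_sam(paths["target_alignments"], self.truth.target_molecules, self.target_reads)
        io.write_peaks(self.source_peaks, paths["source_peaks"])
        io.write_peaks(self.target_peaks, paths["target_peaks"])
        with open(paths["truth"], "w") as handle:
            handle.write("source_peak\ttarget_peak\n")
            for source, target in sorted(self.truth.peak_pairs):
                handle.write(f"{source}\t{target}\n")
        with open(paths["blocks"], "w") as handle:
            handle.write(
                "source_molecule\tsource_start\tsource_end\t"
                "target_molecule\ttarget_start\ttarget_end\torientation\n"
            )
            for block in self.truth.blocks:
                handle.write(
                    f"{block.source.molecule}\t{block.source.start}\t{block.source.end}\t"
                    f"{block.target.molecule}\t{block.target.start}\t{block.target.end}\t"
                    f"{'+' if block.orientation > 0 else '-'}\n"
                )
        return paths


def _write_sam(path: Path, molecules: MoleculeTable, reads: list[AlignedRead]) -> None:
    names = list(molecules)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": molecules[name]} for name in names],
    }
    ref_ids = {name: i for i, name in enumerate(names)}
    ordered = sorted(reads, key=lambda r: (ref_ids[r.interval.molecule], r.interval.start, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header, add_sam_header=True) as out:
        for read in ordered:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.flag = 16 if read.interval.strand == "-" else 0
            rec.reference_id = ref_ids[read.interval.molecule]
            rec.reference_start = read.interval.start
            rec.mapping_quality = read.mapq
            rec.cigarstring = f"{len(read.interval)}M"
            rec.query_sequence = "A" * len(read.interval)
            out.write(rec)


def simulate_assembly_pair(
    seed: int,
    n_molecules: int = 4,
    molecule_bp: int = 200_000,
    blocks_per_molecule: int = 3,
    collapse_fraction: float = 0.0,
    invert_prob: float = 0.25,
    n_target_molecules: int | None = None,
    n_peaks: int = 40,
    peak_width: int = 600,
    peak_gap: int = 400,
    reads_per_peak: int = 20,
    background_reads: int = 400,
    read_length: int = 100,
    out_dir: str | Path | None = None,
) -> SimulatedAssemblyPair:
    """Build a source/target assembly pair with known peak correspondence.

    ``collapse_fraction`` is the fraction of source blocks participating in
    duplicate pairs whose two copies share one target block; 0 disables
    collapse. With ``collapse_fraction=0`` every truth pair is strictly
    one-to-one. Raises if the requested peaks cannot fit in the block grid.
    """
    if n_molecules < 1 or molecule_bp < 1 or blocks_per_molecule < 1:
        raise ValueError("molecule and block counts must be positive")
    if not 0.0 <= collapse_fraction < 1.0:
        raise ValueError("collapse_fraction must lie in [0, 1)")
    if n_peaks < 1 or reads_per_peak < 1 or background_reads < 0:
        raise ValueError("peak and read counts must be positive")
    if peak_width <= read_length:
        raise ValueError("peak_width must exceed read_length")
    rng = np.random.default_rng(seed)

    block_size = molecule_bp // blocks_per_molecule
    if block_size <= peak_width + peak_gap:
        raise ValueError("blocks too small for the requested peak geometry")
    effective_molecule_bp = block_size * blocks_per_molecule
    source_molecules = MoleculeTable(
        {f"src_{m + 1}": effective_molecule_bp for m in range(n_molecules)}
    )
    source_blocks: list[GenomicInterval] = []
    for m in range(n_molecules):
        molecule = f"src_{m + 1}"
        for b in range(blocks_per_molecule):
            source_blocks.append(
                GenomicInterval(molecule, b * block_size, (b + 1) * block_size)
            )
    total_blocks = len(source_blocks)

    # choose duplicate pairs: the first n_dup blocks of a random permutation
    # are the collapsed copies, the next n_dup their retained partners
    n_dup = int(round(collapse_fraction * total_blocks / 2))
    permutation = [int(i) for i in rng.permutation(total_blocks)]
    dup_copies = permutation[:n_dup]
    dup_partners = permutation[n_dup : 2 * n_dup]
    partner_of_copy = dict(zip(dup_copies, dup_partners))
    copy_of_partner = dict(zip(dup_partners, dup_copies))
    dup_set = set(dup_copies)

    # lay the kept blocks onto the target assembly: shuffled order,
    # random inversion, contiguous chunks per target molecule
    kept = [i for i in range(total_blocks) if i not in dup_set]
    order = [kept[int(j)] for j in rng.permutation(len(kept))]
    if n_target_molecules is None:
        n_target_molecules = max(1, n_molecules // 2)
    n_target_molecules = min(n_target_molecules, len(order))
    chunks = np.array_split(np.array(order), n_target_molecules)
    mappings: dict[int, BlockMapping] = {}
    target_lengths: dict[str, int] = {}
    for t, chunk in enumerate(chunks):
        molecule = f"tgt_{t + 1}"
        cursor = 0
        for block_idx in chunk:
            block_idx = int(block_idx)
            orientation = -1 if rng.random() < invert_prob else 1
            target_iv = GenomicInterval(molecule, cursor, cursor + block_size)
            mappings[block_idx] = BlockMapping(
                source_blocks[block_idx], target_iv, orientation
            )
            cursor += block_size
        target_lengths[molecule] = cursor
    for copy_idx, partner_idx in partner_of_copy.items():
        partner_map = mappings[partner_idx]
        mappings[copy_idx] = BlockMapping(
            source_blocks[copy_idx], partner_map.target, partner_map.orientation
        )
    target_molecules = MoleculeTable(target_lengths)

    # peak slots: a regular grid inside each kept block, margins at both ends
    stride = peak_width + peak_gap
    margin = peak_gap // 2 + 1
    slots: list[tuple[int, int]] = []
    for block_idx in kept:
        offset = margin
        while offset + peak_width + margin <= block_size:
            slots.append((block_idx, offset))
            offset += stride
    if n_peaks > len(slots):
        raise ValueError(
            f"cannot fit {n_peaks} peaks: only {len(slots)} slots available"
        )
    chosen = sorted(int(i) for i in rng.choice(len(slots), size=n_peaks, replace=False))

    source_peaks: list[Peak] = []
    target_peaks: list[Peak] = []
    peak_pairs: list[tuple[str, str]] = []
    peak_blocks: list[int] = []  # block index per source peak
    for slot_idx in chosen:
        block_idx, offset = slots[slot_idx]
        block = source_blocks[block_idx]
        source_iv = GenomicInterval(
            block.molecule, block.start + offset, block.start + offset + peak_width
        )
        target_iv = mappings[block_idx].map_interval(source_iv)
        target_name = f"tgt_peak_{len(target_peaks) + 1:04d}"
        target_peaks.append(Peak(GenomicInterval(target_iv.molecule, target_iv.start, target_iv.end), target_name))
        source_name = f"src_peak_{len(source_peaks) + 1:04d}"
        source_peaks.append(Peak(source_iv, source_name))
        peak_blocks.append(block_idx)
        peak_pairs.append((source_name, target_name))
        if block_idx in copy_of_partner:
            # a collapsed duplicate copy of this block exists in the source:
            # mirror the peak there; both source peaks share one target peak
            copy_block = source_blocks[copy_of_partner[block_idx]]
            copy_iv = GenomicInterval(
                copy_block.molecule,
                copy_block.start + offset,
                copy_block.start + offset + peak_width,
            )
            copy_name = f"src_peak_{len(source_peaks) + 1:04d}"
            source_peaks.append(Peak(copy_iv, copy_name))
            peak_blocks.append(copy_of_partner[block_idx])
            peak_pairs.append((copy_name, target_name))

    source_reads: list[AlignedRead] = []
    target_reads: list[AlignedRead] = []

    def emit_read(read_id: str, source_iv: GenomicInterval, block_idx: int) -> None:
        target_iv = mappings[block_idx].map_interval(source_iv)
        source_reads.append(AlignedRead(read_id, source_iv, mapq=60))
        target_reads.append(AlignedRead(read_id, target_iv, mapq=60))

    read_counter = 0
    for peak, block_idx in zip(source_peaks, peak_blocks):
        iv = peak.interval
        for _ in range(reads_per_peak):
            start = iv.start + int(rng.integers(0, len(iv) - read_length + 1))
            strand = "-" if rng.random() < 0.5 else "+"
            read_counter += 1
            emit_read(
                f"read_{read_counter:06d}",
                GenomicInterval(iv.molecule, start, start + read_length, strand),
                block_idx,
            )
    for _ in range(background_reads):
        block_idx = int(rng.integers(0, total_blocks))
        block = source_blocks[block_idx]
        start = block.start + int(rng.integers(0, block_size - read_length + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        read_counter += 1
        emit_read(
            f"read_{read_counter:06d}",
            GenomicInterval(block.molecule, start, start + read_length, strand),
            block_idx,
        )

    truth = AssemblyPairTruth(
        source_molecules=source_molecules,
        target_molecules=target_molecules,
        blocks=[mappings[i] for i in sorted(mappings)],
        peak_pairs=sorted(peak_pairs),
        seed=seed,
    )
    result = SimulatedAssemblyPair(
        truth=truth,
        source_peaks=source_peaks,
        target_peaks=target_peaks,
        source_reads=source_reads,
        target_reads=target_reads,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def simulate_gene_models(
    seed: int,
    molecules: MoleculeTable,
    n_genes: int = 150,
    exons_per_gene: tuple[int, int] = (1, 4),
    gene_length: tuple[int, int] = (2_000, 6_000),
    gap_length: tuple[int, int] = (500, 2_000),
    peaks: list[Peak] | None = None,
    window_bp: int = 500,
    base_high_prob: float = 0.5,
    effect: float = 0.0,
    gff3_path: str | Path | None = None,
    expression_path: str | Path | None = None,
) -> tuple[list[GeneModel], list["io.ExpressionRecord"]]:
    """Place non-overlapping genes and draw FPKM values, optionally peak-linked.

    Expression mechanism: a gene is "high" (FPKM >= 1) with probability
    ``base_high_prob + effect`` when its TSS window is covered by a peak
    and ``base_high_prob - effect`` otherwise. ``effect=0`` is the exact
    null (overlap and expression independent); ``effect`` near 0.4 gives a
    strong, easily detected association. Raises if the genes cannot fit on
    the given molecules.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    lo_e, hi_e = exons_per_gene
    if lo_e < 1 or hi_e < lo_e:
        raise ValueError("exons_per_gene must be a non-empty positive range")
    lo_g, hi_g = gene_length
    if lo_g < 2 * hi_e + 2 or hi_g < lo_g:
        raise ValueError("gene_length range too small for the exon count")
    if not 0.0 <= base_high_prob <= 1.0 or abs(effect) > 1.0:
        raise ValueError("probabilities out of range")
    rng = np.random.default_rng(seed)

    genes: list[GeneModel] = []
    gene_idx = 0
    for molecule, length in molecules.items():
        position = window_bp + int(rng.integers(*gap_length))
        while gene_idx < n_genes:
            span = int(rng.integers(lo_g, hi_g + 1))
            if position + span + window_bp > length:
                break
            strand = "-" if rng.random() < 0.5 else "+"
            n_exons = int(rng.integers(lo_e, hi_e + 1))
            cuts = sorted(
                int(c) for c in rng.choice(span + 1, size=2 * n_exons, replace=False)
            )
            exon_ivs = [
                GenomicInterval(molecule, position + cuts[2 * k], position + cuts[2 * k + 1])
                for k in range(n_exons)
                if cuts[2 * k] < cuts[2 * k + 1]
            ]
            gene_idx += 1
            genes.append(
                GeneModel(
                    f"gene_{gene_idx:04d}",
                    GenomicInterval(molecule, position, position + span, strand),
                    tuple(exon_ivs),
                )
            )
            position += span + int(rng.integers(*gap_length))
        if gene_idx >= n_genes:
            break
    if gene_idx < n_genes:
        raise ValueError(
            f"could not fit {n_genes} genes on the given molecules (placed {gene_idx})"
        )

    overlapped: set[str] = set()
    if peaks:
        windows = tss_windows(genes, molecules, window_bp=window_bp)
        peak_index = build_index((p.interval, p.name) for p in peaks)
        for interval, gene_id in zip(windows.intervals, windows.names):
            if peak_index.query(interval):
                overlapped.add(gene_id)

    records = []
    for gene in genes:
        p_high = base_high_prob + (effect if gene.gene_id in overlapped else -effect)
        p_high = min(1.0, max(0.0, p_high))
        if rng.random() < p_high:
            fpkm = 1.0 + float(rng.exponential(30.0))
        else:
            fpkm = float(rng.uniform(0.0, 1.0))
        records.append(io.ExpressionRecord(gene.gene_id, fpkm))

    if gff3_path is not None:
        io.write_gff3(genes, gff3_path)
    if expression_path is not None:
        io.write_expression(records, expression_path)
    return genes, records
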