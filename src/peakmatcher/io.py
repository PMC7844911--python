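"""Readers and writers for the external formats the toolkit touches.

Peak lists arrive as BED3/BED4 or narrowPeak (columns past the name are
ignored); alignments as SAM/BAM via pysam; gene models as GFF3 via
gffutils; molecule lengths as a FASTA index (.fai) or any two-column
name/length TSV; expression as a two-column gene/FPKM TSV. All coordinates
are normalized to 0-based half-open on the way in.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pysam

from .core import (
    AlignedRead,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    MoleculeTable,
    Peak,
    merge_intervals,
)

PEAK_DIALECTS = ("BED", "narrowPeak")

_SKIP_PREFIXES = ("#", "track", "browser")


def read_peaks(path: str | Path, dialect: str = "BED") -> list[Peak]:
    """Load a BED-like peak list, in file order.

    Records without a name column get the default name
    ``molecule:start-end``. Duplicate names are an error, as is any
    malformed or empty-interval record (reported with its line number).
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"dialect must be one of {PEAK_DIALECTS}, got {dialect!r}")
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {line_no}: expected >= 3 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                interval = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 else f"{fields[0]}:{start}-{end}"
            if name in seen:
                raise ValueError(f"{path}: line {line_no}: duplicate peak name {name!r}")
            seen.add(name)
            peaks.append(Peak(interval, name))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as handle:
        for peak in peaks:
            iv = peak.interval
            handle.write(f"{iv.molecule}\t{iv.start}\t{iv.end}\t{peak.name}\n")


def read_alignments(
    path: str | Path, min_mapq: int = 10, keep_secondary: bool = False
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file, filtered.

    Unmapped records are always dropped; records below ``min_mapq`` are
    dropped; secondary and supplementary records are dropped unless
    ``keep_secondary``. Duplicate-marked reads are kept. The aligned span
    is the full first-to-last aligned reference extent, half-open.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for record in handle.fetch(until_eof=True):
            if record.is_unmapped:
                continue
            if record.mapping_quality < min_mapq:
                continue
            if (record.is_secondary or record.is_supplementary) and not keep_secondary:
                continue
            if record.reference_end is None:
                warnings.warn(
                    f"{path}: mapped record {record.query_name} has no aligned "
                    "span (missing CIGAR); skipped"
                )
                continue
            yield AlignedRead(
                read_id=record.query_name,
                interval=GenomicInterval(
                    record.reference_name,
                    record.reference_start,
                    record.reference_end,
                    "-" if record.is_reverse else "+",
                ),
                mapq=record.mapping_quality,
                is_secondary=record.is_secondary,
                is_supplementary=record.is_supplementary,
                is_duplicate=record.is_duplicate,
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load genes with merged exon chains from GFF3.

    GFF3 1-based closed coordinates become 0-based half-open. Exons are
    attached to genes through any Parent chain (exon -> mRNA -> gene or
    exon -> gene); exons of all isoforms of one gene are merged into a
    single non-overlapping set. An exon whose parent chain does not reach a
    gene is skipped with a warning; a strandless gene is an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for exon in db.features_of_type("exon"):
        parent_genes = list(db.parents(exon, featuretype="gene"))
        if not parent_genes:
            warnings.warn(
                f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} has no "
                "resolvable gene parent; skipped"
            )
            continue
        for gene in parent_genes:
            exons_by_gene.setdefault(gene.id, []).append(
                GenomicInterval(exon.seqid, exon.start - 1, exon.end)
            )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {gene.id} has no strand")
        interval = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exons = tuple(merge_intervals(exons_by_gene.get(gene.id, [])))
        models.append(GeneModel(gene.id, interval, exons))
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (genes plus exons with direct Parent links)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            handle.write(
                f"{iv.molecule}\tpeakmatcher\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                handle.write(
                    f"{exon.molecule}\tpeakmatcher\texon\t{exon.start + 1}\t"
                    f"{exon.end}\t.\t{iv.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


def read_molecule_table(path: str | Path) -> MoleculeTable:
    """Load molecule lengths from a .fai or any name/length TSV."""
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {line_no}: expected >= 2 columns (name, length)"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {line_no}: length is not an integer"
                ) from exc
            if name in lengths:
                raise ValueError(f"{path}: line {line_no}: duplicate molecule {name!r}")
            lengths[name] = length
    return MoleculeTable(lengths)


def write_molecule_table(molecules: MoleculeTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in molecules.items():
            handle.write(f"{name}\t{length}\n")


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Load a two-column gene/FPKM table; a single header row is tolerated."""
    records: list[ExpressionRecord] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {line_no}: expected >= 2 columns (gene_id, fpkm)"
                )
            try:
                fpkm = float(fields[1])
            except ValueError:
                if not records and line_no <= 2:
                    continue  # header row
                raise ValueError(f"{path}: line {line_no}: FPKM is not numeric")
            records.append(ExpressionRecord(fields[0], fpkm))
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tfpkm\n")
        for record in records:
            handle.write(f"{record.gene_id}\t{record.fpkm:.6g}\n")


MATCH_HEADER = ("source_peak", "target_peak", "shared_reads")


def write_matches(matches, path: str | Path) -> None:
    """Write the many-to-many match table, sorted by source then target."""
    rows = sorted(matches, key=lambda m: (m.source_peak, m.target_peak))
    with open(path, "w") as handle:
        handle.write("\t".join(MATCH_HEADER) + "\n")
        for match in rows:
            handle.write(
                f"{match.source_peak}\t{match.target_peak}\t{match.shared_reads}\n"
            )


def read_matches(path: str | Path):
    from .matching import PeakMatch

    matches: list[PeakMatch] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != MATCH_HEADER:
            raise ValueError(f"{path}: unexpected header {header}")
        for line_no, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {line_no}: expected 3 columns")
            matches.append(PeakMatch(fields[0], fields[1], int(fields[2])))
    return matches


def write_read_peak_pairs(pairs, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tpeak_name\n")
        for pair in pairs:
            handle.write(f"{pair.read_id}\t{pair.peak_name}\n")


def write_elements_bed(element_set, path: str | Path) -> None:
    """Write an element set as BED4 (name column: per-element name or label)."""
    names = element_set.names or [element_set.label] * len(element_set.intervals)
    with open(path, "w") as handle:
        for iv, name in zip(element_set.intervals, names):
            handle.write(f"{iv.molecule}\t{iv.start}\t{iv.end}\t{name}\n")
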