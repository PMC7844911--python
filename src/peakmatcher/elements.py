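"""Genomic element sets derived from gene models.

Four element classes are analyzed against open-chromatin peaks: gene
spans, exons, introns (gene minus merged exons), and TSS promoter windows
(a fixed-width window immediately upstream of the gene start, strand
aware). Windows that would extend past either end of their molecule are
removed entirely, not clipped, so every emitted window has the full
requested width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    MoleculeTable,
    subtract_intervals,
    total_bp,
)


@dataclass
class ElementSet:
    """A labelled collection of intervals, optionally named per interval."""

    label: str
    intervals: list[GenomicInterval]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.names is not None and len(self.names) != len(self.intervals):
            raise ValueError("names must parallel intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def merged_coverage_bp(self) -> int:
        return total_bp(self.intervals)


def tss_windows(
    genes: list[GeneModel], molecules: MoleculeTable, window_bp: int = 500
) -> ElementSet:
    """Promoter windows of exactly ``window_bp`` upstream of each gene start.

    A plus-strand gene [s, e) yields [s - w, s); a minus-strand gene yields
    [e, e + w). Windows crossing a molecule boundary are dropped, so the
    set may hold fewer windows than there are genes. Interval names carry
    the gene id.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    for gene in genes:
        iv = gene.interval
        if iv.molecule not in molecules:
            raise KeyError(f"gene {gene.gene_id}: molecule {iv.molecule!r} not in molecule table")
        length = molecules[iv.molecule]
        if iv.strand == "+":
            start, end = iv.start - window_bp, iv.start
        else:
            start, end = iv.end, iv.end + window_bp
        if start < 0 or end > length:
            continue  # window extends past the end of the molecule: removed
        intervals.append(GenomicInterval(iv.molecule, start, end, iv.strand))
        names.append(gene.gene_id)
    return ElementSet("TSS", intervals, names)


def introns(genes: list[GeneModel]) -> ElementSet:
    """Per-gene set difference of the gene span minus its merged exons."""
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    for gene in genes:
        for piece in subtract_intervals(gene.interval, gene.exons):
            intervals.append(piece)
            names.append(gene.gene_id)
    return ElementSet("intron", intervals, names)


def exons(genes: list[GeneModel]) -> ElementSet:
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    for gene in genes:
        for exon in gene.exons:
            intervals.append(exon)
            names.append(gene.gene_id)
    return ElementSet("exon", intervals, names)


def gene_spans(genes: list[GeneModel]) -> ElementSet:
    return ElementSet(
        "gene",
        [g.interval for g in genes],
        [g.gene_id for g in genes],
    )


@dataclass(frozen=True)
class ElementSummary:
    label: str
    count: int
    mean_width_bp: float
    sd_width_bp: float
    coverage_bp: int
    genome_fraction: float


def element_summary(elements: ElementSet, molecules: MoleculeTable) -> ElementSummary:
    """Count, width mean +/- sd, and merged coverage (bp and genome fraction)."""
    widths = np.array([len(iv) for iv in elements.intervals], dtype=float)
    coverage = elements.merged_coverage_bp
    return ElementSummary(
        label=elements.label,
        count=len(elements),
        mean_width_bp=float(widths.mean()) if widths.size else 0.0,
        sd_width_bp=float(widths.std(ddof=1)) if widths.size > 1 else 0.0,
        coverage_bp=coverage,
        genome_fraction=coverage / molecules.genome_bp,
    )
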