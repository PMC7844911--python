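"""Association between promoter openness and gene expression.

Genes are split into high and low expression groups at an FPKM threshold
(>= threshold is "high"); each gene's TSS window is tested for overlap by
at least one peak covering >= ``min_frac_peak`` of the peak's own length
(the ``bedtools intersect -F`` convention). The resulting 2x2 table
(expression group x TSS overlapped) is tested with Pearson's chi-squared
test of independence, 1 degree of freedom, no continuity correction by
default. Because p-values in large data sets can fall far below the
smallest positive double, the log10 survival value is always reported
alongside the linear-space p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import special, stats

from .core import ExpressionRecord, Peak
from .elements import ElementSet
from .index import build_index


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = expression group (high/low), cols = TSS overlapped."""

    high_overlapped: int
    high_not_overlapped: int
    low_overlapped: int
    low_not_overlapped: int

    def __post_init__(self) -> None:
        for count in (
            self.high_overlapped,
            self.high_not_overlapped,
            self.low_overlapped,
            self.low_not_overlapped,
        ):
            if count < 0:
                raise ValueError("contingency counts must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.high_overlapped, self.high_not_overlapped],
                [self.low_overlapped, self.low_not_overlapped],
            ]
        )

    @property
    def high_total(self) -> int:
        return self.high_overlapped + self.high_not_overlapped

    @property
    def low_total(self) -> int:
        return self.low_overlapped + self.low_not_overlapped


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    log10_p: float


def partition_by_expression(
    records: Iterable[ExpressionRecord], threshold: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split gene ids into (high, low) sets at the FPKM threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    high: set[str] = set()
    low: set[str] = set()
    seen: set[str] = set()
    for record in records:
        if record.gene_id in seen:
            raise ValueError(f"duplicate gene_id {record.gene_id!r}")
        seen.add(record.gene_id)
        (high if record.fpkm >= threshold else low).add(record.gene_id)
    return high, low


def build_contingency(
    high: set[str],
    low: set[str],
    tss: ElementSet,
    peaks: list[Peak],
    min_frac_peak: float = 0.1,
) -> ContingencyTable:
    """Tabulate TSS-overlap status per expression group.

    A gene counts as overlapped if any peak overlaps any of its TSS windows
    by >= ``min_frac_peak`` of the peak's length. Genes without a TSS
    window (dropped at a molecule boundary) are excluded from both rows.
    """
    if tss.names is None:
        raise ValueError("TSS element set must carry gene ids as names")
    if not 0.0 <= min_frac_peak <= 1.0:
        raise ValueError("min_frac_peak must lie in [0, 1]")
    index = build_index((p.interval, p) for p in peaks)
    overlapped_genes: set[str] = set()
    for interval, gene_id in zip(tss.intervals, tss.names):
        if gene_id in overlapped_genes:
            continue
        for peak in index.query(interval):
            overlap = interval.overlap_bp(peak.interval)
            if overlap > 0 and overlap >= min_frac_peak * len(peak.interval):
                overlapped_genes.add(gene_id)
                break
    genes_with_window = set(tss.names)
    high_eff = high & genes_with_window
    low_eff = low & genes_with_window
    return ContingencyTable(
        high_overlapped=len(high_eff & overlapped_genes),
        high_not_overlapped=len(high_eff - overlapped_genes),
        low_overlapped=len(low_eff & overlapped_genes),
        low_not_overlapped=len(low_eff - overlapped_genes),
    )


def chi_square_independence(
    table: ContingencyTable, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-squared test of independence on the 2x2 table.

    No continuity correction unless ``yates``. The p-value is computed in
    log space from the chi-squared survival function, so extremely strong
    associations (p far below double-precision range) still compare
    meaningfully; linear-space ``p_value`` may underflow to 0.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined: a marginal total is zero")
    statistic, _, dof, _ = stats.chi2_contingency(arr, correction=yates)
    if dof == 1:
        # chi2(1) sf(x) = 2 * Phi(-sqrt(x)); log_ndtr stays finite in the
        # far tail where chi2.logsf underflows
        log_p = math.log(2.0) + float(special.log_ndtr(-math.sqrt(statistic)))
    else:  # pragma: no cover - 2x2 tables always have dof 1
        log_p = float(stats.chi2.logsf(statistic, dof))
    return ChiSquareResult(
        statistic=float(statistic),
        p_value=float(math.exp(log_p)) if log_p > -700 else 0.0,
        log10_p=float(log_p / math.log(10)),
    )
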