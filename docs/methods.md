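# Methods

## Coordinate model

All in-memory coordinates are 0-based half-open `[start, end)`. BED input is
taken verbatim; GFF3 (1-based closed) is converted once at the parsing
boundary, so a GFF3 feature `a..b` becomes `[a−1, b)` with length
`b − a + 1`. Overlap is strict interval intersection: `[a,b)` and `[c,d)`
overlap iff `a < d and c < b`, so abutting features never count. This single
convention is deliberate — mixed conventions are the dominant source of
off-by-one defects in this kind of tooling.

## Read-mediated peak matching

**Inputs.** Two peak lists (BED-like; narrowPeak accepted, columns past the
name ignored) and two SAM/BAM files containing the *same* reads aligned to
the two assemblies. Alignment filtering mirrors standard practice for
enrichment assays: unmapped reads always dropped, mapping quality < 10
dropped (configurable), secondary/supplementary dropped unless requested,
duplicate-marked reads kept (peak callers handle duplicates themselves, so
matching should see the same evidence the caller saw).

**Read identity and span.** A read is identified by its query name alone;
mates share one identity, so a pair straddling a peak contributes a single
unit of evidence. The read interval is the full aligned reference extent
(first to last aligned base), not the 5′ tag: the matcher measures physical
overlap of sequenced fragments with peaks, and the full extent maximizes
that evidence without inflating counts (deduplication is on read name ×
peak).

**Algorithm.** Per assembly, an interval tree is built per molecule over
the peaks and each read queried against it, emitting deduplicated
`(read_id, peak_name)` pairs. The two pair lists are joined on read name;
every (source, target) peak pair sharing ≥ `min_reads` distinct names is a
match carrying that count. `min_reads` defaults to 1 — the join as defined
emits any shared read — and is exposed because real data with ambiguous
mappings benefits from hardening (2–5). No transitive closure or graph
clustering is applied to the many-to-many output; that is downstream
analysis. Matched-peak fractions are reported against the full input peak
lists.

The interval tree is the `intervaltree` package (a balanced structure with
O(log n + k) queries); query results are materialized and sorted by start,
end, then payload, making output deterministic and independent of insertion
order. Exactness is tested against a brute-force linear scan on randomized
instances.

## Element sets

- **TSS windows**: for a `+` gene `[s, e)` the window is `[s − w, s)`; for a
  `−` gene, `[e, e + w)`. Default `w = 500` bp (promoter-proximal scale for
  a compact insect genome); 2 500 bp for locus reports where regulatory
  elements are expected farther upstream. A window extending past *either*
  end of its molecule is removed entirely, not clipped — every emitted
  window has exactly width `w`, so window counts can be slightly below gene
  counts. Windows are anchored on gene spans (not transcript spans):
  annotation sets at this level are gene-oriented, and per-isoform promoters
  are out of scope.
- **Introns**: per-gene set difference of the gene span minus its merged
  exons. Exons of all isoforms are merged on load, so alternative splicing
  cannot create overlapping exon/intron calls; merged exons and introns
  partition each gene span exactly (property-tested).
- Overlapping TSS windows from dense gene clusters are retained individually
  for counting but merged for coverage-bp, consistent with all coverage
  quantities being defined on the genome, not on the element multiset.

## Enrichment

```
fraction_of_peaks  = observed peak–element intersection (bp) / total peak coverage (bp)
fraction_of_genome = total element coverage (bp) / genome size (bp)
enrichment         = fraction_of_peaks / fraction_of_genome
```

Peaks are merged before coverage computation (no double-counting of
overlapping peak calls). The bp numerator uses raw merged overlaps; the
reciprocal-fraction filter (`-f`-style, default 10 % of the element)
governs only which elements are *counted* as overlapped. Both knobs are
exposed because published descriptions of such pipelines are often silent
on whether the fraction filter applies to the bp sum; the two modes are
separately computable. Enrichment is undefined (an error) for an element
set with zero coverage. Under a uniform null — peaks placed uniformly at
random — mean enrichment of a fixed random element set converges to 1;
this calibration is exercised with 200 seeded replicates at tolerance
±0.1.

## Expression association

Genes are partitioned at FPKM ≥ 1 (inclusive — the natural reading of "a
threshold of 1", documented here because the boundary convention changes
group sizes). A gene's promoter is "open" if ≥ 1 peak overlaps its TSS
window by ≥ 10 % of the *peak's* length (`-F`-style). Genes whose window
was dropped at a molecule boundary are excluded from both rows. The 2×2
table (group × open) is tested with Pearson's χ², 1 df, no Yates
correction by default: the motivating use has thousands of counts per cell
where the correction is negligible, and the uncorrected statistic matches
the closed form `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` used as the test
oracle. Yates is available as a flag.

For 1 df the log-space p-value uses the identity
`sf_χ²₁(x) = 2 Φ(−√x)` via `scipy.special.log_ndtr`; the generic
`chi2.logsf` underflows to −∞ for statistics beyond ~3×10³, whereas the
normal-tail form stays finite, keeping comparisons like *p* < 10⁻¹⁰⁰
meaningful at any effect size.

## Synthetic two-assembly fixtures

The generator emulates an assembly upgrade: the source assembly is cut into
equal blocks; the target is built by shuffling blocks (translocation),
inverting some (default probability 0.25), concatenating them into fewer
molecules (scaffold joins — default half as many), and collapsing chosen
duplicate block pairs onto one target block, which shrinks the target
genome just as resolving artifactual duplication does. Peaks (default 40 of
600 bp) are placed on a slot grid inside blocks with 400 bp gaps, so peaks
never overlap each other and no read can span two peaks; reads (100 bp —
the typical post-trimming short-read length — 20 per peak) are placed
uniformly inside their peak, plus 400 uniform background reads. Every read
and peak is transformed through the block map to produce the target-side
files; read names are conserved across the pair, and the expected
correspondences (including many-to-one pairs from collapse) are written to
a truth table. All output is byte-reproducible from the seed.

In the unambiguous regime (no collapse) this construction makes
precision = recall = 1 the *correct* answer, which the acceptance checks
assert. What passing does and does not show: the fixture validates
coordinate bookkeeping, join logic, orientation handling and many-to-one
recovery, but reads are placed, not aligned — there is no mapping
ambiguity, no multi-mapping noise, no indel-induced span changes, and no
sequence content at all. Matched fractions on real data will be well below
100 % for reasons outside the matcher (unplaced scaffolds, diverged
regions, mapping-quality filtering).

The gene-model generator lays non-overlapping genes (2–6 kb, 1–4 exons,
uniform strand) with gaps ≥ 500 bp, leaving room for promoter windows, and
draws FPKM as `1 + Exp(mean 30)` for "high" genes and `U(0, 1)` for "low",
so the FPKM ≥ 1 partition recovers groups exactly. The high-expression
probability is `0.5 ± effect` depending on whether the gene's TSS window is
covered by a supplied peak: `effect = 0` is an exact independence null
(used for type-I calibration at α = 0.05, 200 replicates, tolerance
±0.03), and `effect = 0.4` gives near-certain detection.

## Problem sizes and numerics

Simulated fixtures use 4 source molecules × 200 kb and 40–60 peaks;
calibration loops use 150 genes × 200 replicates on a 1.2 Mb genome —
sizes chosen so each invariant is exercised with comfortable statistical
resolution while the full suite runs in seconds. Determinism: all
randomness flows through `numpy.random.default_rng` seeds; interval-query
results and all output tables are sorted; SAM emission writes
position-sorted records with a fixed header.

## Known limitations

- CRAM, BigBed/BigWig and GTF dialects are not read.
- The matcher assumes the two alignment sets share read names; it warns (and
  returns nothing useful) when they do not.
- Region reports count intronic peaks by plain ≥ 1 bp overlap rather than a
  fraction-of-intron rule: introns can be orders of magnitude longer than
  peaks, and a fraction filter on the intron would suppress exactly the
  narrow intronic peaks the report exists to show.
- Enrichment significance is not assessed (ratios only, by design).
- The simulator does not model sequence content, sequencing error, mapping
  ambiguity, or quality scores.
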