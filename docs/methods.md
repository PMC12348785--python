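# Methods

This note documents the statistical models, default parameters, and design
choices behind `rddmscan`, and what the simulation benchmarks do and do not
demonstrate about real data.

## Coordinates and contexts

All interfaces use 1-based inclusive genomic coordinates (the convention of
sRNA cluster IDs such as `Chr6;2121001;2122000`); BED input is converted from
0-based half-open on load. A cytosine's context is read 5′→3′ on its own
strand: CG if the next base is G (one downstream base suffices — the Bismark
convention), CHG/CHH from the next two bases (H = A/C/T), and NA when the
window is truncated by the sequence end or contains an N. NA-context sites
are carried through CX reports but excluded from all level and DMR
computations.

## Methylation levels

The level of a site is `meth/total`; undefined (NaN) at zero coverage.
Global and regional levels are *pooled ratios* `100·Σmeth/Σtotal` over
covered sites — a read-count-weighted estimator matching the read-ratio
definition of the level, not the unweighted mean of site fractions (which is
available via `pooled=False` and can differ markedly when coverage and
methylation are correlated).

Functional-region labels partition every position with the precedence
5′UTR > 3′UTR > exon > intron > upstream-2k > downstream-2k > intergenic;
gene-body labels beat flank labels of neighbouring genes, and the result is
independent of gene-list order (labels are painted in reverse precedence).
The "TSS region" used in DMR distribution summaries has no field-standard
definition; it is TSS ± `tss_window` (default 1000 bp) and is recorded in
the run manifest.

## DMR calling

Windows are non-overlapping tiles of `tile_width` (default 1000 bp — chosen
to match the sRNA cluster granularity; no tool-standard width exists).
Within each group the replicates are pooled (Σmeth, Σtotal per window); with
only two replicates a dispersion-aware model is not estimable per window, and
pooling keeps the test deterministic and auditable. The cascade is:

1. coverage: pooled Σtotal ≥ `min_coverage` (30) in both groups (a per-site
   variant is available via `per_site=True`);
2. two-sided Fisher exact test on `[[meth_t, unmeth_t], [meth_c, unmeth_c]]`;
3. BH correction per context per comparison (contexts are reported as
   separate families);
4. effect filters: |level_t − level_c| > `min_diff` (15 percentage points;
   the "level ratio > 15" criterion is read as a difference in points — a
   ratio of 15 is not meaningful next to the separate fold-change clause)
   AND level fold change ≥ 2 or ≤ 0.5. A window with level_c = 0 and
   level_t > 0 has infinite fold change and passes the upper bound;
   both-zero windows are never DMRs.

Polarity is the sign of the difference (hyper = higher in treatment).
Swapping the groups flips every polarity and negates the difference while
leaving p and q unchanged (verified as an invariant).

## sRNA clusters and differential calling

Reads are assigned to bins by their 5′ end so each read counts exactly once;
bin k covers [k·w+1, (k+1)·w]. Size classes: "20–22 nt" pools lengths 20–22,
"24 nt" is exactly 24, "all" is everything 18–30. CPM uses the all-length
library total for every size class, so class-level changes remain visible
(per-class totals would renormalize them away); the generic `cpm()` operation
guarantees every column sums to 10⁶.

DSRs and DEGs share one code path: Welch's t-test on log2(CPM+1) (the
pseudocount avoids log 0; the test is run on the log scale where NB counts
are closer to homoscedastic), BH within a family (all cluster × size-class
tests form one family; genes form another), and direction = up/down only when
q ≤ 0.05 and |log2FC| ≥ 1, where log2FC is the difference of group means of
log2(CPM+1). A raw-p gate is available (`use_raw_p=True`). With fewer than
two replicates in a group the p-value is NaN and the direction falls back to
the fold change, flagged in a `warning` column.

**Power ceiling (important).** With n = 3 replicates and biological
coefficient of variation √0.1 ≈ 0.32, a 4-fold effect yields Welch t ≈ 5 at
≈ 4 degrees of freedom, i.e. p ≈ 3×10⁻³–10⁻²; BH across a mostly-null family
then leaves almost no q ≤ 0.05 calls. This is a property of per-feature
t-tests at small n, not an implementation defect; dispersion-sharing NB
models (DESeq2/edgeR-style) escape it by borrowing strength across features.
All differential testing is concentrated in `call_diff`, so substituting
such a caller is a one-function change; the default remains the plain
t-test to keep a single transparent code path. Consequences for the simulation benchmarks are
quantified by `scripts/acceptance.py` (DSR/DEG recall under the default
caller is low by construction).

## Integration

The DMR×DSR association uses, per stratum (polarity × direction × size
class), the 2×2 table over the background of all *tested* clusters: rows =
cluster has/has not the stratum's DSR direction; columns = cluster does/does
not overlap ≥ 1 DMR of the stratum's polarity. Empty genomic bins are not
part of the background (they would dominate the table). The odds ratio is
(ad)/(bc), with Haldane–Anscombe +0.5 on every cell only when some cell is
zero; the Fisher p is computed on the uncorrected table. Exchanging the
rows (the complementary direction) inverts the OR and preserves p.

DMR target genes are every (gene, DMR) pair whose promoter — 2 kb upstream
to 500 bp downstream of the TSS, strand-aware, clamped to the chromosome —
overlaps the DMR by ≥ 1 bp; both the full target list and the DEG-joined
view are emitted, since "target" may be read either way. The RdDM screen
requires, on one comparison: (i) promoter ∩ CHH hypo-DMR, (ii) a 24-nt
cluster overlapping the DMR *or* the promoter called down, (iii) the gene
called up (mirror mode swaps all three). The sRNA linkage accepts
promoter-adjacent clusters because the siRNA source region is typically
adjacent to, not congruent with, the hypomethylated window. Genes with
several qualifying (DMR, cluster) pairs yield one row each; deduplicate by
`gene_id` for the gene-level view.

Term enrichment is a flat hypergeometric upper tail per term over a
gene→term table with BH across tested terms (k ≥ 1); no ontology DAG
propagation is performed.

## The simulator

The generator emulates the study design: timepoints 0/5/10 dpt with 2 WGBS,
3 sRNA, and 3 RNA replicates; mean coverage λ = 30 (Poisson per site);
baseline methylation at 0 dpt CG 57.55%, CHG 30.23%, CHH 4.6% with an
elevated TE compartment (85/60/15%); beta-binomial site noise with
intraclass correlation ρ = 0.05 (ρ = 0 reduces to binomial — biological
methylome replicates are overdispersed); negative-binomial counts with
dispersion 0.1 (var = μ + 0.1μ²) for sRNA clusters and genes; and an
18–30 nt length mixture whose 24-nt weight rises with treatment
(0.30 → 0.33 → 0.36) at the expense of 20–22 nt, reflecting the cold-induced
shift toward the RdDM-associated class.

Geometry: each gene owns a slot whose first 1-kb tile lies inside the
gene's promoter; planted features (DMR windows, DSR clusters, RdDM loci)
occupy the promoter tiles of disjoint slots, so planted features never
overlap and each RdDM locus is one tile that simultaneously carries the TE,
the CHH hypo-DMR, and the 24-nt cluster of an upregulated gene. The gene
immediately upstream of any planted tile is forced to the + strand so that
no non-planted gene's promoter reaches a planted tile.

Planted DMR windows are methylation islands/valleys: a hypo window has
control level min(base, 30%) + 40 pp falling to min(base, 30%); a hyper
window rises from min(base, 30%) by 40 pp. The caps guarantee the full
effect passes both the 15-pp difference and the 2-fold filters in every
context (CG's 57.55% baseline cannot double). Effects ramp ×0.5 at 5 dpt
and ×1 at 10 dpt. Planted DSRs scale the 24-nt class mean by 2^±2; planted
DEGs scale the gene mean by 2^±2; RdDM loci use the canonical polarities
(down sRNA, up gene).

One integer seed drives everything through independently spawned
`SeedSequence` streams (genome / methylome / sRNA / expression), so outputs
are byte-identical across runs and adding features to one layer does not
perturb another's draws.

What the simulator does *not* model: read-level artifacts (mapping,
bisulfite conversion errors), per-sample library-size variation (expected
depth is constant, so CPM's compositional bias appears only through planted
effects), linkage between methylation and expression beyond the planted
loci, realistic chromosome structure, and miRNA biology. Passing recovery
benchmarks therefore demonstrates the correctness of the statistical
machinery and the co-localization logic under the stated noise models — not
performance on real libraries.

## Numerical choices

- Fisher p-values come from `scipy.stats.fisher_exact` (two-sided); they are
  verified against full hypergeometric enumeration to |Δ| < 10⁻⁹.
- BH q-values come from `statsmodels` and are verified against the textbook
  step-up at 10⁻¹² relative (the two differ only in floating-point
  association of one multiply/divide).
- Identical groups give t = 0/0 → p set to 1 (not NaN) so the feature counts
  as tested.
- Degenerate inputs error loudly with file/line context: negative counts in
  CX reports, zero library sizes in CPM, genes present in both DEG direction
  sets, empty association backgrounds, empty enrichment selections.
- Pipeline tables are written with `%.6g` floats; determinism is asserted at
  byte level in the tests.

## Benchmark problem sizes

The recovery benchmarks run on a 2 × 520-kb genome with 510 genes (10
planted RdDM loci + 500 decoys), 70 planted DMR windows, 50 planted DSR
clusters among 300, and 70 planted DEGs — large enough that every context
has >10⁴ testable sites and each BH family has hundreds of members, while a
full tri-omics simulation plus pipeline completes in well under a minute.
Calibration and null checks use single-chromosome 150–200-kb genomes with no
planted effects (and, for calibration, no TE compartment, since the
configured baselines describe the background compartment by design).
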