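# Methods

## Coordinate conventions

All intervals are 0-based half-open in genome orientation (BED-like);
minus-strand features are stored unreversed. Fixed-step wiggle input is
converted from its 1-based convention on read. CTSS input positions are taken
to be 0-based; CAGE ctss dialects vary on this point, so files produced by
other toolchains may need a one-base shift. Signal queries over `[a, b)`
return exactly `b − a` values with 0.0 for uncovered bases, so concatenating
adjacent queries equals the joint query.

## TSS clustering

Sites on one chromosome/strand are segmented by the parametric
maximal-scoring-segment criterion: segment score `S_d = Σcounts − d·L` with
`L` the bp span from the first to the last site inclusive (a single site has
`L = 1`). For each density `d > 0` the maximal segments are disjoint; across
densities they form a nested family, computed top-down by locating, for each
segment, the weakest prefix/suffix cut — the smallest `d` at which some
prefix or suffix of the segment would score non-positively — recording the
segment's `(min_density, max_density)` optimality window, and splitting at
that cut. Outermost segments carry `min_density = 0` (they are optimal for
every sufficiently small positive density) and are treated as infinitely
stable by the stability filter; this matches the reference behaviour of
parametric clustering tools that print a zero lower bound for top-level
clusters. Ties among equally weak cuts split at the leftmost; the anchor of a
cluster is the 5′-most base (relative to strand) among those with the
maximal count.

Correctness is established against an independent brute-force oracle that,
for a probe density, enumerates every site-delimited segment, keeps those
whose every prefix/suffix cut scores positively, and takes the
inclusion-maximal ones; the implementation's family restricted to each probe
density must match exactly (200 random instances of ≤ 15 sites, plus probes
at the midpoint of every reported density window).

Default filters follow common practice for this cluster family: maximum
length 200 bp, minimum 10 counts, density stability (max/min) ≥ 2, all
configurable. Clusters are defined on the pooled CTSS of all samples and
per-sample counts are then re-tallied inside the cluster intervals, giving
one TSS coordinate system across conditions.

## Peak classification and gene assignment

Peak sets are reduced to their covered bases (overlapping or abutting
intervals merged) before classification, so the outcome depends only on
coverage, never on how a peak caller split a region. A TSS is `BOTH` when a
merged H3K4me3 interval lies within 1 kb of the TSS anchor (0 bp if the
anchor is inside, else the gap to the nearer edge) *and* that interval
shares at least one bp with a TF peak; otherwise `H3K4ME3_ONLY` if an
H3K4me3 interval is within 1 kb (including the residual case where both
marks are near but never overlap as a pair — these are counted and
reported); otherwise `SOX10_ONLY`; otherwise `NEITHER`.

Genes are assigned from the union span of each gene's transcripts, extended
by 1 kb on both sides; the TSS anchor must fall inside the extended span on
the same strand. The nearest such gene wins; ties break by smaller span then
lexicographic gene id, making assignment invariant to input order. TSSs left
unassigned can be retried through a user-supplied coordinate orthology map
(a plain table replacing chain-file remapping).

## Differential expression

The test is the classic conditional exact test for negative-binomial counts
with a single common dispersion:

* **Normalization** — trimmed mean of M-values (TMM): reference sample by
  closest 75th-percentile CPM, M/A computed on rows positive in both
  samples, 30 % trim on M and 5 % on A, inverse-variance (delta-method)
  weights, factors scaled to geometric mean 1.
* **Pseudo-data** — counts are scaled (and rounded) to the geometric mean of
  effective library sizes. This replaces the quantile-adjustment internals of
  the original tool family with a simpler documented step; exactness of the
  conditional test then holds approximately, which the calibration suite
  verifies directly.
* **Dispersion** — pooled method of moments across rows after library-size
  scaling: `φ = Σ(var − mean) / Σ mean²` within groups, floored at 0.
  Recovery is verified on simulated matrices (φ = 0 → estimate ≤ 0.02;
  φ = 0.2 → estimate within [0.15, 0.25] at 2,000 rows).
* **Test** — conditionally on a row's total, the group sums of n iid NB
  variables are NB with dispersion φ/n; the two-sided p doubles the smaller
  tail (capped at 1). φ = 0 reduces to the binomial split test.
* **Calls** — rows where fewer than 2 samples reach 1 CPM in both groups are
  `NOT_EXPRESSED` and excluded before BH-FDR; remaining rows are `UP`/`DOWN`
  when FDR < 0.05 by log2FC sign, else `UNCHANGED`. Thresholds are
  configurable.

Calibration on its own generator: null type-I error at nominal 0.05 falls in
[0.035, 0.065] (2,000 rows, 5 vs 5, φ = 0.1), and a planted |log2FC| = 2
study at 3 vs 3 is recovered with sensitivity ≥ 0.8 at observed FDR ≤ 0.1.

## Metagene aggregation and the permutation AUC test

Windows of ±1 kb around TSS anchors are strand-oriented (positive offsets
downstream); out-of-chromosome bases contribute 0. The class statistic is
the absolute difference in area under the mean profiles, where the area is
the plain sum over 1-bp offsets; since the AUC of a mean profile equals the
mean of per-region window sums, the permutation null shuffles region labels
over pooled window sums. p = (1 + #{null ≥ observed})/(1 + n_perm). The
pooled vector is sorted and the smaller group is always filled first, making
the p-value bit-identical under exchange of the two classes. GC
stratification computes each region's GC over its ±window sequence (N counts
as non-GC), pools the distribution, forms quantile bins (ties to the lower
bin) and profiles each class within each bin.

## Sequence features

**Motifs.** IUPAC consensus matching with a Hamming-style mismatch budget; a
genome N never satisfies a class and therefore counts as a mismatch. Minus
strand hits are matches of the reverse-complement consensus reported in
genome coordinates. Dimeric sites are pairs of opposite-strand half-sites
with a spacer inside configured bounds, paired greedily left-to-right with
each half-site used at most once and each half-site pair reported once. The
shipped default consensus `WWCAAWG` (one mismatch) is a family-level
HMG-box placeholder and must be treated as configuration, not as a validated
binding model. Per-motif conservation is the mean per-base score over the
hit — for dimers over the two half-sites only, excluding the spacer.

**CpG islands.** EMBOSS-default parameters: 100-bp sliding windows (step 1)
scored for GC fraction and CpG observed/expected = `#CG·window/(#C·#G)`
(0 when a window lacks C or G); windows passing GC ≥ 0.5 and obs/exp ≥ 0.6
are merged by span union and runs ≥ 200 bp are reported with the merged
sequence's statistics. A consequence of window-union semantics is a boundary
effect: a window straddling an island edge can pass marginally, so an
island's reported span can extend up to one window beyond its core; flanking
a sequence with island-negative padding therefore preserves islands and
shifts their cores but may move the exact edges by < 100 bp.

## Tissue specificity

Tau is computed on transformed expression x̂ᵢ = tᵢ/max(t) with
t = log2(CPM + 1) by default: τ = Σ(1 − x̂ᵢ)/(n − 1). The log transform
tempers the dominant tissue's weight, making τ respond smoothly to
concentration; raw-CPM mode is available, and only in raw mode is τ
invariant to overall scaling. All-zero profiles are excluded with a reason
code rather than scored.

## The synthetic study

The generator emulates the structure of a four-model promoter study at
desk scale. Defaults: 2 chromosomes × 500 kb at 45 % GC; 50 promoters per
class placed ≥ 3 kb apart on a jittered grid; per-promoter 5′-end counts
drawn NB (mean by class: 300/200/100/30 for BOTH/H3K4ME3_ONLY/SOX10_ONLY/
NEITHER in the nerve model; mean 100, dispersion 0.1 in the cellular
models) and spread multinomially over a triangular 61-bp window peaking at
the true TSS; H3K4me3 peaks 1,000 bp and TF peaks 400 bp with ±200 bp
jitter, planted per class so the 1-kb rule and the peak-on-peak rule are
exercised separately; replicate structure 2/3+3/2+4 (nerve /
control+treated / parental+knockout), mirroring a realistic small design.

Within the candidate (BOTH) class, 40 % of promoters are planted
factor-dependent (log2FC −2 in the knockout), 10 % upregulated, 10 % silent;
of the dependent promoters, 50 % are upregulated and 10 % downregulated with
differentiation. These within-class fractions are deliberately enriched
relative to a genome-scale survey, where dependent TSSs are a few percent of
candidates: a 50-promoter class must contain enough dependent members for
distributional comparisons to be meaningful at all.

Dependent promoters receive more planted motif copies (Poisson mean 4 vs 1),
higher conservation elevation over their motifs (baseline 0.2, +0.8 vs
+0.4), a 3× ChIP signal amplitude, and one-tissue-dominant expression
(20× one tissue drawn from the three factor-positive tissues); non-dependent
promoters are mostly ubiquitous (20 % restricted). CpG-island sequence is
planted at exactly 20 % of dependent vs 90 % of other promoters. The sharper
depletion (rather than the ~2× difference a genome-scale study observes)
is a deliberate design choice: with ~20 promoters per group a binary trait
differing 2-fold is statistically unresolvable even in principle, so the
miniature study plants a contrast that a 50-promoter class can actually
detect; island and restriction assignments use exact per-stratum counts
(not Bernoulli draws) so configured fractions are realized exactly. The
background genome is CpG-depleted (80 % of background CG dinucleotides
deaminated C→T) as vertebrate genomes are — without this, random 100-bp
windows show no CpG suppression and island detection has no specificity.

What the generator does **not** emulate: nucleotide composition beyond
uniform GC with CpG depletion (no repeats, no TATA/Inr elements), mappability
or ChIP background noise, promoter shape diversity beyond the triangular
profile, gene structure (one single-transcript gene per promoter), or
cross-sample batch effects. Passing the recovery suite therefore shows the
pipeline's stages are correct and well-calibrated under their stated models,
not that the defaults are tuned for any particular real dataset.

All randomness flows from one master seed; per-component generators are
derived at fixed offsets, so outputs are byte-identical across runs.

## Numerical and bookkeeping choices

Printed percentages use decimal half-up rounding. Mann–Whitney U uses
midranks, with full enumeration of label assignments when the pooled size is
≤ 12 (valid under ties) and the normal approximation with tie and continuity
corrections otherwise; identical pooled values give p = 1. ECDFs on log10
values exclude zeros and report their count (a pseudo-value offset is
available). Z-score rows use the population SD; constant rows become zeros
and are flagged. Isoform-diversity counting treats annotated TSS positions
as distinct unless within a configurable merge distance (default 0), and
counts distinct non-empty coding-sequence keys independently.

## Problem sizes

The test and analysis runs use 200 promoters (50 per class), 2 × 500 kb of
genome, 2,000-row count matrices for calibration, 200 repetitions at 500
permutations for permutation-test calibration, and oracle sweeps of 200
random clustering instances and 50 random 10-kb motif-scan sequences —
sizes chosen so the complete suite runs in well under a minute while keeping
every statistical check adequately powered.
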