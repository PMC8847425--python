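# Methods

## Model and procedure

The pipeline treats a differential histone-mark analysis as three stages.

**1. Quantification.** Each library (condition × {ChIP, Input}) arrives as
a bedGraph of per-bp depth. Values are binned at a fixed width (default
50 bp; the simulator uses 200 bp) by distributing each record's mass
(value × overlap width) pro-rata over the bins it touches, so total read
mass is conserved regardless of record fragmentation. Bins are normalized
to CPM: bin × 10⁶ / library mass. The unit of gene-based analysis is the
gene-proximal window: [5′ end − 5 kb, 3′ end + 1 kb], strand-aware and
clipped to the chromosome. We read the window as *including* the gene
body; a configuration choosing pure flanks is not offered because broad
repressive domains cover gene bodies, but an `upstream_only` mode (the
5 kb immediately 5′ of the start) serves marks confined to promoters and
enhancers, e.g. H3K27ac. Boundary bins are included whole — a rank test
over ≥ tens of bins is insensitive to one partially covered bin, and the
contract stays simple.

**2. I/U designation and pattern classes.** Per unit and condition, the
per-bin ChIP CPM vector is tested against the matched Input vector with a
one-sided Mann–Whitney U (alternative: ChIP stochastically greater). The
unit is Increased (I) iff p < α (default 0.05) *and* region fold-change
(mean ChIP + c)/(mean Input + c) > 1.5, with pseudocount c = 0.25 CPM —
small against typical signals (tens of CPM) yet enough to keep empty bins
finite. No multiple-testing correction enters the designation (a BH q per
condition is emitted for transparency only). The three per-condition
letters in (reference, disease, rescue) order form a code; IUI, IUU, UII,
UIU are the dynamic classes 1–4 and the rest are static. Peak-mode adds
the consistency filter: for every (I-condition, U-condition) pair the
per-bin log2 fold-changes must separate at one-sided Mann–Whitney
p < 0.05, else the peak demotes to static. Gene mode does not apply the
filter (both are overridable). Units with fewer than 4 bins are called U
with a low-coverage flag: a rank test on 1–3 observations cannot reach
p < 0.05 and silently returning I-eligible values would be misleading.

Mann–Whitney p-values use exact enumeration when both samples are
tie-free and min(n₁, n₂) ≤ 8, otherwise the tie-corrected (midrank)
normal approximation with continuity correction. When every observation
in both samples is identical the statistic is degenerate (zero variance)
and p = 1.0 is returned: no evidence of shift. p-values are clamped into
(0, 1].

**3. Enrichment.** For pattern pt, the background p_b is the fraction of
assessed genes (the universe is the genes with an assignment, not all
annotated genes) carrying pt. For a gene set intersected with the
universe (n genes, k carrying pt) the p-value is the survival probability
P(X > k), X ~ Binomial(n, p_b), computed via the regularized incomplete
beta function rather than term summation for numerical stability. The
inequality is strict — the null is "more than k of n follow pt by
chance". Results sort by raw p; a BH q within each pattern is attached
for reference.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α (designation) | 0.05 | — | conventional per-test level; raw, uncorrected |
| fold-change gate | 1.5 | ratio | conjunctive with α; blocks significant-but-small shifts |
| consistency α | 0.05 | — | same level as designation |
| pseudocount | 0.25 | CPM | stabilizes sparse bins without dominating signal |
| upstream / downstream flank | 5000 / 1000 | bp | broad-domain window around the gene body |
| bin size | 50 (pipeline), 200 (simulator) | bp | coverage-quantification granularity |

Percentage summaries round half away from zero, so counts
2293/786/154/66 of 3299 print as 70/24/5/2.

## The synthetic-data generator

The simulator emulates the statistical structure the caller assumes and
nothing more: three conditions × two channels; negative-binomial bin
counts (variance μ + φμ², dispersion φ = 0.05 — overdispersion is the
realistic stressor for a rank test, which Poisson noise would understate);
genes placed with mutually disjoint proximal windows so the planted truth
is unambiguous; and, inside the window of a gene planted I in a
condition, a ChIP mean multiplied by a fold-change drawn as
2^N(1.58, 0.1) (≈ 3-fold). Defaults: 200 genes of length U(1000, 3000) bp
on two 2-Mb chromosomes, 200-bp bins — so a typical window spans ≈ 40
bins — Input depth 10 counts/bin, equal proportions of GP1–GP4 and
static. Near-threshold stress cases use planted fold-changes of 1.3 and
1.6 to exercise both sides of the 1.5 gate.

It does **not** model read-level artifacts: fragment-length smearing, GC
bias, mappability gaps, replicate variability (replicates are assumed
pre-merged), or overlapping gene windows. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
assumed noise law, not that real libraries at real depths will separate
as cleanly; on real data the effective per-window bin count, depth and
dispersion govern power.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GTF is converted on read;
  chromosome names must match exactly across inputs (no chr1/1 aliasing).
- bedGraph values are per-bp depth; binning conserves mass to 1e-6
  relative (property-tested).
- Condition order is declared in configuration; code semantics depend on
  it, so it is never inferred from input order silently.
- Demotion by the consistency filter is monotone in α: lowering the
  threshold can only demote more peaks, never fewer.
- Output tables carry 6 significant digits; determinism is bit-for-bit
  for a fixed seed, including the simulator's bedGraphs.

## Known limitations

- The strict survival tail P(X > k) is *not* a calibrated p-value over a
  binomial null: over random sets the rejection rate at level α equals
  sf(k*−1) ≥ α, inflated by the point mass at the critical value. When
  sets are drawn without replacement from a modest universe (the package's
  200 assessed genes, sets of 10–60), the hypergeometric tail-thinning
  offsets this — the exact expected rate at α = 0.05 is 0.056, and the
  calibration test bounds the empirical rate by 0.05 + 3·SE — but for
  small sets drawn from a very large universe the strict-tail rate can
  reach ≈ 0.07–0.08. Users wanting guaranteed conservatism should prefer
  P(X ≥ k); we keep the strict form as the method's definition.
- I/U designation uses raw per-condition p-values by design; the BH q
  column is informational.
- Enhancer-aware peak→gene assignment consumes a user-supplied
  enhancer→gene TSV; no enhancer catalogue ships with the package.
- BAM/bigWig input, spike-in normalization, replicate-aware variance
  modeling and signal smoothing are out of scope.
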