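# Methods

`pcx` implements an integrative analysis of how Polycomb (PRC2 / H3K27me3)
dosage relates to DNA methylation and gene expression across directed
differentiation of embryonic stem cells, together with a synthetic
multi-omics cohort generator that makes every stage testable without any
external download. This note documents the models, conventions, defaults
and known limitations.

## Coordinate and unit conventions

All coordinates are 0-based; all intervals are half-open (BED convention).
A CpG unit is anchored at the plus-strand C; evidence from the minus-strand
G at the next base is merged into it. The TSS of a minus-strand gene is
`end - 1`. ChIP signal is reads per million mapped reads (RPM), counted by
5' read position with no fragment extension. Percent methylation is floored
at 0.01% — only for ratio arithmetic; raw counts are never modified.

## Per-CpG methylation calling

Strand-aware per-base tallies (methylation-representative reads /
total reads) are summed per CpG unit. Pairwise analyses use only sites with
coverage ≥ 10x in *every* compared sample (`min_cov = 10`). Genome-wide
methylation distributions are summarised as fractions of sites ≤ 15%
("low"), ≥ 80% ("high") and in between.

The calling deliberately ignores non-CpG cytosines and performs no
bisulfite-conversion-rate correction; inputs are assumed to be standard
per-CpG count files (bismark-coverage dialect or the native wide TSV).
Whether strands should be merged per CpG is exposed
(`merge_strands=False`) since either convention occurs in practice.

## 2-D methylation matrices and the replicate-based null

For a pair of samples, shared ≥10x CpGs are binned by percent methylation
in each sample into a 10 × 10 grid (left-closed bins of 10 percentage
points; the last bin is closed at 100). Bin width is configurable; 10
matches the granularity at which such matrices are usually drawn.

The expected distribution under "no difference" is estimated from
replicates: for each cell type, replicate 1 is binned against replicate 2
on that pair's own shared sites, the count matrix is normalised to
proportions, and the expected matrix is the unweighted mean across cell
types. A pseudocount of 0.5 reads is added per bin before normalising so
the null assigns non-zero probability everywhere — otherwise bins never
visited by replicate pairs (the far off-diagonal corners, exactly where
real signal lands) would be untestable rather than significant. Fold
enrichment is observed/expected proportion; significance per bin is an
exact two-sided binomial test of the observed count given the total and the
expected proportion, reported with Benjamini–Hochberg q-values. The
significance threshold for calling enriched bins is 5 × 10⁻⁷. The choice of
a binomial test is an assumption: it is the minimal model for count data in
a fixed grid; any extra-binomial variation in real data would make it
anti-conservative.

**Exchangeability requirement.** The calibration of the binomial test rests
on the compared pair having the same noise structure as the replicate pairs
behind the background. The pipeline therefore computes enrichment
significance on coverage-matched single replicates. Comparing
replicate-pooled samples (double coverage, hence less per-CpG noise)
against a single-replicate background concentrates observed mass on the
diagonal relative to the null and produces spurious genome-wide-significant
bins even without any planted effect; pooled counts are used only where
precision, not calibration, matters (the per-CpG gain/loss classes).

Per-CpG change classes use a symmetric threshold: *gain* if methylation
rises by ≥ 10 percentage points, *loss* if it falls by ≥ 10, otherwise
*no change*.

## ChIP signal, metagenes and region retention

TSS-window signal is the RPM within TSS ± 2 kb. Metagene profiles average
per-50-bp-bin RPM across a gene set with minus-strand genes flipped so
transcription runs rightward. A wild-type enriched region is *maintained*
in a mutant if the mutant/wild-type region RPM ratio is ≥ 0.5 **and**
mutant RPM ≥ 0.1; otherwise *lost*. The ratio rule is this package's
operational definition of "losing enrichment" (re-calling peaks in the
mutant would be the alternative); both thresholds are configurable.
Regions with zero wild-type RPM carry no evidence of enrichment and are
dropped with a warning.

## Bivalency resolution

A promoter is bivalent when both H3K27me3 and H3K4me3 regions overlap
TSS ± 2 kb. Resolution over differentiation (day 0 → day 5) is classified
on TSS-window RPM with a 0.1 RPM floor, using strict fold thresholds:
*resolved repressed* when H3K27me3 rises more than 4-fold and H3K4me3
falls more than 1.5-fold; *resolved active* when H3K27me3 falls more than
2-fold and H3K4me3 rises more than 2-fold; otherwise *unresolved*. The two
rules cannot both fire. TSS-window RPM (rather than peak-level signal) was
chosen so the same quantity drives metagenes, resolution calls and
quintiles.

## CpG-to-gene assignment

A three-rule cascade, applied in order:

1. **gene body ± 4 kb** — a CpG within 4 kb of a gene body (distance 0
   inside) is assigned to that gene, nearest body first;
2. **neighbor CpG** — otherwise, a CpG within 1 kb of a CpG already
   assigned by rule 1 inherits that CpG's gene. Inheritance never chains
   through other rule-2 assignments, which would otherwise propagate a
   gene label without distance bound. The 1 kb radius is this package's
   default for an intentionally vague "proximity" criterion and is
   configurable;
3. **nearest PRC2 target within 200 kb** — otherwise the CpG goes to the
   nearest PRC2-target gene body within 200 kb; else it is unassigned.

Ties are broken by smaller distance, then lexicographic gene id, making the
assignment a pure function of its inputs.

## Expression integration

Fold changes are `log2(max(b, 0.1) / max(a, 0.1))` — the 0.1 floor applies
to both FPKM and RPM ratios. Quintile analysis ranks genes by H3K27me3
log2 fold change (ties broken by gene id so the five bins differ in size by
at most one) and compares the per-bin log2 expression-change distributions
with classical pooled-variance two-sided t-tests (Welch available via
`equal_var=False`). Degenerate zero-variance comparisons return t = 0,
p = 1 when means agree.

Segmented regression fits one continuous breakpoint by iterative
linearization started at psi = −0.5, restricted to the [5th, 95th]
percentile of x so the break cannot park on a boundary, with a dense
grid-search fallback on non-convergence and a final bounded scalar polish
of the profile RSS. On break-free data the two slopes coincide and the fit
reduces to ordinary least squares. The 2-D kernel density uses a Gaussian
product kernel with a normal-reference bandwidth per axis on a 50 × 50
grid with 14 equally spaced contour levels; the grid extends three
bandwidths past the data range so it covers the bounding box and captures
essentially all density mass.

The methylation/expression association takes the CpGs inside wild-type
H3K27me3 regions, their gain/loss/no-change class, and the expression
change of their assigned genes (genes under 0.1 FPKM in both samples are
excluded). The distributions compared are of *genes*: a gene enters a
class once regardless of how many of its CpGs carry the label. CpGs of one
gene all share its expression change, so testing at CpG level
pseudo-replicates observations and is anti-conservative by orders of
magnitude — with gene-level units the test is calibrated under planted
independence. The family of pairwise class tests is summarised by a
BH-corrected any-significant call.

## The synthetic cohort generator

The generator emulates the deposited study design: genotypes with graded
H3K27me3 retention (defaults wt = 1.0, Suz12GT = 0.5, Suz12D = 0.02,
Eednull = 0.0) × two timepoints × ≥ 2 RRBS replicates. Defaults: 200 genes
(80 PRC2 targets) on a 10 Mb chromosome, 5 CpGs/kb with 30% of CpGs
clustered island-like within ±1 kb of target TSSs, mean CpG coverage 30,
nominal ChIP library 200 000 reads, beta-binomial dispersion rho = 0.02,
planted methylation gain 15 percentage points, expression slope 0.5 with
noise sd 0.3.

* **Chromatin.** PRC2-target promoters are bivalent in wild type at day 0.
  Each mutant retains each wild-type H3K27me3 region independently with its
  genotype's retention probability (recorded as truth). At day 5, 40% of
  targets gain H3K27me3 10-fold while losing H3K4me3 4-fold (resolving
  repressed), 30% lose H3K27me3 entirely while gaining H3K4me3 4-fold
  (resolving active), the rest stay static. Reads are a uniform background
  (85% of the nominal library) plus **absolute** per-region Poisson counts
  calibrated on the wild-type day-0 sample (15% of the nominal library).
  Absolute rates matter: a purely compositional model (fixed library split
  across regions) renormalises away a large planted gain — when 40% of
  regions gain 10-fold, each region's *share* grows far less than 10-fold —
  and the planted fold changes become unrecoverable from RPM. Real
  libraries are dominated by genome-wide background, which the small
  simulated genome can only mimic with absolute region rates.
* **Methylation.** True methylation is Beta(2, 38)-low (~5%) inside
  wild-type day-0 H3K27me3 regions and Beta(30, 6)-high (~83%) outside,
  matching the empirical bimodality of CpG methylation. CpGs inside regions
  lost in a genotype gain `meth_gain_delta` points of true methylation in
  that genotype. Replicates share the true proportion; counts are
  beta-binomial (coverage Poisson) so replicate matrices have realistic
  off-diagonal mass — with pure binomial counts the background model would
  be degenerate on the diagonal.
* **Expression.** log2 FPKM = gene baseline + slope × (−Δlog2 H3K27me3
  pseudo-level) + Gaussian noise, with the wild-type day-0 level as
  reference; non-target levels never move, so non-targets drift only by
  noise. Setting the slope to 0 yields expression-independence cohorts used
  for null calibration.

Each sample draws from its own RNG stream keyed by (seed, sample labels),
so identical configurations are bit-identical and adding samples never
perturbs existing ones.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequence context (no FASTA/FASTQ, no
bisulfite conversion error), fragment-level ChIP structure and input
controls, copy-number and mappability artifacts, more than one chromosome,
inter-gene correlation of expression noise, and any extra-binomial
variation beyond the single beta-binomial dispersion parameter. Results on
real cohorts additionally depend on upstream alignment, peak calling and
FPKM estimation, which this package consumes as inputs by design.

## Problem sizes

The shipped test suite and the acceptance script run entirely on generated
cohorts: 20 effect-free cohorts of ~5 000 CpGs (two genotypes) for null
calibration, one two-genotype cohort with ~3 800 H3K27me3-lost CpGs at
coverage 30 for signal recovery, n = 500 for segmented-regression recovery,
and one full four-genotype cohort (200 genes, 10 Mb) for the structural
checks. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances while keeping the whole suite in well under a
minute per component.
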