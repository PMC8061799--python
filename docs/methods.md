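# Methods

This note documents the statistical models, estimators, numerical
conventions, and deliberate design choices behind `centrodrive`, and what
the synthetic-data generators do and do not emulate.

## Panel model and filters

Lines are treated as effectively haploid: a homozygous diploid VCF call
collapses to a single allele code, and a residual heterozygous call is not a
valid haploid state — it is recorded as a flag and the call set to missing.
Missingness is a first-class code (never NaN), and every statistic recomputes
the per-site sample size n_s from non-missing calls.

Filters follow the panel-analysis conventions and are applied in a fixed
order: (1) restrict to biallelic SNPs inside annotated genes (indels and
multi-allelic records dropped and counted), (2) set genotypes covered by
fewer than 3 reads to missing, (3) remove sites with any heterozygous call,
(4) remove sites called in fewer than 10 lines, (5) remove genes with fewer
than 150 retained sites. Steps 3 and 4 are per-site predicates, so the
membership of the output is order-independent; the order matters only for
rule attribution in the filter log, where a site failing both is charged to
the het rule. The copy-number path deliberately bypasses the het-site and
minimum-depth rules: depth deviations are informative precisely where
genotypes are unreliable. Coordinates are 1-based inclusive throughout;
any half-open arithmetic is private to an operation.

## Diversity statistics

Per-gene π is Nei's average pairwise heterozygosity per site: at a site with
a alternate and b reference alleles among n_s called lines, the pairwise
difference fraction is a·b / C(n_s, 2); the per-gene value divides the sum
over usable sites (n_s ≥ 2) by the number of usable sites. Sites with
n_s < 2 cannot contribute a pair and are excluded from both numerator and
denominator (the count of usable sites is reported alongside). Tajima's D
uses the standard a₁…e₂ constants with the gene-mean n_s rounded to the
nearest integer; it is undefined (None) when S = 0 or when the normalizing
variance vanishes (n ≤ 3 edge cases). d_xy averages the cross-class
mismatch fraction over sites covered in both classes and is undefined — not
zero — when no site is. r² is the squared Pearson correlation of haploid
0/1 codes, algebraically D²/(p₁q₁p₂q₂); SNP pairs with fewer than four
jointly-called lines, or monomorphic among them, are skipped and not
counted.

Bootstrap confidence intervals are percentile intervals of n-of-n resampled
means (1000 replicates, seeded). Resampling *without* replacement at n-of-n
is the identity, so the with-replacement percentile bootstrap is the
implemented reading of that procedure; reported SEs are the bootstrap SD of
the mean.

## Sweep dating

**Mutation clock.** For a non-recombining haplotype that swept recently, the
genealogy of sampled copies is nearly star-like, and each of the n sampled
lines accumulates mutations independently for t generations over L assayed
positions. The Thomson estimator inverts this: t̂ = Σxᵢ/(n·μ·L), with xᵢ
the derived-allele count of each variant. The ancestral allele is the
majority allele among the focal lines, ties broken toward the reference
allele (this reproduces the published ancestral assignments for
singleton/doubleton configurations). Exonic sites only; heterozygous-flagged
sites are excluded, and genes with more than 5 heterozygous exon sites are
excluded entirely, as such genes typically reflect stacked copy-number
variants whose apparent SNVs are alignment artifacts. With missing data, the
optional fully-called restriction keeps variant detection and the L
denominator on the same footing, which is what keeps the estimator unbiased
in the recovery tests. The estimator omits the initial spread of the
haplotype to high frequency and therefore leans young; for a strong driver
that equilibrates within a few generations this bias is negligible.
Generations are years (annual plant) and all labels propagate that
equivalence.

**Haplotype-length clock.** Recombination erodes a swept haplotype at rate
~1/t per Morgan per side, so the shared segment around the selected site has
expected total genetic length 1/t Morgans t generations after the sweep
began, giving t̂ = 100·(kb/cM)/length_kb. Because the local recombination
rate is the dominant unknown, ages are reported over a rate grid
(150–1000 kb/cM by default) with no averaging across grid points. Shared
segments are measured between the midpoints of the last matching and first
mismatching informative SNP on each side (an unbiased convention for
breakpoints uniform between markers); where no mismatch occurs before the
data end, the boundary is the outermost genotyped SNP, so reported lengths
are conservative there.

**Haplotype grouping.** Long-range haplotype groups around the focal gene
are built greedily: each group is seeded with an unassigned line, remaining
lines are tried in decreasing order of their pairwise shared span with the
seed, and a candidate joins only if the group's joint shared segment still
covers at least `min_span_markers` (default 10) genotyped SNPs and does not
shrink the span the group already shares by more than `max_span_shrink`
markers (default 6). The two guards discriminate true co-descendants (which
match across the whole current span) from chance background matches (which
extend over short runs only); without the shrink guard, occasional chance
accretions truncate group segments and bias recovered lengths short by
roughly 10–15% in calibration runs against generator truth. Groups smaller
than 2 are reported as singletons. `max_mismatch` (default 0) tolerates
genotyping errors inside a span for robustness analyses.

## Forward simulator

The simulator is a haploid Wright–Fisher model of chromosomes: each
generation every offspring copies a uniformly chosen parent (with
replacement) and gains Poisson(μ·L) new mutations at uniform positions over
a finite sequence (repeat hits flip the site state; at μL ≈ 2.6×10⁻³
collisions are negligible but are handled exactly). The census follows
N_t = min(round(20·1.1^t), n_max). Every generation a without-replacement
sample of 13 chromosomes is scored and the run stops when the sample first
shows ≥ 9 segregating sites; μ = 0 runs censor at `max_gen`. Chromosomes are
stored as references into a mutation-event tree, so memory scales with the
number of mutation events, not population size × sequence length, and a
replicate at n_max = 50,000 takes tens of milliseconds.

The reported "generations of growth" pin counts complete 10% growth steps
of the founding stock (20 chromosomes carried by 10 diploid individuals)
before the census cap truncates growth: floor(log₁.₁(2·n_max/20)), which is
89 generations for a 50,000-chromosome cap and 113 for 500,000. This is the
unique reading consistent with both published durations; the naive
chromosome-count crossing time (83 generations for 50,000) matches neither.

Two facts about the stopping rule deserve emphasis. First, the sampled
segregating-site count is unbiased: E[S(t)] ≈ 13·μ·L·t during the star-like
phase, and at constant census the long-run sampled S matches Watterson's
θ·a_{n−1} — both are asserted in tests. Second, the *stopping time* of the
rule is systematically earlier than the mean-crossing time
9/(13·μ·L): a fresh sample is scored every generation, so the first passage
is triggered by upward sampling fluctuations (sd(S) ≈ √E[S]) rather than by
the mean. At μ = 10⁻⁸ the mean stop generation is ≈ 150 versus a
mean-crossing value of ≈ 270. Consumers of stop-generation distributions
should treat them as first-passage times, not TMRCA point estimates;
Thomson dating of a sample drawn at a *fixed* generation is unbiased and is
the supported way to invert simulation output to an age.

## Scans

Block permutation: the observed mean of a contiguous block of 8 genes is
compared to the means of 500 uniformly drawn contiguous 8-gene windows along
the chromosome. The focal window itself is never drawn (a tie with itself
would otherwise inflate the minimal attainable p), but overlapping windows
are allowed by default (`exclude_overlap` removes them). The p-value uses
the add-one convention p = (1 + #{null ≤ obs})/(n_perm + 1), so p > 0
always; under an i.i.d. null the p-values are approximately uniform
(asserted by KS test). p-values are invariant to affine transformations of
the statistic for a fixed seed.

Copy number: each depth cell is divided by its line's chromosome-wide median
exonic depth (lines with zero median are excluded with a warning), averaged
per gene, and genes whose swept-class mean lies outside [0.5, 3] are
excluded as likely misassembled or repetitive. The non-swept : swept
coverage ratio is binned at ≤ 0.25 (deleted) and ≥ 1.75 (duplicated); the
upper bin is open-ended since a display capped at 2 is the only reason the
published bins stop there.

## Drive quantification and QTL scan

With selfed families, the driving-allele frequency among progeny is
p = (f + m)/2 where f is the maternal and m = 0.5 the (assumed Mendelian)
paternal transmission rate, so the method-of-moments estimator from progeny
genotype counts is f̂ = 2p̂ − 0.5 with p̂ = (2n_DD + n_het)/(2n), clipped to
[0, 1]. The clip introduces bias only within ~2 progeny-count SDs of the
boundaries; at family size 1000 the bias is below 0.01 everywhere tested.

Genotype probabilities are hardened to calls only when the best class
strictly exceeds 0.8; the scan itself regresses %D_fem on the *expected*
allele dosage 2·P(GG) + P(NG) (Haley–Knott regression), which at dense
markers coincides closely with EM interval mapping while remaining fully
specifiable. The drive-locus class enters both nested models as a binary
cofactor, so LOD = (n/2)·log₁₀(RSS₀/RSS₁) measures each marker's effect
beyond the drive locus. Individuals enter the scan only with ≥ 12 F3
progeny behind their phenotype and < 50% missing hardened calls. The LOD
threshold is fixed at 2.0 (a deliberately generous screen; no permutation
thresholding by default), and the displayed trace is a centered 4-marker
moving average truncated at the edges. The factorial ANOVA of drive
strength on CenH3 × drive-locus genotype uses Type-II sums of squares
(statsmodels) because the genotype classes are unbalanced by segregation;
when an empty cell makes the interaction inestimable, main effects are
reported from the additive model and the interaction is flagged.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume — they are calibrated emulators, not process simulations:

- **Inbred panel** (default 34 lines, 14 swept): background polymorphism is
  site-i.i.d. with derived-count distribution P(i) ∝ 1/i, so expected
  heterozygosity per polymorphic site is 1/a₁(n) and a per-site
  polymorphism probability q = π_target·a₁(n) hits the diversity target
  (default π = 0.01) while centering Tajima's D on zero. Swept lines are
  identical across the drive interval except per-line private mutations
  drawn Poisson(μ·L·t) — the exact inverse of the Thomson clock. Missing
  data are sprinkled i.i.d. (default 10%). Depth is Gaussian around a mean
  of 30 reads (relative SD 0.1); the deleted interval draws
  |N(0, 0.05)|-scaled depth in non-swept lines. Genes are equal-length,
  single-exon, and laid out on one chromosome with the drive interval as a
  central contiguous block.
- **Swept flanks**: lines are assigned to (default 7) founder groups; each
  group draws one shared segment with per-side lengths exponential with
  mean 1/(2t) Morgans — total expectation 1/t Morgans, the exact inverse of
  the length clock — and members are identical inside it, independent
  Bernoulli(1/2) outside. Within-group breakpoint heterogeneity and
  mutation on the shared segment are not modeled.
- **F2 cross**: the drive-locus class is Bernoulli(1/2) (the heterospecific
  mother transmits only the driver); marker genotypes arise from two
  independent gametes per F2 with Haldane map-function recombination along
  each chromosome (no interference); planted modifiers act additively on f
  as (dosage − 1)·effect, clipped with f to [0, 1]; F3 counts are
  multinomial with probabilities (f/2, 1/2, (1−f)/2); genotype
  probabilities carry one-hot calling noise plus a configurable fraction of
  low-confidence triples that fail the hardening threshold.

Because sites are exchangeable and unlinked given the planted structure,
passing recovery tests demonstrates correct inversion of these models; it
does not validate behaviour under linked selection, demographic
non-equilibrium, alignment artifacts, or non-random missingness, all of
which real panels contain.

Problem sizes in the test suite are scaled to the structure being tested
(tens of genes, tens of replicates); the generators' *conditions* — sample
sizes, class frequencies, diversity targets, noise and missingness rates,
family sizes — stay at their study-like defaults. The modifier-power
experiment uses base transmissions (0.93, 0.73), the realized class means
of the mapping cohort, rather than the prior-cross expectations
(0.98, 0.58) that remain the generator defaults: with a base of 0.98 a
+0.1 modifier saturates at f = 1 in the heterospecific half of the cohort
and the planted effect would be partially erased by construction.

## Pipeline

Stages run in a fixed dependency order from one YAML config; each stage
derives its own seed from the master seed by hashing, so partial reruns are
reproducible, and every output TSV carries a header with the package
version, stage seed, and a hash of the scientific configuration (paths
excluded). Reruns with identical config and seed are byte-identical;
manifests are append-only per run directory. Per-gene LD in the pipeline
downsamples to the first 10 polymorphic sites per gene to bound the
quadratic SNP-pair cost; the library function itself is exact.

## Known limitations

- Tajima's D with heavy missingness uses a single rounded mean n for the
  constants rather than site-specific corrections.
- Haplotype grouping is greedy and order-stabilized, not an optimal
  partition; pathological mosaics could split groups.
- The haplotype-length clock ignores the group-size dependence of shared
  segment length (the intersection over k members shortens with k); the
  generator inverts the same convention, so recovery tests are well-posed,
  but on real data the estimator shares the published convention's bias.
- The simulator's stopping-generation distribution is a first-passage
  quantity (see above) and underestimates the mean-crossing age.
- The CLI's `scan-blocks` focal block is chosen as the minimum rolling-mean
  window, which is appropriate for screening but biased as a hypothesis
  test; supply a prespecified focal block for confirmatory use.
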