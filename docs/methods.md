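# Methods

This note documents the statistical procedures, the synthetic-data design
and the numerical choices behind `neuro17q`, in the spirit of a model
documentation page: what is computed, under which assumptions, and what
the test suite does and does not establish.

## Copy-number calling and the 17q balance value

Input is a per-sample table of genomic bins with log2 copy-number ratios
(and optionally integer copy numbers), as produced by standard
shallow-WGS copy-number callers. States are assigned per bin by fixed
log2-ratio thresholds: gain at ≥ +0.3, loss at ≤ −0.4, both inclusive.
These thresholds are conventional for low-coverage tumor sWGS and are
exposed as `Thresholds` fields.

The 17q balance statistic compares the median log2 ratio of the whole 17p
arm with the median over the distal 17q segment from the *IGF2BP1* locus
to the q terminus ("IMP1-ter"):

    bv = −median(IMP1-ter) + median(17p) + 0.2,    bv ≤ 0 ⇒ unbalanced.

Interpretation: a whole-chromosome-17 gain raises both medians equally and
leaves bv at its 0.2 offset (balanced); a q-restricted gain of one copy
(log2 3/2 ≈ 0.58) drives bv to ≈ −0.38 (unbalanced). The 0.2 offset
tolerates arm-median differences smaller than a heterozygous one-copy
event. The boundary bv = 0 is assigned to unbalanced.

Numerical conventions, chosen here and applied uniformly:

* Medians are unweighted over bins and use the mean-of-middle-two rule for
  even counts. Equal-width bins dominate low-coverage sWGS binning, so
  length weighting would change nothing in the common case.
* Arm-scale regions select bins by midpoint; locus-scale regions (e.g. the
  *MYCN* locus, usually smaller than one bin) select by interval overlap.
  A midpoint rule would return no bins for sub-bin loci.
* MNA calling is strict: copy number at the *MYCN* locus must exceed 4.
  Integer copy number is used when present, otherwise derived as
  2·2^log2ratio.
* All coordinates are 0-based half-open internally; BED enters natively,
  GFF3 is converted at the parse boundary.

Region extents (17p, *IGF2BP1* start, q terminus, *MYCN* locus) are
configuration, not constants, so reduced toy genomes work end to end.

## MNA-context essentiality screen

The screen takes a genes × cell-lines dependency matrix (more negative =
more essential), a matched log2 TPM expression matrix, a two-level group
label (MNA vs other) and a common-essential gene list. The cascade:

1. **Expression filter**: gene expressed (log2 TPM strictly > 2) in at
   least round(0.85·n_MNA) MNA lines. The fraction is realized by
   round-half-up so that a 13-line MNA panel requires 11 lines, matching
   the screen design this generalizes; a ceiling rule would demand 12.
2. **Median-dependency filter**: median over MNA lines strictly below
   −0.2 *and* median over other lines strictly above −0.3. The two
   one-sided conditions enforce MNA-selective essentiality.
3. **Presence and common-essential exclusion**: genes missing from either
   group are dropped (logged, not an error); genes on the common-essential
   list are removed so the screen reports context-specific dependencies.
4. **Moderated t-test** on the surviving genes (see below), then
   Benjamini–Hochberg adjustment; hits are genes at FDR < 0.05.

The three filters are independent set predicates, so their order cannot
change the tested set; the implementation applies them in the order above
and retains every intermediate flag per gene in the result table.

### Empirical-Bayes moderated t

For gene g with group-mean difference Δ_g and pooled residual variance
s²_g on d = n₁ + n₂ − 2 degrees of freedom, the prior (d₀, s₀²) of a
scaled inverse-chi-square variance distribution is fitted by moment
matching on e_g = log s²_g − ψ(d/2) + log(d/2): the mean of e identifies
log s₀² (after the analogous ψ(d₀/2) − log(d₀/2) correction) and its
variance in excess of ψ′(d/2) identifies ψ′(d₀/2), inverted by a Newton
iteration on the trigamma function. Non-positive excess variance yields
d₀ = ∞ (full shrinkage to s₀², normal reference distribution). Shrunken
variances s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) feed the statistic
t_g = Δ_g/(s̃_g·√(1/n₁ + 1/n₂)) with d₀ + d reference degrees of freedom,
two-sided.

Choices: the variance prior is constant (no mean-variance trend, no
robustified fitting); hits are not sign-restricted beyond the median
filters, which already impose directionality. Note that when all s²_g are
identical the fitted d₀ is infinite and s₀² is the *bias-corrected*
variance exp(mean e), which differs from s²_g by the factor
exp(log(d/2) − ψ(d/2)) → 1 as d grows; the moderated t then equals the
ordinary t up to that vanishing factor, not exactly. A `prior` override
exists; d₀ = 0 reduces every test to the ordinary pooled t exactly.
Degenerate inputs: all-zero variances raise; a single gene falls back to
the ordinary t with a warning.

The test suite validates the implementation against an independently
written scalar oracle (brentq trigamma inversion, plain loops) to 1e-8 on
100 random instances, and checks recovery of known hyperparameters
(d₀ = 4, s₀² = 0.04) within 25% relative error at 200 genes.

## Chromosome enrichment

For a gene list of size K in an annotation of N autosomal protein-coding
genes, each chromosome with n genes and k list members gets the upper-tail
hypergeometric p-value P(X ≥ k), inclusive of the observed count (the
standard over-representation convention; an exclusive-tail flag exists).
Tail sums are accumulated via the log survival function because the
chromosome-17 enrichment of MNA-essential genes reaches magnitudes near
1e-22. Percentages are 100·k/K. No cross-chromosome multiple-testing
correction is applied; the reported values are raw, matching how such
tables are conventionally printed. The package ships the published
per-chromosome count table of the neuroblastoma screen
(`NEUROBLASTOMA_ESSENTIAL_COUNTS`, N = 19,046, K = 175) as a reference
input; all of its printed p-values reproduce to printed precision under
the inclusive tail.

## Expression association

* **Spearman** is Pearson on average ranks (tie-corrected), delegated to
  scipy; constant vectors return missing with a warning.
* **Correlation-of-correlations** computes genome-wide Spearman profiles
  for an anchor gene (e.g. *IGF2BP1*) and a transcription factor, then
  correlates the two profiles over the shared gene universe. Both the
  anchor and the TF are excluded from that universe by default: their
  trivial self-correlations of 1 would otherwise inflate the statistic.
  A minimum-summed-expression filter (linear-scale sum ≥ 1 across
  samples) is applied by default; zero-variance genes are dropped with a
  logged count. The statistic is symmetric in (anchor, TF).
* **ADRN/MES signature score** is the difference of mean per-gene
  z-scores (adrenergic minus mesenchymal set), z-scoring each gene across
  samples on the log2 scale. A ratio of raw sums would be fragile to
  per-gene scale; the z-score difference is this package's explicit
  definition and the output column is named `adrn_minus_mes` accordingly.
* **E-box scanning** reports every (overlapping) occurrence of CANNTG,
  0-based. The motif is its own reverse complement, so one strand
  suffices. An ambiguous base (N) in the two degenerate positions does
  not assert a match.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines (censorings at an event time follow events, the standard
convention). Expression dichotomization:

* **median**: threshold at the median of log2-transformed values; strictly
  greater = high.
* **best_cutoff**: every distinct observed value within [P10, P90] (median
  always included) is evaluated and the threshold minimizing the log-rank
  p is returned. The minimized p is *not* adjusted for the optimization
  and the result carries a `p_is_optimized` flag; the test suite
  demonstrates the anti-conservatism on null simulations (rejection well
  above the nominal 5%). The percentile bounds prevent degenerate
  near-empty groups.

Genes failing the minimum-summed-expression filter (linear sum < 1 across
samples) are reported as filtered out, not errors. The chi-square
reference of the log-rank test is asymptotic: on a 6-sample toy instance
its p (0.025) differs from the exact permutation p (0.1, only 20 label
splits exist); the suite checks the statistic exactly against a hand
oracle and p agreement at n = 40 where the approximation holds to ~0.02.

## Multi-evidence ranking

Each evidence criterion declares a scaling mode — unit [0, 1] for
occupancy-style scores (ChIP, CLIP), symmetric [−1, 1] for signed
quantities — and an orientation. Rows are min-max scaled (constant rows
map to all zeros: no information, neutral in both modes), oriented so
larger = more oncogenic, and averaged per gene over non-missing criteria.
Missing evidence is excluded from the mean, not scored as zero: absence
of a binding-site record means "no data", not "no binding". The composite
mean is this package's explicit combination rule for what is otherwise a
visual heatmap judgment; ties break lexicographically by gene id. The
ranking is invariant to per-criterion affine transforms and to sign flips
accompanied by orientation flips.

## Synthetic cohort design

The generator emulates the reference study conditions so that passing
tests are meaningful at those operating points:

* **Cohort**: 100 tumors by default; 17q gain prevalence 0.79, of which
  unbalanced (IGF2BP1→q-ter only) gains 0.35 and whole-chromosome-17
  gains the remainder; MNA prevalence 0.17. A toy genome of chr1, chr2
  and chr17 (real lengths, real centromere and *IGF2BP1*/*MYCN*
  positions, 40 bins per chromosome) carries all region-dependent logic.
* **Copy number**: bin log2 ratios are Gaussian around the planted event
  means (+log2(3/2) for one extra copy; noise SD 0.1, matching what
  low-coverage sWGS binning typically achieves). MNA samples get an
  integer amplicon CN drawn uniformly from 8–30 at the *MYCN* bin. The
  Gaussian noise model is a stand-in; real sWGS log2 ratios have
  GC-driven and wave artifacts this generator does not emulate.
* **Expression**: log2 TPM with per-gene baselines; *IGF2BP1*, *MYCN* and
  a 30-gene driver module load on a shared latent Gaussian factor with
  loading √ρ, giving pairwise correlation ρ (default 0.8) between loaded
  genes.
* **Dependency screen**: 13 MNA vs 607 other lines; 2000 genes with 40
  planted MNA-selective dependencies at effect −0.5 and noise SD 0.15; a
  50-gene common-essential set at −1 in both groups; 10% of background
  genes unexpressed to exercise the expression filter (planted and
  common-essential genes always expressed).
* **Survival**: exponential event times, baseline median 10 years, hazard
  multiplied by 8 (the order of magnitude reported for unbalanced-17q in
  multivariate tumor-cohort analyses) for high-risk (MNA or unbalanced)
  samples; 60% uniform censoring.

All randomness derives from one seed split into named per-component
child streams, so adding a component never perturbs the others; fixed
config ⇒ byte-identical outputs. What passing tests show: the pipeline
recovers *planted* structure under Gaussian noise at the stated effect
sizes. What they do not show: robustness to subclonality, batch effects,
segmentation artifacts or non-exponential survival, none of which the
generator emulates.

## Problem sizes used in the test suite

Balance-classifier recovery runs at n = 400 samples; screen recovery at
2000 genes × 620 lines; log-rank power at 200 per arm over 60 replicates;
the best-cutoff null at n = 50 over 120 replicates; the permutation
oracle at 1e5 permutations (memoized over the 20 distinct splits of the
toy instance) and 2e4 at n = 40. These sizes give stable pass/fail
margins for the asserted thresholds.

## Known limitations

* No segmentation, GC correction or calling from reads: the pipeline
  consumes binned copy-number tables.
* The screen does not model a mean-variance trend in the dependency
  scores, and does not attempt to reproduce any specific versioned
  external dependency-portal release (an optional integration test takes
  such an export by path).
* Best-cutoff survival p-values are reported unadjusted (flagged), as is
  conventional in tumor-cohort reports; they should not be read as
  calibrated significance.
* The hypergeometric test is conservative on discrete counts; no mid-p
  correction is applied.
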