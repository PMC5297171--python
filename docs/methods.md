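# Methods

This note documents the statistical models behind `sexbias`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Expression summaries

Expression is handled as a genes × samples matrix of RPKM values (reads per
kilobase of transcript per million mapped reads), optionally paired with raw
counts. Genes whose maximum over all samples is below 1 RPKM are dropped as
uninformative before any testing (the comparison is inclusive: a gene peaking
at exactly 1 RPKM is kept).

The population summary per gene and (tissue, sex) cell is a **trimmed mean**:
with n ≥ 4 samples, one minimum and one maximum are removed and the rest
averaged; with n ≤ 3 the plain mean is used. "Two most extreme" is read as
one from each tail — a symmetric trim removes skew in both directions, which
is the point of trimming outlying donors. Removing the two largest values, or
the two most deviant from the mean, are defensible alternatives; the
symmetric choice is fixed here and tested. Ties at an extreme drop exactly
one instance, so the statistic is deterministic. Note one consequence,
exercised in the tests: duplicating every sample does *not* leave the trimmed
mean unchanged, because the trim still removes only one value per tail.
Cells with no samples (sex-limited tissues, e.g. uterus or testis, for the
other sex) are absent from the summary, never zero-filled.

## Differential-expression engines

Both engines return a probability in [0, 1]; a gene–tissue pair is called
sex-differentially expressed (SDE) at probability ≥ 0.95 (inclusive). No
additional multiple-testing layer is applied on top of that cutoff.

**Population engine.** A permutation test treating donors as biological
replicates: the statistic is the absolute difference of the two sexes'
trimmed means; sex labels are shuffled (default 2000 permutations, enough
resolution for the 0.95 cutoff), and probability = 1 − (r + 1)/(n_perm + 1)
where r counts permutations reaching the observed statistic. The estimator
never returns exactly 1 and is valid (if slightly conservative) under ties.
A vectorized variant shares the permutation indices across all genes of a
tissue; this is how whole-matrix scans are run and makes per-tissue cost
independent of gene count up to array arithmetic. With small groups the
achievable probability is bounded by the number of distinct label splits —
with fewer than ~8 samples per group the 0.95 cutoff may be unreachable, a
resolution limit rather than a defect.

**Multinomial-simulation engine.** For detecting genes whose signal lives in
a sample subset (and is averaged away by a population test), per-condition
trimmed-mean *count* summaries are treated as one pseudo-sample each. Read
counts are modeled as multinomial with feature probabilities equal to each
gene's share of the condition's reads; pseudo-replicates (default 200 per
condition) are drawn at the mean observed library size. The observed
statistics per gene are M = |log2 fold change| and D = |difference| of
CPM-normalized counts (zeros offset by 0.5); the null cloud pools
within-condition replicate pairs across all genes (subsampled to at most
50,000 points), and the probability is the fraction of the null cloud
strictly dominated in both coordinates. A gene is flagged by the
**complementary rule** when its simulation probability is ≥ 0.8 and exceeds
the population probability by ≥ 0.2; such flags enter the score matrix as
significant calls alongside the ≥ 0.95 population calls.

## The SDE score

    SDE(g, t) = log2( (1 + EXPR_w/MAX_g) / (1 + EXPR_m/MAX_g) )

with EXPR the per-sex expression summary in tissue t and MAX_g the gene's
maximal summary over **all** tissues, sex-limited ones included. The score is
bounded in [−1, 1]: +1 iff women's expression equals the gene maximum while
men's is 0, −1 for the mirror, 0 for equality; expression differences in
tissues far below the gene's maximum yield proportionally small scores. The
score matrix covers common tissues only (both sexes sampled), with 0 for
non-significant cells; the trimmed means feed both the score and MAX_g so the
two are on one scale. A gene with MAX_g = 0 scores 0 everywhere.

Pattern clustering is k-medoids under Euclidean distance (seeded random
initialization, alternating assignment/medoid-update until stable). No
k-medoids implementation exists in the installed scientific stack, so it is
implemented here directly; all-zero rows are assigned a background label (−1)
rather than wasting a cluster on them.

## Sex-specificity bands

Per non-Y gene, the maxima of the trimmed means over each sex's tissues give
(max_w, max_m); rules are applied in order on ratio = higher/lower:

1. lower ≥ 1 RPKM and ratio ≥ 4 → sex-specific;
2. lower < 1 RPKM, higher ≥ 1 RPKM, ratio ≥ 2 → sex-specific;
3. lower ≥ 1 RPKM and 2 ≤ ratio < 4 → moderately sex-specific;
4. ratio ≤ 1.1 → sex-similar;
5. otherwise unclassified (this includes genes between 1.1- and 2-fold, and
   genes with both maxima < 1 RPKM, since no rule's expression floor is met).

Band lower bounds are inclusive ("at least 4-fold" style wording, applied
uniformly); whether 4-fold/2-fold boundaries are open or closed was a free
choice and is frozen here as closed. Direction (women/men) follows the sex
holding the higher maximum. Significance of a specific call compares women
samples of the women-maximal tissue with men samples of the men-maximal
tissue using the population engine (≥ 3 samples per side required).

## Substitution enumeration and selection statistics

Every CDS position admits 3 substitutions; consequences are precomputed for
all 64 codons × 3 positions × 3 alternates from the standard genetic code
(and verified in tests against translating the full mutant CDS). Classes:
synonymous (S), non-synonymous (NS), stop-gain, stop-loss, stop-to-stop. An
NS substitution is **deleterious (DNS)** only when both predictors call it
deleterious (predictor 1 vocabulary: deleterious/tolerated; predictor 2:
deleterious, probably-damaging / possibly-damaging, benign — only the first
two count as deleterious calls). Stop-loss and stop-to-stop changes (the
terminal codon's substitutions) are tallied but excluded from every rate, so
per internal codon possible S + NS + stop-gain = 9 and a CDS of length L
contributes 3(L − 3) substitutions to the denominators.

Rates are observed/possible per consequence class. A zero denominator is an
*undefined rate*, signalled explicitly (exception or flag), never silently 0.
Gene-set statistics are **pooled** — sum of observed over sum of possible —
rather than means of per-gene ratios, because per-gene synonymous counts are
frequently zero and single per-group ratios are the quantity of interest; a
regression test pins the difference. MAF thresholds are strict: dDNS uses
variants with MAF > 0.005, dStop with MAF > 0.001 (selection barely acts on
very rare, predominantly new variants, so including them dilutes the
signal). The synonymous rate in each ratio's denominator is computed at that
ratio's own threshold, so each ratio compares classes on the same frequency
stratum; thresholds for the neutral class are not separately specified
anywhere, and this same-stratum convention is the interpretation adopted
here.

**Randomization test.** The target set's ratio is compared with same-size
sets drawn without replacement from a pool (non-Y-linked, non-testis-specific
genes in the pipeline); p = (r + 1)/(n_iter + 1), one-sided in the
reduced-selection direction (random ratio ≥ target), with n_iter = 10,000 by
default so the smallest reportable p is just under 10⁻⁴. The (r+1)/(n+1)
estimator is never zero and unbiased under the null. Random sets whose pooled
synonymous count is zero have an unbounded ratio and are counted in the
≥-target tail (conservative). Random-set mean and standard deviation of the
finite ratios are reported alongside. An exhaustive mode enumerates all
subsets instead of sampling, for small pools and for oracle testing. Group
comparisons of a single rate use Fisher's exact test (two-sided, via scipy)
on the 2×2 table (observed, possible − observed) per group, reported with
the rate fold-change.

**MAF-binned distributions.** Per MAF bin (half-open intervals over (0,
0.5]), per-gene ratios are computed from the bin's variants and histogrammed
into ratio categories (default edges 0, 0.1, 0.5, 1, 2, ∞, plus an
"undefined" column for genes with no synonymous variants in the bin). A
single all-covering bin reproduces the unfiltered per-gene ratios.

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every calibration below is run.

**Transcripts.** Uniform random sense codons between an ATG and one terminal
stop; lengths uniform over multiples of 3 in a configurable range (default
300–900 nt, matching short human CDS scale at desk-scale cost). Chromosome
classes are planted (2% Y, 5% X, rest autosomal) so Y-exclusion logic is
exercisable. No introns, isoforms, UTRs, or codon-usage bias — consequence
enumeration and the downstream rates are insensitive to these, which is what
passing tests establish; they say nothing about, e.g., real human
stop-gain density per gene.

**Expression.** Per-gene baseline RPKM is log-normal (median 5, σ = 1);
per-tissue factors are log-normal (σ = 0.5); both sexes share these means.
Planted classes multiply one sex's mean in that sex's maximal-mean tissue by
the class fold — 10× for sex-specific (comfortably past the 4-fold band),
3× for moderately specific (inside 2–4), 2× in a random sex for
single-tissue SDE genes; sex-similar genes have exactly equal means. Because
the boosted tissue is the sex's maximal one, the expected cross-sex maximal
ratio equals the planted fold. Counts are negative binomial with
var = m + d·m² (default dispersion d = 0.1, typical for bulk RNA-seq
biological replicates) around mean = RPKM × length_kb × library-size, at a
nominal 50 million mapped reads per sample; RPKM values are recomputed from
the sampled counts, and dispersion 0 short-circuits to exact means (no
Poisson floor) for degenerate-noise tests. Ages are uniform 20–79,
pass-through metadata only. Sample sizes default to 20 per tissue per sex —
small enough to run everywhere, large enough for the permutation engine's
resolution; the last two tissues are women-only ("uterus") and men-only
("testis") so sex-limited handling and the testis-specific pool exclusion
are always exercised.

**Variants.** Each possible substitution is observed with its gene's
regime's per-class acceptance probability (S, deleterious NS, benign NS,
stop-gain); stop-loss is never observed. The planted dDNS/dS of a regime is
acceptance(DNS)/acceptance(S) — this is the parameter-recovery target. True
deleteriousness of each possible NS substitution is an independent coin flip
(default P = 0.5); the two predictor labels each equal the truth with
probability `predictor_concordance` (default 0.95). MAFs come from a
three-stratum distribution — below 0.001, 0.001–0.005, above 0.005 with
masses 0.70/0.15/0.15, log-uniform within strata — weighted toward rare
alleles as real site-frequency spectra are, and straddling both analysis
thresholds so either branch is testable; a regime may override the MAF
distribution to couple frequency to consequence. Default regimes plant the
biology under study: relaxed purifying selection on the four sex-specific
classes (dDNS/dS = 0.6) over a purifying background (0.25). Variants are
unlinked and sites at most single-hit per alternate; no coalescent structure.

**Calibration conditions.** Neutral-calibration and parameter-recovery runs
(and the acceptance script's neutral target) use equal acceptance across all
classes, MAF independent of consequence, and `predictor_concordance = 1`.
The concordance choice follows from the estimator, not from tuning: observed
DNS counts scale by concordance² + leakage from misclassified benign NS, a
≈ 0.90 multiplicative bias at the 0.95 default that measures predictor
noise, not selection. The calibration isolates the rate machinery, so
perfect predictors are part of its definition; the pipeline default remains
0.95.

## Problem sizes and numerical conventions

Calibration suites run at 500 genes (CDS 300–900 nt) for neutral calibration,
recovery of planted acceptance ratios {1.0, 0.5, 0.25, 0.1} (each within
±20%, ordering strict), and DE error rates (false-positive rate ≤ 7% at the
0.95 cutoff on sex-similar genes with 20 samples per group; power ≥ 90% at
10-fold effects); the randomization-null uniformity check uses a 200-gene
pool, 200 replicate target sets, 500 iterations each, Kolmogorov–Smirnov
p > 0.01. Bootstrap intervals are percentile intervals over genes (1000
resamples). All randomness flows through numpy Generators seeded from a
single integer, with independent per-stage streams spawned as
`default_rng([seed, stage])`; equal seeds give byte-identical outputs.
Probabilities from permutation/randomization tests always use the
(r + 1)/(n + 1) correction. Ties in medoid assignment and in argmax tissue
selection resolve to the first index (stable order).

## Known limitations

- The generator's RPKM distribution is pragmatic (log-normal), not fitted to
  any real compendium; absolute SDE counts per tissue are not comparable to
  real-data counts.
- The population engine is a plain permutation test; it shares only the
  probability contract (0.95 cutoff semantics) with empirical-Bayes DE
  methods, not their variance pooling across genes.
- Variant positions are CDS-relative throughout; there is no genome
  coordinate system or liftover.
- The multinomial-simulation engine's probability is a dominance fraction
  against a pooled null cloud; with very few genes the cloud is small and
  probabilities are coarse.
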