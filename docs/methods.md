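# Methods

`senesig` implements an analysis of DNA-methylation dynamics in cellular
senescence on Illumina-450K-style beta values: early-proliferating (EP)
versus deeply senescent (DS) cultures profiled in two replicated
experiments, a tissue cohort scored for an in-vivo senescence signature,
germline genotype association with that signature, and a reversal
timecourse after p16 knockdown.  Because the real array data are not
bundled, a synthetic generator with a complete ground-truth record supplies
every input; this note describes the statistical model of each stage, the
generator's assumptions, the numerical conventions, and the known
limitations of what the synthetic tests demonstrate.

## senDMP calling

A senescence-associated differentially methylated position (senDMP) is a
probe whose beta value differs between EP and DS groups with q < 0.01
(Benjamini–Hochberg step-up over all tested probes) and an absolute mean
beta difference Δβ > 0.3.  Both inequalities are strict.  Significance comes
from a per-probe one-way ANOVA F-test with (k−1, n−k) degrees of freedom
computed on beta values directly; no M-value transform is applied because
the effect-size filter is defined on the beta scale, and no empirical-Bayes
variance moderation is used — each probe is judged on its own replicates.
The BH step-up is used wherever a "q-value" is required.

Degenerate probes are resolved deterministically: zero between-group
variance gives F = 0, p = 1; zero within-group variance with unequal means
gives the smallest positive double as p and a `degenerate` flag.  Probes
with fewer than two non-missing values in any group are dropped and logged.
Probe QC removes multimapping and low-detection-flagged probes and, by
default, sex-chromosome probes.

## Signature groups and DS discordance

Calls from the two experiments are combined into five disjoint sets:
`agree` (called in both, same sign of Δβ), `disagree` (called in both,
opposite sign), `exp1_only`/`exp2_only` (called in one with |Δβ| < 0.1 in
the other), and `unclassified` (called in one with |Δβ| ≥ 0.1 in the other
but not called there).  Probes that differ between the two experiments' DS
states are partitioned into four exhaustive categories at threshold 0.1:
batch effect (small in both), unique change (large in exactly one), and
common changes with same or opposite direction.  Equality at the threshold
counts as "change" so that the partition is always exhaustive.

Overlap enrichment of two probe (or gene) sets uses both an analytic fold
(observed / |A||B|/|U|, the hypergeometric expectation) and an empirical
fold against the mean overlap of uniform same-size draws from the universe,
with an add-one empirical p-value (1 + #{resample ≥ observed}) /
(1 + n_resamples) that never reports exactly zero.

Co-methylation takes each called probe ("index"), finds the nearest other
probe on the same chromosome (ties resolve to the upstream probe), keeps
pairs at most 500 bp apart, and reports the Spearman correlation between
index and neighbor Δβ.  Neighbors that are themselves index probes are
retained; removing them would bias the correlation downward.

## The senDMP score

For sample k,

    S_k = (1/n_hyper) Σ_i B_hyper_ik − (1/n_hypo) Σ_i B_hypo_ik + c

with offset c = 0.35 by default, chosen so the lowest score of a reference
cohort sits near zero.  Signature probes absent from the scored matrix are
skipped, guarded by a 50% minimum-coverage gate per probe list, and
per-sample probe usage is reported.  Rank associations of the score (with
age, with expression, and between the hyper and hypo component means) use
Kendall's tau-b with tie correction; the tumor/normal comparison uses the
Welch unequal-variance t-test with sign convention
t = (mean_normal − mean_tumor)/SE, so higher tumor scores give negative t.

## Genotype association

For each SNP, Pearson correlation between risk-allele dosage (0/1/2) and
methylation is computed across individuals for every senDMP
(pairwise-complete; cells with a constant vector or under three complete
pairs are missing).  senDMPs with |r| > 0.15 are binned by direction ×
correlation sign; concordant counts (hyper & r>0, hypo & r<0) mean the risk
allele looks DS-like.  The statistic is the 1-df goodness-of-fit chi-squared
of the concordant/discordant split against 50:50 — equivalently
(concordant − discordant)²/n — signed positive for DS-like, so its magnitude
is bounded by the number of informative senDMPs.  A 2×2 independence-test
variant is available behind a flag.  Significance uses an empirical
permutation null, by default redrawing random probe sets of the same
hyper/hypo sizes from the universe and recomputing everything
(`resample_probes`); shuffling the hyper/hypo labels on the fixed set
(`shuffle_directions`) is kept for sensitivity analysis.  SNPs with a
minor-allele count below 3 are skipped.

Because the statistic saturates at the informative-probe count, a strongly
causal SNP and an extreme null SNP can tie at the cap; "top-ranked" is
therefore best read as competition ranking (no competitor strictly larger),
with the lexicographic snp_id tie-break used only to make tables
deterministic.

### A caveat on the permutation null

In a cohort where a latent per-sample senescence burden drives all
signature probes jointly, a null SNP whose genotype is chance-correlated
with the burden (the sampling sd of such a correlation is ≈ 1/√n ≈ 0.117 at
n = 73) shows a genuinely directional correlation pattern across the
signature, while resampled probe sets carry no burden signal.  The
permutation p-values of null SNPs are then strongly anti-conservative: they
answer "is this SNP associated with the signature as observed in this
cohort", not "is this SNP causal for it".  The package's tests demonstrate
both regimes: with burden heterogeneity switched off the null p-values are
uniform (the machinery is exactly calibrated), and with burden present a
large fraction of null SNPs reach small p — the same heavy-tailed behaviour
that motivates screening thresholds on the chi-squared statistic in real
GWAS-catalogue scans.

## Reversal analysis

Per senDMP the residual from the proliferating state is
|mean over timepoint replicates − mean over EP replicates|, and a site
counts as reverted below threshold t when the residual is strictly below t
(0.3 = back inside the calling threshold, 0.1 = essentially complete
reversal).  Replicate means, not per-replicate calls, are compared.
Residual drift of sites called only in the other experiment is summarized
by Kendall tau-b between (timepoint − DS) and that experiment's (DS − EP)
deltas, plus a sign-concordance fraction; this pairing of delta vectors is
one consistent reading of "similar directionality" and is configurable.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **Baseline methylome** — a bimodal mixture (45% Beta(1,10)-like low, 45%
  Beta(10,1)-like high, 10% intermediate), reflecting the U-shape of array
  beta values.
* **Replicate noise** — observed betas are Beta(mν, (1−m)ν) around the
  group mean m, keeping draws in [0,1] with boundary-shrinking variance.
  The default concentration is ν = 50 (noise sd ≈ 0.05 mid-range).  Real
  450K triplicates are far more concordant (R² > 0.99, implying ν in the
  several-hundreds); with only three replicates per group, ν = 50 leaves
  the F-test underpowered to call |Δβ| ≈ 0.3 at q < 0.01 among 20,000
  probes (the attainable p at Δβ = 0.3 with df = (1,4) is ≈ 3×10⁻³, above
  any plausible BH cutoff).  Recovery-oriented tests and the pipeline
  default therefore use ν = 500, the concordance-matched regime; ν = 50 is
  retained as the default for the score- and genotype-level analyses,
  which average over hundreds of probes and are insensitive to it.
* **Planted senDMPs** — per experiment, a configurable number of hyper and
  hypo sites with |Δβ| ~ Uniform(0.3, 0.5), split between shared
  same-direction, shared opposite-direction and experiment-exclusive
  blocks.  Baselines of planted sites are drawn so the shifted mean stays
  inside [0.01, 0.99] without clipping distortion.
* **Probe layout** — non-neighbor probes are spaced > 1000 bp apart; a
  configurable fraction of planted sites donates a correlated delta
  (index + N(0, 0.1)) to a partner probe placed within 500 bp.  Random
  background sets therefore contain few eligible neighbor pairs, so the
  co-methylation background distribution is informative only about planted
  pairs in this synthetic layout — unlike real arrays, where probes cluster
  densely in CpG islands.
* **Cohort** — each individual draws a latent burden b ~ Uniform(0, 1);
  signature-probe means are baseline + direction·δ·b, so a fully senescent
  sample (b = 1) reproduces the in-vitro DS shift.  Tumors add a burden
  shift of 0.3.  Age is linear in burden (30 + 40·b years) plus N(0, 8)
  noise — chosen to span a plausible adult cohort with a realistic but
  imperfect age–senescence correlation.
* **Genotypes** — Hardy–Weinberg dosages at MAF ~ Uniform(0.05, 0.5);
  causal SNPs add η·dosage·direction (η = 0.15 per allele) to a subset of
  signature probes (default 20% of the signature, so the genotype effect
  perturbs rather than dominates the burden signal in the score).
* **Expression** — log-scale values N(8, 1) per gene with N(0, 0.5) sample
  noise; planted DE genes shift by 2 units in tumors, and a configurable
  fraction of DE genes is drawn from the senDMP-annotated genes to plant a
  known enrichment fold.
* **Reversal** — timepoint means are DS + r·(EP − DS) with per-site
  completeness r ∈ [0, 1] drawn per timepoint (Beta(6,2) at day 2,
  Beta(3,2) at day 5, i.e. day-5 re-senescence), plus a drift of
  experiment-2-only sites toward their experiment-2 delta.  A helper builds
  completeness profiles hitting exact fraction-below targets for noise-free
  validation.

One global seed feeds independent named substreams per output block, so
identical parameters and seed reproduce every output bit-for-bit and adding
a block never perturbs earlier draws.

## Numerical conventions

* Beta values are written to 6 decimal places; "NA" is the missing token.
* Annotation uses BED convention (0-based, half-open); probe position is
  the interval start; probe distance is |pos_i − pos_j|.
* Sum-of-squares below 10⁻²⁴ counts as zero in the ANOVA degenerate-case
  logic.
* Empirical p-values use the add-one estimator and live in
  [1/(n+1), 1].
* All resampling and permutation routines accept an explicit seed and are
  reproducible bit-for-bit.

## Problem sizes used in the test suite

Simulated instances in the tests are scaled to the structure being checked
rather than to array scale: 20,000 probes for null calibration of the
F-test (10 seeds), 2,000–8,000 probes elsewhere, cohorts of 73 individuals
per arm, 200 SNPs with 1,000 permutations for the genotype analysis, and
20-seed medians wherever a criterion is statistical.  These sizes preserve
the per-test power calculations above while keeping the suite fast.

## Known limitations

* The F-test's finite-sample size under skewed Beta noise at n = 3 + 3 is
  slightly conservative (≈ 0.046 at nominal 0.05); the null-calibration
  test tracks the median over seeds against a 3-SE binomial band.
* The generator plants no cell-composition structure, copy-number
  artifacts, probe cross-hybridization, or batch effects beyond the
  experiment-exclusive senDMP blocks; passing tests therefore say nothing
  about robustness to those features of real data.
* One gene per probe; multi-gene annotations are out of scope.
* The permutation null caveat above: in burden-heterogeneous cohorts the
  per-SNP permutation p measures in-sample association with the signature,
  not causality, and its null distribution is not uniform by design.
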