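# Methods

`phenoscreen` implements a phenotype-to-transcriptome inference chain for an
HD (Huntington's disease) mouse cohort: behavioural trait processing and
extreme-performer classification, a rank-correlation screen of gene
expression against traits, a self-contained negative-binomial (NB)
differential-expression stage, a four-way severity partition of the
resulting gene sets, and a presence-progression analysis of those sets
across an allelic-series grid (CAG-repeat length x age). This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic cohorts do and do not establish.

## The synthetic cohort

Real cohorts of this design (24 wild-type and 29 transgenic males from a
few litters, traits measured at weeks 11 and 13, striatal RNA-seq of the
classified extremes) cannot be reproduced from printed numbers alone, so
every stage is exercised on simulated cohorts with planted structure
(`phenoscreen.simulate`).

**Latent severity.** Each mutant carries a latent factor s_i ~ N(0, 1);
*lower* values mean a worse phenotype. Wild-type animals have no severity
component, so no trait-expression correlation is planted in them — the
genotype asymmetry of the design.

**Traits.** value = baseline + genotype_effect * is_mut +
loading * s_i * is_mut + drift * timepoint + noise, with noise ~ N(0, sd).
Defaults emulate the three classification traits on realistic scales:
rotarod latency (s; baseline 220, mutant effect -90), feet-clasping
duration (s; baseline 4, mutant effect +55, orientation -1: larger is
worse) and body weight (g; baseline 27.5, mutant effect -3). Loadings are
signed to align with orientation and default to twice the noise s.d.
(loading/noise = 2), the planted signal-to-noise used throughout the
studies.

**Counts.** counts ~ NB(mean m, variance m + alpha m^2) with
m = base_mean * libfactor * 2^shift; alpha = 0 falls back to Poisson.
Defaults: 2000 genes, base_mean 100, alpha 0.05, library factors uniform on
[0.7, 1.4]. 100 signature genes carry a planted genotype log2 fold change
(default magnitude 1; 30% in the up direction); 60% of them are
severity-linked, deepening their own direction of change by
severity_slope = 0.5 log2 units per s.d. of severity, and 30% of those
couple the other way (deeper change in *good* performers), so all four
partition branches are populated, as in the real data. The remaining
signature genes are dysregulated equally in all mutants and feed the
"rest" sets.

**Allelic series.** External ranked DE tables for a grid of CAG lengths
(Q80–Q175) x ages (2/6/10 months) are simulated by drawing one z per gene
and cell: planted "progressive" genes get a signed shift proportional to a
per-cell scaling, log2fc = 0.25 z and p = 2 Phi(-|z|). Coupling log2fc and
p through the same z makes the zero-scaling null an exact uniform-rank null
and ties the p-ranking to |z|. One consequence: at zero noise, null genes
have z = 0 and belong to neither direction list, so planted sets saturate
at 100% presence rather than tracing a monotone curve; monotonicity is
therefore demonstrated at noise 1 with sub-saturating effects.

Every generator draws from a stream seeded by (seed, call tag), so outputs
are byte-identical under a fixed seed and adding a generator never shifts
another's stream.

**What passing these studies does not show.** The simulations omit litter
random effects, trait floor/ceiling effects and dropouts, count outliers,
GC/length biases, and any real mean-dispersion relationship; the allelic
series has no gene-gene correlation. Calibration and recovery results
transfer to real data only to the extent those features are negligible.

## Trait processing and classification

* Progression rate: Delta = value(week 13) - value(week 11) per animal;
  missing timepoints propagate as missing with a logged count.
* CV = 100 * sample s.d. / mean per trait; summarized across traits by the
  median and the 25th–75th percentiles (linear-interpolation quantiles).
* Mann-Whitney U: exact p by enumerating all C(n+m, n) rank assignments
  when n + m <= 12 without ties; otherwise a normal approximation with tie
  correction and no continuity correction (identical samples then give
  z = 0, p = 1 exactly).
* Z-scores: each measurement is multiplied by the trait's orientation
  (+1 if larger is better) and standardized within genotype x trait x
  timepoint — per-genotype standardization makes the within-group rankings
  comparable and is required for the wild-type split to be meaningful.
  Groups need >= 3 animals and positive s.d.
* Classification: within each genotype, animals with complete data are
  ordered by (number of positive - negative scores) descending, then mean
  Z descending, then animal id (deterministic tie-break); the top and
  bottom k = 4 become "good" and "poor". The mean Z is taken over all six
  measurements (3 traits x 2 weeks); whether the composite should average
  over traits or trait x timepoint cells is underdetermined, and the
  6-measurement average is the simplest consistent choice.

## qPCR quantification

rel = 2^-(Ct_gene - Ct_ref) per sample (amplification efficiency fixed at
2, no standard-curve correction), then divided by the *geometric* mean rel
of the wild-type baseline of the same tissue and gene — folds are log-scale
quantities, so the geometric mean leaves the baseline centred at fold 1.
Plate shifts (a constant added to all Ct of a sample) cancel exactly.

## Correlation screen

For each trait x gene pair within one tissue x genotype panel: Spearman's
rho (Pearson correlation of average ranks; ties get average ranks),
Pearson's r, the regression t-test t = rho sqrt((n-2)/(1-rho^2)) with
two-sided p from Student t(n-2), and Benjamini-Hochberg adjustment over the
panel's whole trait x gene family. Flags follow the panel convention:
tilde at p < 0.05, star at q < 0.1. The BH family is panel-local (one
tissue x genotype call) — conservative relative to a global family and
configurable by screening panels separately or concatenating before
adjustment. Pairs with fewer than 5 overlapping animals, or constant
vectors, are skipped with a logged count. |rho| = 1 is returned as the
limiting case p = 0.

## Differential expression

A deliberately compact two-group NB pipeline in the median-of-ratios /
Wald tradition:

1. **Size factors**: factor_j = median over all-nonzero genes of
   count_gj / geometric mean_g; a pseudo-reference fallback (geometric
   means over nonzero entries) is available when no gene is expressed
   everywhere. Factors are defined up to overall scale.
2. **Dispersion**: per-gene method of moments on normalized counts,
   alpha_raw = max(0, (s^2 - m)/m^2) with the within-group pooled variance;
   a lowess trend of alpha_raw against log mean (fitted on the raw scale)
   acts as a floor, and a quarter of each gene's positive excess over the
   trend is kept: alpha = trend + 0.25 max(alpha_raw - trend, 0). The
   floor matters: with 4 samples per group, plugin dispersions that fall
   below the truth inflate the Wald tails (we measured a null p < 0.05
   fraction of 0.084 and an FDP of 0.20 with symmetric shrinkage; the
   floored estimator gives 0.059 and 0.086 under the same conditions,
   while the Wald test with the *true* alpha is calibrated at 0.052).
3. **Wald test**: per gene, an NB GLM with log link, design intercept +
   group indicator, log size factors as offsets, fitted by IRLS (vectorized
   over genes; 2x2 normal equations solved in closed form; convergence at
   max |Delta beta| < 1e-10, 100 iterations). A ridge of 0.01 on the group
   coefficient keeps all-zero-in-one-group genes finite; it is symmetric in
   the labels, so swapping groups negates every log2fc exactly (verified to
   ~1e-14). Wald = log2fc/se against a standard normal, BH over tested
   genes. All-zero genes are flagged untested, not dropped; non-converged
   genes keep their estimate with a missing p.
4. **DEG calls**: up = {q < FDR, log2fc > 0}, down likewise; FDR
   default 0.05.

Relative to DESeq2 there is no Cook's-distance outlier handling, no
independent filtering and no fold-change shrinkage. On a synthetic fixture
(1000 genes, 5 vs 5, alpha = 0.2, 10% planted log2fc = 1.5) the two agree
closely anyway: log2fc Pearson r = 1.00, p-value Spearman rho = 0.995, and
75 of 80 q < 0.05 calls shared.

## Gene sets and progression

**Partition.** Candidates have q < FDR between poor and good AND q < FDR
vs wild type in >= 1 mutant contrast. Direction is the sign of the
significant vs-wt log2fc; genes significant in both vs-wt contrasts with
opposite signs are excluded and logged. A candidate joins the "poor"
branch when its wt-relative change is deeper in the poor contrast,
measured by |log2fc| (p-based assignment is available behind `by=
"pvalue"`); |log2fc| is the default because p conflates effect size with
variance. Equal |log2fc| falls to the "good" branch (strict inequality
goes to "poor") — an arbitrary but deterministic convention. Rest sets:
q < FDR vs wt in both contrasts, same sign, q >= FDR between poor and
good.

**Presence.** Within one external table, genes whose log2fc sign matches
the set's direction are ranked by ascending p (ties: |log2fc| descending,
then gene id), and presence = 100 |set ∩ top-N| / |set|. The denominator
is the set size; members absent from the table count as not present. The
top-N default is 684 (the conventional cut for genome-scale tables); the
synthetic pipeline uses N = 150 against its 2000-gene universe, the same
~7.5% tail fraction. Presence is invariant to the ordering below rank N.

**Monotonicity.** Spearman rho of presence against CAG length at each age
and against age at each CAG; undefined (NaN) when a set's presence is
constant or fewer than 3 cells exist.

**Over-representation.** Upper-tail hypergeometric P(X >= k) for a set
against an annotation within a universe; the EASE variant decrements k by
one (floor 1) before taking the tail, which is the conservative convention
of DAVID-style tools. k = 0 returns p = 1.

## Study conditions (tests and acceptance script)

* Oracle equivalence: 100 random instances per statistic vs brute-force
  enumeration/closed forms; agreement to 1e-9.
* Classification recovery: 200 cohorts, 29 mutants, loading/noise = 2;
  the k = 4 poor set overlaps the 4 lowest planted severities by >= 3 in
  >= 80% of replicates (measured ~93%).
* Screen: 200 null cohorts (40 genes) for the tilde rate (0.05 +/- 0.02);
  20 planted cohorts (200 genes, 20 signature, all severity-linked) for
  star sensitivity >= 80% with the wild-type subset as negative control.
* DE: 20 replicates of 2000 genes, 4 vs 4, alpha = 0.2 — null p < 0.05
  fraction in [0.03, 0.08]; with 10% planted log2fc = 2, FDP <= 0.10 and
  sensitivity >= 70% at q < 0.05.
* Progression: planted set of 100 genes in a 2000-gene universe, top-150
  cut, effect scale 2.5, unit noise, scaling increasing in CAG and age;
  progressive presence-CAG rho >= 0.9, null set within 3 binomial s.e. of
  the uniform expectation 100 N/G per cell.
* Determinism: two same-seed end-to-end runs must be byte-identical.

These replicate counts and problem sizes are the package's documented
study conditions; the analysis scripts under `analysis/` run the same
machinery at the default cohort scale.

## Known limitations

* Two-group designs only; no covariates, no litter effects.
* The Wald normal approximation is used as-is; below ~3 samples per group
  its calibration is untested.
* The dispersion trend needs >= 10 expressed genes; below that, raw
  method-of-moments estimates are used unshrunk.
* The screen assumes complete expression vectors per animal; missingness
  is handled only on the trait side.
* The allelic-series generator is a rank-model, not a count-level
  simulation of the external study.
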