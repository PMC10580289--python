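# Methods

This note documents the models implemented in `autozyg`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a maintainer needs.

## Genome and recombination model

The synthetic genome defaults to 22 autosomes of 125 Mb at a constant
1 cM/Mb (2.75 Gb, ~2,750 cM), close to the real autosomal totals; both the
genome and the F_ROH denominator are configurable so that reduced genomes
used in tests stay internally consistent.  Meiosis follows the simplest
model consistent with the analyses: per chromosome, the crossover count is
Poisson(length in Morgans), positions are uniform in genetic distance (no
interference), the starting homolog is chosen with probability 1/2, and
chromosomes assort independently.  Maps are sex-averaged and piecewise
linear between (bp, cM) anchors.

## Pedigree templates and gene dropping

Each parental-relatedness (PR) union class is a pedigree template whose
focal child is the offspring of the template's couple.  The expected
inbreeding coefficient is the couple's kinship coefficient, computed by the
classical recursion (exact path counting, valid with inbred ancestors):
sibling 1/4, avuncular 1/8, first cousins 1/16, first cousins once removed
1/32, second cousins 1/64, unrelated 0.  "Two/three generations of first
cousins" chain first-cousin unions along the central sib line — the linking
siblings are themselves offspring of the previous generation's first-cousin
couple — giving expectations ≈ 0.0703 and ≈ 0.0754.  Other chaining
conventions (e.g. double-first-cousin loops) exist; the registry is
extensible if a different convention is needed.

Gene dropping tracks founder-haplotype mosaics (breakpoint lists), so the
focal offspring's *realized* autozygous fraction is measured exactly as the
genome fraction where both homologs descend from the same founder
haplotype, without any marker panel.  Marker genotypes are produced by
looking mosaics up in a founder panel; founders are drawn without
replacement within a pedigree and with replacement across pedigrees.
Founder haplotypes have independent sites (no background LD), so chance
("background") homozygosity is driven purely by allele frequencies —
adequate for length-spectrum work, but real array data have LD, which makes
background ROH slightly longer and more variable than simulated here.
Consequences: classifiers trained on this generator should be retrained,
not transferred, for real data; and passing tests demonstrate correctness
of the machinery, not calibration against any real cohort.

## ROH calling

`roh.call_roh` reproduces the PLINK 1.9 `--homozyg` scanning semantics
with the non-default flags used for array-based consanguinity work:
50-SNP windows, ≤1 heterozygote and ≤5 missing calls per hit window, a SNP
qualifies when ≥5% of its overlapping windows are hits (the PLINK default
threshold, retained because only non-default flags were specified), runs
split at gaps >1,000 kb, and segments kept at ≥50 SNPs, ≥1,500 kb, and
≤50 kb/SNP density.  Segment-level heterozygote counts are unlimited (the
`--homozyg-het -1` default); only the per-window limit applies.  SNPs near
chromosome ends use only the windows that fit; chromosomes with fewer SNPs
than one window yield no calls.  Coordinates are 1-based inclusive and
lengths count both endpoints.  The caller is verified against an
independent, literal quadratic re-implementation of the same rules on
thousands of random inputs.  F_ROH divides summed segment length by
2.7 × 10⁹ bp by default; synthetic genomes pass their own total length.

Site QC removes minor allele frequency < 5% and, optionally, sites failing
the biallelic exact Hardy–Weinberg test below a p-value threshold,
computable within a designated sample subgroup (mirroring QC done within
one ancestry group).  The exact test is implemented in-package (summing
conditional heterozygote-count probabilities no larger than the observed
one) and is checked against full enumeration.

## Parental-relatedness classification

Each genome is summarized by 15 statistics: the summed genetic length of
its ten longest ROHs (one scalar; an alternative 10-separate-lengths
reading is deliberately not used, keeping 1 + 14 = 15 features) and counts
of ROHs in fourteen 10-cM bins over [10, 150) cM.  ROHs shorter than 10 cM
compete for the top-ten sum but fall outside every bin.  The classifier is
an ensemble of ten single-hidden-layer networks (10 logistic hidden units,
softmax output, L2 weight decay 0.01, L-BFGS, ≤500 iterations) trained from
different initializations on standardized features; ensemble scores are
summed member probabilities and ties break toward the earliest class in the
declared order.  Training simulates `n_per_class` offspring per union class
(default 1,000; tests use 80–150 on reduced genomes for speed) through the
same ROH pipeline.  Count bins for ROH lengths longer than any chromosome
are structurally constant and are tolerated (they pass through
standardization with zero weight); a degenerate top-ten-length feature
aborts training with the feature named, since it means the training set
itself carries no signal.

The highly consanguineous subset is individuals classified as avuncular or
first-cousin (any generation) offspring with F_ROH < 0.18, the midpoint
between the avuncular (1/8) and sibling (1/4) expectations.

Fine labels are also reported in three grouped tiers (first cousin or
closer / second cousin or once-removed / unrelated) because adjacent fine
classes overlap strongly; grouped accuracy is the headline metric.
Distinguishing second-cousin offspring from unrelated individuals requires
genome length — on very short test genomes these classes genuinely overlap.

## Association and meta-analysis

`assoc.fit_glm_association` fits phenotype ~ F_ROH + covariates by maximum
likelihood (IRLS for binomial, least squares for gaussian) with Wald
inference on the F_ROH coefficient; effects are reported per unit F_ROH and
as the odds ratio at F_ROH = 0.0625 (the first-cousin expectation), the
interpretable common scale.  Covariates are config-driven; constant columns
are dropped and collinear columns are named in the error.  Fixed-effect IVW
meta-analysis pools per-cohort estimates with Cochran's Q heterogeneity.
Multiplicity uses Benjamini–Hochberg at q = 0.05 and Bonferroni at
alpha/m, with m allowed to exceed the reported p-value count.  The
quintile-trend sensitivity analysis residualizes F_ROH on covariates,
bins residuals (quintiles by default, or explicit reference-cohort edges,
including full-cohort edge lists ending [0.03, 0.18), [0.18, 1)), fits bin
indicators with the lowest bin as reference, and IVW-regresses log(OR) on
bin index.  Relative pruning greedily removes the highest-degree sample
(ties by id order) until no related pair remains.  F_ROH is not Winsorized
or capped anywhere.

## Within-sibling analysis

Binary within-family fits use exact conditional logistic regression
(conditioning on per-family case counts), which for discordant pairs
reduces to a no-intercept logistic fit on within-pair differences.  This
deliberately differs from the bias-corrected unconditional fixed-effect
fits some stacks use: the two coincide asymptotically for discordant pairs,
and conditioning avoids incidental-parameter bias at clique size 2.
Quantitative fits use within-family demeaning with residual degrees of
freedom n − (families) − (slopes).  Families with <2 phenotyped members are
dropped; concordant families are uninformative for the binary model and an
all-concordant input is an error, not a zero.

Replication power simulation follows the published recipe: index-sibling
F_ROH from a configurable distribution (default Normal(0.0037, 0.0050)
truncated at 0, the outbred European-ancestry cohort moments), co-sibling
F_ROH Normal(index, 0.002), disease assigned by a logistic model whose
intercept is solved (Brent) to hit the target prevalence, N_p discordant
pairs retained, conditional-logistic test at alpha.  N_p =
round((mean clique size − 1) × cases in discordant cliques) with
round-half-to-even (the rounding rule is a documented convention).  The
quantitative analogue uses residual SD 9.4 (height scale) and alpha 0.05.
Replication-set powers combine as 1 − Π(1 − pᵢ) for "at least one" — the
independence-complement reading consistent with the printed at-least-two
expansion, whose exactly-one term is subtracted for "at least two"; both
are verified against exhaustive 2^k enumeration.

## Population-attributable risk

Autozygosity is discretized at the first-cousin (0.0625) and second-cousin
(0.015625) expectations.  OR→RR conversion uses
RR = OR / (1 − p_d + p_d·OR) with p_d the disease prevalence in individuals
with unrelated parents, swept over {5%, 15%} by default because it is not
estimable directly.  The combined PAR sums the two Levin terms
100·P·(RR − 1)/(P·(RR − 1) + 1).  Confidence intervals propagate the OR CI
bounds through the PAR map, which is monotone in the log-odds slope; a
parametric bootstrap on beta ~ Normal(beta, SE) is available and agrees
closely.  Both are labelled assumptions: the original intervals' method is
not stated.  The PRS comparison applies the same arithmetic to 1%-wide top
polygenic-score bins and accumulates.  The acceptance run uses
consanguinity-class prevalences P1 = 0.28, P2 = 0.12 for British
Pakistanis, read approximately from a published stacked bar chart (the
precise fractions are not printed); the arithmetic itself is verified to
1e-12 against an independent evaluation.

`par.informative_genotype_count` implements n((1 − F)p² + Fp), the expected
count of alternate homozygotes at a recessive locus under mean inbreeding
F, reducing to np² outbred; an additive-model np variant sits behind a
flag.

## Strictly additive liability simulator

Effect sizes β ~ N(0,1) at 1,000 independent loci; allele frequencies map
1/|β| min-max onto (10⁻³, 0.5], so the largest effects get the rarest
alleles.  |β| (not raw β) is used because raw 1/β is sign-indefinite and
unbounded; any monotone-in-magnitude mapping leaves the F_ROH–variance
relationship unchanged.  Per individual, round(1000·F_ROH) loci (re-drawn
per individual) are autozygous with genotype 2·Bernoulli(p); the rest draw
Binomial(2, p) — hence Var(G) inflates by exactly (1 + F).  Disease
probability is the two-density ratio N(G; d, 1) / (N(G; 0, 1) + N(G; d, 1))
(algebraically logistic(d·G − d²/2), symmetric about G = d/2), with the
case mean-shift d swept over 0.5–1.5 in steps of 0.1; observed-scale
heritability is Nagelkerke pseudo-R² of disease on G.  Power is the
fraction of simulations with a *positive* and significant F_ROH
coefficient, so the null rejection rate is ≈ alpha/2.  The F_ROH source is
lognormal(−2.5, 0.5) truncated to [0.02, 0.18] (the consanguineous-cohort
shape) or Uniform(0, 1).  Generic power calculators replace external
point-and-click tools: a Monte-Carlo logistic Wald-power estimator
(intercept solved for the base rate) and a closed-form noncentral-F power
for the overall linear-model fit with noncentrality n·R²/(1 − R²); both are
cross-checked (simulation vs closed form) rather than bit-matched to any
external tool.

## Orchestration and reproducibility

A YAML config validated by a typed schema drives the stages (simulate →
roh → classify → assoc / sibling / par / addsim); referenced input files
are checked before any stage runs.  A single root seed is expanded by
seed-sequence spawning, one stream per stage; no stage touches global RNG
state, and all generators are bit-reproducible under a fixed seed.  Runs
emit a manifest with a config hash and SHA-256 checksums of every output;
identical config + seed reproduces identical checksums.  Genotypes
interchange as site-major TSV or biallelic GT-only VCF v4.2 (lossless round
trip); segments as a PLINK-.hom-style TSV plus a cM column.

## Problem sizes

Defaults target desk-scale runs: classifier training at 1,000 per class on
the 22-chromosome genome; power simulations at 1,000 replicates.  The test
suite and acceptance script use deliberately reduced sizes chosen for
stable statistics: 2,000 gene-dropped offspring for expectation checks,
500 replicates at n = 50,000 for CI calibration, 100–200 replicates for
the confounding and within-sibling designs, cohorts of 40,000 for the
(1 + F) variance law (the rare-allele/large-effect coupling makes score
variances heavy-tailed, so smaller cohorts estimate the ratio too noisily),
and 400 simulations for the alpha/2 null calibration.

## Known limitations

* No LD in founder haplotypes, no X chromosome, no genotyping error or
  missingness model (missingness is supported by the caller but not
  generated).
* Crossovers are interference-free and sex-averaged.
* The classifier's absolute accuracies depend on genome length and marker
  density; only the grouped tiers are robust on reduced genomes.
* PAR confidence intervals treat class prevalences P1, P2 as known.
* The additive simulator's frequency–effect coupling is a convention; it
  affects score kurtosis (hence Monte-Carlo noise) but not the (1 + F)
  law.
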