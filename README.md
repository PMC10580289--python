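# autozyg

Autozygosity quantification, parental-relatedness inference, and
F<sub>ROH</sub>–disease association analysis on synthetic cohorts.

## The problem

Offspring of related parents carry long stretches of the genome in which
both chromosomes descend from the same ancestral haplotype.  These
autozygous tracts appear on genotype arrays as **runs of homozygosity
(ROH)**, and the fraction of the autosomal genome inside ROHs,

&nbsp;&nbsp;&nbsp;&nbsp;*F*<sub>ROH</sub> = Σ length(ROH) / 2.7 × 10⁹ bp,

estimates the inbreeding coefficient *F*.  Associations between
*F*<sub>ROH</sub> and common diseases are scientifically interesting
(they point to non-additive genetic effects) but severely confounded:
consanguinity co-varies with social, cultural, and environmental
exposures.  Two designs address this:

1. **The highly consanguineous subset.**  Restrict to individuals whose
   parents were first cousins or avuncular pairs (and *F*<sub>ROH</sub> <
   0.18).  Within this group, variation in *F*<sub>ROH</sub> comes only
   from stochastic recombination and Mendelian segregation, so it is
   unconfounded by the correlates of *being* consanguineous.  Parental
   relatedness is inferred by a neural-network ensemble trained on the ROH
   length spectrum (the summed genetic length of the ten longest ROHs plus
   fourteen 10-cM bin counts over [10, 150) cM) of simulated offspring of
   known union classes.
2. **Within-sibling analysis.**  Siblings differ in *F*<sub>ROH</sub> only
   through meiosis, so a family-fixed-effect regression eliminates all
   family-constant confounding, including population structure.

This package implements the full computational pipeline on synthetic
data: a gene-dropping pedigree simulator with recombination, a PLINK-1.9
semantics ROH caller, the parental-relatedness classifier, GLM association
with inverse-variance-weighted (IVW) meta-analysis, conditional-logistic
within-sibling models with replication power simulation,
population-attributable-risk (PAR) arithmetic, and a strictly additive
liability simulator that quantifies how much association the (1 + *F*)
additive-variance inflation alone can produce.

No access-controlled cohort data are required or used; the synthetic-data
module generates cohorts with the statistical structure the analyses
assume.

## Worked example

Simulate first-cousin offspring through a founder panel, call ROHs, and
check the autozygosity expectation:

```python
import numpy as np
from autozyg import synthdata as sd, roh
from autozyg.pedigree import expected_inbreeding

panel = sd.generate_founders(n_founders=50, sites_per_chrom=4500, n_chroms=6,
                             chrom_length_bp=150_000_000, seed=1)
genos, truth = sd.simulate_union_offspring(panel, "first_cousin_1g", 200, seed=2)
segs = roh.call_roh(genos, panel.sites, panel.gmap,
                    sample_ids=truth["sample_id"].tolist())
froh = roh.froh_per_sample(segs, truth["sample_id"].tolist(),
                           denominator_bp=panel.gmap.total_bp)
```

which prints

```
expected F_ROH (path counting): 0.0625
mean called F_ROH:              0.0678
corr(F_ROH, true autozygosity): 1.000
```

— the pedigree expectation for first-cousin offspring is 1/16, the
marker-based calls track the true simulated autozygous fraction, and the
small upward offset reflects chance homozygosity inside called segments on
a short synthetic genome.

Fit the association at cohort scale and convert it to an attributable
risk:

```python
from autozyg import assoc, par

rng = np.random.default_rng(4)
froh_cohort = sd.truncated_lognormal_sampler(-2.5, 0.5, 0.02, 0.18)(20_000, rng)
model = sd.PhenotypeModel.binary_from_or(1.39, intercept=-2.0)
y = sd.simulate_phenotypes(froh_cohort, None, model, seed=5)
res = assoc.fit_glm_association(y, froh_cohort)

risk = par.RiskEstimate.from_or_at_0625(res.or_at_0625, res.or_ci95, pd=0.05)
prev = par.ConsanguinityPrevalence("british_pakistani", p1=0.28, p2=0.12)
out = par.par_from_prevalence(prev, risk)
```

```
recovered OR at F_ROH=0.0625:   1.41 (95% CI 1.33-1.50), n cases 3605
population attributable risk:   10.7% (95% CI 8.7-12.7%)
```

The generating odds ratio (1.39 at *F*<sub>ROH</sub> = 0.0625, the
type-2-diabetes scale) is recovered within its confidence interval, and
with ~28% first-cousin and ~12% second-cousin parental prevalence about a
tenth of disease cases are attributable to autozygosity.

A YAML-configured pipeline and CLI wrap the same functions:

```bash
autozyg run config.yaml          # simulate -> roh -> classify -> assoc -> ...
autozyg par --p1 0.28 --p2 0.12 --or 1.39 --or-ci 1.17 1.63 --pd 0.05
```

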