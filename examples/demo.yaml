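# Desk-scale end-to-end demo: simulate a mixed cohort, call ROHs, train a
# parental-relatedness classifier, fit the F_ROH association, and compute
# the attributable risk.  Run with:  autozyg run examples/demo.yaml
seed: 11
outdir: autozyg_demo_out
stages: [simulate, roh, classify, assoc, par]
synthdata:
  n_founders: 40
  sites_per_chrom: 4000
  n_chroms: 6
  chrom_length_bp: 120000000
  union_mix:
    first_cousin_1g: 40
    unrelated: 40
classify:
  classes: [first_cousin_1g, unrelated]
  n_per_class: 60
assoc:
  model:
    kind: binary
    intercept: -2.0
    or_at_0625: 1.39
par:
  population: british_pakistani
  p1: 0.28
  p2: 0.12
  or_at_0625: 1.39
  or_ci95: [1.17, 1.63]
  pd_grid: [0.05, 0.15]
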