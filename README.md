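# purgekit

Genetic purging and deleterious-burden analysis for conservation genomics.

When a population declines, two forces compete on its deleterious variation:
drift lets weakly selected mutations accumulate and fix, while inbreeding
exposes (partially) recessive mutations as homozygotes, letting selection
remove — *purge* — them.  This package is built for studies that compare a
rare, bottlenecked lineage with a widespread relative from resequencing
data, asking which force won: it pairs a predictive model of the deleterious
burden under a declining effective population size with the empirical
statistics used to measure genetic load (π, heterozygosity, runs of
homozygosity, polarized derived-allele burden ratios), and a synthetic
cohort generator with full ground truth so every estimator is validated
without any external data.

## The model

For a mutation class with genotype fitnesses 1, 1−hs, 1−s and haploid
genomic mutation rate λ, the expected density of derived copy counts
j = 0..2N evolves by exact Wright–Fisher transition-matrix numerics:
selection update q′ = q·w_der/w̄, binomial sampling row
Binomial(2N, q′), influx of 2Nλ new single-copy mutations per generation,
and absorbing loss/fixation boundaries.  Starting from the
mutation–selection–drift equilibrium of an ancestral population, stepwise
reductions of N yield the expected segregating (n_seg) and newly fixed
(n_fixed) derived alleles per diploid genome through time.  A stochastic
forward simulator implements the identical process and serves as the
model's Monte-Carlo oracle; the per-copy purging strength is summarized by
d = s(1−2h)/2.

Measurement-side conventions: derived counts are 2·hom + het per individual,
normalized by derived synonymous counts in the same zygosity class or ROH
stratum; F_ROH is the genome fraction in runs of homozygosity ≥ 100 kb
(> 1 Mb for recent inbreeding), called by a two-state autozygosity HMM.

## Worked example

Predict the burden of strongly deleterious, highly recessive mutations
(s = 0.1, h = 0.05, λ = 1) through a 10-fold bottleneck:

```python
from purgekit import (DemographicTrajectory, SelectionClass,
                      msd_equilibrium, evolve_burden)

traj = DemographicTrajectory([(1000, 1), (100, 300)])   # (N, generations)
sc = SelectionClass(s=0.1, h=0.05, lam=1.0)
eq = msd_equilibrium(1000, sc)
pred = evolve_burden(eq, traj, sc, record_every=75)
print(pred.to_frame().round(3).to_string(index=False))
```

```
 generation_before_present  log10_generation   n_seg  n_fixed  n_total
                     301.0             2.479 275.907      0.0  275.907
                     226.0             2.354 201.246      0.0  201.246
                     151.0             2.179 163.103      0.0  163.103
                      76.0             1.881 152.047      0.0  152.047
                       1.0             0.000 148.943      0.0  148.943
                       0.0               NaN 148.922      0.0  148.922
```

The ancestral population carries ≈ 276 segregating deleterious alleles per
diploid genome; the crash exposes them as homozygotes and purging removes
46% of the burden within 300 generations (n_fixed stays at the ancestral
baseline — drift has not yet fixed anything extra).  Repeating with
h = 0.45 (near-additive) leaves the burden essentially flat, and with
s = 0.001 at a severe crash the total burden *rises* — the drift-accumulation
regime.  `predict_grid` runs the full s ∈ {0.001, 0.01, 0.1} ×
h ∈ {0.05, 0.25, 0.45} panel grid in one call.

The empirical side runs the same way from a VCF or from the built-in
generator:

```
purgekit simulate --seed 1 --out cohort_out          # synthetic cohort + VCF
purgekit load-stats --vcf cohort_out/cohort.vcf --out stats_out
purgekit report --seed 1 --out run_out               # full scenario + summary
purgekit compare-engines                             # matrix vs simulator
```

`report` writes tidy tables (ROH segments, per-window π, load ratios,
ROH-stratified ratios, Welch tests, LD decay, burden predictions) and a
`summary.json` whose `directional_checks` block records the qualitative
contrasts between the bottlenecked and the widespread cohort: lower π and
heterozygosity, higher F_ROH, lower heterozygous- and homozygous-tract
deleterious/synonymous ratios, depletion of deleterious alleles inside ROH,
and the negative F_ROH–heterozygosity correlation.

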