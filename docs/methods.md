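# Methods

## The burden model

`purgekit.purging_model` predicts the expected number of derived deleterious
alleles per diploid genome for a class of unlinked mutations with genotype
fitnesses 1, 1−hs, 1−s, under a demographic history of piecewise-constant
diploid effective sizes N.

The state is the expected density of sites over derived copy counts
j = 0..2N.  One generation applies the deterministic selection update

    q' = [q²(1−s) + pq(1−hs)] / [p² + 2pq(1−hs) + q²(1−s)],   p = 1 − q,

followed by binomial resampling, i.e. row j of the Wright–Fisher transition
matrix is Binomial(2N, q'(j/2N)); the states 0 and 2N are absorbing.  New
mutations enter at copy count 1 at rate 2N·λ per generation, where λ is the
haploid genomic mutation rate of the class (λ = 1 by convention for the
default predictions).  Everything is linear in λ.

* **Ancestral equilibrium.**  The mutation–selection–drift (MSD) stationary
  density solves x = xQ + 2Nλ·e₁ on the transient states by a dense linear
  solve (fixed-point iteration to 1e−10 relative as fallback, capped at 10⁶
  iterations).  The equilibrium fixation flux is recorded and used as the
  baseline for fixed-burden accounting.
* **Demographic change.**  At an epoch boundary N_old → N_new the density is
  remapped by binomial repopulation, m'_k = Σ_j m_j·Binom(2N_new, j/2N_old)(k);
  within an epoch the matrix is iterated one generation at a time with influx
  2N·λ.  Mass is checked for conservation (segregating + lost + fixed =
  injected) to 1e−9 relative every epoch.
* **Reported quantities.**  n_seg = Σ_j m_j·j/N (segregating derived alleles
  per diploid genome); n_fixed = 2·(fixed mass − ancestral fixation flux ×
  elapsed generations), so that the pre-decline burden is flat and changes
  reflect demography — an irreversible-mutation model has no absolute
  fixed-count equilibrium.  The time axis is generations before present;
  calendar labels use g = 50 years/generation and μ = 7.0×10⁻⁹ only for
  presentation.
* **Size guard and rescaling.**  Dense matrices are capped at 2N = 4000
  states.  `rescale_scenario` divides every N by c and multiplies s by c,
  shrinking durations by c, which preserves 4Ns and the diffusion-scale
  dynamics; a c=4 rescaling of a bottleneck with a 30% burden reduction
  reproduces the relative trajectory to ~2%.
* **Per-site closed forms.**  The recessive balance √(u/s) is nonlinear in u
  and therefore outside the linear-influx density; `equilibrium_mean_frequency`
  instead solves the stationary distribution of an ergodic per-site chain with
  symmetric two-way mutation u.  The additive limit u/(hs) is matched within
  ~1% at 4Nhs = 90; the recessive limit is approached from below (~0.88 of
  √(u/s) at 4N√(us) ≈ 28) because drift skews the stationary distribution —
  the checks use u = 1e−4 and u = 2e−3 respectively.

The purging coefficient d = s(1−2h)/2 is exposed as a diagnostic of per-copy
purging strength; the dynamics themselves come from the full numerics, not
from the analytical inbreeding–purging approximation.

## The stochastic engine

`purgekit.wf_simulator` implements the same discrete process by direct
simulation: deterministic selection update, then Binomial(2N, q') sampling per
site, Poisson(2Nλ) influx per generation, binomial repopulation at epoch
boundaries.  Because both engines realize the identical process, the matrix
value is the exact expectation of the simulator; the cross-validation
criterion is |z| ≤ 3 per (s, h) grid cell with 10⁴ replicate populations.
Sites are unlinked (free recombination); a single seeded RNG stream drives
each run.

## Inbreeding in the cohort simulator

For synthetic cohorts, `simulate_diploid_cohort` accepts an inbreeding
coefficient F that shifts genotype frequencies to q²+Fpq, 2pq(1−F), p²+Fpq
before selection.  This is the mechanism of purging under prolonged
inbreeding: autozygosity exposes (partially) recessive alleles to selection
as homozygotes.  At desk-scale population sizes this term is essential — in
a purely panmictic model the *equilibrium* deleterious/synonymous burden
ratio rises monotonically as N falls (drift dominates selection at
4Nhs of order one), so a bottlenecked cohort would never show the reduced
relative burden that inbreeding-driven purging produces.  The default F of
each cohort equals its F_ROH target, tying the selection-side exposure to the
genotype-side autozygosity.  The burden-prediction module and all engine
cross-checks remain panmictic (F = 0).

## The synthetic study design

`synthetic_data.default_config()` defines the two-cohort study all
qualitative checks run on:

| parameter | rare cohort | widespread cohort |
|---|---|---|
| individuals (populations) | 32 (9) | 51 (17) |
| ancestral equilibrium | N = 500, panmictic | shared |
| history | N = 300 for 300 gen | N = 500 for 300 gen |
| inbreeding F | 0.2193 | 0.1202 |
| F_ROH targets | N(0.2193, 0.05) | N(0.1202, 0.04) |

Effect classes (s, h): synonymous (0, 0.5), tolerated (0.001, 0.45),
deleterious (0.1, 0.05), LoF (0.2, 0.05) — the strongly deleterious classes
are highly recessive (h = 0.05), the convention that avoids hiding an
unrealistically large burden at h = 0.  Standing budgets are 150k / 40k /
40k / 10k sites at the ancestral equilibrium; the implied influx (budget ÷
standing mass, scaled by current 2N) continues through the epochs so recent
low-frequency mutations are represented.  The genome is 4 contigs × 25 Mb —
statistics are per-base normalized, so genome scale affects precision, not
correctness.  Genotypes are Binomial(2, q) within cohorts; only sites variant
among the sampled individuals are emitted (VCF semantics), and terminally
fixed derived sites are dropped, as a conspecific reference would not expose
them as SNPs.

**ROH implantation.**  Non-overlapping tracts of length 100 kb +
Exp(200 kb) are placed per individual until the target genome fraction is
reached (achieved fractions recorded; at full genome scale targets are met
within ~1 percentage point).  Inside a tract the genotype is homozygous with

    P(hom-derived) = q·(1−s)^g / (q·(1−s)^g + 1 − q),   g = 20,

and heterozygous at the error rate ε = 0.001.  The exponent g models the
inbred history of the tract: a 100–500-kb IBD segment under a ~1 cM/Mb map
is tens of generations old, so its homozygous state has been exposed to
selection for of order that many generations; g = 20 is conservative.  This
weight is what depletes derived deleterious alleles inside ROH relative to
outside — the within-tract analog of haplotype purging.

**Outgroups and missingness.**  Two outgroup alleles per site are generated
by Jukes–Cantor substitution from the true ancestral allele at divergence
0.05 per branch (2% missing); genotype missingness is 2% completely at
random (the missing-data process of the emulated pipeline is not documented,
so MCAR is the default knob).

What the generator deliberately does **not** emulate: linkage (sites are
unlinked, so LD decay is structurally flat), shared polymorphism between the
cohorts (each site segregates in one cohort; the other carries the ancestral
allele), read-level artifacts beyond the missingness and ε knobs, and gene
structure (effect classes are site labels, not annotations).  Passing tests
therefore validate estimator correctness and the inbreeding-purging
directions, not linked-selection or annotation-driven effects.

## Load statistics

* **π** per variable site is the unbiased pairwise form 2j(n−j)/(n(n−1)) over
  observed alleles (monomorphic bases contribute zero); windowed values
  divide by window length (defaults 100 kb / 10 kb).  Class-restricted π
  normalizes by the class's total site count including invariant positions.
* **Heterozygosity** is the per-bp heterozygous-call rate, directly
  comparable with π; F_het = 1 − obs(het)/exp(het) is exposed separately.
* **ROH detection** is a two-state (autozygous / non-autozygous) Viterbi HMM:
  P(het | auto) = ε, P(het | non-auto) = 2pq at the individual's population
  frequency, missing genotypes uninformative; transition probabilities decay
  with inter-site distance as 1 − exp(−d/L) with L = 500 kb expected tract
  length and a 0.15 autozygosity prior.  Segments < 100 kb are dropped;
  > 1 Mb is the recent-inbreeding class.  The caller is validated by truth
  recovery (per-individual F_ROH within a few percent at the default 0.8
  sites/kb and ε = 0.001), not by matching any particular external tool's
  undocumented defaults.
* **Polarization** is explicit outgroup parsimony: strict mode assigns the
  ancestral allele when both outgroups agree and match REF or ALT;
  disagreements and double mismatches are excluded.  Relaxed mode accepts a
  single informative outgroup (flagged).  At the default divergence the
  misassignment rate against truth is ~0.03%, with ~12% of sites excluded.
* **Burden ratios** count derived alleles as 2·hom + het per individual,
  normalized by the derived synonymous count in the same zygosity class or
  ROH stratum; missing genotypes are excluded from numerators and
  denominators; zero-denominator ratios are NA and excluded from tests.
  Welch's unequal-variance t-test is the only hypothesis test (a handful of
  planned comparisons; no multiplicity correction).
* **LD decay** computes genotype-dosage r² for intra-contig pairs within
  1 Mb, thinned to ≤ 2000 sites per contig, averaged in 10-kb bins, with the
  half-maximum decay distance reported.
* **Hard filters** implement the GATK-style record rule (QUAL < 30 ‖ DP < 5 ‖
  QD < 2 ‖ MQ < 40 ‖ FS > 60 ‖ SOR > 3 ‖ MQRankSum < −12.5 ‖
  ReadPosRankSum < −8); absent annotations pass and are logged.  The site
  filter removes MAF ≤ 0.05 or missingness ≥ 0.10 (inclusive boundaries, as
  stated); LD pruning is greedy windowed r² > 0.2 over 100-variant windows
  slid by 10, removing the later site of an offending pair.

## Numerical choices and degenerate inputs

Dense solves use LAPACK via numpy; binomial pmfs come from scipy.stats and
are exact to double precision (the neutral fixation probability from one
copy reproduces 1/(2N) to ~1e−15).  Lethal classes (s = 1) are handled by
not pushing the absorbing endpoints through the selection update, where mean
fitness vanishes.  Viterbi ties prefer staying autozygous; emission
probabilities are floored at 1e−6.  Zero-length contigs, infeasible budgets,
unsorted sites, overlapping ROH segments and non-biallelic VCF records raise
explicit errors.

## Problem sizes

The default verification runs use: matrix engines at N ≤ 2000 (drift
scenario rescaled from N_anc = 6000 by c = 3), engine cross-validation at
N = 100 → 50 with λ = 0.02 and 10⁴ replicate populations, and the full
two-cohort cohort (≈ 240k sites × 83 individuals) for the directional suite
over five seeds.  These sizes keep the complete test suite around five
minutes on one CPU while leaving every tolerance at its stated value.

## Known limitations

The model is per-site independent and linear in λ: no linked selection, no
interference, no recombination map.  The inbreeding coefficient F is a fixed
per-cohort constant, not an emergent property of a pedigree.  Demographic
trajectories are user inputs (piecewise-constant); the package does not
infer them.  Effect classes are inputs in real-data mode; the package does
not predict variant effects.  The synthetic cohorts place sites uniformly at
random, so class labels are not tied to gene annotations.
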