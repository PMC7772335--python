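# demosfs

Two-population demographic inference from the joint site-frequency
spectrum (SFS), built for comparisons between a derived and an
ancestral-range population of haploid genomes — the motivating system is
a northern-European (Swedish) versus sub-Saharan (Zambian) sample of
*Drosophila melanogaster*, 14 haploid genomes per population.

## The model

All four scenarios share an isolation-with-migration skeleton, in
coalescent units (sizes relative to the ancestral size N<sub>ANC</sub>,
times in units of 2·N<sub>ANC</sub> generations, migration as
M = 2·N<sub>ANC</sub>·m):

* the ancestral (African) population steps from size 1 to ν<sub>AF</sub>
  at time T<sub>exp</sub>;
* the derived (European) population splits off at T<sub>split</sub> <
  T<sub>exp</sub>, is instantaneously reduced to ν<sub>BOT</sub>, and
  recovers exponentially to its present size ν<sub>EU</sub>;
* gene flow after the split distinguishes the scenarios:
  **NOMIG** (none, k=5 free parameters), **SYMIG** (symmetric, k=6),
  **ASYMIG** (asymmetric, k=7), **RASYMIG** (asymmetric, starting only
  at T<sub>mig</sub>, k=8).

The expected joint SFS is computed by Monte-Carlo: structured-coalescent
genealogies are simulated backwards in time (numba-accelerated batch
kernel) and branch lengths are accumulated by the number of descendant
leaves (i, j) they subtend in each population; E[ξ<sub>ij</sub>] =
θ·E[T<sub>ij</sub>]/2. Fitting maximizes the Poisson random-field
composite likelihood Σ (S ln M − M − ln S!) per SFS cell, with θ
profiled analytically; models are ranked by AIC = 2k − 2lnL and
uncertainties come from a 150-replicate parametric bootstrap
(2.5–97.5% percentile intervals). A companion module estimates
time-binned within- and cross-population coalescence rates from
genealogies and the relative cross-coalescence rate
RCCR = 2·cross/(within₁ + within₂), which is 1 under panmixia and 0
under complete isolation.

The package also provides the surrounding toolkit: haploid VCF + panel
input, BED masking (inversions, IBD runs) and intron-style keep-lists,
recombination-class partitioning at 1.5 and 3 cM/Mb, Watterson's θ,
nucleotide diversity, Tajima's D, Hudson's F<sub>ST</sub>, a
Pearson chi-squared SFS-shape test, PCA, and a synthetic-data generator
that emulates the study design (including an optional low-recombination
singleton excess mimicking linked negative selection).

## Worked example

```python
import numpy as np
from demosfs import (ScaledParams, SFSDemographyModel, JointSFS,
                     expected_jsfs, make_model_spec, ScalingConfig)

# realistic Europe/Africa-style truth (autosomal scale)
truth = ScaledParams(nu_af=4.083, nu_bot=0.0892, nu_eu=0.875,
                     T_exp=0.5511, T_split=0.17504, M_AtoE=0.4, M_EtoA=1.23)
spec = make_model_spec("ASYMIG")

# simulate an observed joint SFS of ~55,000 SNPs (14 + 14 haploids)
e = expected_jsfs(spec, truth, 14, 14, 100_000, 4242)
theta = 55_000 / e.total
obs = JointSFS(np.random.default_rng(777).poisson(theta * e.per_theta).astype(float))

# two-phase fit: multi-start search on a fast Monte-Carlo surface,
# then refinement of the winner on a 4x more precise one
guess = ScaledParams(nu_af=4.2, nu_bot=0.13, nu_eu=0.94,
                     T_exp=0.66, T_split=0.08, M_AtoE=1.7, M_EtoA=0.59)
search = SFSDemographyModel(obs, "ASYMIG", n_mc=2000, seed=99).fit(
    start_params=guess, n_starts=10)
res = SFSDemographyModel(obs, "ASYMIG", n_mc=8000, seed=100).fit(
    start_params=search.params, n_starts=1)
print(res.summary(ScalingConfig()))
```

prints:

```
SFS demographic fit: model ASYMIG (k=7 free parameters)
  log-likelihood -790.513   AIC 1595.026   theta_hat 8537
  n_mc 8000   seed 100   starts 1 (1 converged)
  scaled parameters:
       nu_af = 4.3114
      nu_bot = 0.10729
       nu_eu = 0.80988
       T_exp = 0.60033
     T_split = 0.20883
      M_AtoE = 0.42236
      M_EtoA = 1.0871
  physical units (mu=5.21e-09, 15 gens/yr, L=4.02073e+06 bp):
             N_ANC = 101,886
              N_AF = 439,266
             N_BOT = 10,931.1
              N_EU = 82,515.6
     T_split_years = 2,836.93
       T_exp_years = 8,155.42
            M_AtoE = 0.422359
            M_EtoA = 1.08711
```

Every generating size and time is recovered to within ~20% (e.g.
ν_AF 4.31 vs 4.083, T_split 0.209 vs 0.175, M_EtoA 1.09 vs 1.23) —
the remaining gap reflects the Poisson sampling noise of the data and
the Monte-Carlo expectation. `res.parametric_bootstrap(n_boot=150)`
attaches percentile CIs in physical units (individuals / years, via
N_ANC = θ̂/(4μL) and T_years = T·2N_ANC/g with μ = 5.21×10⁻⁹ and 15
generations per year).

A command-line interface covers the same pipeline end to end:

```sh
demosfs simulate --model ASYMIG --set M_EtoA=1.23 --n-loci 500 \
    --vcf sim.vcf --panel sim.panel --sfs obs.fs
demosfs stats --vcf sim.vcf --panel sim.panel --sfs-out obs.fs
demosfs fit --sfs obs.fs --model NOMIG --model ASYMIG --out best.cfg
demosfs bootstrap --sfs obs.fs --config best.cfg --n-boot 150
demosfs rccr --model NOMIG --set T_split=3 --set T_exp=4 --n-reps 5000
```

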