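# Methods

## Demographic model and conventions

The package implements a two-population isolation-with-migration
history. Backwards in time from the present: the derived (European)
population has size ν_EU·N_ANC today and shrinks exponentially to
ν_BOT·N_ANC at the split time T_split, where its lineages merge into the
ancestral (African) population; the African population has size
ν_AF·N_ANC until T_exp (its stepwise expansion, viewed forward) and size
N_ANC earlier. Time is measured in units of 2·N_ANC generations; in
these units the pairwise coalescence rate in a population of relative
size ν is 1/ν.

Migration rates are the scaled M = 2·N_ANC·m of the receiving
(forward-in-time) population: a lineage sampled in Europe jumps to
Africa at per-lineage rate M_AtoE (forward Africa→Europe migrants are,
backwards, European lineages of African origin), and an African lineage
jumps to Europe at rate M_EtoA. This fixes an internal convention the
verbal description "Migration Rate Europe to Africa" leaves open; the
convention is validated end to end by the closed-form single-population
SFS check and the panmictic strong-migration limit (two demes of size
1/2 with M = 100 reproduce the pooled hypergeometrically-split SFS to
within 5%).

Two modelling choices the prose description leaves open are resolved as
follows. (1) European exponential recovery spans the whole (0, T_split)
interval — growth starts immediately after the instantaneous founder
bottleneck, the simplest reading and common practice; ν(t) =
ν_EU·(ν_BOT/ν_EU)^(t/T_split). (2) Under RASYMIG, migration is active on
[0, T_mig] with 0 < T_mig ≤ T_split; with T_mig = T_split the model
reduces exactly to ASYMIG (tested).

## Simulation engine

Genealogies are drawn by competing exponentials epoch by epoch
(boundaries: T_mig where gated, T_split, T_exp). Within-population
coalescence with k lineages has rate C(k,2)/ν(t); during the European
exponential epoch waiting times are drawn by analytic inversion of the
cumulative intensity (exact; no Euler stepping). Migration is a
per-lineage exponential event; migration out of an empty population has
rate zero by construction. Within-locus recombination is not simulated:
loci are unlinked and internally non-recombining, matching the
composite-likelihood treatment of sites.

The engine exists in two deliberately redundant forms: a pure-Python
simulator returning full genealogies (trees, event logs, newick) and a
numba batch kernel (~8 µs per 28-leaf genealogy) that only accumulates
branch-category lengths T[i][j] — the total branch length subtending i
population-1 and j population-2 leaves — and, optionally, Poisson
mutation counts. A branch's category never changes during its lifetime,
so lengths are finalized per lineage rather than per event. The two
routes are cross-checked against each other and against E[ξ_i] = θ/i in
the test suite.

Mutations follow the infinite-sites model at rate θ/2 per unit branch
length, so E[π] = θ for n = 2 and θ = 4Nμ L. The synthetic-data
generator emulates the study design: 14 + 14 haploid genomes, loci
assigned to three recombination classes ([0,1.5), [1.5,3), [3,14.5]
cM/Mb; class boundaries are assigned upward because closed printed
intervals overlap at 1.5 and 3), per-locus rates drawn uniformly within
the class, and an optional external-branch mutation multiplier f ≥ 1 in
the lowest class. The multiplier is a minimal surrogate for the
singleton excess produced by linked negative selection — sufficient to
exercise the chi-squared skew test, with no claim of realism about
background selection; default class fractions are equal thirds (the
genomic composition is not part of the inference problem). What the
generator does not emulate: linkage within and between loci, sequencing
or polarization error, missing data, and selection beyond the singleton
surrogate — so passing tests validate the estimators under the model's
own assumptions, not robustness to those real-data complications.

## Likelihood, optimization, model choice

Each unmasked joint-SFS cell is Poisson with mean θ·E[T_ij]/2. θ is
profiled analytically (θ̂ = Σobs/Σexpected), and is therefore excluded
from the parameter count k in AIC = 2k − 2lnL; since θ is profiled
identically in all four models this convention does not affect ΔAIC.
Cells whose Monte-Carlo expectation is zero but whose observed count is
positive are floored at 10⁻¹² expected rather than returning −∞, so the
optimizer can traverse them.

Optimization is multi-start Nelder–Mead (adaptive) on transformed
parameters: log for sizes, times and migration rates, log(T_exp −
T_split) for the expansion (guaranteeing the ordering), and a logit for
T_mig/T_split. A quadratic penalty steers the search back from a broad
sanity box (ν ∈ [10⁻⁴,10⁴], times ≤ 30, M ≤ 60). The initial simplex
uses an explicit 0.3 step per log-coordinate (scipy's default step
collapses for coordinates near zero, freezing any parameter whose start
value is 1). Within one fit the Monte-Carlo expectation reuses a single
genealogy seed (common random numbers), making the objective
deterministic; the default is 20,000 genealogies per evaluation and 10
starts, the first unperturbed and the rest multiplied by lognormal
factors with σ = 0.5. Identical master seeds give bit-identical fits.

Parametric-bootstrap CIs follow the percentile recipe: simulate
pseudo-observed spectra, re-fit the same model starting from the point
estimate, convert each replicate to physical units, and take the
2.5–97.5% percentiles (default 150 replicates). Pseudo-data are Poisson
draws around the fitted expected SFS — exactly the data model the
likelihood assumes; full genealogy re-simulation is available through
the generator if wanted. Percentile intervals from re-fits can exclude
the point estimate itself; this is flagged, not treated as an error.

## Physical units

N_ANC = θ̂/(4μL) with defaults μ = 5.21×10⁻⁹ per bp per generation and
L = 4,020,733 bp (autosomal intronic total; the X value 5,859,268 is
provided as a constant — the X is analyzed by simply changing L, with no
chromosome-specific rescaling). Times convert via T_years =
T_scaled·2·N_ANC/g at g = 15 generations per year. Scaled migration
rates are reported unchanged.

## Cross-coalescence rates

Rates are estimated from simulated genealogies by a binned hazard
estimator: events ÷ integrated pair exposure per time bin, separately
for within-population-1, within-population-2 and cross pairs, with
RCCR = 2·cross/(within₁+within₂). Lineages ancestral to leaves of both
populations are split fractionally by descendant-leaf composition (a
lineage subtending (i, j) leaves counts as population 1 with weight
i/(i+j)); this keeps the three categories an exact partition of the
n−1 coalescences of every genealogy while remaining asymptotically
unbiased in the panmictic limit. Default bins are log-spaced between the
1st and 99th percentiles of the observed coalescence times; bins with
zero exposure or an undefined denominator are flagged NaN, and RCCR
values above 1 (possible by noise) are flagged, never clipped.

Rate-to-size conversion: with rates in this package's scaled units
(per pair per 2·N_ref generations) a constant panmictic population of
size N_ref has rate 1, so N_e = N_ref/rate; for rates per generation, as
sequence-based HMM tools report them, N_e = 1/(2·rate)
(`rate_units="per_generation"`). The statistic is computed from true
genealogies — the package deliberately does not re-implement a
sequence-level coalescent HMM, so no statement is made about
HMM-specific artefacts in the recent-time limit.

## Problem sizes used in the validation suite

Chosen as the package's standard desk-scale verification settings: the
closed-form SFS oracle uses n = 10 and 50,000 genealogies (3% relative
tolerance); RCCR calibrations use 6,000 (panmictic, n = 8) and 2,000
(isolated, 4 + 4) genealogies with a 0.1 tolerance on the panmictic
mean; parameter recovery fits a 55,000-SNP spectrum (14 + 14) starting
from a lognormally perturbed version of the generating parameters (the
standard recovery-benchmark init), with a 10-start search at 2,000
genealogies per evaluation followed by refinement of the winner at
8,000 — the two-phase design matters because at this SNP count the
Monte-Carlo surface at low n_mc is rough enough to strand a single-
phase search on a ridge — expecting every size and time parameter
within 30%; model selection uses 10 datasets of ~18,000 SNPs with
scaled migration 1 at n_mc = 800; the bootstrap coverage check is
scaled down to 7 + 7 samples, ~2,500 SNPs, 20 replicate datasets × 50
bootstrap re-fits, with ≥80% pooled coverage of nominal-95% intervals;
the skew test uses ~10,000 SNPs per class — near-independent sites
(θ ≤ 0.05 per locus for power; multinomial draws from the engine's
neutral SFS for the 100-rep type-I check), because the chi-squared
table assumes independent sites and dense multi-SNP loci genuinely
overdisperse it (see Known limitations); neutrality statistics use 200
loci at θ = 5. Unit tests validate each component at smaller sizes.

## Known limitations

* The composite likelihood ignores linkage; no Godambe-style variance
  adjustment or likelihood-ratio testing is provided — AIC comparisons
  and bootstrap CIs inherit the independent-sites assumption.
* Monte-Carlo noise in the expected SFS acts as a small extra error on
  parameter estimates; increase `n_mc` for final analyses.
* Percentile bootstrap intervals can be poorly centred for strongly
  biased or boundary-adjacent parameters (migration rates especially).
* The SFS-shape chi-squared test assumes independent sites. Spectra
  pooled from dense multi-SNP loci (or tightly linked real data) share
  genealogies across sites, overdispersing the contingency table and
  inflating the type-I rate; compare spectra of well-spread SNPs, or
  treat small p-values near the threshold with caution.
* PCA is a plain SVD: no LD pruning/clumping, no long-range-LD removal,
  no kinship correction.
* Heterozygous calls in input VCFs are dropped with a logged count, not
  phased — appropriate for haploid or fully inbred designs only.
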