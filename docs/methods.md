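# Methods

This note documents the models, estimators and numerical choices behind
`temporalpop`, and what the synthetic-data validation does and does not
establish.

## The inference problem

Two samples of the same population taken t generations apart carry
information about the effective population size Ne through the variance of
allele-frequency change (drift at rate 1/(2Ne) per generation, plus binomial
sampling noise at each end), while multi-population samples at unlinked
microsatellite loci carry information about divergence times, migration and
size changes through the within- and between-population distribution of
allele repeat lengths.  The package implements both layers for the Cross
River gorilla study design: a historical sample (5 generations before
present, n=14), a modern sample of the same population (n=71), and a modern
outgroup population (n=92), at 8 unlinked microsatellite loci evolving under
the strict stepwise mutation model (SMM: each mutation changes the repeat
count by ±1, equally likely).

## Serial structured coalescent

Time is continuous, measured backwards in generations.  Haploid gene copies
enter the genealogy at their sampling times and coalesce pairwise at rate
1/(2N_deme(t)); diploid sizes are used throughout.

**Isolation with migration (IM).**  Backwards in time: the Cross River deme
grows exponentially from `n_cr_now` at t=0 to `n_cr_now × ratio_old_now` at
`t_bottleneck` (the backward image of the forward exponential decline),
stays constant until `t_divergence`, when all lineages merge into an
ancestral deme of size `n_ancestral`.  Migration is symmetric and active for
t ∈ [t_migration, t_divergence): a lineage in deme d jumps at backward rate
`2Nm / (2 N_d(t))`, so `2Nm/2` migrant lineages per generation enter each
deme — the "roughly Nm individuals per generation" reading of the scaled
parameter.  The western deme is constant at `n_western`.

**Secondary admixture.**  No migration; at `t_admixture_frac × t_divergence`
each Cross River lineage independently traces to a western immigrant with
probability `gamma_admixture` (the backward image of a forward pulse
replacing a fraction γ of the population).  The Uniform(0,1) prior on the
admixture time is interpreted as a fraction of the divergence time; an
absolute time below one generation would be meaningless.

**Event loop.**  Epochs are delimited by sampling times, `t_bottleneck`,
`t_migration` (or the pulse time) and `t_divergence`.  Within an epoch the
total event rate is constant except in the exponential bottleneck window,
where it decreases going backwards; proposals drawn at the epoch-entry rate
are thinned by acceptance probability rate(t)/rate_max, which is exact — no
per-generation discretization anywhere.  The loop is numba-compiled; a
study-sized locus (177 lineages) simulates in ~0.2 ms.

**Mutation.**  Each branch receives Poisson(μ × length) mutations; the net
repeat displacement is 2·Binomial(m, ½) − m.  The root allele is 100
repeats; every downstream summary is invariant under translation of the
root (property-tested), so the choice is inconsequential.

**Validation.**  Mean pairwise coalescence time = 2N within 3 SE; TMRCA
distributions for single-deme (n=5) and two-deme IM configurations match
msprime (KS tests; msprime's haploid size convention differs by a factor of
two and the tests account for it); equilibrium within-sample allele-size
variance = 2Nμ within 10%; the γ→0 admixture limit is indistinguishable
from zero-migration isolation.

## Priors

As published for this system: 2Nm ~ loguniform[1, 15.85]; size ratio ~
loguniform[1, 100]; `n_cr_now` ~ N(200, 100) truncated [68, 300];
`n_ancestral` ~ U[500, 25000]; `n_western` ~ N(24000, 5000) truncated
[10000, 30000]; times loguniform — divergence [10, 3162], bottleneck
[10, 316], migration [10, 3162] generations; μ ~ N(4·10⁻⁴, 10⁻⁴) truncated
[2, 6]·10⁻⁴ per locus per generation.  Draws violating
t_migration ≤ t_divergence or t_bottleneck ≤ t_divergence are rejected and
redrawn.  The admixture model replaces (2Nm, t_migration) with
t_admixture_frac ~ U(0,1) and γ ~ U(0,1).

## Temporal-method Ne

**Moment estimators.**  Per locus, over the union of observed alleles:
Fc = (1/A) Σᵢ (xᵢ−yᵢ)² / [(xᵢ+yᵢ)/2 − xᵢyᵢ] (Nei & Tajima) and
Fk = (1/(A−1)) Σᵢ (xᵢ−yᵢ)² / [(xᵢ+yᵢ)/2] (Pollak, as used by Waples).
Multilocus values are weighted means (weights A and A−1 respectively).
Ne = t / (2[F − 1/(2S₀) − 1/(2Sₜ)]) under sampling plan 2, with S in
**diploid individuals** so each sampling term equals one over the gene-copy
count — the binomial variance of a frequency estimated from 2S gene copies.
Plan 1 (sampling after reproduction from a population whose census size
approximates Ne) replaces t by t−2.  95% bounds treat df·F/F̂ as chi-square
with df = Σ(A−1) independent alleles; the upper Ne bound is +∞ whenever the
lower F limit does not exceed the sampling terms.

**Pseudo-likelihood.**  Each allele of each locus in turn is the focal
allele vs. the pooled rest.  The likelihood of the time-t count given the
time-0 count places a uniform lattice prior on the initial population count,
conditions on the time-0 binomial observation, propagates Wright-Fisher
drift for t generations, and integrates the time-t binomial observation.
Within a locus the focal-allele log-likelihoods are averaged (not summed) to
avoid pseudo-replication; loci are summed.  The point estimate is the argmax
on a log-spaced grid (default max 3000, 64 points) and 95% bounds come from
the profile at a 1.92 log-unit drop.

*Numerical choice — large-Ne drift.*  For 2Ne ≤ 500 the t-step transition
matrix is exact (cached matrix powers).  Above that, t generations of
WF(2Ne) are collapsed into a **single variance-matched binomial step** with
m = 1/(1 − (1 − 1/(2Ne))ᵗ) trials from a fine (500-point) initial lattice.
This keeps every term a proper probability and joins the exact branch to
within ±0.02 log-units at the switch.  A plain Gaussian-diffusion
approximation was evaluated first and rejected: its noisy per-observation
error (±0.05 log-units) created an artificial likelihood bump at the switch
point that attracted ~30% of all calibration point estimates to a single
grid value.  The Gaussian kernel is retained only as a fallback when the
collapsed lattice would exceed 4000 points.

**Calibration.**  On Wright-Fisher datasets (true Ne = 200, t = 5, 8 loci,
10 alleles, 60 diploid individuals per sample) the long-run median of
1/N̂e is within 15% of 1/200 for both moment estimators (Fc ≈ 14.7%,
Fk ≈ 11.8% at 3000 replicates) and the pseudo-likelihood median point
estimate is within ~5% of the truth.  These estimators are noisy at this
design size — single-dataset intervals routinely reach +∞ — which is itself
the realistic behaviour for 8 loci.

## ABC with GLM adjustment for independent loci

Because the K observed loci are independent and exchangeable given the
parameters, the reference table simulates **single loci**: one prior draw,
one locus, one summary vector — reducing computation by 1/K relative to
simulating whole datasets.  Summaries per locus: the within-group variance
of repeat length for the three sample groups and the difference in group
mean repeat length for the three group pairs.  The third pairwise difference
is an exact linear combination of the other two, so the GLM internally uses
a full-rank 5-column subset (rejection distances use all six).

**Preprocessing.**  Summaries are arcsinh-transformed before
standardization: per-locus scatter grows multiplicatively with N·μ, and
after arcsinh the GLM residuals are near-Gaussian (skew ~0.3 versus ~10
raw).  Inside the machinery every strictly positive parameter works on a
log₁₀ scale (summaries respond multiplicatively to sizes, times and rates);
reporting scales are unchanged — loguniform-prior parameters are summarized
on the log scale and back-transformed, all others on their natural scale.

**Fit.**  The closest `retain_fraction` (default 0.05) of simulations by
mean Euclidean distance to the K observed per-locus summary vectors defines
the local parameter region; the linear Gaussian model s = c + Bθ + ε,
ε ~ N(0, Σ), is then fitted by OLS to **all simulations whose parameters lie
in the (padded 5–95%) box spanned by the retained draws**.  Fitting to the
retained rows themselves — selection on the regression response — attenuates
the slopes and measurably mis-calibrates the posterior (the ancestral size
was systematically overestimated, the same direction of bias reported for
this class of pipeline); selecting the fit set on the covariates keeps the
approximation local without biasing it.

**Posterior.**  π(θ | data) ∝ prior(θ) × Π_k N(s_obs⁽ᵏ⁾; c + Bθ, Σ).  The
Gaussian-in-θ likelihood is conjugated with a moment-matched Gaussian prior
to build a proposal (mean clipped into the support box, covariance
inflated), and the posterior is drawn by self-normalized importance sampling
from a defensive 50/50 mixture of that Gaussian and the exact prior — the
prior component bounds the weights when the Gaussianized likelihood peaks
against a hard prior bound.  Effective sample size is monitored, with
covariance-inflation retries.  Modes are kernel-density argmaxes; HDIs are
interval hulls of density superlevel sets, which makes the 50/90/95%
intervals nested and mode-containing by construction (for near-flat
densities the interval is centered on the probability mass).

**Model choice.**  The marginal density of the observed summaries under a
model is the Monte-Carlo average, over all prior draws in its reference
table, of the per-dataset Gaussian likelihood from that model's fitted GLM;
log₁₀ BF is the difference of log marginals.  Both models' summaries are
standardized on a common (pooled) scale so the densities are comparable and
the Jacobians of the shared transforms cancel.  The Bayes factor is
evaluated at several retained counts to produce a robustness curve; it is
antisymmetric under swapping the models by construction.

**Validation.**  On 20 pseudo-observed datasets drawn from the prior
(5·10⁴-row table, retain 0.05): overall 90%-HDI coverage ≈ 0.88, no
parameter's posterior-quantile uniformity rejected at α = 0.001 (minimum KS
p ≈ 0.007–0.08 across seeds), and a shuffled-summaries negative control
rejected at KS p ~ 10⁻¹¹.  Strong-signal model recovery: with data generated
under the inferred migration history, log₁₀ BF > 0 in 20/20 replicates with
the sign stable across retained counts.  Residual known biases, visible in
the signed-bias diagnostics at these design sizes: the past/present size
ratio and the divergence time retain positive mean bias of ~0.1–0.2 of the
prior range — parameters that 8 single-locus summaries simply constrain
weakly.

## Synthetic data

`generate_study_like_dataset` pairs consecutive haploid copies from the
coalescent into diploid genotypes (random mating within panmictic demes —
property-tested: thinning back to one haplotype per individual reproduces
the raw haploid summary distributions) and applies uniform-at-random
per-genotype missingness.  It emulates sample sizes, sampling times, locus
count and mutation model of the study design; it does **not** emulate
allelic dropout, null alleles, stutter, population substructure within the
modern sample, or the age-structured overlapping generations of real gorilla
populations.  Passing tests on these data therefore validate the estimators
under their own model assumptions, not robustness to those real-data
complications (the published analyses screened for them upstream).
`generate_temporal_wf_dataset` provides forward multinomial Wright-Fisher
drift with symmetric-Dirichlet initial frequencies and binomial endpoint
sampling for calibrating the temporal estimators.

## Problem sizes and tolerances

Simulator physics: 10,000 pairwise-TMRCA replicates (3 SE band), 2,000 loci
for the SMM equilibrium (10% band).  Temporal calibration: 500 Wright-Fisher
datasets for the moment estimators (15% band on 1/Ne, a band the Fc
estimator approaches — its long-run value is ≈14.7%), 120–150 for the
pseudo-likelihood (25% band), exact-oracle agreement at 2Ne = 4 to 10⁻¹⁰.
ABC: 5·10⁴ single-locus simulations, 20 pseudo-observed datasets, retain
0.05; model choice: 2·10⁴-row admixture table, 20 replicates.  These sizes
keep the full validation within a few minutes on one CPU while leaving each
check's Monte-Carlo error well inside its band; the seeds are fixed in the
tests and flow from `--seed` in the acceptance script.

## Known limitations

* Asymmetric migration, more than two descendant demes, recombination,
  selection, range-constrained or multi-step microsatellite mutation are out
  of scope (the mutation model is strict SMM by design).
* The pseudo-likelihood treats loci as exchangeable and reduces multiallelic
  information to focal-vs-rest contrasts; it is a pseudo- (composite)
  likelihood, so its profile intervals are approximate.
* The ABC posterior is only as good as the linear-Gaussian summary model;
  the validation harness (quantile uniformity, coverage, negative controls)
  is the arbiter, and weakly identified parameters lean on their priors.
* Genepop files are limited to 2- and 3-digit allele codes; alleles are
  repeat counts, and the fragment-length conversion helper is never applied
  implicitly.
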