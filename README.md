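# temporalpop

Demographic inference from **temporally sampled microsatellite genotypes** —
the analysis design used to study the Critically Endangered Cross River
gorilla (*Gorilla gorilla diehli*), where ~100-year-old museum genotypes are
compared with modern samples of the same population plus an outgroup
(western lowland gorillas) to reconstruct both recent and long-term
population history.

The study's raw genotypes are not publicly deposited, so the package ships a
first-class synthetic-data generator that emulates the study design
(14 historical Cross River individuals sampled 5 generations before present,
71 modern Cross River, 92 modern western lowland; 8 unlinked microsatellite
loci) and every analysis stage is validated on that machinery.

## What it does

* **Genepop I/O with sampling times** (`temporalpop.genotype`) — diploid
  repeat-count genotype tables, a plain-text sidecar annotation giving each
  population sample a deme and a sampling time in generations, and a
  one-haplotype-per-individual thinning that avoids spurious bottleneck
  signals from structured sampling.
* **Diversity statistics** (`temporalpop.diversity`) — observed and Nei's
  unbiased expected heterozygosity, rarefaction allelic richness
  AR(g) = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)], Weir & Cockerham (1984) F_IS and
  F_ST (variance components combined across loci as ratios of sums, with a
  permutation test), and the sample-size-matched H_e resampling comparison
  of historical vs. modern samples.
* **Temporal-method Ne** (`temporalpop.temporal_ne`) — Nei & Tajima's Fc and
  Pollak/Waples' Fk moment estimators with chi-square 95% bounds,
  Ne = t / (2[F − 1/(2S₀) − 1/(2Sₜ)]) (plan 2; plan 1 replaces t with t−2),
  and a pseudo-likelihood estimator that reduces each locus to focal-allele
  vs. pooled-rest comparisons and integrates binomial sampling at both ends
  over exact Wright-Fisher drift.
* **Serial structured coalescent** (`temporalpop.coalescent`) — a
  continuous-time, backwards coalescent for serially sampled gene copies
  under two demographic models: isolation-with-migration (2Nm migrants until
  T_migration, exponential Cross River bottleneck from T_bottleneck) and
  divergence with a secondary-admixture pulse (fraction γ replaced at a
  fraction of the divergence time); stepwise mutation (±1 repeat) along
  branches.  The event loop is numba-compiled (~0.2 ms per study-sized
  locus), with prior distributions matching the published study.
* **ABC with GLM adjustment** (`temporalpop.abc`) — single-locus reference
  tables, the 6-number summary vector (within-group allele-size variances,
  pairwise group mean differences), rejection plus a linear-Gaussian
  adjustment whose per-locus likelihoods are multiplied across the K
  independent observed loci, posterior modes and 50/90/95% highest-density
  intervals, log₁₀ Bayes-factor model comparison with a retained-count
  robustness curve, and a self-validation harness (posterior-quantile
  uniformity, HDI coverage, negative controls).

## Worked example

```bash
python examples/02_temporal_ne.py
```

```
8 microsatellite loci, 60 diploid individuals per sample, t = 5 generations, true Ne = 200

moment (fc): Ne =   215.1   95% [104, 599]   F = 0.0283
moment (fk): Ne =   200.7   95% [99, 522]   F = 0.0291
pseudo-likelihood: Ne =   185.0   95% [41, inf]
```

Both moment estimators and the pseudo-likelihood recover the true effective
size of 200 from 8 loci; the wide (partly unbounded) intervals show how much
of the observed allele-frequency change at these sample sizes is compatible
with sampling noise alone.  `examples/03_abc_posterior.py` runs the full
ABC-GLM fit on a pseudo-observed dataset generated at the study's inferred
history (divergence 891 generations ago, migration until 21 generations ago,
60-fold bottleneck from 16 generations ago) and prints posterior modes with
90% HDIs covering the truth, plus the times converted to years at the
20-year gorilla generation time.  `examples/04_model_choice.py` shows the
log₁₀ Bayes factor favoring the migration model at every retained-simulation
count when the data were generated with gene flow.

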