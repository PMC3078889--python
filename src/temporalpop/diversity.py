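"""Heterozygosity, allelic richness, F-statistics and sample-size-matched
resampling comparison of population samples.

Conventions follow the classical microsatellite toolkit: Nei's unbiased
expected heterozygosity, rarefaction allelic richness, and Weir & Cockerham
(1984) variance-component F-statistics combined across loci as ratios of
summed components (not averages of per-locus ratios).  Individuals missing a
genotype at a locus are dropped locus-wise, never list-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype import GenotypeTable, allele_frequencies

__all__ = [
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "allelic_richness",
    "f_is",
    "f_st",
    "he_resampling_test",
    "DiversityReport",
    "diversity_report",
]


def observed_heterozygosity(table: GenotypeTable, sample_label: str):
    """Fraction of non-missing individuals heterozygous at each locus.

    Returns ``(per_locus, mean)``; loci with no calls are excluded from the
    unweighted mean and reported as ``nan``.
    """
    sub = table.subset(sample_label)
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(sub.locus_names):
        het = n = 0
        for row in sub.calls:
            g = row[j]
            if g is None:
                continue
            n += 1
            het += g[0] != g[1]
        per_locus[locus] = het / n if n else float("nan")
    vals = [v for v in per_locus.values() if np.isfinite(v)]
    return per_locus, (float(np.mean(vals)) if vals else float("nan"))


def unbiased_expected_heterozygosity(table: GenotypeTable, sample_label: str):
    """Nei's unbiased expected heterozygosity per locus, and its mean.

    H_e = n/(n-1) * (1 - sum p_i^2), with n the number of non-missing gene
    copies.  Loci with n < 2 are undefined (``nan``) and excluded from the
    mean.
    """
    afs = allele_frequencies(table, sample_label)
    per_locus: dict[str, float] = {}
    for locus in table.locus_names:
        entry = afs.spectra.get(locus)
        if entry is None:
            per_locus[locus] = float("nan")
            continue
        freqs, n = entry
        if n < 2:
            per_locus[locus] = float("nan")
            continue
        p = np.array(list(freqs.values()))
        per_locus[locus] = float(n / (n - 1) * (1.0 - np.sum(p**2)))
    vals = [v for v in per_locus.values() if np.isfinite(v)]
    return per_locus, (float(np.mean(vals)) if vals else float("nan"))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(allele_counts, g: int, locus: str = "?") -> float:
    """Rarefaction allelic richness: expected number of distinct alleles in a
    subsample of ``g`` gene copies.

    AR(g) = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles i with count N_i,
    where N is the total gene-copy count at the locus.
    """
    counts = np.asarray(list(allele_counts), dtype=float)
    if np.any(counts <= 0):
        raise ValueError(f"locus {locus}: allele counts must be positive")
    N = counts.sum()
    if g < 1 or g > N:
        raise ValueError(f"locus {locus}: rarefaction size g={g} outside [1, N={int(N)}]")
    rest = N - counts
    # C(N - N_i, g) is zero when N - N_i < g
    with np.errstate(invalid="ignore"):
        ratio = np.where(
            rest >= g, np.exp(_log_comb(np.maximum(rest, g), g) - _log_comb(N, g)), 0.0
        )
    return float(np.sum(1.0 - ratio))


def _wc_components_single(genos: list[tuple[int, int]]):
    """Weir & Cockerham within-population variance components (b, c) summed
    over alleles at one locus of one sample.  f = 1 - sum(c)/sum(b + c)."""
    n = len(genos)
    alleles = sorted({a for g in genos for a in g})
    b_sum = c_sum = 0.0
    for al in alleles:
        p = sum((g[0] == al) + (g[1] == al) for g in genos) / (2 * n)
        h = sum((al in g) and (g[0] != g[1]) for g in genos) / n
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def f_is(table: GenotypeTable, sample_label: str):
    """Weir & Cockerham's inbreeding coefficient f within one sample.

    Returns ``(per_locus, multilocus)``.  The multilocus value combines
    variance components across loci (ratio of sums).  Monomorphic loci have an
    undefined per-locus value and contribute nothing to the sums.
    """
    sub = table.subset(sample_label)
    per_locus: dict[str, float] = {}
    B = C = 0.0
    for locus in sub.locus_names:
        genos = sub.locus_genotypes(locus)
        if len(genos) < 2:
            per_locus[locus] = float("nan")
            continue
        alleles = {a for g in genos for a in g}
        if len(alleles) < 2:
            per_locus[locus] = float("nan")
            continue
        b, c = _wc_components_single(genos)
        per_locus[locus] = 1.0 - c / (b + c) if (b + c) != 0 else float("nan")
        B += b
        C += c
    multi = 1.0 - C / (B + C) if (B + C) != 0 else float("nan")
    return per_locus, float(multi)


def _wc_theta_components(groups: list[list[tuple[int, int]]]):
    """Weir & Cockerham (1984) a, b, c variance components summed over the
    alleles of one locus across ``r`` population samples of diploid genotypes.
    """
    r = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    alleles = sorted({a for grp in groups for g in grp for a in g})
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p = np.array(
            [sum((g[0] == al) + (g[1] == al) for g in grp) / (2 * len(grp)) for grp in groups]
        )
        h = np.array(
            [sum((al in g) and (g[0] != g[1]) for g in grp) / len(grp) for grp in groups]
        )
        pbar = np.sum(ns * p) / (r * nbar)
        s2 = np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns * h) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _theta_from_tables(groupsA, groupsB):
    A = D = 0.0
    for gA, gB in zip(groupsA, groupsB):
        if len(gA) < 2 or len(gB) < 2:
            continue
        alleles = {al for g in gA + gB for al in g}
        if len(alleles) < 2:
            continue
        a, b, c = _wc_theta_components([gA, gB])
        A += a
        D += a + b + c
    return A / D if D != 0 else float("nan")


def f_st(
    table: GenotypeTable,
    sample_a: str,
    sample_b: str,
    n_perm: int = 999,
    seed: int = 0,
):
    """Weir & Cockerham theta between two samples with a permutation p-value.

    Individuals are shuffled between the two samples ``n_perm`` times; the
    p-value is the smoothed fraction of permutations with theta at least the
    observed value: (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subA, subB = table.subset(sample_a), table.subset(sample_b)
    if len(subA.individuals) < 2 or len(subB.individuals) < 2:
        raise ValueError("each sample needs at least 2 individuals for theta")
    loci = table.locus_names

    def _group_lists(rows):
        return [[row[j] for row in rows if row[j] is not None] for j in range(len(loci))]

    theta_obs = _theta_from_tables(_group_lists(subA.calls), _group_lists(subB.calls))

    rng = np.random.default_rng(seed)
    pooled = subA.calls + subB.calls
    nA = len(subA.calls)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        rowsA = [pooled[i] for i in perm[:nA]]
        rowsB = [pooled[i] for i in perm[nA:]]
        th = _theta_from_tables(_group_lists(rowsA), _group_lists(rowsB))
        if np.isfinite(th) and th >= theta_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return float(theta_obs), float(p)


def he_resampling_test(
    modern_table: GenotypeTable,
    historical_table: GenotypeTable,
    modern_label: str,
    historical_label: str,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Sample-size-matched comparison of mean expected heterozygosity.

    Repeatedly draws, without replacement, a subset of modern individuals
    equal in size to the historical sample, computes mean unbiased H_e across
    loci, and returns the fraction of draws with mean H_e >= the historical
    mean.  A small fraction indicates the historical sample is more diverse
    than same-sized modern subsamples.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    modern = modern_table.subset(modern_label)
    _, he_hist = unbiased_expected_heterozygosity(historical_table, historical_label)
    n_hist = len(historical_table.subset(historical_label).individuals)
    n_mod = len(modern.individuals)
    if n_mod < n_hist:
        raise ValueError("modern sample smaller than historical sample")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        idx = rng.choice(n_mod, size=n_hist, replace=False)
        he_vals = []
        for j in range(len(modern.locus_names)):
            counts: dict[int, int] = {}
            n = 0
            for i in idx:
                g = modern.calls[i][j]
                if g is None:
                    continue
                counts[g[0]] = counts.get(g[0], 0) + 1
                counts[g[1]] = counts.get(g[1], 0) + 1
                n += 2
            if n < 2:
                continue
            p = np.array(list(counts.values())) / n
            he_vals.append(n / (n - 1) * (1 - np.sum(p**2)))
        if he_vals and np.mean(he_vals) >= he_hist:
            hits += 1
    return hits / reps


@dataclass
class DiversityReport:
    """Per-locus and mean diversity summaries for one sample, plus optional
    pairwise differentiation against a second sample."""

    sample_label: str
    h_obs: dict[str, float]
    h_obs_mean: float
    h_exp: dict[str, float]
    h_exp_mean: float
    allelic_richness: dict[str, float]
    rarefaction_g: int
    f_is: dict[str, float]
    f_is_multilocus: float
    f_st: float | None = None
    f_st_pvalue: float | None = None


def diversity_report(
    table: GenotypeTable,
    sample_label: str,
    rarefaction_g: int | None = None,
    other_sample: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> DiversityReport:
    """One-stop per-sample diversity summary.

    ``rarefaction_g`` defaults to the smallest per-locus gene-copy count
    across the reported sample (and ``other_sample`` if given), the usual
    rarefaction convention.
    """
    labels = [sample_label] + ([other_sample] if other_sample else [])
    min_n = None
    for lab in labels:
        for freqs, n in allele_frequencies(table, lab).spectra.values():
            min_n = n if min_n is None else min(min_n, n)
    if rarefaction_g is None:
        if min_n is None:
            raise ValueError("no called loci; cannot choose rarefaction size")
        rarefaction_g = min_n

    ho, ho_mean = observed_heterozygosity(table, sample_label)
    he, he_mean = unbiased_expected_heterozygosity(table, sample_label)
    afs = allele_frequencies(table, sample_label)
    ar = {}
    for locus, (freqs, n) in afs.spectra.items():
        counts = [round(f * n) for f in freqs.values()]
        ar[locus] = allelic_richness(counts, min(rarefaction_g, n), locus)
    fis, fis_multi = f_is(table, sample_label)
    fst = pval = None
    if other_sample is not None:
        fst, pval = f_st(table, sample_label, other_sample, n_perm=n_perm, seed=seed)
    return DiversityReport(
        sample_label=sample_label,
        h_obs=ho,
        h_obs_mean=ho_mean,
        h_exp=he,
        h_exp_mean=he_mean,
        allelic_richness=ar,
        rarefaction_g=rarefaction_g,
        f_is=fis,
        f_is_multilocus=fis_multi,
        f_st=fst,
        f_st_pvalue=pval,
    )
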