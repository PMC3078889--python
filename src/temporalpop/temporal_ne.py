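"""Short-term effective population size from two temporally spaced samples.

Implements the temporal method: allele-frequency change between samples taken
``t`` generations apart reflects drift at rate 1/(2Ne) per generation plus
binomial sampling noise at each end.  Two moment estimators are provided —
Nei & Tajima's standardized variance Fc and Pollak's Fk as used by Waples —
together with a pseudo-likelihood estimator that reduces each multi-allelic
locus to a series of biallelic (focal allele vs. pooled rest) comparisons and
integrates binomial sampling at both ends over Wright-Fisher drift.

Sampling plans follow Nei & Tajima: plan 1 assumes individuals were sampled
after reproduction from a population whose census size approximates Ne
(giving the (t - 2) numerator); plan 2 assumes sampled individuals do not
contribute to the next generation (numerator t).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TemporalPair",
    "NeEstimate",
    "temporal_pairs_from_table",
    "fc_statistic",
    "fk_statistic",
    "ne_from_temporal_f",
    "moment_ne",
    "pseudo_likelihood_ne",
]


@dataclass
class TemporalPair:
    """Allele frequencies of one locus at two time points.

    ``x`` and ``y`` are frequency vectors over the union of alleles observed
    at either time (each summing to 1); ``s0`` and ``st`` are the gene-copy
    counts sampled at time 0 and time t.
    """

    x: np.ndarray
    y: np.ndarray
    s0: int
    st: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("x and y must be 1-d frequency vectors over the same support")
        for v, name in ((self.x, "x"), (self.y, "y")):
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.s0 < 2 or self.st < 2:
            raise ValueError("need at least 2 gene copies per time point")

    @property
    def n_alleles(self) -> int:
        return int(self.x.size)

    def is_polymorphic(self) -> bool:
        """False when one allele is fixed in both samples."""
        return self.n_alleles > 1 and not np.any((self.x >= 1.0) & (self.y >= 1.0))


@dataclass
class NeEstimate:
    """Point estimate of effective size with 95% bounds (diploid individuals).

    ``point`` and ``upper`` may be ``inf`` when the observed frequency change
    is fully explained by sampling.
    """

    point: float
    lower: float
    upper: float
    method: str
    plan: int
    f_value: float | None = None
    df: float | None = None
    profile: dict | None = field(default=None, repr=False)


def temporal_pairs_from_table(table, label_first: str, label_second: str):
    """Build per-locus :class:`TemporalPair` objects from two population
    samples of a genotype table (earlier sample first).

    Frequencies are taken over the union of alleles observed in either
    sample; loci with no calls in one of the samples are skipped.
    """
    from .genotype import allele_frequencies

    afs0 = allele_frequencies(table, label_first).spectra
    afs1 = allele_frequencies(table, label_second).spectra
    pairs = []
    for locus in table.locus_names:
        if locus not in afs0 or locus not in afs1:
            continue
        f0, n0 = afs0[locus]
        f1, n1 = afs1[locus]
        support = sorted(set(f0) | set(f1))
        x = np.array([f0.get(a, 0.0) for a in support])
        y = np.array([f1.get(a, 0.0) for a in support])
        pairs.append(TemporalPair(x=x, y=y, s0=n0, st=n1))
    return pairs


def _per_locus_stat(pairs, kind: str):
    values, weights = [], []
    for pair in pairs:
        if not pair.is_polymorphic():
            values.append(float("nan"))
            weights.append(0.0)
            continue
        x, y = pair.x, pair.y
        A = pair.n_alleles
        if kind == "fc":
            denom = (x + y) / 2 - x * y
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(denom > 0, (x - y) ** 2 / denom, 0.0)
            values.append(float(terms.sum() / A))
            weights.append(float(A))
        else:
            denom = (x + y) / 2
            terms = np.where(denom > 0, (x - y) ** 2 / denom, 0.0)
            values.append(float(terms.sum() / (A - 1)))
            weights.append(float(A - 1))
    vals = np.array(values)
    w = np.array(weights)
    if w.sum() == 0:
        warnings.warn("all loci monomorphic; temporal F undefined")
        return values, float("nan")
    multi = float(np.nansum(vals * w) / w.sum())
    return values, multi


def fc_statistic(pairs):
    """Nei & Tajima's Fc per locus and the multilocus value.

    Fc = (1/A) sum_i (x_i - y_i)^2 / [(x_i + y_i)/2 - x_i y_i]; the multilocus
    statistic is the mean weighted by the allele count of each locus.  Loci
    monomorphic at both times are excluded (nan per-locus, zero weight).
    """
    return _per_locus_stat(pairs, "fc")


def fk_statistic(pairs):
    """Pollak's Fk per locus and the multilocus value (Waples' usage).

    Fk = (1/(A-1)) sum_i (x_i - y_i)^2 / [(x_i + y_i)/2]; multilocus weighting
    is by the number of independent alleles (A - 1) per locus.
    """
    return _per_locus_stat(pairs, "fk")


def ne_from_temporal_f(
    F: float, s0: float, st: float, t: int, plan: int = 2, df: float | None = None,
    method: str = "temporal-F",
) -> NeEstimate:
    """Effective size from a multilocus temporal F statistic.

    plan 2: Ne = t / (2 [F - 1/(2 S0) - 1/(2 St)]);
    plan 1: Ne = (t - 2) / (2 [F - 1/(2 S0) - 1/(2 St)]) under the assumption
    that the census size equals Ne.  A non-positive denominator gives +inf.

    ``s0`` and ``st`` are the numbers of diploid individuals sampled, so the
    sampling-noise terms 1/(2 S) equal one over the gene-copy counts (the
    binomial sampling variance of an allele frequency from 2S gene copies is
    p(1-p)/(2S)).

    95% bounds use chi-square limits on F with ``df`` total independent
    alleles (sum over loci of A - 1): F in [df F / chi2_{0.975}, df F /
    chi2_{0.025}]; when the lower F limit does not exceed the sampling term
    the upper Ne bound is +inf.
    """
    if F <= 0:
        raise ValueError("F must be positive")
    if plan not in (1, 2):
        raise ValueError("plan must be 1 or 2")
    if plan == 1 and t <= 2:
        raise ValueError("plan 1 estimator undefined for t <= 2")
    sampling = 1.0 / (2 * s0) + 1.0 / (2 * st)
    numer = (t - 2) if plan == 1 else t

    def _ne(f: float) -> float:
        d = f - sampling
        return numer / (2 * d) if d > 0 else float("inf")

    lower = upper = float("nan")
    if df is not None and df > 0:
        f_hi = df * F / stats.chi2.ppf(0.025, df)
        f_lo = df * F / stats.chi2.ppf(0.975, df)
        lower, upper = _ne(f_hi), _ne(f_lo)
    return NeEstimate(
        point=float(_ne(F)), lower=float(lower), upper=float(upper),
        method=method, plan=plan, f_value=float(F), df=df,
    )


def moment_ne(pairs, t: int, plan: int = 2, statistic: str = "fc") -> NeEstimate:
    """Multilocus moment estimate of Ne from a set of :class:`TemporalPair`.

    ``statistic`` selects Nei & Tajima's Fc (``"fc"``) or Waples/Pollak Fk
    (``"fk"``).  Sample sizes entering the sampling-noise correction are
    harmonic means across loci.
    """
    stat_fn = fc_statistic if statistic == "fc" else fk_statistic
    _, F = stat_fn(pairs)
    poly = [p for p in pairs if p.is_polymorphic()]
    if not poly or not np.isfinite(F) or F <= 0:
        return NeEstimate(float("inf"), float("nan"), float("inf"),
                          f"moment-{statistic}", plan, f_value=F, df=0.0)
    # harmonic-mean gene-copy counts, halved to diploid individuals for the
    # 1/(2S) sampling terms
    s0 = len(poly) / sum(1.0 / p.s0 for p in poly) / 2.0
    st = len(poly) / sum(1.0 / p.st for p in poly) / 2.0
    df = float(sum(p.n_alleles - 1 for p in poly))
    est = ne_from_temporal_f(F, s0, st, t, plan=plan,
                             df=df, method=f"moment-{statistic}")
    return est


# ---------------------------------------------------------------------------
# Pseudo-likelihood estimator
# ---------------------------------------------------------------------------

#: exact Wright-Fisher transition matrices are used up to this many gene copies
EXACT_2NE_MAX = 500


@functools.lru_cache(maxsize=16)
def _wf_matrix_power(two_ne: int, t: int) -> np.ndarray:
    """t-generation Wright-Fisher allele-count transition matrix (exact)."""
    j = np.arange(two_ne + 1)
    p = j / two_ne
    T = stats.binom.pmf(j[None, :], two_ne, p[:, None])
    return np.linalg.matrix_power(T, t)


@functools.lru_cache(maxsize=200_000)
def _wM(two_ne: int, t: int, s0: int, x_cnt: int):
    """Posterior over population counts given the time-0 sample, propagated
    t generations: w_j P^t, cached since it is shared across datasets."""
    M = _wf_matrix_power(two_ne, t)
    p = np.arange(two_ne + 1) / two_ne
    w = stats.binom.pmf(x_cnt, s0, p)
    tot = w.sum()
    if tot <= 0:
        return None
    return (w / tot) @ M


@functools.lru_cache(maxsize=200_000)
def _emission(two_ne: int, st: int, y_cnt: int):
    p = np.arange(two_ne + 1) / two_ne
    return stats.binom.pmf(y_cnt, st, p)


def _loglik_exact(two_ne: int, t: int, x_cnt, s0, y_cnt, st) -> float:
    wM = _wM(two_ne, t, int(s0), int(x_cnt))
    if wM is None:
        return -np.inf
    L = float(wM @ _emission(two_ne, int(st), int(y_cnt)))
    return np.log(L) if L > 0 else -np.inf


# quadrature grid for the diffusion approximation
_N_GRID = 400


@functools.lru_cache(maxsize=256)
def _diffusion_transition(ne_key: float, t: int):
    """Row-normalized Gaussian-drift transition on the frequency grid, with
    drift mass beyond [0, 1] lumped into loss/fixation columns."""
    g = _N_GRID
    p0 = (np.arange(g) + 0.5) / g
    var = p0 * (1 - p0) * (1.0 - (1.0 - 1.0 / (2 * ne_key)) ** t)
    sd = np.sqrt(np.maximum(var, 1e-300))
    z = (p0[None, :] - p0[:, None]) / sd[:, None]
    dens = stats.norm.pdf(z) / sd[:, None] / g
    lo = stats.norm.cdf((0.0 - p0) / sd)
    hi = stats.norm.sf((1.0 - p0) / sd)
    norm = dens.sum(axis=1) + lo + hi
    return dens / norm[:, None], lo / norm, hi / norm


@functools.lru_cache(maxsize=200_000)
def _diffusion_dv(ne_key: float, t: int, st: int, y_cnt: int):
    """Transition matrix applied to the time-t emission vector, plus boundary
    contributions; depends on the data only through (st, y_cnt)."""
    dens, lo, hi = _diffusion_transition(ne_key, t)
    pt = (np.arange(_N_GRID) + 0.5) / _N_GRID
    v = stats.binom.pmf(y_cnt, st, pt)
    dv = dens @ v
    if y_cnt == 0:
        dv = dv + lo
    if y_cnt == st:
        dv = dv + hi
    return dv


@functools.lru_cache(maxsize=200_000)
def _diffusion_w(s0: int, x_cnt: int):
    p0 = (np.arange(_N_GRID) + 0.5) / _N_GRID
    w = stats.binom.pmf(x_cnt, s0, p0)
    tot = w.sum()
    return w / tot if tot > 0 else None


def _loglik_diffusion(ne: float, t: int, x_cnt, s0, y_cnt, st) -> float:
    """Gaussian-drift approximation of the Wright-Fisher transition for large
    Ne: p_t | p_0 ~ N(p_0, p_0 (1 - p_0) [1 - (1 - 1/(2Ne))^t])."""
    w = _diffusion_w(int(s0), int(x_cnt))
    if w is None:
        return -np.inf
    L = float(w @ _diffusion_dv(round(float(ne), 6), t, int(st), int(y_cnt)))
    return np.log(L) if L > 0 else -np.inf


#: above this collapsed lattice size the Gaussian diffusion takes over
_COLLAPSE_NMAX = 4000

#: initial-frequency lattice of the collapsed transition
_COLLAPSE_L = 500


@functools.lru_cache(maxsize=16)
def _collapse_transition(m: int) -> np.ndarray:
    """One-step binomial transition from the fine initial lattice (j/L) to a
    variance-matched m-point lattice: T[j, l] = Bin(l; m, j/L)."""
    j = np.arange(_COLLAPSE_L + 1) / _COLLAPSE_L
    l = np.arange(m + 1)
    return stats.binom.pmf(l[None, :], m, j[:, None])


@functools.lru_cache(maxsize=200_000)
def _collapse_wT(m: int, s0: int, x_cnt: int):
    """Initial-count posterior on the fine lattice propagated through the
    collapsed drift step; shared across datasets."""
    p = np.arange(_COLLAPSE_L + 1) / _COLLAPSE_L
    w = stats.binom.pmf(x_cnt, s0, p)
    tot = w.sum()
    if tot <= 0:
        return None
    return (w / tot) @ _collapse_transition(m)


def _loglik_collapsed(ne: float, t: int, x_cnt, s0, y_cnt, st) -> float:
    """Large-Ne drift likelihood: t generations of WF(2Ne) are collapsed into
    a single binomial step with m = 1/(1 - (1 - 1/(2Ne))^t) trials, which
    matches the drift variance exactly and keeps every term a proper
    probability."""
    m = max(int(round(1.0 / (1.0 - (1.0 - 1.0 / (2 * ne)) ** t))), 2)
    wT = _collapse_wT(m, int(s0), int(x_cnt))
    if wT is None:
        return -np.inf
    v = stats.binom.pmf(y_cnt, st, np.arange(m + 1) / m)
    L = float(wT @ v)
    return np.log(L) if L > 0 else -np.inf


def _locus_loglik(pair: TemporalPair, ne: float, t: int) -> float:
    """Mean log-likelihood over focal alleles of one locus (focal vs. pooled
    rest); averaging, not summing, avoids pseudo-replication within a locus.

    Drift over t generations uses the exact transition-matrix power for
    2Ne <= 500; for larger sizes the t-generation process is collapsed into a
    single variance-matched binomial step on a lattice of
    n* = 1/(1 - (1 - 1/(2Ne))^t) gene copies, falling back to the Gaussian
    diffusion only when that lattice would be impractically large.
    """
    x_cnt = np.rint(pair.x * pair.s0).astype(int)
    y_cnt = np.rint(pair.y * pair.st).astype(int)
    two_ne = int(round(2 * ne))
    lls = []
    for i in range(pair.n_alleles):
        if x_cnt[i] + y_cnt[i] == 0 or (x_cnt[i] == pair.s0 and y_cnt[i] == pair.st):
            continue
        if two_ne <= EXACT_2NE_MAX:
            ll = _loglik_exact(two_ne, t, x_cnt[i], pair.s0, y_cnt[i], pair.st)
        else:
            n_eff = int(round(1.0 / (1.0 - (1.0 - 1.0 / (2 * ne)) ** t)))
            if n_eff <= _COLLAPSE_NMAX:
                ll = _loglik_collapsed(ne, t, x_cnt[i], pair.s0, y_cnt[i], pair.st)
            else:
                ll = _loglik_diffusion(ne, t, x_cnt[i], pair.s0, y_cnt[i], pair.st)
        lls.append(ll)
    return float(np.mean(lls)) if lls else 0.0


def pseudo_likelihood_ne(
    pairs,
    t: int,
    ne_grid_max: int = 3000,
    n_grid: int = 64,
    ne_grid_min: float = 2.0,
    seed: int | None = None,
) -> NeEstimate:
    """Pseudo-likelihood Ne estimate on a log-spaced grid up to ``ne_grid_max``.

    For every focal allele of every locus the likelihood of the time-t sample
    count given the time-0 sample count is computed by integrating binomial
    sampling at both ends over Wright-Fisher drift (exact transition matrices
    for 2Ne <= 500, Gaussian diffusion above).  Per-locus log-likelihoods are
    the mean over focal alleles; loci are summed.  The point estimate is the
    grid argmax and 95% bounds come from the profile at a drop of 1.92
    log-units.  ``seed`` is accepted for interface uniformity; the computation
    is deterministic.
    """
    if ne_grid_max < 10:
        raise ValueError("ne_grid_max must be >= 10")
    poly = [p for p in pairs if p.is_polymorphic()]
    grid = np.unique(np.round(
        np.logspace(np.log10(ne_grid_min), np.log10(ne_grid_max), n_grid) * 2
    ) / 2)
    if not poly:
        warnings.warn("monomorphic dataset: flat pseudo-likelihood, Ne unbounded")
        prof = {"ne": grid, "loglik": np.zeros_like(grid)}
        return NeEstimate(float("inf"), float("nan"), float("inf"),
                          "pseudo-likelihood", 1, profile=prof)
    ll = np.array([sum(_locus_loglik(p, ne, t) for p in poly) for ne in grid])
    k = int(np.argmax(ll))
    keep = ll >= ll[k] - 1.92
    lower = float(grid[keep].min())
    upper = float(grid[keep].max())
    point = float(grid[k])
    if k == len(grid) - 1:
        point = float("inf")
        upper = float("inf")
    elif keep[-1]:
        upper = float("inf")
    return NeEstimate(point, lower, upper, "pseudo-likelihood", 1,
                      profile={"ne": grid, "loglik": ll})
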