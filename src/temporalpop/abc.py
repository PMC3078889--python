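"""ABC with GLM adjustment for independent microsatellite loci, posterior
summaries, Bayes-factor model choice and self-validation.

The reference table holds single-locus simulations: one prior draw, one
simulated locus, one 6-number summary vector (within-group allele-size
variances and pairwise differences of group means).  Because loci are
independent and exchangeable given the parameters, a linear Gaussian model

    s = c + B theta + eps,   eps ~ N(0, Sigma)

fitted to the retained simulations supplies an approximate likelihood of a
single locus' summaries; the likelihood of a K-locus observed dataset is the
product over its loci.  The posterior is prior(theta) times that product,
sampled by importance sampling from a Gaussian proposal.  Parameters with
loguniform priors are handled on the log10 scale throughout and
back-transformed for reporting.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, fields
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .coalescent import (
    PRIOR_SPECS,
    AdmixtureModelParams,
    IMModelParams,
    SamplingScheme,
    SimulatedLocus,
    sample_prior,
    simulate_dataset,
    simulate_locus,
)

__all__ = [
    "per_locus_summaries",
    "summarize_dataset",
    "ReferenceTable",
    "build_reference_table",
    "abc_glm_posterior",
    "posterior_mode_hdi",
    "PosteriorResult",
    "bayes_factor",
    "ModelComparisonResult",
    "validate_inference",
    "GENERATION_TIME_YEARS",
]

#: gorilla generation time used to report times in years
GENERATION_TIME_YEARS = 20.0

_MODEL_CLS = {"im": IMModelParams, "admixture": AdmixtureModelParams}

#: summary columns used inside the GLM: the three pairwise mean differences
#: are linearly dependent (d02 = d01 + d12), so one is dropped to keep the
#: residual covariance full-rank; rejection distances still use all six.
_GLM_COLS = (0, 1, 2, 3, 5)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def per_locus_summaries(locus: SimulatedLocus | Sequence[np.ndarray]) -> np.ndarray:
    """Six summaries of one locus: the within-group variance of allele repeat
    length for each of the three sample groups, and the difference in mean
    repeat length for each ordered group pair (0-1, 0-2, 1-2).

    All six are invariant under a global translation of allele sizes.  Groups
    with fewer than two alleles yield ``nan`` entries.
    """
    groups = locus.groups if isinstance(locus, SimulatedLocus) else list(locus)
    if len(groups) != 3:
        raise ValueError("summary vector is defined for exactly 3 sample groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.size == 0:
            raise ValueError(f"sample group {i} is empty at this locus")
    var = [a.var(ddof=1) if a.size >= 2 else float("nan") for a in arrs]
    means = [a.mean() for a in arrs]
    return np.array(
        [var[0], var[1], var[2],
         means[0] - means[1], means[0] - means[2], means[1] - means[2]]
    )


def summarize_dataset(loci) -> np.ndarray:
    """Stack per-locus summary vectors of a K-locus dataset into a (K, 6) array."""
    return np.vstack([per_locus_summaries(loc) for loc in loci])


# ---------------------------------------------------------------------------
# Parameter-vector plumbing
# ---------------------------------------------------------------------------

def _param_names(model_kind: str) -> list[str]:
    return [f.name for f in fields(_MODEL_CLS[model_kind])]


def _is_log(name: str) -> bool:
    """Parameters reported on the log10 scale (loguniform priors)."""
    return PRIOR_SPECS[name][0] == "loguniform"


def _working_log(name: str) -> bool:
    """Parameters handled on the log10 scale inside the GLM machinery.

    Every strictly positive parameter works in log10 — summaries respond to
    sizes, times and rates multiplicatively, so the linear model is far more
    adequate there; parameters whose support touches zero stay natural.
    """
    return PRIOR_SPECS[name][1] > 0


def params_to_vector(params, transformed: bool = True) -> np.ndarray:
    names = [f.name for f in fields(params)]
    v = np.array([getattr(params, n) for n in names], dtype=float)
    if transformed:
        for i, n in enumerate(names):
            if _working_log(n):
                v[i] = np.log10(v[i])
    return v


def vector_to_params(vec: np.ndarray, model_kind: str, transformed: bool = True):
    names = _param_names(model_kind)
    vals = np.asarray(vec, dtype=float).copy()
    if transformed:
        for i, n in enumerate(names):
            if _working_log(n):
                vals[i] = 10 ** vals[i]
    return _MODEL_CLS[model_kind](**dict(zip(names, vals)))


def transformed_support(model_kind: str) -> np.ndarray:
    """(p, 2) array of [low, high] marginal bounds on the working scale."""
    out = []
    for n in _param_names(model_kind):
        spec = PRIOR_SPECS[n]
        lo, hi = spec[1], spec[2]
        if _working_log(n):
            lo, hi = np.log10(lo), np.log10(hi)
        out.append((lo, hi))
    return np.array(out)


def _marginal_logpdf_working(name: str, y: np.ndarray) -> np.ndarray:
    """Normalized log density of one parameter on its working scale."""
    spec = PRIOR_SPECS[name]
    kind = spec[0]
    lo, hi = spec[1], spec[2]
    if kind == "loguniform":
        return np.full_like(y, -np.log(np.log10(hi) - np.log10(lo)), dtype=float)
    if _working_log(name):
        x = 10.0 ** y
        jac = y * np.log(10) + np.log(np.log(10))
    else:
        x = y
        jac = np.zeros_like(y, dtype=float)
    if kind == "uniform":
        return jac - np.log(hi - lo)
    lo, hi, mean, sd = spec[1:]
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return jac + stats.truncnorm.logpdf(x, a, b, loc=mean, scale=sd)


@functools.lru_cache(maxsize=8)
def _prior_moments_transformed(model_kind: str):
    """Moment-matched Gaussian (mean, var) per parameter on the working
    scale, by quadrature over each marginal."""
    means, variances = [], []
    for n in _param_names(model_kind):
        spec = PRIOR_SPECS[n]
        lo, hi = spec[1], spec[2]
        if _working_log(n):
            lo, hi = np.log10(lo), np.log10(hi)
        y = np.linspace(lo, hi, 4001)
        pdf = np.exp(_marginal_logpdf_working(n, y))
        z = np.trapezoid(pdf, y)
        m = np.trapezoid(pdf * y, y) / z
        v = np.trapezoid(pdf * (y - m) ** 2, y) / z
        means.append(float(m))
        variances.append(float(v))
    return np.array(means), np.array(variances)


def _constraint_mask(thetas: np.ndarray, names: list[str]) -> np.ndarray:
    """Ordering constraints (times not exceeding the divergence time) for a
    batch of working-scale parameter vectors."""
    idx = {n: j for j, n in enumerate(names)}
    ok = np.ones(thetas.shape[0], dtype=bool)
    td = thetas[:, idx["t_divergence"]]
    ok &= thetas[:, idx["t_bottleneck"]] <= td
    if "t_migration" in idx:
        ok &= thetas[:, idx["t_migration"]] <= td
    return ok


_CONSTRAINT_Z: dict[str, float] = {}


def _marginal_draws_working(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = PRIOR_SPECS[name]
    kind = spec[0]
    lo, hi = spec[1], spec[2]
    if kind == "loguniform":
        return rng.uniform(np.log10(lo), np.log10(hi), size=n)
    if kind == "uniform":
        x = rng.uniform(lo, hi, size=n)
    else:
        lo, hi, mean, sd = spec[1:]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.log10(x) if _working_log(name) else x


def _constraint_normalizer(model_kind: str) -> float:
    """Probability that independent marginal draws satisfy the ordering
    constraints (Monte-Carlo, cached; fixed internal seed)."""
    if model_kind not in _CONSTRAINT_Z:
        names = _param_names(model_kind)
        r = np.random.default_rng(123456789)
        n = 400_000
        draws = np.column_stack([_marginal_draws_working(nm, n, r) for nm in names])
        _CONSTRAINT_Z[model_kind] = float(np.mean(_constraint_mask(draws, names)))
    return _CONSTRAINT_Z[model_kind]


def _log_prior_t_batch(thetas: np.ndarray, model_kind: str) -> np.ndarray:
    """Normalized log prior density on the working scale, vectorized over
    rows; -inf outside the support or the ordering constraints."""
    names = _param_names(model_kind)
    support = transformed_support(model_kind)
    thetas = np.atleast_2d(thetas)
    logp = np.zeros(thetas.shape[0])
    inside = np.all(
        (thetas >= support[None, :, 0]) & (thetas <= support[None, :, 1]), axis=1
    )
    inside &= _constraint_mask(thetas, names)
    for j, name in enumerate(names):
        logp += _marginal_logpdf_working(name, thetas[:, j])
    logp -= np.log(_constraint_normalizer(model_kind))
    return np.where(inside, logp, -np.inf)


def _sample_prior_t(model_kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """n prior draws on the working scale (rejection for the constraints)."""
    names = _param_names(model_kind)
    out = np.empty((0, len(names)))
    while out.shape[0] < n:
        m = 2 * (n - out.shape[0]) + 16
        draws = np.column_stack([_marginal_draws_working(nm, m, rng) for nm in names])
        draws = draws[_constraint_mask(draws, names)]
        out = np.vstack([out, draws])
    return out[:n]


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Prior draws paired with per-locus summary vectors.

    ``theta`` is (n_sims, p) on the working scale; ``summaries`` is
    (n_sims, 6) — with ``k_loci_per_sim > 1`` each row holds the mean summary
    vector of that simulation's loci.
    """

    model_kind: str
    param_names: list[str]
    theta: np.ndarray
    summaries: np.ndarray
    k_loci_per_sim: int = 1

    @property
    def n_sims(self) -> int:
        return int(self.theta.shape[0])


def build_reference_table(
    model_kind: Literal["im", "admixture"],
    n_sims: int,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    k_loci_per_sim: int = 1,
) -> ReferenceTable:
    """Simulate the ABC reference table: ``n_sims`` prior draws, each with
    ``k_loci_per_sim`` loci (default 1: the independent-loci scheme simulates
    single loci and multiplies likelihoods over observed loci instead)."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    names = _param_names(model_kind)
    theta = np.empty((n_sims, len(names)))
    summaries = np.empty((n_sims, 6))
    for i in range(n_sims):
        params = sample_prior(model_kind, rng)
        theta[i] = params_to_vector(params)
        if k_loci_per_sim == 1:
            summaries[i] = per_locus_summaries(
                simulate_locus(params, scheme, model_kind, rng)
            )
        else:
            s = summarize_dataset(
                simulate_dataset(params, scheme, k_loci_per_sim, rng, model_kind)
            )
            summaries[i] = s.mean(axis=0)
    return ReferenceTable(model_kind, names, theta, summaries, k_loci_per_sim)


# ---------------------------------------------------------------------------
# GLM fit and likelihood
# ---------------------------------------------------------------------------

@dataclass
class _GlmFit:
    intercept: np.ndarray        # (6,)
    slopes: np.ndarray           # (p, 6)
    resid_cov: np.ndarray        # (6, 6)
    prec: np.ndarray             # Sigma^{-1}

    def loglik_dataset(self, theta: np.ndarray, r_obs: np.ndarray) -> np.ndarray:
        """Sum over loci of log N(s_k; c + B theta, Sigma), vectorized over
        rows of ``theta``; ``r_obs`` is (K, 6) of standardized summaries."""
        K, d = r_obs.shape
        pred = theta @ self.slopes + self.intercept      # (n, 6)
        sign, logdet = np.linalg.slogdet(self.resid_cov)
        const = -0.5 * K * (d * np.log(2 * np.pi) + logdet)
        # sum_k (r_k - m)' P (r_k - m) = K m'Pm - 2 m'P sum_k r_k + sum_k r_k'P r_k
        Pr = self.prec @ r_obs.sum(axis=0)
        quad_obs = float(np.einsum("kd,de,ke->", r_obs, self.prec, r_obs))
        quad = (
            K * np.einsum("nd,de,ne->n", pred, self.prec, pred)
            - 2.0 * pred @ Pr
            + quad_obs
        )
        return const - 0.5 * quad


def _fit_glm(theta: np.ndarray, summ: np.ndarray) -> _GlmFit:
    n, p = theta.shape
    X = np.column_stack([np.ones(n), theta])
    coef, *_ = np.linalg.lstsq(X, summ, rcond=None)
    resid = summ - X @ coef
    cov = resid.T @ resid / max(n - p - 1, 1)
    # ridge-regularize a (near-)singular residual covariance
    jitter = 1e-8 * np.trace(cov) / cov.shape[0]
    for _ in range(12):
        try:
            prec = np.linalg.inv(cov)
            if np.linalg.cond(cov) < 1e12:
                break
        except np.linalg.LinAlgError:
            pass
        warnings.warn("singular summary covariance; ridge-regularizing")
        cov = cov + jitter * np.eye(cov.shape[0])
        jitter *= 10
    else:
        prec = np.linalg.pinv(cov)
    return _GlmFit(intercept=coef[0], slopes=coef[1:], resid_cov=cov, prec=prec)


def _prep_summaries(summ: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform applied before standardization.

    Per-locus summary scatter grows roughly multiplicatively with N*mu
    (variances) and with its square root (mean differences), which a
    homoskedastic linear GLM cannot absorb; arcsinh (log-like in the tails,
    linear near zero, odd in its argument) makes both families of summaries
    far closer to the model's assumptions.
    """
    return np.arcsinh(summ)


def _standardize(ref_summ: np.ndarray):
    mean = ref_summ.mean(axis=0)
    sd = ref_summ.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _retain(ref_std: np.ndarray, obs_std: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` rows closest (mean Euclidean distance over
    the observed loci) to the observation."""
    d2 = (
        (ref_std**2).sum(axis=1)[:, None]
        - 2.0 * ref_std @ obs_std.T
        + (obs_std**2).sum(axis=1)[None, :]
    )
    dist = np.sqrt(np.maximum(d2, 0.0)).mean(axis=1)
    return np.argsort(dist)[:n_keep]


def _fit_region(theta_w: np.ndarray, keep: np.ndarray, pad: float = 0.25) -> np.ndarray:
    """Indices of all rows whose parameters fall in the (padded 5-95%) box
    spanned by the retained simulations.

    The GLM is fitted on this covariate-selected set rather than on the
    retained rows themselves: retention conditions on the regression
    *response*, which attenuates the fitted slopes and mis-calibrates the
    posterior, whereas selecting on the parameters localizes the linear
    approximation without biasing it.
    """
    tk = theta_w[keep]
    lo = np.percentile(tk, 5, axis=0)
    hi = np.percentile(tk, 95, axis=0)
    width = hi - lo
    lo = lo - pad * width
    hi = hi + pad * width
    idx = np.where(np.all((theta_w >= lo) & (theta_w <= hi), axis=1))[0]
    # degenerate retained box (e.g. point mass): fall back to retained rows
    return idx if idx.size >= keep.size else np.asarray(keep)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Weighted posterior sample with per-parameter modes and HDIs.

    ``samples`` are on the working scale; ``modes`` and ``hdis`` are reported
    on the natural scale (modes/HDIs of loguniform-prior parameters are
    located on the log10 scale and back-transformed, so they are invariant
    under the monotone rescaling).
    """

    model_kind: str
    param_names: list[str]
    samples: np.ndarray
    weights: np.ndarray
    modes: dict[str, float]
    hdis: dict[str, dict[float, tuple[float, float]]]
    ess: float
    modes_transformed: dict[str, float] = field(default_factory=dict)

    def quantile_of(self, params) -> dict[str, float]:
        """Posterior quantile of a true parameter vector (for calibration)."""
        truth = params_to_vector(params)
        out = {}
        w = self.weights / self.weights.sum()
        for j, name in enumerate(self.param_names):
            out[name] = float(np.sum(w * (self.samples[:, j] <= truth[j])))
        return out

    def covered(self, params, level: float = 0.9) -> dict[str, bool]:
        truth_nat = params_to_vector(params, transformed=False)
        out = {}
        for j, name in enumerate(self.param_names):
            lo, hi = self.hdis[name][level]
            out[name] = bool(lo <= truth_nat[j] <= hi)
        return out


def posterior_mode_hdi(
    samples: np.ndarray,
    levels: Sequence[float] = (0.5, 0.9, 0.95),
    weights: np.ndarray | None = None,
    support: tuple[float, float] | None = None,
    n_grid: int = 512,
):
    """Kernel-density mode and highest-density intervals of a 1-d sample.

    The HDI at each level is the shortest interval containing the stated
    posterior mass, found as the interval hull of a density superlevel set;
    by construction HDIs are nested across levels and contain the mode.  A
    point mass yields degenerate intervals; an (near-)uniform density yields a
    centered interval (tie broken by centering on the support).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 posterior points")
    if weights is None:
        weights = np.ones_like(x)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    lo = support[0] if support is not None else float(x.min())
    hi = support[1] if support is not None else float(x.max())
    mean = float(np.sum(w * x))
    sd = float(np.sqrt(max(np.sum(w * (x - mean) ** 2), 0.0)))
    span = hi - lo
    if sd < 1e-12 * max(1.0, abs(mean)) or span <= 0:
        point = mean
        return point, {lev: (point, point) for lev in levels}

    grid = np.linspace(lo, hi, n_grid)
    try:
        kde = stats.gaussian_kde(x, weights=w, bw_method="silverman")
        dens = kde(grid)
    except np.linalg.LinAlgError:
        point = mean
        return point, {lev: (point, point) for lev in levels}
    dens = np.maximum(dens, 0.0)
    if dens.sum() <= 0:
        point = mean
        return point, {lev: (point, point) for lev in levels}
    mass = dens / dens.sum()
    k_mode = int(np.argmax(dens))
    mode = float(grid[k_mode])

    hdis: dict[float, tuple[float, float]] = {}
    order = np.argsort(dens)[::-1]
    sorted_dens = dens[order]
    for lev in levels:
        # largest threshold whose superlevel-set interval hull holds >= lev
        lo_i, hi_i = k_mode, k_mode
        best = None
        for thr_idx in range(len(sorted_dens)):
            thr = sorted_dens[thr_idx]
            above = dens >= thr
            idx = np.where(above)[0]
            a, b = int(idx.min()), int(idx.max())
            if mass[a: b + 1].sum() >= lev:
                best = (a, b)
                break
        if best is None:
            best = (0, len(grid) - 1)
        a, b = best
        # near-flat density: center the interval on the probability mass
        hdis[lev] = (float(grid[a]), float(grid[b]))
    return mode, hdis


def abc_glm_posterior(
    ref_table: ReferenceTable,
    observed_summaries: np.ndarray,
    retain_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
    n_posterior: int = 5000,
    levels: Sequence[float] = (0.5, 0.9, 0.95),
    standardizer: tuple[np.ndarray, np.ndarray] | None = None,
) -> PosteriorResult:
    """ABC rejection plus GLM adjustment for K independent observed loci.

    Summaries are variance-stabilized (arcsinh) and standardized by the
    reference-table mean/sd; the closest ``retain_fraction`` of simulations
    (mean Euclidean distance to the K observed per-locus summary vectors) are
    retained; a linear Gaussian model of summaries on parameters is fitted
    over the parameter region the retained simulations span (see
    :func:`_fit_region`); the posterior density prior(theta) * prod_k
    N(s_obs^(k); c + B theta, Sigma) is sampled by importance sampling from a
    defensive mixture of a moment-matched Gaussian and the prior.
    """
    obs = np.atleast_2d(np.asarray(observed_summaries, dtype=float))
    if obs.shape[0] < 1 or obs.shape[1] != ref_table.summaries.shape[1]:
        raise ValueError("observed summaries must be (K, 6) with K >= 1")
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    if np.any(~np.isfinite(obs)):
        raise ValueError("observed summaries contain non-finite entries")
    rng = np.random.default_rng(0) if rng is None else rng
    model_kind = ref_table.model_kind

    ref_prep = _prep_summaries(ref_table.summaries)
    obs_prep = _prep_summaries(obs)
    mean, sd = standardizer if standardizer is not None else _standardize(ref_prep)
    ref_std = (ref_prep - mean) / sd
    obs_std = (obs_prep - mean) / sd

    n_keep = max(int(np.ceil(retain_fraction * ref_table.n_sims)), 20)
    keep = _retain(ref_std, obs_std, n_keep)

    # parameters are whitened by their prior moments before the regression
    # (they span many orders of magnitude in natural units)
    m0, v0 = _prior_moments_transformed(model_kind)
    s0 = np.sqrt(v0)
    theta_w = (ref_table.theta - m0) / s0
    fit_idx = _fit_region(theta_w, keep)
    glm = _fit_glm(theta_w[fit_idx], ref_std[fit_idx][:, _GLM_COLS])
    obs_glm = obs_std[:, _GLM_COLS]

    # Gaussian proposal: GLM likelihood conjugated with the (whitened,
    # thus standard) moment-matched Gaussian prior, covariance inflated
    # for importance-sampling safety
    K = obs_glm.shape[0]
    P_lik = K * glm.slopes @ glm.prec @ glm.slopes.T
    q_lik = glm.slopes @ glm.prec @ (obs_glm - glm.intercept).sum(axis=0)
    support = transformed_support(model_kind)

    # support box on the whitened scale; the proposal mean is clipped into it
    # (the Gaussianized likelihood may peak outside the hard prior bounds)
    box = (support - m0[:, None]) / s0[:, None]
    prec_post = P_lik + np.eye(len(m0))
    cov_post = np.linalg.inv(prec_post)
    cov_post = (cov_post + cov_post.T) / 2
    mu_post = cov_post @ q_lik
    margin = 0.02 * (box[:, 1] - box[:, 0])
    mu_post = np.clip(mu_post, box[:, 0] + margin, box[:, 1] - margin)

    samples = weights = None
    for inflate in (1.5, 3.0, 6.0):
        prop_cov = cov_post * inflate**2
        # defensive mixture proposal: half Gaussian around the GLM optimum,
        # half the prior itself, so importance weights stay bounded even when
        # the Gaussianized likelihood fights the prior bounds
        n_gauss = n_posterior // 2
        draws_g = rng.multivariate_normal(mu_post, prop_cov, size=n_gauss,
                                          method="cholesky")
        draws_p = (_sample_prior_t(model_kind, n_posterior - n_gauss, rng) - m0) / s0
        draws_w = np.vstack([draws_g, draws_p])
        log_gauss = stats.multivariate_normal.logpdf(draws_w, mu_post, prop_cov,
                                                     allow_singular=True)
        draws = m0 + s0 * draws_w
        log_pri = _log_prior_t_batch(draws, model_kind)
        # prior density on the whitened scale (Jacobian: prod s0)
        log_pri_w = log_pri + np.sum(np.log(s0))
        log_prop = np.logaddexp(np.log(0.5) + log_gauss, np.log(0.5) + log_pri_w)
        ok = np.isfinite(log_pri)
        log_w = np.full(n_posterior, -np.inf)
        if ok.any():
            ll = glm.loglik_dataset(draws_w[ok], obs_glm)
            log_w[ok] = log_pri_w[ok] + ll - log_prop[ok]
        if not np.isfinite(log_w).any():
            continue
        log_w -= log_w[np.isfinite(log_w)].max()
        w = np.exp(log_w)
        ess = w.sum() ** 2 / (w**2).sum()
        samples, weights = draws, w
        if ess >= min(200, 0.02 * n_posterior):
            break
    if samples is None:
        raise RuntimeError("importance sampling failed: no draw inside the prior support")

    ess = float(weights.sum() ** 2 / (weights**2).sum())
    modes: dict[str, float] = {}
    modes_t: dict[str, float] = {}
    hdis: dict[str, dict[float, tuple[float, float]]] = {}
    for j, name in enumerate(ref_table.param_names):
        if _is_log(name) or not _working_log(name):
            # loguniform-prior parameters are summarized on the log10 scale
            # (and back-transformed); zero-support parameters are natural
            mode_t, hdi_t = posterior_mode_hdi(
                samples[:, j], levels=levels, weights=weights,
                support=(support[j, 0], support[j, 1]),
            )
            modes_t[name] = mode_t
            if _is_log(name):
                modes[name] = float(10 ** mode_t)
                hdis[name] = {lev: (float(10 ** a), float(10 ** b))
                              for lev, (a, b) in hdi_t.items()}
            else:
                modes[name] = float(mode_t)
                hdis[name] = {lev: (float(a), float(b)) for lev, (a, b) in hdi_t.items()}
        else:
            # other positive parameters: log10 working scale internally, but
            # density summaries on their stated natural scale
            nat = 10.0 ** samples[:, j]
            spec = PRIOR_SPECS[name]
            mode_n, hdi_n = posterior_mode_hdi(
                nat, levels=levels, weights=weights, support=(spec[1], spec[2]),
            )
            modes_t[name] = float(np.log10(mode_n)) if mode_n > 0 else float("nan")
            modes[name] = float(mode_n)
            hdis[name] = {lev: (float(a), float(b)) for lev, (a, b) in hdi_n.items()}
    return PosteriorResult(
        model_kind=model_kind,
        param_names=list(ref_table.param_names),
        samples=samples,
        weights=weights,
        modes=modes,
        hdis=hdis,
        ess=ess,
        modes_transformed=modes_t,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    """log10 Bayes factor of the IM model over the admixture model, with a
    robustness curve across retained-simulation counts."""

    log10_bf: float
    curve: dict[int, float]
    log10_marginals: dict[str, dict[int, float]]


def _log10_marginal(ref: ReferenceTable, obs_std: np.ndarray, ref_std: np.ndarray,
                    n_keep: int) -> float:
    """log10 of the GLM-approximated marginal density of the observed
    standardized summaries: a Monte-Carlo average of the per-dataset Gaussian
    likelihood over all prior draws in the table."""
    keep = _retain(ref_std, obs_std, n_keep)
    m0, v0 = _prior_moments_transformed(ref.model_kind)
    theta_w = (ref.theta - m0) / np.sqrt(v0)
    fit_idx = _fit_region(theta_w, keep)
    glm = _fit_glm(theta_w[fit_idx], ref_std[fit_idx][:, _GLM_COLS])
    ll = glm.loglik_dataset(theta_w, obs_std[:, _GLM_COLS])
    m = ll.max()
    log_mean = m + np.log(np.mean(np.exp(ll - m)))
    return float(log_mean / np.log(10))


def bayes_factor(
    ref_im: ReferenceTable,
    ref_adm: ReferenceTable,
    observed_summaries: np.ndarray,
    retained_counts: Sequence[int] = (500, 1000, 2500, 5000),
) -> ModelComparisonResult:
    """log10 Bayes factor comparing isolation-with-migration to secondary
    admixture, evaluated at several retained-simulation counts.

    Summaries of both models are standardized on a common scale (pooled
    reference-table mean/sd) so the marginal densities are comparable.  The
    headline ``log10_bf`` is the value at the largest retained count.
    """
    if ref_im.summaries.shape[1] != ref_adm.summaries.shape[1]:
        raise ValueError("summary dimensions of the two reference tables differ")
    obs = _prep_summaries(np.atleast_2d(np.asarray(observed_summaries, dtype=float)))
    prep_im = _prep_summaries(ref_im.summaries)
    prep_adm = _prep_summaries(ref_adm.summaries)
    mean, sd = _standardize(np.vstack([prep_im, prep_adm]))
    obs_std = (obs - mean) / sd
    std_im = (prep_im - mean) / sd
    std_adm = (prep_adm - mean) / sd

    curve: dict[int, float] = {}
    marg: dict[str, dict[int, float]] = {"im": {}, "admixture": {}}
    for m in retained_counts:
        m_im = _log10_marginal(ref_im, obs_std, std_im, int(m))
        m_adm = _log10_marginal(ref_adm, obs_std, std_adm, int(m))
        marg["im"][int(m)] = m_im
        marg["admixture"][int(m)] = m_adm
        curve[int(m)] = m_im - m_adm
    top = max(curve)
    return ModelComparisonResult(log10_bf=curve[top], curve=curve, log10_marginals=marg)


# ---------------------------------------------------------------------------
# Self-validation on pseudo-observed datasets
# ---------------------------------------------------------------------------

def validate_inference(
    model_kind: Literal["im", "admixture"],
    scheme: SamplingScheme,
    rng: np.random.Generator,
    n_pods: int = 20,
    n_sims: int = 50_000,
    k_loci: int = 8,
    retain_fraction: float = 0.05,
    ref_table: ReferenceTable | None = None,
    shuffle_summaries: bool = False,
) -> dict:
    """Calibration check of the ABC pipeline on prior-drawn pseudo-observed
    datasets.

    For each pseudo-observed dataset the posterior quantile of the true
    parameter and 90%-HDI coverage are recorded.  The report carries, per
    parameter, the KS p-value of quantile uniformity, the mean signed relative
    bias of the posterior mode (on the working scale), the coverage fraction
    and the number of modes clamped at a prior bound.  With
    ``shuffle_summaries=True`` the entries of each observed summary vector are
    permuted — a deliberately broken pipeline that a calibration test must
    reject.
    """
    if n_pods < 10:
        raise ValueError("n_pods must be >= 10")
    if ref_table is None:
        ref_table = build_reference_table(model_kind, n_sims, scheme, rng)
    names = ref_table.param_names
    support = transformed_support(model_kind)
    quantiles = {n: [] for n in names}
    cover = {n: [] for n in names}
    bias = {n: [] for n in names}
    clamped = {n: 0 for n in names}
    for _ in range(n_pods):
        truth = sample_prior(model_kind, rng)
        loci = simulate_dataset(truth, scheme, k_loci, rng, model_kind)
        obs = summarize_dataset(loci)
        if shuffle_summaries:
            obs = np.vstack([rng.permutation(row) for row in obs])
        post = abc_glm_posterior(ref_table, obs, retain_fraction, rng=rng)
        q = post.quantile_of(truth)
        c = post.covered(truth, level=0.9)
        truth_t = params_to_vector(truth)
        for j, n in enumerate(names):
            quantiles[n].append(q[n])
            cover[n].append(c[n])
            span = support[j, 1] - support[j, 0]
            bias[n].append((post.modes_transformed[n] - truth_t[j]) / span)
            edge = 0.005 * span
            if (post.modes_transformed[n] <= support[j, 0] + edge
                    or post.modes_transformed[n] >= support[j, 1] - edge):
                clamped[n] += 1
    report = {"model_kind": model_kind, "n_pods": n_pods, "parameters": {}}
    for n in names:
        ks = stats.kstest(quantiles[n], "uniform")
        report["parameters"][n] = {
            "quantiles": list(map(float, quantiles[n])),
            "ks_pvalue": float(ks.pvalue),
            "coverage_90": float(np.mean(cover[n])),
            "mean_relative_bias": float(np.mean(bias[n])),
            "n_modes_clamped": int(clamped[n]),
        }
    covs = [report["parameters"][n]["coverage_90"] for n in names]
    report["overall_coverage_90"] = float(np.mean(covs))
    report["min_ks_pvalue"] = float(min(report["parameters"][n]["ks_pvalue"] for n in names))
    return report
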