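"""Serial structured-coalescent simulation of microsatellite loci.

Two demographic models of the western gorilla system are supported, both with
serially sampled gene copies and stepwise-mutation microsatellites:

* **isolation with migration (IM)** — the Cross River population diverged from
  the western lowland population ``t_divergence`` generations ago and the two
  exchanged migrants (``2Nm`` scaled rate) until ``t_migration`` generations
  ago; a bottleneck starting ``t_bottleneck`` generations ago shrank Cross
  River exponentially from ``n_cr_now * ratio_old_now`` to ``n_cr_now``.
* **secondary admixture** — divergence in strict isolation, followed by a
  single pulse at a fraction ``t_admixture_frac`` of the divergence time in
  which a fraction ``gamma_admixture`` of the Cross River population was
  replaced by western immigrants.

Sizes are diploid effective sizes; haploid gene copies coalesce pairwise at
rate 1/(2N) per generation.  Alleles are repeat counts evolved under the
strict stepwise mutation model from a root size of 100; every downstream
summary is invariant under translation of the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Literal, Sequence

import numpy as np

from ._kernels import genealogy_kernel, mutate_kernel

__all__ = [
    "IMModelParams",
    "AdmixtureModelParams",
    "SampleGroup",
    "SamplingScheme",
    "default_study_scheme",
    "sample_prior",
    "prior_log_density",
    "simulate_locus",
    "simulate_dataset",
    "SimulatedLocus",
    "pairwise_tmrca",
    "PRIOR_SPECS",
    "ROOT_ALLELE_SIZE",
]

ROOT_ALLELE_SIZE = 100
_DEME_CODE = {"crossriver": 0, "western": 1}


@dataclass(frozen=True)
class IMModelParams:
    """Parameter vector of the isolation-with-migration model."""

    two_Nm: float
    n_cr_now: float
    ratio_old_now: float
    n_ancestral: float
    n_western: float
    t_divergence: float
    t_bottleneck: float
    t_migration: float
    mu: float

    def validate(self) -> None:
        if min(self.n_cr_now, self.n_ancestral, self.n_western) <= 0:
            raise ValueError("population sizes must be positive")
        if self.ratio_old_now < 1:
            raise ValueError("ratio_old_now must be >= 1")
        if self.t_migration > self.t_divergence:
            raise ValueError("t_migration must not exceed t_divergence")
        if self.t_bottleneck > self.t_divergence:
            raise ValueError("t_bottleneck must not exceed t_divergence")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass(frozen=True)
class AdmixtureModelParams:
    """Parameter vector of the divergence-with-secondary-admixture model."""

    n_cr_now: float
    ratio_old_now: float
    n_ancestral: float
    n_western: float
    t_divergence: float
    t_bottleneck: float
    t_admixture_frac: float
    gamma_admixture: float
    mu: float

    def validate(self) -> None:
        if min(self.n_cr_now, self.n_ancestral, self.n_western) <= 0:
            raise ValueError("population sizes must be positive")
        if self.ratio_old_now < 1:
            raise ValueError("ratio_old_now must be >= 1")
        if self.t_bottleneck > self.t_divergence:
            raise ValueError("t_bottleneck must not exceed t_divergence")
        if not (0 < self.t_admixture_frac < 1):
            raise ValueError("t_admixture_frac must be in (0, 1)")
        if not (0 < self.gamma_admixture < 1):
            raise ValueError("gamma_admixture must be in (0, 1)")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass(frozen=True)
class SampleGroup:
    deme: str
    n_haploid: int
    time_bp: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.deme not in _DEME_CODE:
            raise ValueError(f"unknown deme {self.deme!r}")
        if self.n_haploid < 1:
            raise ValueError("n_haploid must be >= 1")
        if self.time_bp < 0:
            raise ValueError("time_bp must be non-negative")


@dataclass(frozen=True)
class SamplingScheme:
    """Ordered sample groups: (deme, haploid size, time in generations BP)."""

    groups: tuple[SampleGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scheme must contain at least one sample group")

    @property
    def n_total(self) -> int:
        return sum(g.n_haploid for g in self.groups)

    def labels(self) -> list[str]:
        return [g.label or f"{g.deme}@{g.time_bp:g}" for g in self.groups]


def default_study_scheme(haploid: bool = True) -> SamplingScheme:
    """The study design: 14 historical Cross River gene copies at 5
    generations BP, 71 modern Cross River and 92 modern western at present.

    With ``haploid=False`` the sizes are doubled (two gene copies per
    individual), as used when building diploid genotype tables.
    """
    m = 1 if haploid else 2
    return SamplingScheme(
        groups=(
            SampleGroup("crossriver", 14 * m, 5.0, label="crossriver_historical"),
            SampleGroup("crossriver", 71 * m, 0.0, label="crossriver_modern"),
            SampleGroup("western", 92 * m, 0.0, label="western_modern"),
        )
    )


@dataclass
class SimulatedLocus:
    """Haploid allele repeat sizes per sample group from one realization."""

    groups: list[np.ndarray]
    labels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

#: prior specification per parameter: (kind, low, high[, mean, sd])
PRIOR_SPECS: dict[str, tuple] = {
    "two_Nm": ("loguniform", 1.0, 15.85),
    "ratio_old_now": ("loguniform", 1.0, 100.0),
    "n_cr_now": ("truncnormal", 68.0, 300.0, 200.0, 100.0),
    "n_ancestral": ("uniform", 500.0, 25000.0),
    "n_western": ("truncnormal", 10000.0, 30000.0, 24000.0, 5000.0),
    "t_divergence": ("loguniform", 10.0, 3162.0),
    "t_bottleneck": ("loguniform", 10.0, 316.0),
    "t_migration": ("loguniform", 10.0, 3162.0),
    "t_admixture_frac": ("uniform", 0.0, 1.0),
    "gamma_admixture": ("uniform", 0.0, 1.0),
    "mu": ("truncnormal", 0.0002, 0.0006, 0.0004, 0.0001),
}

_MODEL_FIELDS = {
    "im": [f.name for f in fields(IMModelParams)],
    "admixture": [f.name for f in fields(AdmixtureModelParams)],
}


def _draw_one(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "loguniform":
        return float(10 ** rng.uniform(np.log10(spec[1]), np.log10(spec[2])))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "truncnormal":
        lo, hi, mean, sd = spec[1:]
        for _ in range(10_000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        raise RuntimeError("truncated-normal rejection failed")
    raise ValueError(f"unknown prior kind {kind!r}")


def sample_prior(
    model_kind: Literal["im", "admixture"], rng: np.random.Generator
):
    """One draw from the joint prior of the chosen model.

    Draws violating the ordering constraints (t_migration <= t_divergence,
    t_bottleneck <= t_divergence) are rejected and redrawn.
    """
    if model_kind not in _MODEL_FIELDS:
        raise ValueError("model_kind must be 'im' or 'admixture'")
    cls = IMModelParams if model_kind == "im" else AdmixtureModelParams
    for _ in range(1_000_000):
        kwargs = {name: _draw_one(PRIOR_SPECS[name], rng) for name in _MODEL_FIELDS[model_kind]}
        params = cls(**kwargs)
        try:
            params.validate()
        except ValueError:
            continue
        return params
    raise RuntimeError("prior rejection loop failed to satisfy constraints")


def prior_log_density(params, transformed: bool = False) -> float:
    """Unnormalized log prior density of a parameter vector.

    With ``transformed=True`` the density is with respect to the ABC working
    scale (log10 for loguniform parameters, natural for the rest), under which
    loguniform priors are flat.  Returns ``-inf`` outside the support.
    """
    from scipy.stats import norm

    try:
        params.validate()
    except ValueError:
        return float("-inf")
    logp = 0.0
    for name in (f.name for f in fields(params)):
        v = getattr(params, name)
        spec = PRIOR_SPECS[name]
        kind = spec[0]
        if kind == "loguniform":
            lo, hi = spec[1], spec[2]
            if not (lo <= v <= hi):
                return float("-inf")
            if not transformed:
                logp -= np.log(v)
        elif kind == "uniform":
            if not (spec[1] <= v <= spec[2]):
                return float("-inf")
        else:
            lo, hi, mean, sd = spec[1:]
            if not (lo <= v <= hi):
                return float("-inf")
            logp += norm.logpdf(v, mean, sd)
    return float(logp)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _kernel_args(params, scheme: SamplingScheme, model_kind: str):
    order = np.argsort([g.time_bp for g in scheme.groups], kind="stable")
    times = np.array([scheme.groups[i].time_bp for i in order], dtype=np.float64)
    demes = np.array([_DEME_CODE[scheme.groups[i].deme] for i in order], dtype=np.int64)
    counts = np.array([scheme.groups[i].n_haploid for i in order], dtype=np.int64)
    if model_kind == "im":
        extra = (True, float(params.two_Nm), float(params.t_migration), 0.0, 0.0)
    else:
        t_adm = params.t_admixture_frac * params.t_divergence
        extra = (False, 0.0, 0.0, float(t_adm), float(params.gamma_admixture))
    args = (
        times, demes, counts,
        float(params.n_cr_now), float(params.ratio_old_now),
        float(params.t_bottleneck), float(params.n_western),
        float(params.n_ancestral), float(params.t_divergence),
    ) + extra
    return order, counts, args


def _split_leaves(values: np.ndarray, order, counts, scheme: SamplingScheme):
    bounds = np.concatenate([[0], np.cumsum(counts)])
    sorted_groups = [values[bounds[i]: bounds[i + 1]] for i in range(len(counts))]
    out: list[np.ndarray] = [None] * len(scheme.groups)  # type: ignore[list-item]
    for pos, orig in enumerate(order):
        out[orig] = sorted_groups[pos]
    return out


def simulate_locus(
    params,
    scheme: SamplingScheme,
    model_kind: Literal["im", "admixture"],
    rng: np.random.Generator,
    root_size: int = ROOT_ALLELE_SIZE,
) -> SimulatedLocus:
    """One coalescent realization of a microsatellite locus.

    Lineages enter the genealogy at their sampling times, coalesce pairwise at
    rate 1/(2N) in their deme, migrate according to the model, merge into the
    ancestral deme at the divergence time, and carry stepwise mutations at
    rate ``params.mu`` per generation.
    """
    params.validate()
    order, counts, args = _kernel_args(params, scheme, model_kind)
    seed_g = int(rng.integers(1, 2**31 - 1))
    seed_m = int(rng.integers(1, 2**31 - 1))
    parent, node_time = genealogy_kernel(seed_g, *args)
    alleles = mutate_kernel(seed_m, parent, node_time, float(params.mu), root_size)
    n = int(counts.sum())
    groups = _split_leaves(alleles[:n], order, counts, scheme)
    return SimulatedLocus(groups=groups, labels=scheme.labels())


def simulate_dataset(
    params,
    scheme: SamplingScheme,
    k_loci: int,
    rng: np.random.Generator,
    model_kind: Literal["im", "admixture"] = "im",
    root_size: int = ROOT_ALLELE_SIZE,
) -> list[SimulatedLocus]:
    """``k_loci`` independent loci under one shared parameter vector."""
    if k_loci < 1:
        raise ValueError("k_loci must be >= 1")
    return [
        simulate_locus(params, scheme, model_kind, rng, root_size=root_size)
        for _ in range(k_loci)
    ]


def pairwise_tmrca(
    params,
    scheme: SamplingScheme,
    model_kind: Literal["im", "admixture"],
    rng: np.random.Generator,
) -> float:
    """Time to the most recent common ancestor of one simulated genealogy.

    Mainly useful for checking the simulator's coalescent physics against
    analytic expectations or an independent engine.
    """
    params.validate()
    _, _, args = _kernel_args(params, scheme, model_kind)
    seed_g = int(rng.integers(1, 2**31 - 1))
    _, node_time = genealogy_kernel(seed_g, *args)
    return float(node_time[-1])
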