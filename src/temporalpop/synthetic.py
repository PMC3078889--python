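"""Study-shaped synthetic datasets.

The original study's genotype matrices are not deposited anywhere, so every
pipeline stage here is exercised on simulated data shaped like the study
design: 14 historical Cross River individuals sampled 5 generations before
present, 71 modern Cross River and 92 modern western lowland individuals, at
8 unlinked microsatellite loci.  Diploid genotypes are formed by pairing
consecutive haploid copies from the serial coalescent (random mating within
panmictic demes); missingness is uniform at random per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .coalescent import SampleGroup, SamplingScheme, simulate_dataset
from .genotype import GenotypeTable, SampleAnnotation, write_annotations, write_genepop
from .temporal_ne import TemporalPair

__all__ = ["StudyDesign", "generate_study_like_dataset", "generate_temporal_wf_dataset"]


@dataclass(frozen=True)
class DesignGroup:
    label: str
    deme: str
    n_individuals: int
    time_bp: int


@dataclass
class StudyDesign:
    """Sample-group layout and genotyping parameters of a synthetic dataset."""

    groups: tuple[DesignGroup, ...] = (
        DesignGroup("crossriver_historical", "crossriver", 14, 5),
        DesignGroup("crossriver_modern", "crossriver", 71, 0),
        DesignGroup("western_modern", "western", 92, 0),
    )
    k_loci: int = 8
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(g.n_individuals < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    def scheme(self) -> SamplingScheme:
        """Haploid sampling scheme with two gene copies per individual."""
        return SamplingScheme(
            groups=tuple(
                SampleGroup(g.deme, 2 * g.n_individuals, float(g.time_bp), label=g.label)
                for g in self.groups
            )
        )

    def annotations(self) -> list[SampleAnnotation]:
        return [SampleAnnotation(g.label, g.deme, g.time_bp) for g in self.groups]


def generate_study_like_dataset(
    params,
    design: StudyDesign | None = None,
    seed: int = 0,
    model_kind: Literal["im", "admixture"] = "im",
    out_prefix: Optional[str] = None,
):
    """Simulate a diploid genotype table under the chosen demographic model.

    Consecutive haploid copies of each individual are paired into a genotype;
    each genotype is independently set to missing with ``design.missing_rate``.
    Returns ``(table, annotations)``; with ``out_prefix`` the table is also
    written as ``<prefix>.gen`` (Genepop) plus ``<prefix>.annotations.txt``.
    Deterministic for a fixed seed.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    scheme = design.scheme()
    loci = simulate_dataset(params, scheme, design.k_loci, rng, model_kind)

    locus_names = [f"locus{j + 1}" for j in range(design.k_loci)]
    individuals: list[tuple[str, str]] = []
    calls: list[list[Optional[tuple[int, int]]]] = []
    for gi, g in enumerate(design.groups):
        for i in range(g.n_individuals):
            individuals.append((f"{g.label}_{i + 1:03d}", g.label))
            row: list[Optional[tuple[int, int]]] = []
            for loc in loci:
                if design.missing_rate > 0 and rng.random() < design.missing_rate:
                    row.append(None)
                    continue
                hap = loc.groups[gi]
                a, b = int(hap[2 * i]), int(hap[2 * i + 1])
                row.append((a, b))
            calls.append(row)
    table = GenotypeTable(locus_names=locus_names, individuals=individuals, calls=calls)
    annotations = design.annotations()
    if out_prefix is not None:
        write_genepop(table, f"{out_prefix}.gen", annotations)
        write_annotations(annotations, f"{out_prefix}.annotations.txt")
    return table, annotations


def generate_temporal_wf_dataset(
    ne: int,
    s0: int,
    st: int,
    t: int,
    k_loci: int = 8,
    n_alleles: int = 10,
    seed: int = 0,
) -> list[TemporalPair]:
    """Forward Wright-Fisher calibration data for the temporal Ne estimators.

    Per locus: initial frequencies are symmetric-Dirichlet over ``n_alleles``;
    ``s0`` gene copies are binomially sampled at generation 0; the population
    drifts for ``t`` generations by multinomial resampling of ``2 ne`` gene
    copies; ``st`` gene copies are sampled at the end.  Frequency vectors are
    reduced to the union of alleles observed in either sample.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(k_loci):
        p = rng.dirichlet(np.ones(n_alleles))
        x_cnt = rng.multinomial(s0, p)
        for _ in range(t):
            cnt = rng.multinomial(2 * ne, p)
            p = cnt / (2 * ne)
        y_cnt = rng.multinomial(st, p)
        seen = (x_cnt + y_cnt) > 0
        pairs.append(
            TemporalPair(
                x=x_cnt[seen] / s0, y=y_cnt[seen] / st, s0=s0, st=st
            )
        )
    return pairs
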