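"""Data model and I/O for temporally annotated diploid microsatellite genotypes.

Genotypes are stored as allele *repeat counts* (positive integers), not
fragment lengths.  Sampling times are attached per population sample through a
plain-text sidecar annotation, since the Genepop format itself has no notion
of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenotypeTable",
    "SampleAnnotation",
    "AlleleFrequencySpectrum",
    "read_genepop",
    "write_genepop",
    "read_annotations",
    "write_annotations",
    "allele_frequencies",
    "one_haplotype_per_individual",
    "repeats_to_fragment_lengths",
]

#: valid demes for this study design
DEMES = ("crossriver", "western")


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


class AnnotationError(ValueError):
    """Raised when sample annotations do not match the genotype file."""


@dataclass(frozen=True)
class SampleAnnotation:
    """One population sample: a label, a deme and a sampling time.

    ``time_bp`` is in generations before present; a modern sample has
    ``time_bp == 0``.
    """

    sample_label: str
    deme: str
    time_bp: int

    def __post_init__(self) -> None:
        if self.deme not in DEMES:
            raise AnnotationError(f"unknown deme {self.deme!r}; expected one of {DEMES}")
        if self.time_bp < 0:
            raise AnnotationError("time_bp must be a non-negative integer")


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls per individual x locus.

    ``calls[i][j]`` is an unordered pair ``(a, b)`` of positive integer repeat
    counts for individual ``i`` at locus ``j``, or ``None`` for a missing
    genotype.  Missingness is atomic: there are no half-called genotypes.

    ``individuals`` holds ``(individual_id, sample_label)`` pairs; the
    ``sample_label`` groups individuals into population samples that carry a
    :class:`SampleAnnotation`.
    """

    locus_names: list[str]
    individuals: list[tuple[str, str]]
    calls: list[list[Optional[tuple[int, int]]]]
    #: 2 for diploid genotype calls; 1 for a haploid view, where each call is
    #: a degenerate pair (a, a) counting as a single gene copy
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        k = len(self.locus_names)
        if len(self.calls) != len(self.individuals):
            raise ValueError("one row of calls per individual required")
        for (ind, _), row in zip(self.individuals, self.calls):
            if len(row) != k:
                raise ValueError(
                    f"individual {ind!r} has {len(row)} loci, expected {k}"
                )
            for g in row:
                if g is None:
                    continue
                a, b = g
                if a <= 0 or b <= 0:
                    raise ValueError(
                        f"alleles must be strictly positive integers, got {g} for {ind!r}"
                    )
        # canonicalize: unordered pairs stored sorted
        self.calls = [
            [None if g is None else (min(g), max(g)) for g in row] for row in self.calls
        ]

    # -- convenience -------------------------------------------------------

    @property
    def sample_labels(self) -> list[str]:
        """Unique sample labels in order of first appearance."""
        seen: dict[str, None] = {}
        for _, lab in self.individuals:
            seen.setdefault(lab, None)
        return list(seen)

    def subset(self, sample_label: str) -> "GenotypeTable":
        """Rows of one population sample, as a new table."""
        idx = [i for i, (_, lab) in enumerate(self.individuals) if lab == sample_label]
        if not idx:
            raise KeyError(f"no individuals with sample label {sample_label!r}")
        return GenotypeTable(
            locus_names=list(self.locus_names),
            individuals=[self.individuals[i] for i in idx],
            calls=[list(self.calls[i]) for i in idx],
            ploidy=self.ploidy,
        )

    def locus_genotypes(self, locus: str, sample_label: str | None = None):
        """Non-missing genotypes at one locus, optionally within one sample."""
        j = self.locus_names.index(locus)
        out = []
        for (_, lab), row in zip(self.individuals, self.calls):
            if sample_label is not None and lab != sample_label:
                continue
            if row[j] is not None:
                out.append(row[j])
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.locus_names == other.locus_names
            and self.individuals == other.individuals
            and self.calls == other.calls
            and self.ploidy == other.ploidy
        )


@dataclass
class AlleleFrequencySpectrum:
    """Per-locus allele relative frequencies with their gene-copy counts.

    ``spectra[locus]`` is ``(freqs, n)`` where ``freqs`` maps allele -> relative
    frequency and ``n`` is the number of non-missing gene copies it was
    computed from.  Loci with zero non-missing calls are absent from
    ``spectra`` (never represented as a zero-division).
    """

    spectra: dict[str, tuple[dict[int, float], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, (freqs, n) in self.spectra.items():
            if n <= 0:
                raise ValueError(f"locus {locus!r}: gene-copy count must be positive")
            tot = sum(freqs.values())
            if any(f < 0 for f in freqs.values()) or abs(tot - 1.0) > 1e-12:
                raise ValueError(f"locus {locus!r}: frequencies must sum to 1, got {tot}")


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

def _parse_allele_code(code: str, path: str, lineno: int) -> Optional[tuple[int, int]]:
    if len(code) == 4:
        w = 2
    elif len(code) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"{path}:{lineno}: genotype code {code!r} is neither 4 (2-digit) "
            f"nor 6 (3-digit) characters"
        )
    try:
        a, b = int(code[:w]), int(code[w:])
    except ValueError as exc:
        raise GenepopParseError(f"{path}:{lineno}: non-numeric genotype {code!r}") from exc
    if a == 0 or b == 0:
        # all-zero = missing; a half-zero code is treated as missing too
        # (missingness is atomic per genotype)
        return None
    return (a, b)


def read_annotations(path: str) -> list[SampleAnnotation]:
    """Read the sidecar annotation config: one ``label deme time_bp`` line per
    POP block, in file order.  Blank lines and ``#`` comments are ignored."""
    anns: list[SampleAnnotation] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise AnnotationError(
                    f"{path}: expected 'label deme time_bp', got {raw.strip()!r}"
                )
            anns.append(SampleAnnotation(parts[0], parts[1], int(parts[2])))
    labels = [a.sample_label for a in anns]
    if len(set(labels)) != len(labels):
        raise AnnotationError(f"{path}: duplicate sample labels")
    return anns


def write_annotations(annotations: Sequence[SampleAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.sample_label} {a.deme} {a.time_bp}\n")


def read_genepop(path: str, annotations: Sequence[SampleAnnotation]) -> GenotypeTable:
    """Read a Genepop file into a :class:`GenotypeTable`.

    Both the 2-digit and the 3-digit allele-code dialects are accepted; allele
    code 0 (``00``/``000``) marks a missing genotype.  Allele codes are
    interpreted directly as repeat counts.  ``annotations`` maps POP blocks,
    in file order, to population samples.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file")

    # title line, then locus names until the first POP line.  Locus names may
    # be one per line or comma-separated on one line.
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if not locus_names:
        raise GenepopParseError(f"{path}: no locus names before first POP block")

    individuals: list[tuple[str, str]] = []
    calls: list[list[Optional[tuple[int, int]]]] = []
    pop_index = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_index += 1
            if pop_index >= len(annotations):
                raise AnnotationError(
                    f"{path}: {pop_index + 1} POP blocks but only "
                    f"{len(annotations)} annotations supplied"
                )
            continue
        if pop_index < 0:
            raise GenepopParseError(f"{path}:{lineno + 1}: data line before first POP")
        if "," not in line:
            raise GenepopParseError(
                f"{path}:{lineno + 1}: expected 'id, genotypes...', got {line!r}"
            )
        ind_id, geno_part = line.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(locus_names):
            raise GenepopParseError(
                f"{path}:{lineno + 1}: {len(codes)} genotypes for "
                f"{len(locus_names)} loci"
            )
        row = [_parse_allele_code(c, path, lineno + 1) for c in codes]
        individuals.append((ind_id.strip(), annotations[pop_index].sample_label))
        calls.append(row)

    if pop_index + 1 != len(annotations) and not (pop_index == -1 and not annotations):
        if pop_index + 1 < len(annotations):
            raise AnnotationError(
                f"{path}: {pop_index + 1} POP blocks but {len(annotations)} annotations"
            )
    return GenotypeTable(locus_names=locus_names, individuals=individuals, calls=calls)


def write_genepop(
    table: GenotypeTable,
    path: str,
    annotations: Sequence[SampleAnnotation],
    title: str = "temporalpop export",
) -> None:
    """Write a Genepop file in the 3-digit dialect (missing = ``000000``).

    One POP block is emitted per annotation, in annotation order; output is
    byte-stable for identical inputs.
    """
    for row in table.calls:
        for g in row:
            if g is not None and max(g) > 999:
                raise ValueError(
                    f"allele {max(g)} cannot be encoded in the 3-digit dialect"
                )
    by_label: dict[str, list[int]] = {}
    for i, (_, lab) in enumerate(table.individuals):
        by_label.setdefault(lab, []).append(i)
    table_labels = set(by_label)
    ann_labels = {a.sample_label for a in annotations}
    if table_labels - ann_labels:
        raise AnnotationError(
            f"samples {sorted(table_labels - ann_labels)} have no annotation"
        )

    out = [title]
    out.extend(table.locus_names)
    for ann in annotations:
        idx = by_label.get(ann.sample_label)
        if idx is None:
            continue
        out.append("POP")
        for i in idx:
            codes = []
            for g in table.calls[i]:
                if g is None:
                    codes.append("000000")
                else:
                    codes.append(f"{g[0]:03d}{g[1]:03d}")
            out.append(f"{table.individuals[i][0]}, " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Summaries and views
# ---------------------------------------------------------------------------

def allele_frequencies(table: GenotypeTable, sample_label: str) -> AlleleFrequencySpectrum:
    """Allele relative frequencies per locus within one population sample.

    ``n`` is twice the number of non-missing individuals (diploid data).
    Loci where every individual is missing are omitted from the spectrum.
    """
    sub = table.subset(sample_label)
    spectra: dict[str, tuple[dict[int, float], int]] = {}
    for j, locus in enumerate(sub.locus_names):
        counts: dict[int, int] = {}
        n = 0
        for row in sub.calls:
            g = row[j]
            if g is None:
                continue
            if sub.ploidy == 2:
                counts[g[0]] = counts.get(g[0], 0) + 1
                counts[g[1]] = counts.get(g[1], 0) + 1
                n += 2
            else:
                counts[g[0]] = counts.get(g[0], 0) + 1
                n += 1
        if n == 0:
            continue
        spectra[locus] = ({a: c / n for a, c in counts.items()}, n)
    return AlleleFrequencySpectrum(spectra)


def one_haplotype_per_individual(table: GenotypeTable, seed: int) -> GenotypeTable:
    """Keep exactly one allele per individual per locus, chosen uniformly.

    Returns a table whose genotypes are homozygous pairs ``(a, a)`` so the
    haploid view flows through the same machinery; downstream consumers should
    count each individual as a single gene copy.  Missing stays missing.
    Deterministic for a fixed seed.
    """
    if table.ploidy != 2:
        raise ValueError("input table must be diploid")
    rng = np.random.default_rng(seed)
    new_calls: list[list[Optional[tuple[int, int]]]] = []
    for row in table.calls:
        new_row: list[Optional[tuple[int, int]]] = []
        for g in row:
            if g is None:
                new_row.append(None)
            else:
                a = g[0] if rng.random() < 0.5 else g[1]
                new_row.append((a, a))
        new_calls.append(new_row)
    return GenotypeTable(
        locus_names=list(table.locus_names),
        individuals=list(table.individuals),
        calls=new_calls,
        ploidy=1,
    )


def haploid_alleles(table: GenotypeTable, sample_label: str, locus: str) -> np.ndarray:
    """One allele per individual at a locus (for tables produced by
    :func:`one_haplotype_per_individual`, or any table where the first allele
    is the haploid call)."""
    return np.array([g[0] for g in table.locus_genotypes(locus, sample_label)], dtype=float)


def repeats_to_fragment_lengths(
    repeats: np.ndarray, motif_length: int, flank_length: int = 0
) -> np.ndarray:
    """Convert repeat counts to PCR fragment lengths in base pairs.

    Provided for interoperating with datasets coded as fragment sizes; it is
    never applied implicitly anywhere in this package.
    """
    return np.asarray(repeats) * motif_length + flank_length
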