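"""Probability model for hybrid formation and independent coincidence of
multilocus genotypes.

A hybrid clone's genotype arises from the random union of one paternal
and one maternal gamete.  Given paternal allele frequencies ``p`` and
maternal frequencies ``q``:

* heterozygous locus with alleles i, j:  ``p_i * q_j + p_j * q_i``
* homozygous locus with allele i:
  - ``random_union`` mode:  ``p_i * q_i``
  - ``conversion`` mode:    ``(p_i + q_i) / 2`` — the locus was
    heterozygous at formation and later lost one allele at random, so
    only one parent needs to have carried the observed allele.  This is
    the conservative (larger) value: ``(p+q)/2 >= p*q`` always.

The formation probability of a multilocus genotype is the product of
per-locus factors; the coincidence probability across two or three
putatively independent origins is the product of the per-origin
formation probabilities (plain squaring/cubing when the parental pairs
coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

from msatclone.genotype_io import AllelePair, FrequencyTable

__all__ = [
    "ParentalPair",
    "MultilocusGenotype",
    "FormationResult",
    "CoincidenceResult",
    "hybrid_formation_prob",
    "enumerate_formation_prob",
    "coincidence_prob",
    "theoretical_curves",
    "triploid_balanced_gamete_prob",
]

HomMode = Literal["conversion", "random_union"]


@dataclass(frozen=True)
class ParentalPair:
    """Paternal and maternal allele-frequency tables for one origin."""

    paternal: FrequencyTable
    maternal: FrequencyTable

    def check_loci(self, loci: Sequence[str]) -> None:
        for table, role in ((self.paternal, "paternal"), (self.maternal, "maternal")):
            missing = [l for l in loci if l not in table.freqs]
            if missing:
                raise KeyError(
                    f"{role} table {table.group!r} lacks frequencies for loci {missing}"
                )


@dataclass
class MultilocusGenotype:
    """Complete unphased diploid genotype over a chosen locus subset."""

    calls: dict[str, AllelePair]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError("genotype needs >= 1 locus")
        for locus, pair in self.calls.items():
            if pair.is_missing:
                raise ValueError(f"genotype has MISSING call at {locus}")

    @property
    def n(self) -> int:
        return len(self.calls)

    @property
    def loci(self) -> list[str]:
        return list(self.calls)


@dataclass
class FormationResult:
    prob: float
    per_locus: dict[str, float]
    zero_frequency_alleles: list[tuple[str, str, int]] = field(default_factory=list)
    hom_mode: HomMode = "conversion"


@dataclass
class CoincidenceResult:
    formation_prob_per_species: list[float]
    per_locus_factors: list[dict[str, float]]
    coincidence_prob: float
    zero_frequency_alleles: list[tuple[str, str, int]] = field(default_factory=list)
    hom_mode: HomMode = "conversion"


def _locus_factor(
    pair: AllelePair,
    locus: str,
    parents: ParentalPair,
    hom_mode: HomMode,
    zero_flags: list[tuple[str, str, int]],
) -> float:
    i, j = pair.alleles()
    p = parents.paternal.frequency
    q = parents.maternal.frequency
    for tbl, role in ((parents.paternal, "paternal"), (parents.maternal, "maternal")):
        for a in {i, j}:
            if tbl.frequency(locus, a) == 0.0:
                zero_flags.append((role + ":" + tbl.group, locus, a))
    if pair.is_heterozygous:
        return p(locus, i) * q(locus, j) + p(locus, j) * q(locus, i)
    if hom_mode == "conversion":
        return 0.5 * (p(locus, i) + q(locus, i))
    if hom_mode == "random_union":
        return p(locus, i) * q(locus, i)
    raise ValueError(f"unknown hom_mode {hom_mode!r}")


def hybrid_formation_prob(
    genotype: MultilocusGenotype,
    parents: ParentalPair,
    hom_mode: HomMode = "conversion",
) -> FormationResult:
    """Probability that a single hybridization produces ``genotype``.

    Loci absent from either frequency table raise ``KeyError``; alleles
    present in the table's loci but at zero frequency yield a zero
    factor with a machine-readable flag instead of an exception.
    """
    parents.check_loci(genotype.loci)
    zero_flags: list[tuple[str, str, int]] = []
    per_locus: dict[str, float] = {}
    prob = 1.0
    for locus, pair in genotype.calls.items():
        f = _locus_factor(pair, locus, parents, hom_mode, zero_flags)
        per_locus[locus] = f
        prob *= f
    # flags only matter if they zeroed a needed term; keep het-irrelevant
    # ones out (a het factor can survive one zero-frequency side)
    relevant = [z for z in zero_flags if per_locus[z[1]] == 0.0]
    return FormationResult(prob, per_locus, relevant, hom_mode)


def enumerate_formation_prob(
    genotype: MultilocusGenotype, parents: ParentalPair
) -> float:
    """Brute-force formation probability over all 2**n phase assignments.

    Independent oracle for the factorized computation: for every
    assignment of which allele at each locus came from the paternal
    gamete, multiply ``p(paternal) * q(maternal)`` across loci and sum.
    Heterozygous genotypes only (the assignment is degenerate for
    homozygous loci); n <= 20.
    """
    parents.check_loci(genotype.loci)
    pairs = list(genotype.calls.items())
    if len(pairs) > 20:
        raise ValueError("enumeration limited to n <= 20 loci")
    for locus, pair in pairs:
        if pair.is_homozygous:
            raise ValueError(f"enumeration oracle is het-only; {locus} is homozygous")
    p = parents.paternal.frequency
    q = parents.maternal.frequency
    total = 0.0
    for phases in product((0, 1), repeat=len(pairs)):
        term = 1.0
        for (locus, pair), phase in zip(pairs, phases):
            alleles = pair.alleles()
            pat, mat = alleles[phase], alleles[1 - phase]
            term *= p(locus, pat) * q(locus, mat)
        total += term
    return total


def coincidence_prob(
    genotype: MultilocusGenotype,
    parental_pairs: Sequence[ParentalPair],
    hom_mode: HomMode = "conversion",
) -> CoincidenceResult:
    """Probability of independent coincidence across 2-3 origins.

    One :class:`ParentalPair` per putative independent origin; passing
    the same pair twice (or thrice) reduces to squaring (cubing) the
    single-origin formation probability.
    """
    if not (2 <= len(parental_pairs) <= 3):
        raise ValueError("coincidence requires 2 or 3 parental pairs")
    formations = [
        hybrid_formation_prob(genotype, pp, hom_mode) for pp in parental_pairs
    ]
    prob = 1.0
    zero_flags: list[tuple[str, str, int]] = []
    for f in formations:
        prob *= f.prob
        zero_flags.extend(f.zero_frequency_alleles)
    return CoincidenceResult(
        formation_prob_per_species=[f.prob for f in formations],
        per_locus_factors=[f.per_locus for f in formations],
        coincidence_prob=prob,
        zero_frequency_alleles=zero_flags,
        hom_mode=hom_mode,
    )


def theoretical_curves(
    scenario: Literal["a", "b", "c", "d"],
    n_max: int,
    freq: float = 0.5,
) -> list[float]:
    """Theoretical coincidence-probability curves vs number of loci.

    Each locus carries a heterozygote's two alleles at frequencies
    ``freq`` and ``1 - freq`` (identical in both parental populations;
    the reference setting is ``freq = 1/2``), or a homozygote's single
    allele at ``freq``.  Scenarios:

    * ``a`` — two unisexual populations, independent hybrid origins:
      per-locus het formation factor ``2 * freq * (1 - freq)``, raised
      to n, squared.
    * ``b`` — parthenogen vs bisexual population, all-heterozygous
      genotype: formation probability times the Hardy-Weinberg
      heterozygote frequency ``2 * freq * (1 - freq)`` per locus.
    * ``c`` — parthenogen vs bisexual, all-homozygous genotype:
      conversion-mode formation probability (factor ``freq``) times the
      HW homozygote frequency ``freq**2`` per locus.
    * ``d`` — two parthenogens via allelic conversion (homozygous
      genotypes only): conversion factor ``freq`` to the n, squared.

    Returns the probability for n = 1..n_max.
    """
    if not (0.0 < freq < 1.0):
        raise ValueError("freq must be in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    het = 2.0 * freq * (1.0 - freq)  # het formation factor, alleles f / 1-f
    conv = freq                      # conversion-mode hom factor (f+f)/2
    out = []
    for n in range(1, n_max + 1):
        if scenario == "a":
            v = (het**n) ** 2
        elif scenario == "b":
            v = het**n * (2.0 * freq * (1.0 - freq)) ** n
        elif scenario == "c":
            v = conv**n * (freq * freq) ** n
        elif scenario == "d":
            v = (conv**n) ** 2
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        out.append(v)
    return out


def triploid_balanced_gamete_prob(x: int) -> tuple[float, int]:
    """Probability that triploid meiosis sends all univalents to one pole.

    For a haploid chromosome number ``x`` the probability is
    ``0.5**(x-1)``; the second return value is the exact reciprocal
    ``2**(x-1)`` (expected gametes per balanced gamete).
    """
    if not isinstance(x, int) or isinstance(x, bool) or x < 1:
        raise ValueError("x must be an integer >= 1")
    return 0.5 ** (x - 1), 2 ** (x - 1)
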