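"""Forward simulator of hybrid clonal microsatellite evolution.

Pipeline building blocks: draw bisexual parental populations in
Hardy-Weinberg proportions, form an F1 hybrid founder clone, propagate
it clonally with stepwise mutation (single repeat-unit steps) and
allelic conversion (whole-locus loss of heterozygosity), optionally
backcross with a donor population, and sample a GenotypeDataset with a
missing-call mask.  Every stochastic event is logged in a
SimulationTruth record whose replay reproduces the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from msatclone.genotype_io import (
    AllelePair,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
)

__all__ = [
    "FounderGenotype",
    "SimulationTruth",
    "simulate_parental_population",
    "form_hybrid",
    "evolve_clonal_lineage",
    "backcross",
    "sample_dataset",
    "simulate_two_species_scenario",
]

FreqSpec = Mapping[str, Mapping[int, float]]


@dataclass
class FounderGenotype:
    """A hybrid founder clone; per locus (paternal_allele, maternal_allele)."""

    calls: dict[str, tuple[int, int]]
    maternal_parent: str = ""
    paternal_parent: str = ""

    def to_pairs(self) -> dict[str, AllelePair]:
        return {l: AllelePair(a, b) for l, (a, b) in self.calls.items()}


@dataclass
class SimulationTruth:
    """Ground truth for a simulated scenario.

    ``events`` holds tuples ``(lineage, generation, locus, kind, detail)``
    with kind in {"mutation", "conversion", "backcross"}.  ``origin_map``
    records which groups descend from which founder.
    """

    founders: dict[str, FounderGenotype] = field(default_factory=dict)
    events: list[tuple] = field(default_factory=list)
    origin_map: dict[str, str] = field(default_factory=dict)
    missing_mask: list[tuple[str, str]] = field(default_factory=list)


def _check_freq_spec(freq_spec: FreqSpec) -> None:
    for locus, fmap in freq_spec.items():
        s = sum(fmap.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"locus {locus}: frequencies sum to {s}")


def _draw_allele(fmap: Mapping[int, float], rng: np.random.Generator) -> int:
    alleles = sorted(fmap)
    probs = np.array([fmap[a] for a in alleles], dtype=float)
    probs /= probs.sum()
    return int(alleles[rng.choice(len(alleles), p=probs)])


def simulate_parental_population(
    freq_spec: FreqSpec,
    n: int,
    rng: np.random.Generator,
    species: str = "parental",
    population: str | None = None,
    id_prefix: str | None = None,
) -> list[IndividualRecord]:
    """Draw ``n`` diploid individuals in HWE from per-locus frequencies."""
    _check_freq_spec(freq_spec)
    prefix = id_prefix or species
    out = []
    for k in range(n):
        calls = {
            locus: AllelePair(_draw_allele(fmap, rng), _draw_allele(fmap, rng))
            for locus, fmap in freq_spec.items()
        }
        out.append(
            IndividualRecord(f"{prefix}_{k + 1}", species, population or species, calls)
        )
    return out


def form_hybrid(
    maternal_group: Sequence[IndividualRecord],
    paternal_group: Sequence[IndividualRecord],
    rng: np.random.Generator,
    truth: SimulationTruth | None = None,
    name: str = "founder",
) -> FounderGenotype:
    """One random gamete from a random individual of each group -> F1 clone."""
    mother = maternal_group[rng.integers(len(maternal_group))]
    father = paternal_group[rng.integers(len(paternal_group))]
    loci = [l for l in mother.calls if l in father.calls]
    calls = {}
    for locus in loci:
        mp = mother.calls[locus]
        fp = father.calls[locus]
        if mp.is_missing or fp.is_missing:
            raise ValueError(f"parental individuals unscored at {locus}")
        mat = mp.alleles()[rng.integers(2)]
        pat = fp.alleles()[rng.integers(2)]
        calls[locus] = (pat, mat)
    founder = FounderGenotype(calls, mother.species, father.species)
    if truth is not None:
        truth.founders[name] = founder
    return founder


def evolve_clonal_lineage(
    founder: FounderGenotype,
    G: int,
    mu: float,
    c: float,
    rng: np.random.Generator,
    loci: Sequence[LocusDef] | None = None,
    truth: SimulationTruth | None = None,
    lineage: str = "lineage",
) -> FounderGenotype:
    """Propagate a clone for ``G`` generations of mutation and conversion.

    Each generation, independently per locus: with probability ``mu``
    one allele (random choice) steps one repeat unit up or down (bp
    step = the locus motif length, default 1); with probability ``c``
    the locus becomes homozygous for one of its current alleles
    (a no-op when already homozygous, but still logged).
    """
    if not (0.0 <= mu <= 1.0 and 0.0 <= c <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if G < 0:
        raise ValueError("G must be >= 0")
    step = {l: 1 for l in founder.calls}
    if loci is not None:
        for ld in loci:
            step[ld.name] = ld.motif_length
    calls = dict(founder.calls)
    for gen in range(1, G + 1):
        for locus in calls:
            if mu > 0 and rng.random() < mu:
                which = int(rng.integers(2))
                direction = 1 if rng.random() < 0.5 else -1
                a = list(calls[locus])
                a[which] += direction * step[locus]
                calls[locus] = (a[0], a[1])
                if truth is not None:
                    truth.events.append(
                        (lineage, gen, locus, "mutation", (which, direction))
                    )
            if c > 0 and rng.random() < c:
                keep = int(rng.integers(2))
                kept = calls[locus][keep]
                calls[locus] = (kept, kept)
                if truth is not None:
                    truth.events.append((lineage, gen, locus, "conversion", keep))
    return FounderGenotype(calls, founder.maternal_parent, founder.paternal_parent)


def replay_lineage(
    founder: FounderGenotype, events: Sequence[tuple], lineage: str,
    loci: Sequence[LocusDef] | None = None,
) -> FounderGenotype:
    """Re-apply a logged event sequence; must reproduce the simulator output."""
    step = {l: 1 for l in founder.calls}
    if loci is not None:
        for ld in loci:
            step[ld.name] = ld.motif_length
    calls = dict(founder.calls)
    for ev in events:
        lin, _gen, locus, kind, detail = ev
        if lin != lineage:
            continue
        if kind == "mutation":
            which, direction = detail
            a = list(calls[locus])
            a[which] += direction * step[locus]
            calls[locus] = (a[0], a[1])
        elif kind == "conversion":
            kept = calls[locus][detail]
            calls[locus] = (kept, kept)
        elif kind == "backcross":
            which, allele = detail
            a = list(calls[locus])
            a[which] = allele
            calls[locus] = (a[0], a[1])
    return FounderGenotype(calls, founder.maternal_parent, founder.paternal_parent)


def backcross(
    lineage_genotype: FounderGenotype,
    donor_group: Sequence[IndividualRecord],
    replace_prob: float,
    rng: np.random.Generator,
    truth: SimulationTruth | None = None,
    lineage: str = "backcrossed",
) -> FounderGenotype:
    """Replace the paternal allele with a random donor gamete per locus.

    Each locus is hit independently with probability ``replace_prob``;
    the replaced copy is the paternal-in-origin one (slot 0).
    """
    if not (0.0 <= replace_prob <= 1.0):
        raise ValueError("replace_prob must be in [0, 1]")
    donor = donor_group[rng.integers(len(donor_group))]
    calls = dict(lineage_genotype.calls)
    for locus in calls:
        if rng.random() < replace_prob:
            dp = donor.calls.get(locus)
            if dp is None or dp.is_missing:
                continue
            allele = dp.alleles()[rng.integers(2)]
            calls[locus] = (allele, calls[locus][1])
            if truth is not None:
                truth.events.append((lineage, 0, locus, "backcross", (0, allele)))
    return FounderGenotype(
        calls, lineage_genotype.maternal_parent, donor.species
    )


def sample_dataset(
    groups: Mapping[str, Sequence[IndividualRecord]],
    loci: Sequence[LocusDef],
    missing_rate: float,
    rng: np.random.Generator,
    truth: SimulationTruth | None = None,
    max_missing: int | None = None,
) -> GenotypeDataset:
    """Assemble groups into a dataset, masking calls MISSING at random.

    ``max_missing`` defaults to unbounded because a random mask can
    exceed a per-individual cap; pass a value to enforce one.
    """
    individuals = []
    for group in groups.values():
        for ind in group:
            calls = {}
            for locus in (l.name for l in loci):
                p = ind.calls.get(locus, AllelePair.missing())
                if not p.is_missing and missing_rate > 0 and rng.random() < missing_rate:
                    calls[locus] = AllelePair.missing()
                    if truth is not None:
                        truth.missing_mask.append((ind.id, locus))
                else:
                    calls[locus] = p
            individuals.append(IndividualRecord(ind.id, ind.species, ind.population, calls))
    return GenotypeDataset(list(loci), individuals, max_missing=max_missing)


def clone_group(
    founder: FounderGenotype,
    n: int,
    G: int,
    mu: float,
    c: float,
    rng: np.random.Generator,
    species: str,
    loci: Sequence[LocusDef] | None = None,
    truth: SimulationTruth | None = None,
) -> list[IndividualRecord]:
    """Sample ``n`` clones, each an independent lineage from the founder."""
    out = []
    for k in range(n):
        lineage = f"{species}_{k + 1}"
        g = evolve_clonal_lineage(founder, G, mu, c, rng, loci, truth, lineage)
        out.append(IndividualRecord(lineage, species, species, g.to_pairs()))
        if truth is not None:
            truth.origin_map[lineage] = species
    return out


def simulate_two_species_scenario(
    parental_freqs: Mapping[str, FreqSpec],
    maternal: str,
    paternal: str,
    loci: Sequence[LocusDef],
    n_parental: int = 30,
    n_clonal: int = 20,
    G: int = 50,
    mu: float = 0.005,
    c: float = 0.0,
    single_origin: bool = True,
    backcross_prob: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Two parthenogenetic species plus their bisexual parents.

    ``single_origin=True`` founds both parthenogens from one F1 clone
    (the second optionally backcrossed with the paternal donor at
    ``backcross_prob`` per locus); ``single_origin=False`` draws two
    independent F1 founders.  Returns the sampled dataset and truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = SimulationTruth()
    mat_group = simulate_parental_population(
        parental_freqs[maternal], n_parental, rng, species=maternal
    )
    pat_group = simulate_parental_population(
        parental_freqs[paternal], n_parental, rng, species=paternal
    )
    f1 = form_hybrid(mat_group, pat_group, rng, truth, name="founder1")
    if single_origin:
        f2 = f1
        if backcross_prob > 0:
            f2 = backcross(f1, pat_group, backcross_prob, rng, truth, "founder2")
        truth.founders["founder2"] = f2
        truth.origin_map["parth_B"] = "founder1"
    else:
        f2 = form_hybrid(mat_group, pat_group, rng, truth, name="founder2")
    groups = {
        maternal: mat_group,
        paternal: pat_group,
        "parth_A": clone_group(f1, n_clonal, G, mu, c, rng, "parth_A", loci, truth),
        "parth_B": clone_group(f2, n_clonal, G, mu, c, rng, "parth_B", loci, truth),
    }
    ds = sample_dataset(groups, loci, missing_rate, rng, truth)
    return ds, truth
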