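"""Shared alleles and shared diploid genotypes between groups.

Allele-level sharing gives partial credit (multiset intersection of the
two allele pairs at a locus, divided by 2).  Genotype-level statistics
require exact equality of the unordered diploid genotype at every locus
considered — no partial credit.  Group means average over all
cross-group individual pairs, excluding pairs with no commonly scored
locus (exclusion, not zero-fill, is the documented policy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from msatclone.genotype_io import (
    AllelePair,
    GenotypeDataset,
    IndividualRecord,
)

__all__ = [
    "SharedGenotypeReport",
    "prop_shared_alleles",
    "prop_shared_alleles_group",
    "shared_klocus_genotype_proportion",
    "max_shared_loci",
    "find_shared_multilocus_genotypes",
    "write_shared_reports",
]


@dataclass
class SharedGenotypeReport:
    """A complete diploid genotype on a locus subset shared between groups."""

    species_set: tuple[str, ...]
    loci: tuple[str, ...]
    genotype: dict[str, AllelePair]
    freq_per_species: dict[str, float]
    carriers_per_species: dict[str, int]
    scored_per_species: dict[str, int]
    zygosity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, pair in self.genotype.items():
            if pair.is_missing:
                raise ValueError(f"shared genotype has MISSING call at {locus}")
            self.zygosity.setdefault(locus, "het" if pair.is_heterozygous else "hom")
        for sp, f in self.freq_per_species.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{sp}: carrier frequency {f} outside (0, 1]")

    def genotype_string(self) -> str:
        return ";".join(
            f"{l}={self.genotype[l].a1}/{self.genotype[l].a2}" for l in self.loci
        )


# ---------------------------------------------------------------------------
# shared alleles


def _locus_shared_fraction(pa: AllelePair, pb: AllelePair) -> float:
    """|multiset intersection of the two allele pairs| / 2."""
    a = list(pa.alleles())
    b = list(pb.alleles())
    shared = 0
    for x in a:
        if x in b:
            b.remove(x)
            shared += 1
    return shared / 2.0


def prop_shared_alleles(ind_a: IndividualRecord, ind_b: IndividualRecord) -> float:
    """Mean per-locus shared-allele fraction over commonly scored loci.

    NaN when the pair has no commonly scored locus.
    """
    fracs = []
    for locus, pa in ind_a.calls.items():
        pb = ind_b.calls.get(locus)
        if pb is None or pa.is_missing or pb.is_missing:
            continue
        fracs.append(_locus_shared_fraction(pa, pb))
    if not fracs:
        return float("nan")
    return sum(fracs) / len(fracs)


def prop_shared_alleles_group(
    dataset: GenotypeDataset,
    group_a: str,
    group_b: str,
    group_by: str = "species",
) -> float:
    """Mean of :func:`prop_shared_alleles` over all cross-group pairs."""
    inds_a = dataset.subset(group_a, by=group_by)
    inds_b = dataset.subset(group_b, by=group_by)
    vals = []
    for ia in inds_a:
        for ib in inds_b:
            v = prop_shared_alleles(ia, ib)
            if v == v:
                vals.append(v)
    if not vals:
        raise ValueError(f"no comparable pairs between {group_a!r} and {group_b!r}")
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# shared k-locus genotypes


def shared_klocus_genotype_proportion(
    dataset: GenotypeDataset,
    group_a: str,
    group_b: str,
    k: int = 1,
    group_by: str = "species",
) -> float:
    """Proportion of shared k-locus diploid genotypes between two groups.

    Every k-subset of loci is treated as one synthetic haploid marker
    whose allele is the complete unordered diploid genotype on that
    subset; an individual missing any subset locus is unscored there.
    For each cross-group pair the shared fraction (1 if identical, else
    0 per subset) is averaged over subsets scored in both, then over
    pairs; pairs with no scored subset are excluded.
    """
    loci = dataset.locus_names
    if not (1 <= k <= len(loci)):
        raise ValueError(f"k={k} out of range 1..{len(loci)}")
    subsets = list(combinations(loci, k))
    inds_a = dataset.subset(group_a, by=group_by)
    inds_b = dataset.subset(group_b, by=group_by)

    def profile(ind: IndividualRecord) -> list[tuple | None]:
        out: list[tuple | None] = []
        for sub in subsets:
            pairs = [ind.calls.get(l) for l in sub]
            if any(p is None or p.is_missing for p in pairs):
                out.append(None)
            else:
                out.append(tuple((p.a1, p.a2) for p in pairs))  # type: ignore[union-attr]
        return out

    prof_a = [profile(i) for i in inds_a]
    prof_b = [profile(i) for i in inds_b]
    pair_means = []
    for pa in prof_a:
        for pb in prof_b:
            scored = matched = 0
            for ga, gb in zip(pa, pb):
                if ga is None or gb is None:
                    continue
                scored += 1
                if ga == gb:
                    matched += 1
            if scored:
                pair_means.append(matched / scored)
    if not pair_means:
        raise ValueError(
            f"no scorable {k}-locus subsets between {group_a!r} and {group_b!r}"
        )
    return sum(pair_means) / len(pair_means)


# ---------------------------------------------------------------------------
# maximum shared loci


def count_shared_loci(ind_a: IndividualRecord, ind_b: IndividualRecord) -> int:
    """Number of loci with identical complete diploid genotypes."""
    shared = 0
    for locus, pa in ind_a.calls.items():
        pb = ind_b.calls.get(locus)
        if pb is None or pa.is_missing or pb.is_missing:
            continue
        if pa == pb:
            shared += 1
    return shared


def max_shared_loci(
    dataset: GenotypeDataset,
    group_a: str,
    group_b: str,
    group_by: str = "species",
) -> tuple[int, dict[str, int]]:
    """Maximum shared-locus count between two groups.

    Returns the overall maximum over cross-group pairs and, per
    individual, the maximum over its partners in the other group.
    """
    inds_a = dataset.subset(group_a, by=group_by)
    inds_b = dataset.subset(group_b, by=group_by)
    per_ind: dict[str, int] = {i.id: 0 for i in inds_a + inds_b}
    overall = 0
    for ia in inds_a:
        for ib in inds_b:
            s = count_shared_loci(ia, ib)
            per_ind[ia.id] = max(per_ind[ia.id], s)
            per_ind[ib.id] = max(per_ind[ib.id], s)
            overall = max(overall, s)
    return overall, per_ind


# ---------------------------------------------------------------------------
# discovery of cross-group shared multilocus genotypes


def find_shared_multilocus_genotypes(
    dataset: GenotypeDataset,
    groups: Sequence[str] | None = None,
    min_freq: float = 0.05,
    max_loci: int = 6,
    group_by: str = "species",
) -> list[SharedGenotypeReport]:
    """Enumerate maximal locus subsets carrying a genotype shared between groups.

    For every locus subset of size 1..``max_loci``, a complete diploid
    genotype is reported when >= 2 of the requested groups each carry it
    at frequency >= ``min_freq`` (denominator: individuals scored at all
    subset loci).  Only maximal reports survive: a report is dropped if
    another report over a locus superset, with the same species set,
    restricts to the same genotype.  Sorted by (species count, locus
    count, combined frequency), all descending.
    """
    if groups is None:
        groups = dataset.groups(group_by)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    loci = dataset.locus_names
    by_group = {g: dataset.subset(g, by=group_by) for g in groups}

    raw: list[SharedGenotypeReport] = []
    for k in range(1, min(max_loci, len(loci)) + 1):
        for sub in combinations(loci, k):
            # genotype -> group -> carrier count; plus per-group scored counts
            counts: dict[tuple, dict[str, int]] = {}
            scored: dict[str, int] = {}
            for g, inds in by_group.items():
                n_scored = 0
                for ind in inds:
                    pairs = [ind.calls.get(l) for l in sub]
                    if any(p is None or p.is_missing for p in pairs):
                        continue
                    n_scored += 1
                    key = tuple((p.a1, p.a2) for p in pairs)  # type: ignore[union-attr]
                    counts.setdefault(key, {}).setdefault(g, 0)
                    counts[key][g] += 1
                scored[g] = n_scored
            for key, per_group in counts.items():
                qual = {
                    g: c
                    for g, c in per_group.items()
                    if scored[g] and c / scored[g] >= min_freq
                }
                if len(qual) < 2:
                    continue
                species = tuple(sorted(qual))
                raw.append(
                    SharedGenotypeReport(
                        species_set=species,
                        loci=sub,
                        genotype={
                            l: AllelePair(*alleles) for l, alleles in zip(sub, key)
                        },
                        freq_per_species={g: qual[g] / scored[g] for g in species},
                        carriers_per_species={g: qual[g] for g in species},
                        scored_per_species={g: scored[g] for g in species},
                    )
                )

    # maximality filter
    maximal: list[SharedGenotypeReport] = []
    for r in raw:
        dominated = False
        for other in raw:
            if other is r or other.species_set != r.species_set:
                continue
            if set(r.loci) < set(other.loci) and all(
                other.genotype[l] == r.genotype[l] for l in r.loci
            ):
                dominated = True
                break
        if not dominated:
            maximal.append(r)

    maximal.sort(
        key=lambda r: (
            -len(r.species_set),
            -len(r.loci),
            -sum(r.freq_per_species.values()),
            r.genotype_string(),
        )
    )
    return maximal


def write_shared_reports(
    reports: Sequence[SharedGenotypeReport], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    with Path(tsv_path).open("w") as fh:
        fh.write("species\tn_species\tloci\tgenotype\tfrequency\tcarriers\tscored\tzygosity\n")
        for r in reports:
            zyg = ";".join(f"{l}:{r.zygosity[l]}" for l in r.loci)
            for sp in r.species_set:
                fh.write(
                    f"{sp}\t{len(r.species_set)}\t{','.join(r.loci)}\t"
                    f"{r.genotype_string()}\t{r.freq_per_species[sp]:.6g}\t"
                    f"{r.carriers_per_species[sp]}\t{r.scored_per_species[sp]}\t{zyg}\n"
                )
    if json_path is not None:
        payload = [
            {
                "species": list(r.species_set),
                "loci": list(r.loci),
                "alleles": {l: list(r.genotype[l].alleles()) for l in r.loci},
                "frequency": r.freq_per_species,
                "carriers": r.carriers_per_species,
                "scored": r.scored_per_species,
                "zygosity": r.zygosity,
            }
            for r in reports
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
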