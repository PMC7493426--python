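"""Per-group diversity and clonal genotype statistics.

Covers rarefied allelic richness (hypergeometric rarefaction in gene
copies), observed / unbiased expected heterozygosity and homozygous-call
proportion, and the clonal genotype-diversity table (distinct
multilocus genotype counts, top genotype frequencies, and Bruvo
distances between the most common / most distant genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

from msatclone.distances import bruvo_genotype_distance
from msatclone.genotype_io import AllelePair, GenotypeDataset, allele_frequencies

__all__ = [
    "DiversitySummary",
    "GenotypeDiversityRow",
    "rarefied_allelic_richness",
    "heterozygosity",
    "genotype_diversity_table",
    "default_rarefaction_size",
    "write_diversity_tsv",
]


@dataclass
class DiversitySummary:
    group: str
    AR_per_locus: dict[str, float]
    AR_sum: float
    OH: float
    EH: float | None
    het_excess: float | None
    hoz: float
    flags: list[str] = field(default_factory=list)


@dataclass
class GenotypeDiversityRow:
    group: str
    N: int
    GT: int
    DR: float
    MD: float
    top_freqs: list[float]
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# allelic richness


def _allele_counts(dataset: GenotypeDataset, group: str, by: str) -> dict[str, dict[int, int]]:
    out: dict[str, dict[int, int]] = {}
    for locus in dataset.locus_names:
        counts: dict[int, int] = {}
        for ind in dataset.subset(group, by=by):
            p = ind.calls.get(locus)
            if p is None or p.is_missing:
                continue
            for a in p.alleles():
                counts[a] = counts.get(a, 0) + 1
        out[locus] = counts
    return out


def default_rarefaction_size(
    dataset: GenotypeDataset, groups: Sequence[str], by: str = "species"
) -> int:
    """Smallest scored gene-copy count over all (group, locus) pairs."""
    g = None
    for group in groups:
        for locus, counts in _allele_counts(dataset, group, by).items():
            n = sum(counts.values())
            if n > 0 and (g is None or n < g):
                g = n
    if g is None:
        raise ValueError("no scored loci in any group")
    return g


def rarefied_allelic_richness(
    dataset: GenotypeDataset,
    group: str,
    g: int,
    group_by: str = "species",
) -> tuple[dict[str, float], float, list[str]]:
    """Hypergeometric rarefied allele counts per locus, plus their sum.

    Per locus with n scored gene copies and allele counts n_a:
    ``AR = sum_a [1 - C(n - n_a, g) / C(n, g)]`` — the expected number
    of distinct alleles in a subsample of ``g`` gene copies.  Loci
    scored with fewer than ``g`` copies (or not at all) are excluded
    and flagged.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    per_locus: dict[str, float] = {}
    flags: list[str] = []
    for locus, counts in _allele_counts(dataset, group, group_by).items():
        n = sum(counts.values())
        if n == 0:
            flags.append(f"{locus}: unscored in {group}")
            continue
        if n < g:
            flags.append(f"{locus}: only {n} gene copies (< g={g}) in {group}")
            continue
        denom = comb(n, g)
        ar = sum(1.0 - comb(n - na, g) / denom for na in counts.values())
        per_locus[locus] = ar
    return per_locus, sum(per_locus.values()), flags


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(
    dataset: GenotypeDataset, group: str, group_by: str = "species"
) -> DiversitySummary:
    """Observed and unbiased expected heterozygosity for one group.

    OH averages the per-locus heterozygote fraction over scored loci;
    EH uses the small-sample correction ``n/(n-1) * (1 - sum p^2)``
    with ``n`` gene copies, averaged over loci with n >= 2 copies
    (flagged undefined when no locus qualifies).  ``hoz`` is the pooled
    proportion of homozygous scored calls over all loci/individuals.
    """
    inds = dataset.subset(group, by=group_by)
    oh_per_locus: list[float] = []
    eh_per_locus: list[float] = []
    flags: list[str] = []
    n_hom = n_scored_calls = 0
    freq = allele_frequencies(dataset, group_by=group_by, groups=[group])[group]
    for locus in dataset.locus_names:
        het = tot = 0
        for ind in inds:
            p = ind.calls.get(locus)
            if p is None or p.is_missing:
                continue
            tot += 1
            if p.is_heterozygous:
                het += 1
            else:
                n_hom += 1
        n_scored_calls += tot
        if tot == 0:
            flags.append(f"{locus}: unscored in {group}")
            continue
        oh_per_locus.append(het / tot)
        n_copies = freq.n_scored.get(locus, 0)
        if n_copies < 2:
            flags.append(f"{locus}: <2 gene copies, EH undefined")
            continue
        p2 = sum(f * f for f in freq.freqs[locus].values())
        eh_per_locus.append(n_copies / (n_copies - 1) * (1.0 - p2))
    if not oh_per_locus:
        raise ValueError(f"group {group!r} has no scored loci")
    oh = sum(oh_per_locus) / len(oh_per_locus)
    eh = sum(eh_per_locus) / len(eh_per_locus) if eh_per_locus else None
    if eh is None:
        flags.append("EH undefined for all loci (n=1 group?)")
    return DiversitySummary(
        group=group,
        AR_per_locus={},
        AR_sum=float("nan"),
        OH=oh,
        EH=eh,
        het_excess=(oh - eh) if eh is not None else None,
        hoz=n_hom / n_scored_calls if n_scored_calls else float("nan"),
        flags=flags,
    )


def diversity_summary(
    dataset: GenotypeDataset,
    group: str,
    g: int,
    group_by: str = "species",
) -> DiversitySummary:
    """Heterozygosity stats plus rarefied allelic richness in one record."""
    summ = heterozygosity(dataset, group, group_by)
    per_locus, ar_sum, flags = rarefied_allelic_richness(dataset, group, g, group_by)
    summ.AR_per_locus = per_locus
    summ.AR_sum = ar_sum
    summ.flags.extend(flags)
    return summ


# ---------------------------------------------------------------------------
# genotype diversity (clonal structure)


def _genotype_key(ind, locus_order: Sequence[str]) -> tuple:
    """Hashable multilocus genotype key; missing-data individuals are
    their own class (keyed by individual id), per the counting rule that
    treats them as distinct genotypes."""
    pairs = [ind.calls.get(l, AllelePair.missing()) for l in locus_order]
    if any(p.is_missing for p in pairs):
        return ("__missing__", ind.id)
    return tuple((p.a1, p.a2) for p in pairs)


def genotype_diversity_table(
    dataset: GenotypeDataset, group: str, group_by: str = "species"
) -> GenotypeDiversityRow:
    """Distinct-genotype count and clonal frequency/distance statistics.

    GT counts distinct complete multilocus genotypes, with every
    individual carrying a MISSING locus counted as its own genotype.
    DR is the maximum pairwise Bruvo distance between distinct
    genotypes, MD the Bruvo distance between the two most frequent ones
    (ties broken by higher frequency, then lexicographic genotype key).
    """
    inds = dataset.subset(group, by=group_by)
    order = dataset.locus_names
    classes: dict[tuple, list] = {}
    for ind in inds:
        classes.setdefault(_genotype_key(ind, order), []).append(ind)
    N = len(inds)
    GT = len(classes)
    flags: list[str] = []

    # frequency ranking: by count desc, then lexicographic key (str) asc
    ranked = sorted(classes.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    top_freqs = [len(members) / N for _, members in ranked[:4]]

    if GT < 2:
        return GenotypeDiversityRow(group, N, GT, 0.0, 0.0, top_freqs, ["<2 distinct genotypes"])

    reps = [members[0] for _, members in ranked]
    dr = 0.0
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            d = bruvo_genotype_distance(reps[i].calls, reps[j].calls, dataset.loci)
            if d == d and d > dr:  # skip NaN
                dr = d
    md = bruvo_genotype_distance(reps[0].calls, reps[1].calls, dataset.loci)
    if md != md:
        flags.append("MD undefined (no common scored loci between top genotypes)")
        md = 0.0
    return GenotypeDiversityRow(group, N, GT, dr, md, top_freqs, flags)


def write_diversity_tsv(
    rows: Sequence[GenotypeDiversityRow],
    summaries: Mapping[str, DiversitySummary],
    path: str | Path,
) -> None:
    header = ["group", "N", "GT", "DR", "MD", "1st", "2nd", "3rd", "4th",
              "AR_sum", "OH", "EH", "OH_minus_EH", "HoZ"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            s = summaries.get(row.group)
            tf = row.top_freqs + [float("nan")] * (4 - len(row.top_freqs))
            cells = [
                row.group, str(row.N), str(row.GT), f"{row.DR:.4g}", f"{row.MD:.4g}",
                *(f"{v:.4g}" for v in tf[:4]),
            ]
            if s is not None:
                eh = f"{s.EH:.4g}" if s.EH is not None else "NA"
                hx = f"{s.het_excess:.4g}" if s.het_excess is not None else "NA"
                cells += [f"{s.AR_sum:.4g}", f"{s.OH:.4g}", eh, hx, f"{s.hoz:.4g}"]
            else:
                cells += ["NA"] * 5
            fh.write("\t".join(cells) + "\n")
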