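"""Data model and I/O for diploid microsatellite genotype tables.

Alleles are stored as fragment sizes in base pairs.  Conversion to
repeat units (needed by Bruvo distances) happens explicitly through
:func:`to_repeat_units` with per-locus motif lengths; when a motif
length is unknown it can be inferred as the GCD of pairwise allele-size
differences (:func:`infer_motif_length`).

Two table dialects are supported:

* ``wide``  — one header row; columns ``id, species, population`` then
  two columns per locus named ``<locus>.1`` and ``<locus>.2``.
* ``genalex`` — GenAlEx-style CSV: row 1 ``n_loci,n_samples,n_pops,...``,
  row 2 a free title, row 3 ``Sample,Pop`` followed by one locus name
  per pair of columns (second column of each pair left blank).  The
  ``Pop`` column is split as ``species`` (population set equal to it).

Missing calls are encoded on input as ``0``, empty string, ``NA`` or
``-9`` and always written back as ``0``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MISSING",
    "LocusDef",
    "AllelePair",
    "IndividualRecord",
    "GenotypeDataset",
    "FrequencyTable",
    "read_genotype_table",
    "write_genotype_table",
    "read_locus_meta",
    "write_locus_meta",
    "allele_frequencies",
    "pool_groups",
    "to_repeat_units",
    "infer_motif_length",
    "write_frequency_table",
]

#: Sentinel for a missing allele call.
MISSING = None

_MISSING_TOKENS = {"0", "", "NA", "-9", "na", "n/a", "N/A"}


class GenotypeTableError(ValueError):
    """Raised for malformed genotype tables or invalid datasets."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus and its repeat-unit geometry.

    Parameters
    ----------
    name:
        Unique locus identifier (e.g. ``"Du183"``).
    motif_length:
        Repeat-unit length in bp; must be >= 1.
    reference_offset:
        Non-repeat flank length in bp subtracted from the fragment size
        before dividing by ``motif_length``.
    """

    name: str
    motif_length: int = 1
    reference_offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name!r}: motif_length must be >= 1")


@dataclass(frozen=True, order=True)
class AllelePair:
    """Unordered diploid allele call at one locus (sizes in bp).

    Either both alleles are present or both are MISSING; half-calls are
    rejected.  The pair canonicalizes to ``a1 <= a2`` so that ``(a, b)``
    and ``(b, a)`` compare and hash identically.
    """

    a1: int | None
    a2: int | None

    def __post_init__(self) -> None:
        if (self.a1 is None) != (self.a2 is None):
            raise GenotypeTableError(f"half-call not allowed: ({self.a1}, {self.a2})")
        if self.a1 is not None and self.a2 is not None and self.a1 > self.a2:
            lo, hi = self.a2, self.a1
            object.__setattr__(self, "a1", lo)
            object.__setattr__(self, "a2", hi)

    @classmethod
    def missing(cls) -> "AllelePair":
        return cls(MISSING, MISSING)

    @property
    def is_missing(self) -> bool:
        return self.a1 is None

    @property
    def is_homozygous(self) -> bool:
        if self.is_missing:
            raise GenotypeTableError("zygosity undefined for a MISSING call")
        return self.a1 == self.a2

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_homozygous

    def alleles(self) -> tuple[int, int]:
        if self.is_missing:
            raise GenotypeTableError("alleles() on a MISSING call")
        return (self.a1, self.a2)  # type: ignore[return-value]


@dataclass
class IndividualRecord:
    """One genotyped individual with its group labels."""

    id: str
    species: str
    population: str
    calls: dict[str, AllelePair] = field(default_factory=dict)

    def n_missing(self) -> int:
        return sum(1 for p in self.calls.values() if p.is_missing)

    def scored_loci(self) -> list[str]:
        return [l for l, p in self.calls.items() if not p.is_missing]


@dataclass
class GenotypeDataset:
    """An ordered set of loci plus genotyped individuals.

    ``max_missing`` bounds the number of MISSING loci allowed per
    individual (validation raises beyond it).
    """

    loci: list[LocusDef]
    individuals: list[IndividualRecord]
    max_missing: int | None = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.loci:
            raise GenotypeTableError("dataset has no loci")
        if not self.individuals:
            raise GenotypeTableError("dataset has no individuals")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeTableError("duplicate locus names")
        known = set(names)
        for ind in self.individuals:
            unknown = set(ind.calls) - known
            if unknown:
                raise GenotypeTableError(
                    f"individual {ind.id!r}: unknown loci {sorted(unknown)}"
                )
            # loci absent from `calls` count as missing
            n_miss = ind.n_missing() + (len(known) - len(ind.calls))
            if self.max_missing is not None and n_miss > self.max_missing:
                raise GenotypeTableError(
                    f"individual {ind.id!r} has {n_miss} missing loci "
                    f"(max_missing={self.max_missing})"
                )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def missing_proportion(self) -> float:
        """Fraction of locus calls that are MISSING over all individuals."""
        total = len(self.individuals) * len(self.loci)
        miss = 0
        for ind in self.individuals:
            for l in self.locus_names:
                p = ind.calls.get(l)
                if p is None or p.is_missing:
                    miss += 1
        return miss / total

    def groups(self, by: str = "species") -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(getattr(ind, by), None)
        return list(seen)

    def subset(self, group: str, by: str = "species") -> list[IndividualRecord]:
        out = [ind for ind in self.individuals if getattr(ind, by) == group]
        if not out:
            raise KeyError(f"no individuals with {by}={group!r}")
        return out


@dataclass
class FrequencyTable:
    """Per-locus allele relative frequencies for one group.

    ``freqs[locus][allele_bp]`` holds the relative frequency;
    ``n_scored[locus]`` the number of scored gene copies.  Loci with
    zero scored copies are absent from both maps and listed in
    ``unscored_loci``.
    """

    group: str
    freqs: dict[str, dict[int, float]]
    n_scored: dict[str, int]
    unscored_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus, fmap in self.freqs.items():
            s = sum(fmap.values())
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"locus {locus}: frequencies sum to {s}, not 1")
            for a, f in fmap.items():
                if not (0.0 < f <= 1.0):
                    raise ValueError(f"locus {locus} allele {a}: frequency {f}")

    def frequency(self, locus: str, allele: int) -> float:
        """Frequency of ``allele`` at ``locus`` (0.0 when unobserved)."""
        return self.freqs.get(locus, {}).get(allele, 0.0)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_allele(tok: str, row: int, locus: str) -> int | None:
    tok = tok.strip()
    if tok in _MISSING_TOKENS:
        return MISSING
    try:
        return int(tok)
    except ValueError:
        raise GenotypeTableError(
            f"row {row}: locus {locus!r}: cannot parse allele {tok!r}"
        ) from None


def _pair_from_tokens(t1: str, t2: str, row: int, locus: str) -> AllelePair:
    a1 = _parse_allele(t1, row, locus)
    a2 = _parse_allele(t2, row, locus)
    if (a1 is None) != (a2 is None):
        raise GenotypeTableError(f"row {row}: locus {locus!r}: half-call {t1!r}/{t2!r}")
    return AllelePair(a1, a2)


def read_genotype_table(
    path: str | Path,
    format: str = "wide",
    loci_meta: Sequence[LocusDef] | None = None,
    max_missing: int | None = 3,
) -> GenotypeDataset:
    """Read a genotype table (``wide`` or ``genalex`` dialect).

    When ``loci_meta`` is given its entries replace the default
    ``LocusDef`` (motif 1, offset 0) for loci found in the header; a
    metadata locus absent from the header is an error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if format == "wide":
        ds = _read_wide(rows, max_missing)
    elif format == "genalex":
        ds = _read_genalex(rows, max_missing)
    else:
        raise ValueError(f"unknown format {format!r}")
    if loci_meta is not None:
        have = {l.name for l in ds.loci}
        meta = {l.name: l for l in loci_meta}
        unknown = set(meta) - have
        if unknown:
            raise GenotypeTableError(f"loci_meta names not in table: {sorted(unknown)}")
        ds.loci = [meta.get(l.name, l) for l in ds.loci]
    return ds


def _read_wide(rows: list[list[str]], max_missing: int | None) -> GenotypeDataset:
    if not rows:
        raise GenotypeTableError("empty file")
    header = [h.strip() for h in rows[0]]
    if header[:3] != ["id", "species", "population"]:
        raise GenotypeTableError(
            "wide dialect requires header starting 'id,species,population'"
        )
    locus_cols = header[3:]
    if len(locus_cols) % 2 != 0:
        raise GenotypeTableError("odd number of allele columns")
    loci: list[str] = []
    for i in range(0, len(locus_cols), 2):
        c1, c2 = locus_cols[i], locus_cols[i + 1]
        if not (c1.endswith(".1") and c2.endswith(".2") and c1[:-2] == c2[:-2]):
            raise GenotypeTableError(f"bad locus column pair {c1!r}/{c2!r}")
        loci.append(c1[:-2])
    individuals = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise GenotypeTableError(f"row {r}: expected {len(header)} fields, got {len(row)}")
        calls = {}
        for k, locus in enumerate(loci):
            calls[locus] = _pair_from_tokens(row[3 + 2 * k], row[4 + 2 * k], r, locus)
        individuals.append(IndividualRecord(row[0].strip(), row[1].strip(), row[2].strip(), calls))
    return GenotypeDataset(
        loci=[LocusDef(name) for name in loci],
        individuals=individuals,
        max_missing=max_missing,
    )


def _read_genalex(rows: list[list[str]], max_missing: int | None) -> GenotypeDataset:
    if len(rows) < 4:
        raise GenotypeTableError("GenAlEx file needs >= 4 rows")
    header = rows[2]
    if len(header) < 4 or header[0].strip().lower() != "sample":
        raise GenotypeTableError("GenAlEx row 3 must start 'Sample,Pop,...'")
    locus_cols = header[2:]
    loci = [locus_cols[i].strip() for i in range(0, len(locus_cols), 2)]
    if any(not name for name in loci):
        raise GenotypeTableError("GenAlEx locus name columns must be non-empty")
    individuals = []
    for r, row in enumerate(rows[3:], start=4):
        if not row or all(not c.strip() for c in row):
            continue
        calls = {}
        for k, locus in enumerate(loci):
            calls[locus] = _pair_from_tokens(row[2 + 2 * k], row[3 + 2 * k], r, locus)
        pop = row[1].strip()
        individuals.append(IndividualRecord(row[0].strip(), pop, pop, calls))
    return GenotypeDataset(
        loci=[LocusDef(name) for name in loci],
        individuals=individuals,
        max_missing=max_missing,
    )


def write_genotype_table(
    dataset: GenotypeDataset, path: str | Path, format: str = "wide"
) -> None:
    """Write a dataset back to CSV; inverse of :func:`read_genotype_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if format == "wide":
            header = ["id", "species", "population"]
            for l in dataset.locus_names:
                header += [f"{l}.1", f"{l}.2"]
            w.writerow(header)
            for ind in dataset.individuals:
                row = [ind.id, ind.species, ind.population]
                for l in dataset.locus_names:
                    p = ind.calls.get(l, AllelePair.missing())
                    row += ["0", "0"] if p.is_missing else [str(p.a1), str(p.a2)]
                w.writerow(row)
        elif format == "genalex":
            n_loci = len(dataset.loci)
            pops = dataset.groups("species")
            counts = [len(dataset.subset(p)) for p in pops]
            w.writerow([n_loci, len(dataset.individuals), len(pops), *counts])
            w.writerow(["msatclone export"])
            header = ["Sample", "Pop"]
            for l in dataset.locus_names:
                header += [l, ""]
            w.writerow(header)
            for ind in dataset.individuals:
                row = [ind.id, ind.species]
                for l in dataset.locus_names:
                    p = ind.calls.get(l, AllelePair.missing())
                    row += ["0", "0"] if p.is_missing else [str(p.a1), str(p.a2)]
                w.writerow(row)
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# locus metadata (TOML-style key/value file)


def read_locus_meta(path: str | Path) -> list[LocusDef]:
    """Read locus metadata from a TOML file.

    Expected shape::

        [Du183]
        motif_length = 4
        reference_offset = 1
    """
    import tomllib

    with Path(path).open("rb") as fh:
        data = tomllib.load(fh)
    out = []
    for name, vals in data.items():
        out.append(
            LocusDef(
                name,
                motif_length=int(vals.get("motif_length", 1)),
                reference_offset=int(vals.get("reference_offset", 0)),
            )
        )
    return out


def write_locus_meta(loci: Iterable[LocusDef], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for l in loci:
            fh.write(f"[{l.name}]\n")
            fh.write(f"motif_length = {l.motif_length}\n")
            fh.write(f"reference_offset = {l.reference_offset}\n\n")


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(
    dataset: GenotypeDataset,
    group_by: str = "species",
    groups: Sequence[str] | None = None,
) -> dict[str, FrequencyTable]:
    """Per-group, per-locus allele relative frequencies.

    MISSING pairs contribute to neither numerator nor denominator.  A
    locus with zero scored copies in a group is absent from the table's
    ``freqs`` and listed in ``unscored_loci``.
    """
    if groups is None:
        groups = dataset.groups(group_by)
    out: dict[str, FrequencyTable] = {}
    for group in groups:
        inds = dataset.subset(group, by=group_by)
        freqs: dict[str, dict[int, float]] = {}
        n_scored: dict[str, int] = {}
        unscored: list[str] = []
        for locus in dataset.locus_names:
            counts: dict[int, int] = {}
            for ind in inds:
                p = ind.calls.get(locus)
                if p is None or p.is_missing:
                    continue
                for a in p.alleles():
                    counts[a] = counts.get(a, 0) + 1
            total = sum(counts.values())
            if total == 0:
                unscored.append(locus)
                continue
            freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
            n_scored[locus] = total
        out[group] = FrequencyTable(group, freqs, n_scored, unscored)
    return out


def pool_groups(
    tables: Sequence[FrequencyTable], weights: str = "by_sample", group: str | None = None
) -> FrequencyTable:
    """Pool several frequency tables into one.

    ``by_sample`` sums allele counts before renormalizing; ``equal``
    averages the frequency vectors.  Only loci scored in every input
    table are pooled (the dropped ones are listed in ``unscored_loci``).
    """
    if not tables:
        raise ValueError("no tables to pool")
    if weights not in ("by_sample", "equal"):
        raise ValueError(f"unknown weights {weights!r}")
    common = set(tables[0].freqs)
    union = set(tables[0].freqs) | set(tables[0].unscored_loci)
    for t in tables[1:]:
        common &= set(t.freqs)
        union |= set(t.freqs) | set(t.unscored_loci)
    freqs: dict[str, dict[int, float]] = {}
    n_scored: dict[str, int] = {}
    for locus in sorted(common):
        if weights == "by_sample":
            counts: dict[int, float] = {}
            for t in tables:
                n = t.n_scored[locus]
                for a, f in t.freqs[locus].items():
                    counts[a] = counts.get(a, 0.0) + f * n
            total = sum(counts.values())
            freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
            n_scored[locus] = int(round(total))
        else:
            acc: dict[int, float] = {}
            for t in tables:
                for a, f in t.freqs[locus].items():
                    acc[a] = acc.get(a, 0.0) + f
            k = len(tables)
            freqs[locus] = {a: v / k for a, v in sorted(acc.items())}
            n_scored[locus] = sum(t.n_scored[locus] for t in tables)
    name = group or "+".join(t.group for t in tables)
    return FrequencyTable(name, freqs, n_scored, sorted(union - common))


def write_frequency_table(
    tables: Mapping[str, FrequencyTable] | Sequence[FrequencyTable], path: str | Path
) -> None:
    """Export frequency tables as long-format TSV."""
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    with Path(path).open("w") as fh:
        fh.write("group\tlocus\tallele_bp\tfrequency\tn_copies\n")
        for t in tables:
            for locus in sorted(t.freqs):
                for a, f in sorted(t.freqs[locus].items()):
                    fh.write(f"{t.group}\t{locus}\t{a}\t{f:.10g}\t{t.n_scored[locus]}\n")


# ---------------------------------------------------------------------------
# repeat-unit conversion


def to_repeat_units(size_bp: int, locus: LocusDef) -> tuple[int, bool]:
    """Convert an allele size in bp to a repeat count.

    Returns ``(count, off_ladder)``: the nearest integer repeat count,
    and a flag raised when the rounding distance is >= 0.25 repeat
    units (an off-ladder allele relative to the locus geometry).
    """
    if size_bp is None:
        raise GenotypeTableError("cannot convert a MISSING allele")
    raw = (size_bp - locus.reference_offset) / locus.motif_length
    count = round(raw)
    return int(count), abs(raw - count) >= 0.25 - 1e-12


def infer_motif_length(dataset: GenotypeDataset, locus: str) -> int:
    """Infer a motif length as the GCD of pairwise allele-size differences.

    Falls back to 1 for monomorphic (or unscored) loci.
    """
    sizes: set[int] = set()
    for ind in dataset.individuals:
        p = ind.calls.get(locus)
        if p is not None and not p.is_missing:
            sizes.update(p.alleles())
    diffs = [abs(a - b) for a, b in combinations(sorted(sizes), 2)]
    if not diffs:
        return 1
    return math.gcd(*diffs)


def with_inferred_motifs(dataset: GenotypeDataset) -> GenotypeDataset:
    """Return a dataset whose loci carry GCD-inferred motif lengths."""
    loci = [
        LocusDef(l.name, infer_motif_length(dataset, l.name), l.reference_offset)
        for l in dataset.loci
    ]
    return GenotypeDataset(loci, dataset.individuals, dataset.max_missing)
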