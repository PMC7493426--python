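"""Bruvo distances, minimum spanning networks, and neighbor-joining trees.

The Bruvo allele distance is ``d = 1 - 2**(-|x|)`` with ``x`` the
repeat-unit difference between two alleles.  Diploid genotypes are
combined with the minimal-assignment rule: the per-locus distance is
the smaller of the two one-to-one allele pairings, and the genotype
distance averages over loci scored in both individuals (pairwise
deletion).  No ploidy above 2 is supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from msatclone.genotype_io import (
    AllelePair,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
    to_repeat_units,
)

__all__ = [
    "DistanceMatrix",
    "GenotypeNetwork",
    "bruvo_allele_distance",
    "bruvo_genotype_distance",
    "bruvo_matrix",
    "shared_locus_distance",
    "shared_locus_matrix",
    "minimum_spanning_network",
    "nj_tree",
    "Tree",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix; NaN marks undefined pairs."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("nonzero diagonal")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")

    def to_phylip(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab:<10s} {row}\n")


@dataclass
class GenotypeNetwork:
    """Unique multilocus genotypes with multiplicities, plus weighted edges."""

    nodes: list[dict]
    edges: list[tuple[str, str, float]]
    components: list[list[str]] = field(default_factory=list)
    annotations: dict[str, int] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node["id"], **node)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    def total_multiplicity(self) -> int:
        return sum(n["multiplicity"] for n in self.nodes)

    def to_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for u, v, w in self.edges:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")

    def to_gml(self, path: str | Path) -> None:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node["id"],
                multiplicity=node["multiplicity"],
                group=str(node.get("group", "")),
            )
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        nx.write_gml(g, str(path))


# ---------------------------------------------------------------------------
# Bruvo distances


def bruvo_allele_distance(x: int | float) -> float:
    """Distance between two alleles ``x`` repeat units apart: 1 - 2**-|x|."""
    return 1.0 - 2.0 ** (-abs(x))


def _locus_bruvo(a: AllelePair, b: AllelePair, locus: LocusDef) -> float:
    ra = [to_repeat_units(s, locus)[0] for s in a.alleles()]
    rb = [to_repeat_units(s, locus)[0] for s in b.alleles()]
    d_straight = 0.5 * (
        bruvo_allele_distance(ra[0] - rb[0]) + bruvo_allele_distance(ra[1] - rb[1])
    )
    d_crossed = 0.5 * (
        bruvo_allele_distance(ra[0] - rb[1]) + bruvo_allele_distance(ra[1] - rb[0])
    )
    return min(d_straight, d_crossed)


def bruvo_genotype_distance(
    calls_a: Mapping[str, AllelePair],
    calls_b: Mapping[str, AllelePair],
    loci: Sequence[LocusDef],
) -> float:
    """Mean per-locus Bruvo distance over commonly scored loci.

    Returns NaN when the two genotypes share no scored locus.
    """
    dists = []
    for locus in loci:
        pa = calls_a.get(locus.name)
        pb = calls_b.get(locus.name)
        if pa is None or pb is None or pa.is_missing or pb.is_missing:
            continue
        dists.append(_locus_bruvo(pa, pb, locus))
    if not dists:
        return float("nan")
    return sum(dists) / len(dists)


def bruvo_matrix(
    dataset: GenotypeDataset,
    individuals: Sequence[IndividualRecord] | None = None,
) -> DistanceMatrix:
    """Pairwise Bruvo distance matrix over individuals."""
    inds = list(individuals) if individuals is not None else dataset.individuals
    labels = [ind.id for ind in inds]
    n = len(inds)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bruvo_genotype_distance(inds[i].calls, inds[j].calls, dataset.loci)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)


# ---------------------------------------------------------------------------
# shared-locus distance


def shared_locus_distance(
    ind_a: IndividualRecord, ind_b: IndividualRecord, total_loci: int
) -> float:
    """``total_loci`` minus the count of loci with identical diploid genotypes.

    A locus missing in either individual is not shared.
    """
    shared = 0
    for locus, pa in ind_a.calls.items():
        pb = ind_b.calls.get(locus)
        if pb is None or pa.is_missing or pb.is_missing:
            continue
        if pa == pb:
            shared += 1
    return float(total_loci - shared)


def shared_locus_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    inds = dataset.individuals
    L = len(dataset.loci)
    n = len(inds)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = shared_locus_distance(inds[i], inds[j], L)
    return DistanceMatrix([ind.id for ind in inds], vals)


# ---------------------------------------------------------------------------
# minimum spanning network


def minimum_spanning_network(
    matrix: DistanceMatrix,
    tie_tol: float = 1e-9,
    node_meta: Mapping[str, dict] | None = None,
) -> GenotypeNetwork:
    """MST plus every edge that ties (within ``tie_tol``, relative) the
    maximum-weight edge on the MST cycle it would close.

    Undefined (NaN) pairs carry no edge; if they disconnect the graph
    each component gets its own spanning network and the component
    membership is reported.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.labels)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.values[i, j]
            if not math.isnan(w):
                g.add_edge(matrix.labels[i], matrix.labels[j], weight=w)

    edges: list[tuple[str, str, float]] = []
    components = [sorted(c) for c in nx.connected_components(g)]
    for comp in components:
        sub = g.subgraph(comp)
        mst = nx.minimum_spanning_tree(sub, weight="weight")
        kept = {tuple(sorted(e)) for e in mst.edges}
        for u, v, data in sorted(sub.edges(data=True), key=lambda e: (e[0], e[1])):
            key = tuple(sorted((u, v)))
            if key in kept:
                continue
            # max edge weight on the MST path between u and v
            path = nx.shortest_path(mst, u, v)
            cyc_max = max(
                mst[a][b]["weight"] for a, b in zip(path, path[1:])
            )
            if data["weight"] <= cyc_max * (1.0 + tie_tol) + tie_tol:
                kept.add(key)
        for u, v in sorted(kept):
            edges.append((u, v, float(g[u][v]["weight"])))

    nodes = []
    for label in matrix.labels:
        meta = dict(node_meta.get(label, {})) if node_meta else {}
        meta.setdefault("multiplicity", 1)
        meta["id"] = label
        nodes.append(meta)
    return GenotypeNetwork(nodes=nodes, edges=edges, components=components)


def collapse_genotypes(
    dataset: GenotypeDataset,
    individuals: Sequence[IndividualRecord] | None = None,
) -> tuple[list[IndividualRecord], dict[str, dict]]:
    """Collapse identical complete multilocus genotypes into single nodes.

    Individuals with any MISSING locus stay as their own node (they are
    distinct genotype classes).  Returns representative records (ids are
    ``MLG1..k`` in first-seen order) and per-node metadata with
    multiplicity, member ids and majority group label.
    """
    inds = list(individuals) if individuals is not None else dataset.individuals
    order = dataset.locus_names
    groups: dict[tuple, list[IndividualRecord]] = {}
    for ind in inds:
        pairs = tuple(
            ind.calls.get(l, AllelePair.missing()) for l in order
        )
        if any(p.is_missing for p in pairs):
            key = ("__missing__", ind.id)
        else:
            key = tuple((p.a1, p.a2) for p in pairs)
        groups.setdefault(key, []).append(ind)
    reps: list[IndividualRecord] = []
    meta: dict[str, dict] = {}
    for k, (key, members) in enumerate(groups.items(), start=1):
        rep = members[0]
        node_id = f"MLG{k}"
        reps.append(
            IndividualRecord(node_id, rep.species, rep.population, dict(rep.calls))
        )
        counts: dict[str, int] = {}
        for m in members:
            counts[m.species] = counts.get(m.species, 0) + 1
        majority = max(sorted(counts), key=lambda s: counts[s])
        meta[node_id] = {
            "multiplicity": len(members),
            "members": [m.id for m in members],
            "group": majority,
        }
    return reps, meta


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class Tree:
    """Minimal unrooted tree node for NJ output."""

    name: str | None = None
    children: list[tuple["Tree", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner}){self.name or ''}"

    def leaf_names(self) -> list[str]:
        if not self.children:
            return [self.name] if self.name else []
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (for additivity checks)."""
        g = nx.Graph()

        def walk(node: "Tree") -> object:
            key = node.name if not node.children else ("__int__", id(node))
            g.add_node(key)
            for child, bl in node.children:
                ck = walk(child)
                g.add_edge(key, ck, weight=bl)
            return key

        walk(self)
        leaves = sorted(n for n in g.nodes if isinstance(n, str))
        pairs: dict[tuple[str, str], float] = {}
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                pairs[(a, b)] = lengths[a][b]
        return pairs


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbor-joining tree (Saitou & Nei agglomeration).

    Negative branch lengths are clamped to 0 with the deficit moved to
    the sister branch.  Ties in the Q criterion break on lexicographic
    label order for determinism.
    """
    if len(matrix.labels) < 3:
        raise ValueError("NJ needs >= 3 labels")
    if np.isnan(matrix.values).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or drop those "
            "individuals before tree building"
        )
    nodes: dict[str, Tree] = {l: Tree(name=l) for l in matrix.labels}
    labels = list(matrix.labels)
    D = {a: {b: float(matrix[a, b]) for b in labels if b != a} for a in labels}

    counter = 0
    while len(labels) > 3:
        r = {a: sum(D[a].values()) for a in labels}
        n = len(labels)
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (n - 2) * D[a][b] - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        _, a, b = best
        d_ab = D[a][b]
        bl_a = 0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2))
        bl_b = d_ab - bl_a
        if bl_a < 0:
            bl_b += -bl_a
            bl_a = 0.0
        if bl_b < 0:
            bl_a += -bl_b
            bl_b = 0.0
        counter += 1
        new = f"__nj{counter}"
        nodes[new] = Tree(children=[(nodes[a], bl_a), (nodes[b], bl_b)])
        D[new] = {}
        for c in labels:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - d_ab)
            D[new][c] = D[c][new] = max(d, 0.0)
        for c in labels:
            D[c].pop(a, None)
            D[c].pop(b, None)
        del D[a], D[b], nodes[a], nodes[b]
        labels = [l for l in labels if l not in (a, b)] + [new]

    a, b, c = sorted(labels)
    d_ab, d_ac, d_bc = D[a][b], D[a][c], D[b][c]
    bl_a = max(0.5 * (d_ab + d_ac - d_bc), 0.0)
    bl_b = max(0.5 * (d_ab + d_bc - d_ac), 0.0)
    bl_c = max(0.5 * (d_ac + d_bc - d_ab), 0.0)
    return Tree(children=[(nodes[a], bl_a), (nodes[b], bl_b), (nodes[c], bl_c)])
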