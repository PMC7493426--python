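from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatclone.distances import (
    DistanceMatrix,
    bruvo_allele_distance,
    bruvo_genotype_distance,
    bruvo_matrix,
    collapse_genotypes,
    minimum_spanning_network,
    nj_tree,
    shared_locus_distance,
    shared_locus_matrix,
)
from msatclone.genotype_io import AllelePair, GenotypeDataset, LocusDef

from conftest import make_individual, random_dataset


class TestBruvoAllele:
    @pytest.mark.parametrize(
        "x,expected", [(0, 0.0), (1, 0.5), (-3, 0.875), (2, 0.75)]
    )
    def test_closed_form(self, x, expected):
        assert bruvo_allele_distance(x) == pytest.approx(expected)

    @given(st.integers(-30, 30))
    def test_sign_invariant_and_bounded(self, x):
        d = bruvo_allele_distance(x)
        assert d == bruvo_allele_distance(-x)
        assert 0.0 <= d < 1.0


def brute_force_diploid_bruvo(ra, rb):
    """Min over the two one-to-one pairings of mean allele distances."""
    best = None
    for perm in permutations(rb):
        v = sum(bruvo_allele_distance(a - b) for a, b in zip(ra, perm)) / 2
        best = v if best is None else min(best, v)
    return best


class TestBruvoGenotype:
    def _one_locus(self, ga, gb, motif=1):
        loci = [LocusDef("LA", motif)]
        a = make_individual("a", "s", {"LA": ga})
        b = make_individual("b", "s", {"LA": gb})
        return bruvo_genotype_distance(a.calls, b.calls, loci)

    def test_identical_is_zero(self):
        assert self._one_locus((48, 49), (48, 49)) == 0.0

    def test_pairings(self):
        assert self._one_locus((48, 49), (49, 48)) == 0.0
        assert self._one_locus((48, 48), (49, 49)) == pytest.approx(0.5)

    def test_motif_scaling(self):
        # 4 bp apart at a tetranucleotide = one repeat unit
        assert self._one_locus((100, 100), (104, 104), motif=4) == pytest.approx(0.5)

    def test_exhaustive_oracle_random_pairs(self, rng):
        loci = [LocusDef(f"L{i}", 1) for i in range(5)]
        for _ in range(50):
            ga = {l.name: tuple(sorted(rng.integers(40, 60, 2))) for l in loci}
            gb = {l.name: tuple(sorted(rng.integers(40, 60, 2))) for l in loci}
            a = make_individual("a", "s", ga)
            b = make_individual("b", "s", gb)
            expected = np.mean(
                [
                    brute_force_diploid_bruvo(list(ga[l.name]), list(gb[l.name]))
                    for l in loci
                ]
            )
            got = bruvo_genotype_distance(a.calls, b.calls, loci)
            assert got == pytest.approx(expected)

    def test_symmetry_and_bounds(self, rng):
        ds = random_dataset(rng, n_loci=4, n_ind=8, missing_rate=0.2)
        for a, b in combinations(ds.individuals, 2):
            d1 = bruvo_genotype_distance(a.calls, b.calls, ds.loci)
            d2 = bruvo_genotype_distance(b.calls, a.calls, ds.loci)
            if d1 == d1:
                assert d1 == pytest.approx(d2)
                assert 0.0 <= d1 <= 1.0

    def test_no_common_loci_nan(self):
        loci = [LocusDef("LA"), LocusDef("LB")]
        a = make_individual("a", "s", {"LA": (1, 2), "LB": None})
        b = make_individual("b", "s", {"LA": None, "LB": (1, 2)})
        assert np.isnan(bruvo_genotype_distance(a.calls, b.calls, loci))


class TestSharedLocusDistance:
    def test_identical(self):
        calls = {f"L{i}": (100 + i, 104 + i) for i in range(10)}
        a = make_individual("a", "s", calls)
        b = make_individual("b", "s", dict(calls))
        assert shared_locus_distance(a, b, 10) == 0.0

    def test_disjoint(self):
        a = make_individual("a", "s", {f"L{i}": (1, 2) for i in range(10)})
        b = make_individual("b", "s", {f"L{i}": (3, 4) for i in range(10)})
        assert shared_locus_distance(a, b, 10) == 10.0

    def test_six_shared(self):
        calls_a = {f"L{i}": (100, 104) for i in range(10)}
        calls_b = dict(calls_a)
        for i in range(6, 10):
            calls_b[f"L{i}"] = (200, 204)
        a = make_individual("a", "s", calls_a)
        b = make_individual("b", "s", calls_b)
        assert shared_locus_distance(a, b, 10) == 4.0

    def test_missing_not_shared(self):
        a = make_individual("a", "s", {"L0": (1, 2), "L1": None})
        b = make_individual("b", "s", {"L0": (1, 2), "L1": (3, 4)})
        assert shared_locus_distance(a, b, 2) == 1.0


def exhaustive_mst_weight(matrix: DistanceMatrix) -> float:
    """Minimum spanning-tree weight by enumeration over all spanning trees."""
    import networkx as nx

    n = len(matrix.labels)
    edges = [
        (i, j, matrix.values[i, j]) for i in range(n) for j in range(i + 1, n)
    ]
    best = None
    for subset in combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_weighted_edges_from(subset)
        if nx.is_connected(g):
            w = sum(e[2] for e in subset)
            best = w if best is None else min(best, w)
    return best


class TestMSN:
    def test_three_node_example(self):
        m = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
        )
        net = minimum_spanning_network(m)
        assert {(u, v) for u, v, _ in net.edges} == {("A", "B"), ("B", "C")}
        assert sum(w for _, _, w in net.edges) == pytest.approx(0.3)

    def test_all_equal_keeps_complete_graph(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        net = minimum_spanning_network(DistanceMatrix(list("ABCD"), vals))
        assert len(net.edges) == 6

    def test_mst_weight_matches_exhaustive(self, rng):
        for _ in range(5):
            n = 6
            v = np.round(rng.random((n, n)), 3)
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            m = DistanceMatrix([f"N{i}" for i in range(n)], v)
            net = minimum_spanning_network(m, tie_tol=0.0)
            g = net.graph()
            import networkx as nx

            mst = nx.minimum_spanning_tree(g, weight="weight")
            w = sum(d["weight"] for _, _, d in mst.edges(data=True))
            assert w == pytest.approx(exhaustive_mst_weight(m))

    def test_edges_superset_of_mst_and_tie_rule(self, rng):
        import networkx as nx

        n = 7
        v = np.round(rng.random((n, n)), 1)  # coarse -> ties likely
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        m = DistanceMatrix([f"N{i}" for i in range(n)], v)
        net = minimum_spanning_network(m)
        g = net.graph()
        mst = nx.minimum_spanning_tree(g, weight="weight")
        kept = {tuple(sorted(e)) for e in g.edges}
        # every retained non-MST edge ties the cycle max it closes
        for u, v_, w in net.edges:
            if tuple(sorted((u, v_))) in {tuple(sorted(e)) for e in mst.edges}:
                continue
            path = nx.shortest_path(mst, u, v_)
            cyc_max = max(mst[a][b]["weight"] for a, b in zip(path, path[1:]))
            assert w <= cyc_max * (1 + 1e-9) + 1e-9

    def test_disconnected_components_reported(self):
        v = np.array(
            [
                [0, 0.1, np.nan, np.nan],
                [0.1, 0, np.nan, np.nan],
                [np.nan, np.nan, 0, 0.2],
                [np.nan, np.nan, 0.2, 0],
            ]
        )
        net = minimum_spanning_network(DistanceMatrix(list("ABCD"), v))
        assert len(net.components) == 2

    def test_multiplicity_sums_to_individuals(self, rng):
        ds = random_dataset(rng, n_loci=2, n_ind=12, missing_rate=0.0, n_alleles=2)
        reps, meta = collapse_genotypes(ds)
        m = bruvo_matrix(ds, reps)
        net = minimum_spanning_network(m, node_meta=meta)
        assert net.total_multiplicity() == 12


class TestNJ:
    def additive_matrix(self):
        # unrooted tree: ((A:1,B:2):1,C:3,D:4)
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        v = np.zeros((4, 4))
        for (a, b), w in d.items():
            i, j = labels.index(a), labels.index(b)
            v[i, j] = v[j, i] = w
        return DistanceMatrix(labels, v), d

    def test_recovers_additive_4taxon(self):
        m, d = self.additive_matrix()
        tree = nj_tree(m)
        got = tree.leaf_distances()
        for pair, w in d.items():
            assert got[pair] == pytest.approx(w)

    def test_recovers_additive_6taxon(self, rng):
        # random additive matrix from a caterpillar tree
        import networkx as nx

        g = nx.Graph()
        leaves = [f"T{i}" for i in range(6)]
        spine = [f"S{i}" for i in range(4)]
        g.add_edge(leaves[0], spine[0], weight=rng.uniform(1, 5))
        g.add_edge(leaves[1], spine[0], weight=rng.uniform(1, 5))
        for i in range(3):
            g.add_edge(spine[i], spine[i + 1], weight=rng.uniform(1, 5))
            g.add_edge(leaves[2 + i], spine[i + 1], weight=rng.uniform(1, 5))
        g.add_edge(leaves[5], spine[3], weight=rng.uniform(1, 5))
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        v = np.zeros((6, 6))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i != j:
                    v[i, j] = lengths[a][b]
        tree = nj_tree(DistanceMatrix(leaves, v))
        got = tree.leaf_distances()
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert got[(a, b)] == pytest.approx(lengths[a][b])

    def test_label_permutation_invariant_topology(self):
        m, _ = self.additive_matrix()
        t1 = nj_tree(m)
        order = [2, 0, 3, 1]
        labels = [m.labels[i] for i in order]
        t2 = nj_tree(m.submatrix(labels))
        assert t1.leaf_distances() == pytest.approx(t2.leaf_distances())

    def test_three_taxon(self):
        v = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), v))
        d = tree.leaf_distances()
        assert d[("A", "B")] == pytest.approx(2.0)

    def test_nan_rejected(self):
        v = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(list("ABC"), v))

    def test_newick_parses(self):
        m, _ = self.additive_matrix()
        nwk = nj_tree(m).newick()
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")


class TestFiltering:
    def test_het_filter_submatrix(self, rng):
        """Filtering to >=2 het loci yields a principal submatrix."""
        ds = random_dataset(rng, n_loci=4, n_ind=10, missing_rate=0.0)
        full = bruvo_matrix(ds)
        keep = [
            i for i in ds.individuals
            if sum(1 for p in i.calls.values() if p.is_heterozygous) >= 2
        ]
        if len(keep) >= 2:
            filtered = bruvo_matrix(ds, keep)
            sub = full.submatrix([i.id for i in keep])
            assert np.allclose(filtered.values, sub.values, equal_nan=True)


def test_matrix_io_roundtrip(tmp_path, rng):
    ds = random_dataset(rng, n_loci=3, n_ind=5, missing_rate=0.0)
    m = bruvo_matrix(ds)
    m.to_tsv(tmp_path / "d.tsv")
    m.to_phylip(tmp_path / "d.phy")
    lines = (tmp_path / "d.tsv").read_text().splitlines()
    assert len(lines) == 6
    assert (tmp_path / "d.phy").read_text().splitlines()[0] == "5"


def test_shared_locus_matrix_symmetric(rng):
    ds = random_dataset(rng, n_loci=4, n_ind=6, missing_rate=0.1)
    m = shared_locus_matrix(ds)
    assert np.allclose(m.values, m.values.T)
    assert m.values.max() <= 4
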