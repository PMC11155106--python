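import numpy as np
import pytest

from parallelscan.core import MISSING, PopulationMap
from parallelscan.ibd_haplotypes import (
    DistanceMatrix,
    collapse_haplotypes,
    geo_distance,
    hamming,
    haplotype_network,
    ibs_distance,
    mantel,
    network_edge_table,
)

from conftest import make_gm


class TestIbsDistance:
    def pm(self, n_pops, per_pop):
        return PopulationMap(
            {f"s{i}": f"pop{i // per_pop}" for i in range(n_pops * per_pop)}
        )

    def test_identical_genotypes_zero(self):
        gm = make_gm(np.array([[0, 1, 2]] * 4))
        dm = ibs_distance(gm, self.pm(2, 2))
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        gm = make_gm(np.array([[0, 0], [0, 0], [2, 2], [2, 2]]))
        dm = ibs_distance(gm, self.pm(2, 2))
        assert dm.values[0, 1] == 1.0

    def test_hand_computed_plink_convention(self):
        # 3 samples x 4 sites; pops: {s0}, {s1, s2} would need >=1 sample each
        dosage = np.array(
            [
                [0, 1, 2, MISSING],
                [1, 1, 0, 0],
                [2, 0, 2, 0],
            ]
        )
        gm = make_gm(dosage)
        pm = PopulationMap({"s0": "A", "s1": "B", "s2": "B"})
        dm = ibs_distance(gm, pm)
        # d(s0,s1): sites 0..2 co-genotyped: |0-1|,|1-1|,|2-0| = 1,0,2 -> mean/2 = 0.5
        # d(s0,s2): |0-2|,|1-0|,|2-2| = 2,1,0 -> mean/2 = 0.5
        assert dm.values[0, 1] == pytest.approx(np.mean([0.5, 0.5]))

    def test_site_order_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        gm = make_gm(dosage)
        perm = rng.permutation(30)
        gm2 = make_gm(dosage[:, perm])
        pm = self.pm(2, 2)
        np.testing.assert_allclose(ibs_distance(gm, pm).values, ibs_distance(gm2, pm).values)

    def test_bounded_in_unit_interval(self, null_sim):
        sub = PopulationMap(
            {s: p for s, p in null_sim.popmap.assignment.items() if p != "outgroup"}
        )
        gm = null_sim.genotypes.take_samples(list(sub.assignment))
        dm = ibs_distance(gm, sub)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()

    def test_no_cogenotyped_sites_errors(self):
        dosage = np.array([[0, MISSING], [MISSING, 0]])
        gm = make_gm(dosage)
        pm = PopulationMap({"s0": "A", "s1": "B"})
        with pytest.raises(ValueError, match="no genotyped sites"):
            ibs_distance(gm, pm)


class TestGeoDistance:
    def test_identical_coordinates_zero(self):
        dm = geo_distance({"a": (10.0, 20.0), "b": (10.0, 20.0)})
        assert dm.values[0, 1] == 0.0

    def test_quarter_circumference(self):
        dm = geo_distance({"a": (0.0, 0.0), "b": (0.0, 90.0)})
        assert dm.values[0, 1] == pytest.approx(2 * np.pi * 6371 / 4, abs=0.1)

    def test_symmetry(self):
        dm = geo_distance({"a": (31.2, 103.5), "b": (29.9, 99.1), "c": (34.0, 108.0)})
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_invalid_latitude_errors(self):
        with pytest.raises(ValueError, match="latitude"):
            geo_distance({"a": (95.0, 0.0), "b": (0.0, 0.0)})


def random_dm(rng, n, labels=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(labels or [f"p{i}" for i in range(n)], m)


class TestMantel:
    def test_proportional_matrices_r_one_min_p(self, rng):
        dm1 = random_dm(rng, 10)
        dm2 = DistanceMatrix(dm1.labels, 2 * dm1.values)
        res = mantel(dm1, dm2, n_perm=999, seed=5)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_consistent_relabeling_invariance(self, rng):
        dm1 = random_dm(rng, 5)
        dm2 = random_dm(rng, 5)
        perm = rng.permutation(5)
        labels = [dm1.labels[i] for i in perm]
        dm1p = DistanceMatrix(labels, dm1.values[np.ix_(perm, perm)])
        dm2p = DistanceMatrix(labels, dm2.values[np.ix_(perm, perm)])
        r1 = mantel(dm1, dm2, n_perm=199, seed=7)
        r2 = mantel(dm1p, dm2p, n_perm=199, seed=7)
        assert r1.r == pytest.approx(r2.r)

    def test_agrees_with_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dm1 = random_dm(rng, 7)
        dm2 = random_dm(rng, 7)
        res = mantel(dm1, dm2, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(dm1.values, dm1.labels),
            skbio_stats.DistanceMatrix(dm2.values, dm2.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)
        assert abs(res.p_value - float(p_ref)) < 0.05

    def test_null_p_roughly_uniform(self, rng):
        """Under independence, permutation p-values should span (0,1) rather
        than cluster; a coarse Kolmogorov-Smirnov sanity check."""
        from scipy import stats

        ps = []
        for k in range(40):
            local = np.random.default_rng(1000 + k)
            dm1 = random_dm(local, 6)
            dm2 = random_dm(local, 6)
            ps.append(mantel(dm1, dm2, n_perm=199, seed=k).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_constant_matrix_errors(self):
        labels = ["a", "b", "c"]
        ones = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="constant"):
            mantel(DistanceMatrix(labels, ones), DistanceMatrix(labels, ones), n_perm=9)


class TestCollapseHaplotypes:
    def test_all_identical(self):
        seqs = {f"s{i}": "ACGT" for i in range(5)}
        hs = collapse_haplotypes(seqs)
        assert len(hs) == 1 and hs.counts == [5]

    def test_all_distinct(self):
        seqs = {"a": "AAAA", "b": "AACA", "c": "AACC"}
        hs = collapse_haplotypes(seqs)
        assert len(hs) == 3

    def test_ambiguous_column_removal_merges(self):
        # two sequences differ only at a column that is ambiguous in another
        seqs = {"a": "AMCG", "b": "AACG", "c": "ATCG", "d": "GACG"}
        hs = collapse_haplotypes(seqs)
        # column 2 dropped (M in 'a'): a=ACG, b=ACG, c=ACG? no: column idx 1
        # remaining columns 0,2,3: a,b,c -> "ACG"; d -> "GCG"
        assert len(hs) == 2
        assert sorted(hs.counts) == [1, 3]

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError, match="all columns"):
            collapse_haplotypes({"a": "MN", "b": "RN"})

    def test_per_population_counts(self):
        seqs = {"a": "AC", "b": "AC", "c": "GT"}
        pm = PopulationMap({"a": "east", "b": "west", "c": "west"})
        hs = collapse_haplotypes(seqs, pm)
        assert hs.pop_counts.loc["H1", "east"] == 1
        assert hs.pop_counts.loc["H2", "west"] == 1


def brute_force_mst_weight(haps):
    """Minimum total weight over all spanning trees, by exhaustive search."""
    from itertools import combinations

    n = len(haps)
    edges = [
        (hamming(haps[i], haps[j]), i, j) for i, j in combinations(range(n), 2)
    ]
    best = np.inf
    for tree in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for w, i, j in tree:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for w, _, _ in tree))
    return best


class TestHaplotypeNetwork:
    def test_two_haplotypes_single_edge(self):
        hs = collapse_haplotypes({"a": "AAAA", "b": "AATT"})
        g = haplotype_network(hs)
        assert g.number_of_edges() == 1
        assert g.edges["H1", "H2"]["weight"] == 2

    def test_star_topology(self):
        center = "AAAA"
        leaves = ["CAAA", "ATAA", "AACA", "AAAG"]
        seqs = {"c": center, **{f"l{i}": s for i, s in enumerate(leaves)}}
        g = haplotype_network(collapse_haplotypes(seqs))
        hs = collapse_haplotypes(seqs)
        center_label = [h for h, m in hs.members.items() if "c" in m][0]
        assert g.degree[center_label] == 4
        assert g.number_of_edges() == 4

    def test_connected_for_random_sets(self, rng):
        import networkx as nx

        for _ in range(5):
            haps = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(rng.integers(1, 7))]
            seqs = {f"s{i}": h for i, h in enumerate(haps)}
            g = haplotype_network(collapse_haplotypes(seqs))
            assert nx.is_connected(g) or g.number_of_nodes() == 1

    def test_mst_weight_matches_exhaustive_oracle(self, rng):
        import networkx as nx

        for trial in range(3):
            local = np.random.default_rng(50 + trial)
            haps = list({"".join(local.choice(list("ACGT"), 5)) for _ in range(6)})
            seqs = {f"s{i}": h for i, h in enumerate(haps)}
            hs = collapse_haplotypes(seqs)
            g = haplotype_network(hs)
            mst = nx.minimum_spanning_tree(g, weight="weight")
            got = sum(d["weight"] for _, _, d in mst.edges(data=True))
            assert got == brute_force_mst_weight(hs.haplotypes)

    def test_edge_table(self):
        g = haplotype_network(collapse_haplotypes({"a": "AA", "b": "AT"}))
        table = network_edge_table(g)
        assert list(table.columns) == ["hap_a", "hap_b", "steps"]
        assert len(table) == 1
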