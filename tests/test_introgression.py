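import numpy as np
import pandas as pd
import pytest

from parallelscan.core import MISSING, PopulationMap, RegionSet
from parallelscan.introgression import (
    TrioConfig,
    abba_baba,
    call_introgressed,
    f4_ratio,
    fd_windows,
    overlap_report,
    random_region_null,
    site_pattern_weights,
)
from parallelscan.window_stats import WindowSpec
from parallelscan.divergence_scan import HDRSet, chi_square_2x2
from parallelscan.introgression import IntrogressionSet

from conftest import make_gm

TRIO = TrioConfig("p1", "p2", "p3", "out")
POPMAP = PopulationMap(
    {
        "a1": "p1", "a2": "p1",
        "b1": "p2", "b2": "p2",
        "c1": "p3", "c2": "p3",
        "o1": "out", "o2": "out",
    }
)
SAMPLES = ["a1", "a2", "b1", "b2", "c1", "c2", "o1", "o2"]


def pattern_gm(patterns, spacing=100):
    """Build a matrix from per-site (p1, p2, p3, out) fixed dosage patterns."""
    cols = []
    for p1, p2, p3, o in patterns:
        cols.append([p1, p1, p2, p2, p3, p3, o, o])
    dosage = np.array(cols).T
    return make_gm(dosage, samples=SAMPLES, spacing=spacing)


ABBA = (0, 2, 2, 0)
BABA = (2, 0, 2, 0)


def brute_force_weights(gm, popmap, trio):
    """Independent per-site loop oracle for ABBA/BABA weight sums."""
    sum_abba = sum_baba = 0.0
    pops = {p: [gm.samples.index(s) for s in popmap.samples_in(p)]
            for p in (trio.p1, trio.p2, trio.p3, trio.outgroup)}
    for j in range(gm.n_sites):
        freqs = {}
        ok = True
        for pop, idx in pops.items():
            alleles = [gm.dosage[i, j] for i in idx if gm.dosage[i, j] != MISSING]
            if not alleles:
                ok = False
                break
            freqs[pop] = sum(alleles) / (2 * len(alleles))
        if not ok:
            continue
        po = freqs[trio.outgroup]
        if po == 0.5:
            continue
        if po > 0.5:
            freqs = {k: 1 - v for k, v in freqs.items()}
        p1, p2, p3, po = (freqs[p] for p in (trio.p1, trio.p2, trio.p3, trio.outgroup))
        sum_abba += (1 - p1) * p2 * p3 * (1 - po)
        sum_baba += p1 * (1 - p2) * p3 * (1 - po)
    return sum_abba, sum_baba


class TestAbbaBaba:
    def test_balanced_patterns_give_zero(self):
        gm = pattern_gm([ABBA] * 5 + [BABA] * 5)
        res = abba_baba(gm, POPMAP, TRIO, n_blocks=5, genome=[("chr1", 1000)])
        assert res.d == 0.0
        assert res.sum_abba == 5.0 and res.sum_baba == 5.0

    def test_all_abba_gives_one(self):
        gm = pattern_gm([ABBA] * 10)
        res = abba_baba(gm, POPMAP, TRIO, n_blocks=5, genome=[("chr1", 1000)])
        assert res.d == 1.0

    def test_weight_sums_match_loop_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(8, 200)).astype(np.int8)
        dosage[rng.random((8, 200)) < 0.05] = MISSING
        gm = make_gm(dosage, samples=SAMPLES, spacing=11)
        res = abba_baba(gm, POPMAP, TRIO, n_blocks=5, genome=[("chr1", 3000)])
        oa, ob = brute_force_weights(gm, POPMAP, TRIO)
        assert res.sum_abba == pytest.approx(oa, abs=1e-12)
        assert res.sum_baba == pytest.approx(ob, abs=1e-12)

    def test_swap_p1_p2_negates_d(self, null_sim):
        trio = TrioConfig("kan_east", "eca_east", "eca_west", "outgroup")
        genome = null_sim.truth.scenario.genome
        a = abba_baba(null_sim.genotypes, null_sim.popmap, trio, genome=genome)
        b = abba_baba(null_sim.genotypes, null_sim.popmap, trio.swapped(), genome=genome)
        assert b.d == pytest.approx(-a.d, abs=1e-12)
        assert abs(abs(a.z) - abs(b.z)) / max(abs(a.z), 1e-9) < 0.25 or abs(a.z) < 0.5

    def test_jackknife_block_count_stability(self, null_sim):
        trio = TrioConfig("kan_east", "eca_east", "eca_west", "outgroup")
        genome = null_sim.truth.scenario.genome
        z20 = abba_baba(null_sim.genotypes, null_sim.popmap, trio, n_blocks=20, genome=genome).z
        z40 = abba_baba(null_sim.genotypes, null_sim.popmap, trio, n_blocks=40, genome=genome).z
        assert abs(z40 - z20) <= 0.2 * max(abs(z20), 1.0)

    def test_no_informative_sites_errors(self):
        gm = pattern_gm([(0, 0, 0, 0)] * 3)
        with pytest.raises(ValueError):
            abba_baba(gm, POPMAP, TRIO, n_blocks=5, genome=[("chr1", 1000)])


class TestF4Ratio:
    def test_p2_copy_of_p3_gives_one(self, null_sim):
        """When P2 is literally a resampling of P3's population, the
        admixture fraction estimate approaches 1."""
        gm = null_sim.genotypes
        pm = null_sim.popmap
        donors = pm.samples_in("eca_west")
        half = len(donors) // 2
        assignment = dict(pm.assignment)
        # relabel half the donor population as a fake "P2"
        for s in donors[:half]:
            assignment[s] = "fake_p2"
        pm2 = PopulationMap(assignment)
        trio = TrioConfig("kan_west", "fake_p2", "eca_west", "outgroup")
        f = f4_ratio(gm, pm2, trio, seed=3)
        assert abs(f - 1.0) < 0.1

    def test_no_admixture_near_zero(self, null_sim):
        trio = TrioConfig("kan_east", "eca_east", "eca_west", "outgroup")
        f = f4_ratio(null_sim.genotypes, null_sim.popmap, trio, seed=3)
        assert abs(f) < 0.05

    def test_seeded_determinism(self, null_sim):
        trio = TrioConfig("kan_east", "eca_east", "eca_west", "outgroup")
        f1 = f4_ratio(null_sim.genotypes, null_sim.popmap, trio, seed=9)
        f2 = f4_ratio(null_sim.genotypes, null_sim.popmap, trio, seed=9)
        assert f1 == f2

    def test_small_p3_errors(self):
        pm = PopulationMap({**POPMAP.assignment, "c2": "p1"})  # P3 left with 1 sample
        gm = pattern_gm([ABBA] * 4)
        with pytest.raises(ValueError, match="P3"):
            f4_ratio(gm, pm, TRIO, seed=1)


class TestFdWindows:
    def test_equal_p2_p3_fd_one(self):
        # p2 == p3 at every site, D > 0 in the window
        gm = pattern_gm([(0, 1, 1, 0)] * 12, spacing=10)
        track = fd_windows(gm, POPMAP, TRIO, WindowSpec(size=5000), [("chr1", 5000)], min_informative=5)
        assert track["fd"].iloc[0] == pytest.approx(1.0)

    def test_negative_d_clamped_to_zero(self):
        gm = pattern_gm([BABA] * 12, spacing=10)
        track = fd_windows(gm, POPMAP, TRIO, WindowSpec(size=5000), [("chr1", 5000)], min_informative=5)
        assert track["fd"].iloc[0] == 0.0

    def test_sparse_window_undefined(self):
        gm = pattern_gm([ABBA] * 3, spacing=10)
        track = fd_windows(gm, POPMAP, TRIO, WindowSpec(size=5000), [("chr1", 5000)], min_informative=10)
        assert np.isnan(track["fd"].iloc[0])

    def test_matches_per_site_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(8, 90)).astype(np.int8)
        gm = make_gm(dosage, samples=SAMPLES, spacing=50)  # spans 3 windows of 1500bp
        track = fd_windows(
            gm, POPMAP, TRIO, WindowSpec(size=1500), [("chr1", 4500)], min_informative=1
        )
        # oracle: recompute numerator/denominator per window by direct loop
        for w, (ws, we) in enumerate([(0, 1500), (1500, 3000), (3000, 4500)]):
            num = den = 0.0
            for j in range(gm.n_sites):
                pos0 = gm.sites["pos"].iat[j] - 1
                if not ws <= pos0 < we:
                    continue
                freqs = {}
                for pop in ("p1", "p2", "p3", "out"):
                    idx = [gm.samples.index(s) for s in POPMAP.samples_in(pop)]
                    al = [gm.dosage[i, j] for i in idx if gm.dosage[i, j] != MISSING]
                    freqs[pop] = sum(al) / (2 * len(al))
                if freqs["out"] == 0.5:
                    continue
                if freqs["out"] > 0.5:
                    freqs = {k: 1 - v for k, v in freqs.items()}
                p1, p2, p3, po = freqs["p1"], freqs["p2"], freqs["p3"], freqs["out"]
                pdn = max(p2, p3)
                num += (1 - p1) * p2 * p3 * (1 - po) - p1 * (1 - p2) * p3 * (1 - po)
                den += (1 - p1) * pdn * pdn * (1 - po) - p1 * (1 - pdn) * pdn * (1 - po)
            fd = track["fd"].iloc[w]
            if num <= 0:
                assert fd == 0.0 or np.isnan(fd)
            elif den > 0:
                assert fd == pytest.approx(min(num / den, 1.0), abs=1e-12)


def fd_frame(fds, size=5000):
    n = len(fds)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * size,
            "end": (np.arange(n) + 1) * size,
            "n_informative": 50,
            "d_sign": 1.0,
            "fd": fds,
        }
    )


class TestCallIntrogressed:
    def test_target_zero_empty(self):
        assert len(call_introgressed(fd_frame([0.1, 0.2]), 0.0)) == 0

    def test_target_one_all_defined(self):
        track = fd_frame([0.1, np.nan, 0.3])
        result = call_introgressed(track, 1.0)
        assert len(result) == 2

    def test_top_k_sort_oracle(self, rng):
        fds = rng.random(10)
        track = fd_frame(fds)
        result = call_introgressed(track, 0.2)
        top2 = set(np.argsort(-fds)[:2])
        expected = {("chr1", int(i) * 5000, (int(i) + 1) * 5000) for i in top2}
        assert result.regions.as_set() == expected
        assert result.achieved_proportion == pytest.approx(0.2)

    def test_monotone_in_target(self, rng):
        track = fd_frame(rng.random(50))
        prev: set = set()
        for target in (0.1, 0.2, 0.5, 1.0):
            cur = call_introgressed(track, target).regions.as_set()
            assert prev <= cur
            prev = cur


class TestRandomRegionNull:
    def grid(self, n=40):
        return fd_frame(np.zeros(n))[["chrom", "start", "end"]]

    def test_constant_statistic_p_one(self):
        grid = self.grid()
        obs = RegionSet([("chr1", 0, 5000), ("chr1", 20000, 30000)])
        null = random_region_null(obs, [("chr1", 200000)], grid, np.full(40, 2.5), n=50, seed=1)
        assert np.allclose(null.replicates, null.observed)
        assert null.p_value == 1.0

    def test_maximal_observed_minimal_p(self):
        # Observed = the top-5 windows of a 200-window chromosome.  Random
        # placements tie only by landing on exactly those windows, which is
        # vanishingly unlikely, so the empirical p attains its floor.
        grid = self.grid(200)
        values = np.arange(200, dtype=float)
        obs = RegionSet([("chr1", i * 5000, (i + 1) * 5000) for i in range(195, 200)])
        null = random_region_null(obs, [("chr1", 1_000_000)], grid, values, n=99, seed=2)
        assert null.p_value == pytest.approx(1 / 100)

    def test_replicate_size_multiset_preserved(self):
        # sizes are implicitly preserved: re-run with a tracking statistic
        grid = self.grid()
        obs = RegionSet([("chr1", 0, 5000), ("chr1", 10000, 25000)])
        null = random_region_null(obs, [("chr1", 200000)], grid, np.ones(40), n=20, seed=3)
        # every replicate mean over 1s is 1 -> 4 windows always covered
        assert np.allclose(null.replicates, 1.0)

    def test_region_longer_than_chromosome_errors(self):
        grid = self.grid()
        with pytest.raises(ValueError, match="longer"):
            random_region_null(
                RegionSet([("chr1", 0, 500000)]), [("chr1", 200000)], grid, np.ones(40), n=5, seed=1
            )

    def test_empirical_p_bounds(self, rng):
        grid = self.grid()
        values = rng.normal(size=40)
        obs = RegionSet([("chr1", 50000, 55000)])
        null = random_region_null(obs, [("chr1", 200000)], grid, values, n=99, seed=4)
        assert 1 / 100 <= null.p_value <= 1.0


class TestOverlapReport:
    def hdrs(self, idx, n=40):
        return HDRSet(RegionSet([("chr1", i * 5000, (i + 1) * 5000) for i in idx]))

    def intro(self, idx):
        return IntrogressionSet(
            RegionSet([("chr1", i * 5000, (i + 1) * 5000) for i in idx]), 0.1, 0.1, 0.5
        )

    def test_full_and_zero_overlap(self):
        hdr = self.hdrs([0, 1, 2])
        assert overlap_report(self.intro(range(40)), hdr)["frac_hdrs_overlapping"] == 1.0
        assert overlap_report(self.intro([10, 11]), hdr)["frac_hdrs_overlapping"] == 0.0

    def test_chi_square_against_direct_formula(self):
        intro = self.intro([0, 1, 2, 3, 10, 11])
        hdr = self.hdrs(range(10))
        shared = self.hdrs(range(5))
        rep = overlap_report(intro, hdr, shared)
        # table: shared {0..4}: 4 overlap, 1 not; remaining {5..9}: 0 overlap, 5 not
        chi2, p = chi_square_2x2(np.array([[4, 1], [0, 5]], dtype=float))
        assert rep["chi2"] == pytest.approx(chi2)
        assert rep["p_value"] == pytest.approx(p)
        assert rep["frac_shared_overlapping"] == pytest.approx(0.8)
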