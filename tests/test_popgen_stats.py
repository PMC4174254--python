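import numpy as np
import pytest

from unidem.popgen_stats import (
    DistanceMatrix,
    amova,
    diversity_stats,
    great_circle_distances,
    mantel,
    mpd_ratio_resample,
    pairwise_differences,
    pairwise_phist,
)
from unidem.haplotype_io import SampleTable
import pandas as pd

from conftest import make_matrix


class TestDiversityStats:
    def test_four_haplotype_worked_example(self, fixtures):
        toy = fixtures["tajima4"]
        d = diversity_stats(toy["matrix"], L=toy["L"])
        exp = toy["expected"]
        assert d.S == exp["S"]
        assert d.mpd == pytest.approx(exp["mpd"], abs=1e-12)
        assert d.pi == pytest.approx(exp["pi"], abs=1e-12)
        assert d.H == pytest.approx(exp["H"], abs=1e-12)
        assert d.theta_S == pytest.approx(exp["theta_S"], abs=1e-12)
        assert d.tajimas_D == pytest.approx(exp["tajimas_D"], abs=1e-6)

    def test_monomorphic_sample(self):
        d = diversity_stats(make_matrix(["000", "000", "000"]), L=10)
        assert d.S == 0 and d.mpd == 0 and d.H == 0
        assert d.tajimas_D is None  # undefined, not zero

    def test_duplicated_haplotypes_pair_counting(self):
        # {A, A, B, B} with d(A,B)=k: 4 of 6 pairs differ -> mpd = (4/6) k
        k = 5
        rows = ["0" * k, "0" * k, "1" * k, "1" * k]
        d = diversity_stats(make_matrix(rows), L=k)
        assert d.mpd == pytest.approx(4 / 6 * k)

    def test_pi_equals_mpd_over_length(self, rng):
        G = rng.integers(0, 2, (8, 20)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        d = diversity_stats(m, L=777)
        assert d.pi == pytest.approx(d.mpd / 777, rel=1e-12)

    def test_invariance_to_reordering_and_polarity(self, rng):
        G = rng.integers(0, 2, (10, 25)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        base = diversity_stats(m, L=100)
        perm = rng.permutation(10)
        m2 = m.take_samples(list(perm))
        flip = rng.random(25) < 0.5
        G3 = G.copy()
        G3[:, flip] = 1 - G3[:, flip]
        m3 = make_matrix(["".join(map(str, r)) for r in G3])
        for other in (diversity_stats(m2, L=100), diversity_stats(m3, L=100)):
            assert other.S == base.S
            assert other.mpd == pytest.approx(base.mpd)
            assert other.H == pytest.approx(base.H)
            assert other.tajimas_D == pytest.approx(base.tajimas_D)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            diversity_stats(make_matrix(["010"]), L=3)


class TestPhiST:
    def test_fixed_populations_give_one(self):
        m = make_matrix(["000", "000", "111", "111"])
        dm, table = pairwise_phist(m, ["p1", "p1", "p2", "p2"], n_permutations=0)
        assert table["phi_st"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_two_plus_two(self, fixtures):
        toy = fixtures["phist22"]
        res = amova(toy["matrix"], toy["populations"], n_permutations=0)
        assert res.components["sigma_a"] == pytest.approx(toy["expected"]["sigma_a"])
        assert res.components["sigma_c"] == pytest.approx(toy["expected"]["sigma_c"])
        assert res.phi["phi_st"] == pytest.approx(toy["expected"]["phi_st"])

    def test_random_split_of_panmictic_set_near_zero(self, rng):
        G = rng.integers(0, 2, (20, 40)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        vals = []
        for _ in range(100):
            labels = np.array(["a"] * 10 + ["b"] * 10)
            rng.shuffle(labels)
            res = amova(m, labels, n_permutations=0)
            vals.append(res.phi["phi_st"])
        assert abs(np.mean(vals)) < 0.05

    def test_small_population_excluded_with_warning(self):
        m = make_matrix(["000", "001", "110", "111", "101"])
        with pytest.warns(UserWarning, match="n<2"):
            dm, table = pairwise_phist(
                m, ["p1", "p1", "p2", "p2", "tiny"], n_permutations=0
            )
        assert dm.labels == ["p1", "p2"]


class TestAmova:
    def test_two_level_matches_pairwise_phist_exactly(self, rng):
        G = rng.integers(0, 2, (12, 30)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        pops = ["a"] * 6 + ["b"] * 6
        res = amova(m, pops, n_permutations=0)
        _, table = pairwise_phist(m, pops, n_permutations=0)
        assert res.phi["phi_st"] == pytest.approx(table["phi_st"].iloc[0], rel=1e-12)

    def test_percentages_sum_to_100(self, rng):
        G = rng.integers(0, 2, (16, 30)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
        grps = ["g1"] * 8 + ["g2"] * 8
        for res in (amova(m, pops, n_permutations=0),
                    amova(m, pops, groups=grps, n_permutations=0)):
            assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_identical_population_composition(self):
        rows = ["000", "111"] * 4
        pops = ["a", "a", "b", "b", "c", "c", "d", "d"]
        res = amova(make_matrix(rows), pops, n_permutations=0)
        assert res.percentages["sigma_c"] == pytest.approx(100.0, abs=1e-6) or \
            res.percentages["sigma_c"] > 100  # negative among-component allowed

    def test_fixed_distinct_populations(self):
        rows = ["000", "000", "110", "110", "011", "011", "101", "101"]
        pops = ["a", "a", "b", "b", "c", "c", "d", "d"]
        res = amova(make_matrix(rows), pops, n_permutations=0)
        assert res.percentages["sigma_a"] == pytest.approx(100.0)

    def test_three_level_hand_computed_example(self):
        # frozen from an independent exact-arithmetic solve of the
        # sums-of-squares / expected-mean-squares equations
        rows = ["0000", "0001", "0011", "0011", "1100", "1110", "1111", "1101"]
        pops = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        grps = ["g1"] * 4 + ["g2"] * 4
        res = amova(make_matrix(rows), pops, groups=grps, n_permutations=0)
        assert res.components["sigma_a"] == pytest.approx(0.75)
        assert res.components["sigma_b"] == pytest.approx(0.375)
        assert res.components["sigma_c"] == pytest.approx(0.375)
        assert res.phi["phi_st"] == pytest.approx(0.75)
        assert res.phi["phi_ct"] == pytest.approx(0.5)
        assert res.phi["phi_sc"] == pytest.approx(0.5)
        assert res.ssd["total"] == pytest.approx(63 / 8)

    def test_degenerate_stratum_rejected(self):
        rows = ["00", "01", "10", "11"]
        pops = ["p1", "p1", "p2", "p2"]
        grps = ["g1", "g1", "g2", "g2"]  # one population per group
        with pytest.raises(ValueError, match="fewer than two populations"):
            amova(make_matrix(rows), pops, groups=grps, n_permutations=0)

    def test_permutation_p_value_detects_structure(self):
        rows = ["0000", "0000", "0001", "1111", "1111", "1110"]
        pops = ["a"] * 3 + ["b"] * 3
        res = amova(make_matrix(rows), pops, n_permutations=199, seed=0)
        assert res.p_values["phi_st"] < 0.2


class TestMpdRatio:
    def test_identical_matrices_ratio_one(self, rng):
        G = rng.integers(0, 2, (10, 30)).astype(np.int8)
        m = make_matrix(["".join(map(str, r)) for r in G])
        res = mpd_ratio_resample(m, m, m.sample_ids[:4], reps=200, seed=0)
        assert res.observed_ratio == pytest.approx(1.0)
        assert np.allclose(res.null_ratios, 1.0)

    def test_group_equals_universe_gives_p_one(self, rng):
        G = rng.integers(0, 2, (8, 30)).astype(np.int8)
        m1 = make_matrix(["".join(map(str, r)) for r in G])
        G2 = rng.integers(0, 2, (8, 30)).astype(np.int8)
        m2 = make_matrix(["".join(map(str, r)) for r in G2])
        res = mpd_ratio_resample(m1, m2, m1.sample_ids, reps=100, seed=0)
        assert res.p_value == 1.0
        assert np.allclose(res.null_ratios, res.observed_ratio)

    def test_monomorphic_mt_group_rejected(self):
        nry = make_matrix(["01", "10", "11", "00"])
        mt = make_matrix(["00", "00", "11", "11"])
        with pytest.raises(ValueError, match="undefined"):
            mpd_ratio_resample(nry, mt, ["h1", "h2"], reps=10, seed=0)


class TestMantelAndGeography:
    def _random_dm(self, rng, n=8):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return DistanceMatrix([f"p{i}" for i in range(n)], a)

    def test_identity_and_affine_give_r_one(self, rng):
        d1 = self._random_dm(rng)
        r, _ = mantel(d1, d1, reps=99, seed=0)
        assert r == pytest.approx(1.0)
        d2 = DistanceMatrix(d1.labels, 2 * d1.values + 3 * (1 - np.eye(8)))
        r, _ = mantel(d1, d2, reps=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_independent_matrices_center_on_zero(self, rng):
        rs = []
        for _ in range(50):
            r, _ = mantel(self._random_dm(rng, 12), self._random_dm(rng, 12),
                          reps=0, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        const = DistanceMatrix(labels, 1 - np.eye(4))
        other = DistanceMatrix(labels, np.abs(np.subtract.outer(range(4), range(4))) * 1.0)
        with pytest.raises(ValueError, match="constant"):
            mantel(const, other, reps=10, seed=0)

    def test_haversine_known_values(self):
        table = SampleTable(pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "sex": ["M"] * 3,
            "population": ["P1", "P2", "P3"],
            "region": ["Africa", "Africa", "Africa"],
            "latitude": [0.0, 0.0, 0.0],
            "longitude": [0.0, 180.0, 0.0],
            "excluded_flag": [False] * 3,
        }))
        dm = great_circle_distances(table, by="population")
        i, j = dm.labels.index("P1"), dm.labels.index("P2")
        assert dm.values[i, j] == pytest.approx(np.pi * 6371.0, rel=1e-6)
        k = dm.labels.index("P3")
        assert dm.values[i, k] == 0.0
        assert np.allclose(dm.values, dm.values.T)

    def test_population_without_coordinates_excluded(self):
        table = SampleTable(pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "sex": ["M"] * 3,
            "population": ["P1", "P2", "P3"],
            "region": ["Africa"] * 3,
            "latitude": [0.0, np.nan, 10.0],
            "longitude": [0.0, np.nan, 10.0],
            "excluded_flag": [False] * 3,
        }))
        with pytest.warns(UserWarning, match="lacks coordinates"):
            dm = great_circle_distances(table, by="population")
        assert dm.labels == ["P1", "P3"]


class TestPairwiseDifferences:
    def test_pairwise_deletion(self):
        m = make_matrix(["01N", "011", "NN1"])
        D = pairwise_differences(m)
        assert D[0, 1] == 0  # sites 1,2 both observed, equal
        assert D[1, 2] == 0  # only site 3 shared, equal
        assert D[0, 2] == 0  # no shared variable difference
        m2 = make_matrix(["00", "11"])
        assert pairwise_differences(m2)[0, 1] == 2
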