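import numpy as np
import pytest

from unidem import abc_inference as abc
from unidem import coalsim as cs
from unidem.popgen_stats import amova, diversity_stats, pairwise_phist


def constant_model(N=1000.0):
    """Degenerate history: every deme constant at N, ancient split times."""
    return cs.DemographicModel(
        T1=5e6, T2=4e5, T3=3e5, T4=2e5, T5=1e5, T6=5e4,
        N_anc_africa=N, N_ooa=N,
        N_anc={r: N for r in cs.REGION_ORDER[1:]},
        N_cur={r: N for r in cs.REGION_ORDER},
    )


class TestGenealogySimulation:
    def test_single_sample_is_a_leaf(self):
        cfg = cs.SampleConfig(counts={"Africa": 1, "Europe": 1})
        g = cs.simulate_genealogy(constant_model(), cs.SampleConfig(
            counts={"Africa": 1, "Europe": 1}), seed=0)
        assert g.n_leaves == 2
        single = cs.SampleConfig.__new__(cs.SampleConfig)  # bypass total>=2
        single.counts = {"Africa": 1}
        g1 = cs.simulate_genealogy(constant_model(), single, seed=0)
        assert g1.n_leaves == 1 and g1.tmrca == 0.0

    def test_pair_coalescence_time_matches_closed_form(self):
        N, reps = 500.0, 4000
        cfg = cs.SampleConfig(counts={"Africa": 2})
        t = np.array([
            cs.simulate_genealogy(constant_model(N), cfg, seed=i).tmrca
            for i in range(reps)
        ])
        se = t.std() / np.sqrt(reps)
        assert abs(t.mean() - N) < 3 * se

    def test_tmrca_n10_matches_closed_form(self):
        N, n, reps = 800.0, 10, 4000
        cfg = cs.SampleConfig(counts={"Africa": n})
        t = np.array([
            cs.simulate_genealogy(constant_model(N), cfg, seed=i).tmrca
            for i in range(reps)
        ])
        expect = 2 * N * (1 - 1 / n)
        se = t.std() / np.sqrt(reps)
        assert abs(t.mean() - expect) < 3 * se

    def test_invalid_time_ordering_rejected(self):
        with pytest.raises(ValueError, match="T1 > "):
            cs.DemographicModel(
                T1=1e5, T2=2e5, T3=9e4, T4=5e4, T5=3e4, T6=1e4,
                N_anc_africa=10, N_ooa=10,
                N_anc={r: 10 for r in cs.REGION_ORDER[1:]},
                N_cur={r: 100 for r in cs.REGION_ORDER},
            )

    def test_deterministic_given_seed(self):
        cfg = cs.SampleConfig()
        m = constant_model()
        g1 = cs.simulate_genealogy(m, cfg, seed=42)
        g2 = cs.simulate_genealogy(m, cfg, seed=42)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.allclose(g1.node_time, g2.node_time)


class TestMutationDropping:
    def test_zero_rate_means_zero_sites(self):
        cfg = cs.SampleConfig(counts={"Africa": 5})
        g = cs.simulate_genealogy(constant_model(), cfg, seed=0)
        locus = cs.LocusSpec("synthetic", [(1000, 1e-30)])
        m = cs.drop_mutations(g, locus, seed=0)
        assert m.n_sites == 0

    def test_fixed_pair_distance_poisson_mean(self):
        # two leaves joined at time t: E[#diffs] = 2 t mu L
        t, mu_site_year, L, g_years = 400.0, 1e-6, 1000, 25.0
        gen = cs.Genealogy(
            parent=np.array([2, 2, -1]),
            node_time=np.array([0.0, 0.0, t]),
            leaf_regions=np.array([0, 0]),
            region_names=list(cs.REGION_ORDER) + [cs.MENA],
            generation_time=g_years,
        )
        locus = cs.LocusSpec("synthetic", [(L, mu_site_year)])
        diffs = []
        for seed in range(2000):
            m = cs.drop_mutations(gen, locus, seed=seed)
            diffs.append(int((m.genotypes[0] != m.genotypes[1]).sum()))
        diffs = np.array(diffs)
        expect = 2 * t * mu_site_year * g_years * L
        se = diffs.std() / np.sqrt(len(diffs))
        assert abs(diffs.mean() - expect) < 3 * se

    def test_watterson_segregating_sites(self):
        # constant deme, n=10: E[S] = theta * a_9 with theta = 2 N mu_gen L
        N, n = 400.0, 10
        locus = cs.LocusSpec("synthetic", [(10_000, 4e-8)])
        mu_gen = 10_000 * 4e-8 * 25.0
        theta = 2 * N * mu_gen
        cfg = cs.SampleConfig(counts={"Africa": n})
        model = constant_model(N)
        S = []
        for seed in range(3000):
            g = cs.simulate_genealogy(model, cfg, seed=seed)
            S.append(cs.drop_mutations(g, locus, seed=seed + 1).n_sites)
        S = np.array(S)
        a9 = sum(1 / i for i in range(1, n))
        se = S.std() / np.sqrt(len(S))
        assert abs(S.mean() - theta * a9) < 3 * se

    def test_mpd_scales_linearly_with_rate(self):
        cfg = cs.SampleConfig(counts={"Africa": 8})
        model = constant_model(300.0)
        mpds = {}
        for factor in (1.0, 2.0):
            locus = cs.LocusSpec("synthetic", [(20_000, factor * 2e-8)])
            vals = []
            for seed in range(1500):
                agg = cs.simulate_aggregates(model, cfg, locus, seed=seed)
                stats = cs.stats_from_aggregates(*agg)
                vals.append(stats[1])  # mpd_Africa
            mpds[factor] = np.array(vals)
        ratio = mpds[2.0].mean() / mpds[1.0].mean()
        se = ratio * np.sqrt(
            mpds[2.0].std() ** 2 / mpds[2.0].mean() ** 2
            + mpds[1.0].std() ** 2 / mpds[1.0].mean() ** 2
        ) / np.sqrt(1500)
        assert abs(ratio - 2.0) < 4 * se

    def test_infinite_sites_positions_distinct(self):
        cfg = cs.SampleConfig(counts={"Africa": 10})
        g = cs.simulate_genealogy(constant_model(), cfg, seed=3)
        m = cs.drop_mutations(g, cs.nry_locus(), seed=4)
        positions = m.positions
        assert len(np.unique(positions)) == len(positions)
        assert (np.diff(positions) > 0).all()


class TestPriors:
    def test_draws_respect_ordering_and_support(self, rng):
        priors = cs.PriorSpec()
        for _ in range(500):
            model = cs.draw_parameters(priors, rng)
            times = model.times_years
            assert (times[:-1] > times[1:]).all()
            assert model.T2 > model.T3
            assert 10_000 <= model.T6 <= 20_000
            assert 100_000 <= model.T1 <= 150_000

    def test_size_prior_support(self, rng):
        priors = cs.PriorSpec()
        draws = [cs.draw_parameters(priors, rng) for _ in range(300)]
        anc = np.array([m.N_anc_africa for m in draws])
        cur = np.array([m.N_cur["Africa"] for m in draws])
        assert anc.min() >= 1.0 and anc.max() <= 1e4
        assert cur.min() >= 1e2 and cur.max() <= 2e5

    def test_deterministic_given_seed(self):
        p = cs.PriorSpec()
        d1 = cs.draw_parameters(p, np.random.default_rng(7))
        d2 = cs.draw_parameters(p, np.random.default_rng(7))
        assert d1 == d2

    def test_empty_prior_range_rejected(self):
        with pytest.raises(ValueError):
            cs.PriorSpec(time_ranges={**cs.PriorSpec().time_ranges,
                                      "T6": (20_000.0, 20_000.0)})


class TestStatisticalConsistency:
    """The branch-aggregate fast path must agree with the matrix route."""

    def test_aggregate_stats_match_matrix_statistics(self):
        model = constant_model(400.0)
        cfg = cs.SampleConfig(counts={r: 6 for r in cs.REGION_ORDER})
        g = cs.simulate_genealogy(model, cfg, seed=9)
        m = cs.drop_mutations(g, cs.LocusSpec("synthetic", [(50_000, 2e-8)]),
                              seed=10)
        regions = [g.region_names[r] for r in g.leaf_regions]
        vec = abc.summarize(nry=m, region_labels=regions)
        labels = cs.stat_labels()
        # per-region S / mpd / D against diversity_stats on the subset
        for i, region in enumerate(cs.REGION_ORDER):
            idx = [k for k, r in enumerate(regions) if r == region]
            d = diversity_stats(m.take_samples(idx), L=50_000)
            assert vec[3 * i] == d.S
            assert vec[3 * i + 1] == pytest.approx(d.mpd, rel=1e-9)
            assert vec[3 * i + 2] == pytest.approx(d.tajimas_D, rel=1e-9)
        # pairwise Phi_ST against the AMOVA-based implementation
        pops = np.array(regions)
        dm, table = pairwise_phist(m, regions, n_permutations=0)
        offset = 3 * len(cs.REGION_ORDER)
        k = 0
        for i, r1 in enumerate(cs.REGION_ORDER):
            for r2 in cs.REGION_ORDER[i + 1:]:
                row = table[((table.pop1 == r1) & (table.pop2 == r2))
                            | ((table.pop1 == r2) & (table.pop2 == r1))]
                assert vec[offset + k] == pytest.approx(
                    row["phi_st"].iloc[0], rel=1e-9, abs=1e-12
                )
                k += 1
        # Africa vs pooled non-Africa AMOVA components
        two_pop = ["Africa" if r == "Africa" else "nonAfrica" for r in regions]
        res = amova(m, two_pop, n_permutations=0)
        assert vec[offset + k] == pytest.approx(res.components["sigma_a"], rel=1e-9)
        assert vec[offset + k + 1] == pytest.approx(res.components["sigma_c"], rel=1e-9)

    def test_panmixia_degeneracy_phi_near_zero(self):
        # equal sizes everywhere and (near-)zero split times: region labels
        # exchangeable, so Phi_ST across regions should center on zero
        model = cs.DemographicModel(
            T1=2e6, T2=150.0, T3=125.0, T4=100.0, T5=75.0, T6=50.0,
            N_anc_africa=500.0, N_ooa=500.0,
            N_anc={r: 500.0 for r in cs.REGION_ORDER[1:]},
            N_cur={r: 500.0 for r in cs.REGION_ORDER},
        )
        cfg = cs.SampleConfig(counts={r: 8 for r in cs.REGION_ORDER})
        locus = cs.LocusSpec("synthetic", [(50_000, 4e-8)])
        phis = []
        for seed in range(400):
            agg = cs.simulate_aggregates(model, cfg, locus, seed=seed)
            vec = cs.stats_from_aggregates(*agg)
            phis.extend(vec[18:33][np.isfinite(vec[18:33])])
        assert abs(np.mean(phis)) < 0.02

    def test_locus_defaults_match_study_constants(self):
        mt = cs.mtdna_locus()
        assert mt.total_length == 16_569
        assert mt.partitions == [(1_122, 9.883e-8), (15_447, 1.708e-8)]
        nry = cs.nry_locus()
        assert nry.partitions == [(501_108, (1.00e-9 + 6.17e-10) / 2)]
        cfg = cs.SampleConfig()
        assert cfg.total == 511
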