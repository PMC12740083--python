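"""Synthetic universe/DEG generation and beta recovery."""

import numpy as np
import pytest

import stratashift as ss
from stratashift.errors import ConfigurationError, InputError


class TestConfig:
    def test_composition_must_sum_to_one(self):
        bad = np.full(19, 1 / 19) * 1.01
        with pytest.raises(ConfigurationError):
            ss.SyntheticConfig(composition=bad)

    def test_degenerate_composition_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.SyntheticConfig(composition=np.zeros(19))

    def test_n_deg_bounded_by_universe(self):
        with pytest.raises(ConfigurationError):
            ss.SyntheticConfig(universe_size=100, n_deg=101)


class TestSampleUniverse:
    def test_point_mass_composition(self):
        comp = np.zeros(19)
        comp[0] = 1.0
        m = ss.sample_universe(
            ss.SyntheticConfig(universe_size=50, n_deg=10, composition=comp, seed=1)
        )
        assert (m.entries == 1).all()

    def test_uniform_composition_counts_within_tail_bound(self):
        comp = np.full(19, 1 / 19)
        m = ss.sample_universe(
            ss.SyntheticConfig(universe_size=19_000, composition=comp, seed=0)
        )
        counts = m.universe().M
        sd = np.sqrt(19_000 * (1 / 19) * (18 / 19))
        assert np.all(np.abs(counts - 1000) <= 5 * sd)

    def test_determinism(self):
        cfg = ss.SyntheticConfig(universe_size=300, n_deg=30, seed=42)
        a = ss.sample_universe(cfg)
        b = ss.sample_universe(cfg)
        assert a.entries.equals(b.entries)


class TestSampleDegSet:
    def test_null_draw_matches_hypergeometric_expectation(self):
        # beta = 0: expected per-stratum count is n*M_s/N; check over replicates
        cfg = ss.SyntheticConfig(universe_size=3000, n_deg=150, seed=0)
        universe_map = ss.sample_universe(cfg)
        uni = universe_map.universe()
        reps = 500
        rng = np.random.default_rng(0)
        counts = np.zeros(19)
        for _ in range(reps):
            deg = ss.sample_deg_set(universe_map, cfg, rng)
            counts += deg.stratum_counts()
        mean = counts / reps
        expect = cfg.n_deg * uni.M / uni.N
        # SE of the replicate mean from the hypergeometric variance
        var = (
            cfg.n_deg
            * (uni.M / uni.N)
            * (1 - uni.M / uni.N)
            * (uni.N - cfg.n_deg)
            / (uni.N - 1)
        )
        se = np.sqrt(var / reps)
        ok = se > 0
        assert np.all(np.abs(mean[ok] - expect[ok]) <= 3.5 * se[ok])

    def test_extreme_beta_takes_only_most_ancient(self):
        comp = np.full(19, 1 / 19)
        cfg = ss.SyntheticConfig(
            universe_size=1900, composition=comp, n_deg=50, beta=50.0, seed=3
        )
        universe_map = ss.sample_universe(cfg)
        deg = ss.sample_deg_set(universe_map, cfg)
        assert (deg.ranks == 1).all()

    def test_symmetric_direction_model(self):
        cfg = ss.SyntheticConfig(universe_size=4000, n_deg=2000, seed=5)
        universe_map = ss.sample_universe(cfg)
        deg = ss.sample_deg_set(universe_map, cfg)
        frac_up = (deg.records["direction"] == "up").mean()
        assert abs(frac_up - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_direction_model_slope(self):
        # positive slope: young strata more often upregulated
        cfg = ss.SyntheticConfig(
            universe_size=8000, n_deg=4000, seed=5, p_up_slope=0.4, p_up_intercept=-4.0
        )
        universe_map = ss.sample_universe(cfg)
        deg = ss.sample_deg_set(universe_map, cfg)
        rec = deg.records
        old = rec[rec["rank"] <= 5]
        young = rec[rec["rank"] >= 15]
        assert (young["direction"] == "up").mean() > (old["direction"] == "up").mean()

    def test_bundle_determinism_byte_identical(self, tmp_path):
        cfg = ss.SyntheticConfig(universe_size=500, n_deg=50, beta=0.3, seed=12)
        for d in ("a", "b"):
            ss.make_bundle(cfg).write(tmp_path / d)
        for f in ("universe.tsv", "degs.tsv", "truth.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_bundle_round_trips_through_ingest(self, tmp_path):
        cfg = ss.SyntheticConfig(universe_size=600, n_deg=80, beta=0.4, seed=2)
        bundle = ss.make_bundle(cfg)
        bundle.write(tmp_path)
        ages = ss.load_gene_ages(tmp_path / "universe.tsv", ss.StrataScale.default())
        deg = ss.read_deg_table(tmp_path / "degs.tsv").intersect(ages)
        assert deg.n == 80
        assert deg.n_unmapped == 0
        assert np.array_equal(
            np.sort(deg.records["gene"].to_numpy()),
            np.sort(bundle.deg_set.records["gene"].to_numpy()),
        )


class TestEstimateBeta:
    def test_null_draw_estimates_near_zero(self):
        cfg = ss.SyntheticConfig(universe_size=19_000, n_deg=5000, seed=0)
        universe_map = ss.sample_universe(cfg)
        deg = ss.sample_deg_set(universe_map, cfg)
        est = ss.estimate_beta(deg, universe_map.universe())
        assert abs(est.beta) < 0.05
        assert not est.at_upper_bound

    def test_recovery_at_moderate_bias(self):
        cfg = ss.SyntheticConfig(universe_size=19_000, n_deg=5000, beta=0.5, seed=1)
        universe_map = ss.sample_universe(cfg)
        deg = ss.sample_deg_set(universe_map, cfg)
        est = ss.estimate_beta(deg, universe_map.universe())
        assert 0.4 <= est.beta <= 0.6

    def test_all_most_ancient_hits_upper_bound(self):
        uni = ss.UniverseDistribution(N=190, M=np.full(19, 10))
        est = ss.estimate_beta(np.ones(10, dtype=int), uni)
        assert est.at_upper_bound
        assert est.beta == pytest.approx(50.0)

    def test_expected_mean_rank_decreases_in_beta(self, small_universe):
        means = [ss.expected_mean_rank(b, small_universe, 200) for b in (0.0, 0.25, 0.5, 1.0)]
        assert means[0] == pytest.approx(small_universe.mean_rank, rel=1e-9)
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_consistency_bias_shrinks_with_n(self):
        # RMSE of beta-hat shrinks as the set grows
        rng = np.random.default_rng(0)
        cfg = ss.SyntheticConfig(universe_size=19_000, seed=0)
        universe_map = ss.sample_universe(cfg)
        uni = universe_map.universe()
        ranks_all = universe_map.entries.to_numpy()
        rmse = []
        for n in (200, 1000, 5000):
            errs = []
            for _ in range(20):
                keys = -0.5 * (ranks_all - 1) + rng.gumbel(size=ranks_all.size)
                idx = np.argpartition(-keys, n - 1)[:n]
                errs.append(ss.estimate_beta(ranks_all[idx], uni).beta - 0.5)
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2] < rmse[0]

    def test_empty_set_rejected(self, small_universe):
        with pytest.raises(InputError):
            ss.estimate_beta(np.array([]), small_universe)
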