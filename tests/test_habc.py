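"""Hierarchical ABC engine: hyperprior, rejection, adjustment, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codivabc import (
    HyperPrior,
    PairMeta,
    SimTable,
    abc_reject,
    draw_hyper,
    effective_migrants,
    omega,
    regression_adjust,
    run_simulations,
    summarize,
)
from codivabc.abc import PARAM_COLUMNS, _kde_mode, observed_vector, psi_mode_logit
from codivabc.priors import draw_hyper_batch
from codivabc.stats import study_vector_names

TINY_META = [PairMeta(f"p{i}", 4, 4, 120, 1.0) for i in range(3)]


def tiny_prior(**kw):
    base = dict(n_pairs=3, tau_max=3.0, theta_max=0.02, m_mean=0.0,
                n_sims=10_000, n_accept=100)
    base.update(kw)
    return HyperPrior(**base)


class TestOmega:
    def test_zero_variance(self):
        assert omega([1.0, 1.0, 1.0]) == 0.0

    def test_population_variance_convention(self):
        assert omega([0.0, 2.0]) == pytest.approx(1.0)

    def test_var_nine_mean_five(self):
        assert omega([2.0, 2.0, 8.0, 8.0]) == pytest.approx(1.8)

    def test_all_zero_times(self):
        assert omega([0.0, 0.0]) == 0.0

    def test_sample_variance_flag(self):
        assert omega([0.0, 2.0], sample_variance=True) == pytest.approx(2.0)

    def test_scale_covariance(self, rng):
        for _ in range(20):
            taus = rng.uniform(0.01, 3.0, size=int(rng.integers(2, 9)))
            c = float(rng.uniform(0.1, 10))
            assert omega(c * taus) == pytest.approx(c * omega(taus))


class TestEffectiveMigrants:
    def test_zero_migration(self):
        assert effective_migrants(0.0, 1.2) == 0.0

    def test_stated_convention(self):
        assert effective_migrants(0.5, 2.0) == pytest.approx(0.5)

    def test_linear_in_theta(self):
        assert effective_migrants(0.3, 2.0) == pytest.approx(
            2 * effective_migrants(0.3, 1.0))


class TestHyperPrior:
    def test_psi_max_one_forces_shared_tau(self, rng):
        prior = tiny_prior(psi_max=1)
        for _ in range(50):
            d = draw_hyper(prior, TINY_META, rng)
            assert d.psi == 1
            assert np.unique(d.tau_per_pair).size == 1
            assert omega(d.tau_per_pair) == pytest.approx(0.0, abs=1e-12)

    def test_pair_tau_consistent_with_assignment(self, rng):
        prior = tiny_prior()
        for _ in range(50):
            d = draw_hyper(prior, TINY_META, rng)
            assert d.psi <= prior.psi_max
            assert np.array_equal(d.tau_per_pair,
                                  d.tau_values[d.assignment])
            assert 1 <= d.psi_realized <= d.psi

    def test_psi_uniform_chi_square(self, rng):
        prior = tiny_prior()
        b = draw_hyper_batch(prior, TINY_META, 10_000, rng)
        counts = np.bincount(b["psi"], minlength=4)[1:]
        chi2, p = sps.chisquare(counts)
        assert p > 0.01

    def test_same_class_probability_given_psi2(self, rng):
        meta = TINY_META[:2]
        prior = HyperPrior(n_pairs=2, psi_max=2, theta_max=0.02,
                           n_sims=1000, n_accept=10)
        b = draw_hyper_batch(prior, meta, 20_000, rng)
        sel = b["psi"] == 2
        same = (b["assignment"][sel, 0] == b["assignment"][sel, 1]).mean()
        n = sel.sum()
        assert abs(same - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            tiny_prior(psi_max=4)
        with pytest.raises(ValueError):
            tiny_prior(n_accept=20_000)


class TestRejection:
    @pytest.fixture(scope="class")
    def table(self):
        return run_simulations(tiny_prior(), TINY_META, seed=5, n_sims=2000)

    def test_observed_row_accepted_at_distance_zero(self, table):
        obs = table.stats[17].copy()
        accepted, distances = abc_reject(obs, table, 10)
        assert accepted[0] == 17
        assert distances[17] == 0.0

    def test_accept_all_is_identity(self, table):
        accepted, _ = abc_reject(table.stats[0], table, table.n_sims)
        assert np.array_equal(np.sort(accepted), np.arange(table.n_sims))

    def test_accepted_distances_below_rejected(self, table):
        obs = table.stats.mean(axis=0)
        accepted, distances = abc_reject(obs, table, 50)
        rejected = np.setdiff1d(np.arange(table.n_sims), accepted)
        assert distances[accepted].max() <= distances[rejected].min()

    def test_zero_variance_column_excluded_with_warning(self, table):
        stats = table.stats.copy()
        stats[:, 3] = 1.234
        t2 = SimTable(params=table.params, stats=stats,
                      stat_names=table.stat_names, provenance={})
        with pytest.warns(UserWarning, match="zero-variance"):
            accepted, _ = abc_reject(stats[0], t2, 10)
        assert accepted[0] == 0

    def test_layout_mismatch_rejected(self, table):
        with pytest.raises(ValueError, match="entries"):
            abc_reject(np.zeros(3), table, 10)


class TestRegressionAdjustment:
    def _table_from_arrays(self, params, stats):
        n = len(params["omega"])
        df = pd.DataFrame({k: params.get(k, np.zeros(n)) for k in PARAM_COLUMNS})
        names = [f"s{i}" for i in range(stats.shape[1])]
        return SimTable(params=df, stats=stats, stat_names=names, provenance={})

    def test_uncorrelated_statistics_leave_draws_unchanged(self, rng):
        # statistic orthogonal to the parameter: regression slope ~ 0
        n = 2000
        om = rng.uniform(0, 2, n)
        stats = np.column_stack([rng.normal(size=n)])
        table = self._table_from_arrays({"omega": om, "e_tau": om}, stats)
        obs = np.array([0.0])
        accepted = np.arange(n)
        distances = np.abs(stats[:, 0])
        adj = regression_adjust(table, accepted, obs, distances, tau_max=3.0)
        # slope is O(1/sqrt(n)); adjusted draws stay close to the originals
        assert np.corrcoef(adj["omega"], om)[0, 1] > 0.99

    def test_perfectly_linear_relation_collapses_to_truth(self, rng):
        n = 300
        s = rng.normal(size=n)
        om = 1.0 + 0.5 * s  # exact linear parameter-statistic relation
        stats = s[:, None]
        table = self._table_from_arrays({"omega": om, "e_tau": om}, stats)
        obs = np.array([0.0])  # truth at s=0 is omega=1
        accepted = np.arange(n)
        distances = np.abs(s)
        adj = regression_adjust(table, accepted, obs, distances, tau_max=3.0)
        np.testing.assert_allclose(adj["omega"], 1.0, atol=1e-8)

    def test_adjusted_omega_clamped_nonnegative(self, rng):
        n = 200
        s = rng.normal(size=n)
        om = np.clip(0.05 + 0.5 * s, 0, None)
        table = self._table_from_arrays({"omega": om, "e_tau": om}, s[:, None])
        adj = regression_adjust(table, np.arange(n), np.array([-5.0]),
                                np.abs(s + 5), tau_max=3.0)
        assert (adj["omega"] >= 0).all()


class TestSummaries:
    def _params_frame(self, psi, om, e_tau=None):
        n = len(psi)
        return pd.DataFrame({
            "psi": psi, "psi_realized": psi,
            "e_tau": e_tau if e_tau is not None else np.ones(n),
            "var_tau": np.zeros(n), "omega": om,
        })

    def test_degenerate_accepted_set(self):
        df = self._params_frame([2] * 6, [0.7] * 6)
        s = summarize(df)
        assert s.psi_mode == 2
        for val in (s.omega_mode, s.omega_mean, s.omega_q025, s.omega_q975):
            assert val == pytest.approx(0.7)

    def test_psi_counts(self):
        df = self._params_frame([1, 1, 1, 2], [0.1, 0.2, 0.3, 0.4])
        s = summarize(df)
        assert s.psi_mode == 1
        assert s.psi_mean == pytest.approx(1.25)

    def test_kde_mode_near_peak_of_unimodal_sample(self, rng):
        x = rng.normal(3.0, 0.5, size=2000)
        bw = 1.06 * x.std() * x.size ** (-1 / 5)  # Silverman scale
        assert abs(_kde_mode(x) - 3.0) < 2 * bw

    def test_logit_single_category_fallback(self):
        table = run_simulations(tiny_prior(psi_max=1), TINY_META, seed=2,
                                n_sims=200)
        obs = table.stats[0]
        accepted, distances = abc_reject(obs, table, 20)
        mode, probs = psi_mode_logit(table, accepted, obs, distances)
        assert mode == 1 and probs == {1: 1.0}


class TestDistanceFeatures:
    def test_hyper_features_have_fixed_dimension(self, rng):
        from codivabc.abc import distance_features

        for Y in (2, 5, 10):
            meta = [PairMeta(f"p{i}", 4, 4, 100, 1.0) for i in range(Y)]
            vec = rng.normal(size=8 * Y + 16)
            feats = distance_features(vec, meta, "hyper")
            assert feats.shape == (16,)
            mat = distance_features(rng.normal(size=(7, 8 * Y + 16)), meta, "hyper")
            assert mat.shape == (7, 16)

    def test_rate_normalization_equalizes_divergence_scales(self):
        from codivabc.abc import distance_features
        from codivabc.stats import study_vector

        # two pairs with identical per-unit-time divergence, one on a 20x
        # locus: normalized features see zero across-pair variance
        slow = np.array([0.01, 0.01, 0.05, 0.04, 0.01, 0.01, 0.0, 0.0])
        fast = slow.copy()
        fast[2:4] *= 20.0
        vec = study_vector(np.vstack([slow, fast]))
        meta = [PairMeta("s", 4, 4, 100, 1.0), PairMeta("f", 4, 4, 100, 20.0)]
        feats = distance_features(vec, meta, "hyper")
        names_var_pib, names_var_pinet = 8 + 2, 8 + 3
        assert feats[names_var_pib] == pytest.approx(0.0, abs=1e-15)
        assert feats[names_var_pinet] == pytest.approx(0.0, abs=1e-15)

    def test_unknown_mode_rejected(self):
        from codivabc.abc import distance_features

        with pytest.raises(ValueError, match="feature mode"):
            distance_features(np.zeros(32), [PairMeta("p", 4, 4, 100, 1.0)] * 2,
                              "bogus")

    def test_hyper_rejection_matches_manual_distance(self):
        from codivabc.abc import distance_features

        table = run_simulations(tiny_prior(), TINY_META, seed=21, n_sims=500)
        obs = table.stats[7]
        accepted, distances = abc_reject(obs, table, 20, pair_meta=TINY_META,
                                         feature_mode="hyper")
        F = distance_features(table.stats, TINY_META, "hyper")
        fo = distance_features(obs, TINY_META, "hyper")
        sd = F.std(axis=0)
        keep = sd > 1e-12 * np.maximum(1, np.abs(F.mean(axis=0)))
        z = (F[:, keep] - fo[keep]) / sd[keep]
        manual = np.sqrt((z ** 2).sum(axis=1))
        np.testing.assert_allclose(distances, manual)
        assert accepted[0] == 7 and distances[7] == 0.0


class TestPriorRecovery:
    def test_accept_all_recovers_uniform_psi(self):
        """With n_accept = n_sims the posterior equals the uniform prior."""
        prior = tiny_prior(n_sims=20_000, n_accept=20_000)
        table = run_simulations(prior, TINY_META, seed=11, n_sims=20_000)
        # observed vector = an arbitrary simulated row
        obs = table.stats[123]
        accepted, _ = abc_reject(obs, table, 20_000)
        psi = table.params["psi"].to_numpy(int)[accepted]
        counts = np.bincount(psi, minlength=4)[1:]
        chi2, p = sps.chisquare(counts)
        assert p > 0.01


class TestSimTableRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        table = run_simulations(tiny_prior(), TINY_META, seed=9, n_sims=100)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = SimTable.from_tsv(path)
        assert back.stat_names == table.stat_names
        assert back.provenance["seed"] == 9
        np.testing.assert_allclose(back.stats, table.stats, rtol=1e-9)
        np.testing.assert_allclose(back.params.to_numpy(),
                                   table.params.to_numpy(), rtol=1e-9)

    def test_stat_names_match_layout(self):
        table = run_simulations(tiny_prior(), TINY_META, seed=1, n_sims=50)
        assert table.stat_names == study_vector_names(3)
        assert table.stats.shape == (50, 3 * 8 + 16)
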