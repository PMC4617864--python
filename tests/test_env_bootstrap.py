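"""Climatology smoothing, residuals, blocks, reconstruction, bootstrap loop."""

import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

from jellybloom import env_bootstrap as eb
from jellybloom import synthetic_data as sd


def env_table(values_by_year, site_id=0, var_value=None):
    """Daily table for one site, one variable pattern repeated over years."""
    frames = []
    for year, vals in values_by_year.items():
        dates = sd.season_dates(year)
        row = {
            "site_id": site_id, "date": dates,
        }
        for v in sd.ENV_VARS:
            row[v] = np.full(len(dates), float(vals)) if np.isscalar(vals) \
                else np.asarray(vals, dtype=float)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


class TestSmoothSeries:
    def test_constant_series(self):
        env = env_table({2007: 3.5, 2008: 3.5})
        sm = eb.smooth_series(env, 15)
        np.testing.assert_allclose(sm.mean, 3.5)
        np.testing.assert_allclose(sm.sd, 0.0)

    def test_two_year_pooled_sd(self):
        """Years at constant 0 and 2: every focal day pools 15 zeros and 15
        twos → mean 1, sample SD sqrt(30/29) ≈ 1.0171 (edge days included,
        because boundary repetition keeps the pool size constant)."""
        env = env_table({2007: 0.0, 2008: 2.0})
        sm = eb.smooth_series(env, 15)
        np.testing.assert_allclose(sm.mean, 1.0)
        np.testing.assert_allclose(sm.sd, np.sqrt(30.0 / 29.0), rtol=1e-12)

    def test_pool_size_is_window_times_years(self):
        # variance of iid N(0,1) pooled over 15 days x 4 years has SE ~ 1/sqrt(2*59)
        rng = np.random.default_rng(0)
        env = env_table({y: rng.standard_normal(153) for y in range(2007, 2011)})
        sm = eb.smooth_series(env, 15)
        assert abs(np.mean(sm.sd) - 1.0) < 0.05

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            eb.smooth_series(env_table({2007: 1.0, 2008: 1.0}), 14)

    def test_window_longer_than_season_rejected(self):
        with pytest.raises(ValueError, match="season"):
            eb.smooth_series(env_table({2007: 1.0, 2008: 1.0}), 155)


class TestStandardizeResiduals:
    def test_mean_and_unit_offsets(self):
        env = env_table({2007: 0.0, 2008: 2.0})
        sm = eb.smooth_series(env, 15)
        res = eb.standardize_residuals(env, sm)
        # year 2007 sits (0-1)/sd below, year 2008 (2-1)/sd above
        expect = 1.0 / np.sqrt(30.0 / 29.0)
        np.testing.assert_allclose(res.values[:, :, 0, :], -expect, rtol=1e-12)
        np.testing.assert_allclose(res.values[:, :, 1, :], +expect, rtol=1e-12)

    def test_zero_sd_day_yields_zero_residual(self):
        env = env_table({2007: 1.0, 2008: 1.0})
        sm = eb.smooth_series(env, 15)
        with pytest.warns(UserWarning, match="zero climatological SD"):
            res = eb.standardize_residuals(env, sm)
        np.testing.assert_allclose(res.values, 0.0)

    def test_roundtrip_identity(self, small_env):
        arr = eb.env_to_arrays(small_env)
        sm = eb.smooth_series(arr, 15)
        res = eb.standardize_residuals(arr, sm)
        rec = eb.reconstruct(res, sm)
        np.testing.assert_allclose(rec, arr.values, atol=1e-10)

    def test_residuals_near_standardized(self, small_env):
        arr = eb.env_to_arrays(small_env)
        res = eb.standardize_residuals(arr, eb.smooth_series(arr, 15))
        assert abs(res.values.mean()) < 0.05
        assert abs(res.values.std() - 1.0) < 0.1


class TestDecorrelationTime:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        assert eb.decorrelation_time(x, max_lag=10) == 1

    def test_iid_series_short_time(self):
        hits = [
            eb.decorrelation_time(
                np.random.default_rng(s).standard_normal(10_000), max_lag=60
            )
            for s in range(40)
        ]
        assert np.mean(np.array(hits) <= 5) >= 0.95

    def test_stronger_ar_longer_decorrelation(self):
        def ar1(phi, seed, n=10_000):
            rng = np.random.default_rng(seed)
            x = np.empty(n)
            x[0] = rng.standard_normal()
            for i in range(1, n):
                x[i] = phi * x[i - 1] + rng.standard_normal()
            return x

        wins = sum(
            eb.decorrelation_time(ar1(0.9, s), max_lag=200)
            > eb.decorrelation_time(ar1(0.5, s + 500), max_lag=200)
            for s in range(10)
        )
        assert wins >= 9

    def test_per_variable_dict(self, small_env):
        res = eb.standardize_residuals(
            small_env, eb.smooth_series(small_env, 15)
        )
        per_var = eb.decorrelation_time(res)
        assert set(per_var) == set(sd.ENV_VARS)
        assert all(1 <= v <= 60 for v in per_var.values())


class TestSkewnessDiagnostic:
    def make_series(self, values, mean=0.0):
        v = np.asarray(values, float)[None, None, None, :]
        res = eb.ResidualSeries(values=v, variables=["sst"],
                                site_ids=np.array([0]), years=np.array([2007]))
        sm = eb.SmoothedSeries(
            mean=np.full((1, 1, v.shape[-1]), mean),
            sd=np.ones((1, 1, v.shape[-1])),
            window_days=3, variables=["sst"], site_ids=np.array([0]),
        )
        return res, sm

    def test_hand_computed_index(self):
        # window (0, 0, 3): m2 = 2, m3 = 2 → index 1.0 (1/n moments)
        res, sm = self.make_series([0.0, 0.0, 3.0])
        table, _ = eb.skewness_diagnostic(res, sm, window_days=3)
        assert table["skew_index"].iloc[0] == pytest.approx(1.0)

    def test_symmetric_residuals_small_index(self):
        rng = np.random.default_rng(1)
        res, sm = self.make_series(rng.standard_normal(15_000))
        table, _ = eb.skewness_diagnostic(res, sm, window_days=15)
        assert abs(table["skew_index"].mean()) < 0.05

    def test_homoskedastic_index_uncorrelated_with_mean(self):
        rng = np.random.default_rng(2)
        n = 15_000  # 1000 windows of 15
        res, sm = self.make_series(rng.standard_normal(n))
        # give the deterministic mean per-window variety
        sm.mean[0, 0, :] = np.repeat(rng.standard_normal(n // 15), 15)
        _, summary = eb.skewness_diagnostic(res, sm, window_days=15)
        assert abs(summary["pearson_r"].iloc[0]) < 0.1
        assert not summary["flagged"].iloc[0]


@pytest.fixture(scope="module")
def residuals(small_env):
    arr = eb.env_to_arrays(small_env)
    return eb.standardize_residuals(arr, eb.smooth_series(arr, 15))


class TestBlockRandomize:
    def test_single_block_is_identity(self, residuals):
        scheme = eb.build_block_scheme(residuals, 153)
        # one block per year; any permutation only reorders whole seasons
        perm, idx = eb.block_randomize(residuals, scheme, seed=0)
        flat = residuals.values.reshape(*residuals.values.shape[:2], -1)
        pflat = perm.values.reshape(*perm.values.shape[:2], -1)
        np.testing.assert_allclose(np.sort(flat, axis=-1), np.sort(pflat, axis=-1))
        one_year = eb.BlockScheme(block_length_days=153, season_length=153,
                                  n_years=1)
        assert np.array_equal(eb.permuted_day_index(one_year,
                                                    np.random.default_rng(0)),
                              np.arange(153))

    def test_multiset_of_values_preserved(self, residuals):
        scheme = eb.build_block_scheme(residuals, 7)
        perm, _ = eb.block_randomize(residuals, scheme, seed=3)
        np.testing.assert_allclose(
            np.sort(perm.values.ravel()), np.sort(residuals.values.ravel())
        )

    def test_same_day_cross_variable_correlation_exact(self, residuals):
        scheme = eb.build_block_scheme(residuals, 7)
        perm, _ = eb.block_randomize(residuals, scheme, seed=4)
        a0 = residuals.values[0].ravel()
        a1 = residuals.values[1].ravel()
        # ravel order is (site, year, day): same joint reindexing for both
        p0 = perm.values[0].ravel()
        p1 = perm.values[1].ravel()
        before = np.corrcoef(a0, a1)[0, 1]
        after = np.corrcoef(p0, p1)[0, 1]
        assert after == pytest.approx(before, abs=1e-12)

    def test_within_block_order_untouched(self, residuals):
        scheme = eb.build_block_scheme(residuals, 7)
        idx = eb.permuted_day_index(scheme, np.random.default_rng(5))
        # consecutive positions inside any block differ by exactly 1
        jumps = np.diff(idx)
        assert np.sum(jumps != 1) <= len(scheme.blocks)

    def test_blocks_confined_to_year_segments(self, residuals):
        scheme = eb.build_block_scheme(residuals, 10)
        D = scheme.season_length
        for year, start, stop in scheme.blocks:
            assert 0 <= start < stop <= D

    def test_mismatched_scheme_rejected(self, residuals):
        bad = eb.BlockScheme(block_length_days=7, season_length=100, n_years=2)
        with pytest.raises(ValueError, match="scheme"):
            eb.block_randomize(residuals, bad, seed=0)


class TestReconstruct:
    def test_zero_residuals_give_climatology(self, small_env):
        arr = eb.env_to_arrays(small_env)
        sm = eb.smooth_series(arr, 15)
        res = eb.standardize_residuals(arr, sm)
        res.values[:] = 0.0
        rec = eb.reconstruct(res, sm)
        np.testing.assert_allclose(rec, np.broadcast_to(
            sm.mean[:, :, None, :], rec.shape))

    def test_monte_carlo_mean_conservation(self, small_env):
        """Replicate day-means match the permutation expectation within MC
        error, and that expectation sits on the smoothed signal up to the
        (small) finite-sample offset of the standardized residuals."""
        arr = eb.env_to_arrays(small_env)
        sm = eb.smooth_series(arr, 15)
        res = eb.standardize_residuals(arr, sm)
        L = 9  # divides the 153-day season: uniform block permutation
        scheme = eb.build_block_scheme(res, L)
        V, S5 = res.values.shape[0], 5
        acc = np.zeros_like(arr.values[:, :S5])
        acc2 = np.zeros_like(acc)
        n_rep = 400
        for rep in range(n_rep):
            perm, _ = eb.block_randomize(res, scheme, seed=rep)
            x = eb.reconstruct(perm, sm)[:, :S5]
            acc += x
            acc2 += x * x
        mc_mean = acc / n_rep
        mc_sd = np.sqrt(np.maximum(acc2 / n_rep - mc_mean**2, 0.0))
        # exact expectation: day t receives a uniformly drawn block at the
        # same within-block offset → mean residual per offset class
        Y, D = res.values.shape[2], res.values.shape[3]
        r_off = res.values[:, :S5].reshape(V, S5, Y * D // L, L).mean(axis=2)
        offsets = np.tile(np.arange(D) % L, Y).reshape(Y, D)
        exp_r = r_off[:, :, offsets]                       # (V, S, Y, D)
        sd_b = np.broadcast_to(sm.sd[:, :S5, None, :], mc_mean.shape)
        mean_b = np.broadcast_to(sm.mean[:, :S5, None, :], mc_mean.shape)
        expected = mean_b + exp_r * sd_b
        se = np.where(mc_sd == 0, 1.0, mc_sd) / np.sqrt(n_rep)
        dev = np.abs(mc_mean - expected) / se
        assert (dev < 3.0).mean() > 0.985   # ~0.3% outside 3 SE by chance
        # the standardization offset is MC noise around zero: offset-class
        # means over ~Y*D/L blocks have SD ≈ 1/sqrt(n_blocks) ≈ 0.12
        n_blocks = Y * D // L
        assert abs(exp_r.mean()) < 0.02
        assert np.sqrt((exp_r**2).mean()) < 2.0 / np.sqrt(n_blocks)


@pytest.fixture(scope="module")
def planted_system():
    """Two-driver system: SST dominated by its seasonal curve, currents
    purely stochastic; β loads on SST only."""
    sites = sd.generate_sites(n_sites=12, seed=61)
    p = sd.EnvParams()
    p.seasonal = {"sst": (19.0, 6.0, 4.0), "pp": (500.0, 0.0, 0.0),
                  "chl": (0.5, 0.0, 0.0), "u_cur": (0.0, 0.0, 0.0),
                  "v_cur": (0.0, 0.0, 0.0)}
    p.anomaly_sd = {"sst": 0.3, "pp": 10.0, "chl": 0.05,
                    "u_cur": 6.0, "v_cur": 6.0}
    env = sd.generate_environment(sites, range(2006, 2011), p, seed=62)
    fit = SimpleNamespace(
        beta_names=["intercept", "sst", "u_cur"],
        beta_mean=np.array([5.0, -0.25, 0.01]),
        latent_mean=None,
        projector=None,
        standardize_stats={},
        theta_hat={"sigma_t2": np.nan},
        spec=SimpleNamespace(covariates=["sst", "u_cur"]),
        time_index=pd.DataFrame({
            "t": range(10),
            "year": np.repeat([2009, 2010], 5),
            "month": list(range(5, 10)) * 2,
        }),
    )
    return sites, env, fit


class TestRunBootstrap:
    def test_identity_permutation_reproduces_baseline(self, planted_system):
        sites, env, fit = planted_system
        outs = {}
        for mode in ("stochastic", "deterministic"):
            outs[mode] = eb.run_bootstrap(
                fit, env, sites, mode=mode, n_iter=1, seed=9,
                response_draws=False, identity_permutation=True,
            )
        np.testing.assert_allclose(
            outs["stochastic"].predictions, outs["deterministic"].predictions,
            rtol=1e-10,
        )
        # equals a direct prediction from observed monthly means
        cov = sd.monthly_mean_covariates(env, sites, years=[2009, 2010])
        eta = 5.0 - 0.25 * cov["sst"] + 0.01 * cov["u_cur"]
        lam = np.exp(eta).to_numpy()
        got = outs["stochastic"].predictions[0]
        cov_sorted = cov.sort_values(["site_id", "year", "month"])
        lam_grid = lam[cov_sorted.index.to_numpy()].reshape(len(sites), -1)
        np.testing.assert_allclose(got, lam_grid, rtol=1e-8)

    def test_zero_variance_residuals_identical_replicates(self, planted_system):
        # flat seasonal curves AND zero anomalies: every day equals its
        # climatological mean, so residuals are exactly zero everywhere
        sites, _, fit = planted_system
        p = sd.EnvParams()
        p.seasonal = {v: (1.0, 0.0, 0.0) for v in sd.ENV_VARS}
        p.anomaly_sd = {v: 0.0 for v in sd.ENV_VARS}
        p.site_offset_sd = {v: 0.0 for v in sd.ENV_VARS}
        env0 = sd.generate_environment(sites, range(2006, 2011), p, seed=63)
        with pytest.warns(UserWarning, match="zero climatological SD"):
            out = eb.run_bootstrap(
                fit, env0, sites, mode="stochastic", n_iter=5, seed=10,
                response_draws=False, block_length=7,
            )
        for it in range(1, 5):
            np.testing.assert_allclose(out.predictions[it], out.predictions[0])

    def test_dominant_deterministic_driver_direction(self, planted_system):
        """Randomizing the dominant (seasonal SST) component spreads
        predictions more than randomizing the weak residual component."""
        from jellybloom import compare as cmp

        sites, env, fit = planted_system
        boots = {
            mode: eb.run_bootstrap(fit, env, sites, mode=mode, n_iter=200,
                                   seed=11, response_draws=False)
            for mode in ("stochastic", "deterministic")
        }
        paired = cmp.pair_sd_tables(
            cmp.per_site_sd(boots["stochastic"]),
            cmp.per_site_sd(boots["deterministic"]),
        )
        res = cmp.wilcoxon_signed_rank(paired)
        assert paired["sd_deterministic"].median() > paired["sd_stochastic"].median()
        assert res.p_value < 0.01

    def test_maxima_consistent_with_predictions(self, planted_system):
        sites, env, fit = planted_system
        out = eb.run_bootstrap(fit, env, sites, mode="stochastic", n_iter=3,
                               seed=12, response_draws=False)
        months = out.time_index["month"].to_numpy()
        for it in range(3):
            for m in np.unique(months):
                expected = out.predictions[it][:, months == m].max()
                got = out.maxima.query("iteration == @it and month == @m")[
                    "maximum"].iloc[0]
                assert got == pytest.approx(expected)

    def test_bad_mode_and_iterations_rejected(self, planted_system):
        sites, env, fit = planted_system
        with pytest.raises(ValueError):
            eb.run_bootstrap(fit, env, sites, mode="both")
        with pytest.raises(ValueError):
            eb.run_bootstrap(fit, env, sites, n_iter=0)
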