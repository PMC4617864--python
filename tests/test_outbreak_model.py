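"""Aggregation, VIF, splitting, model fitting, prediction and validation."""

import numpy as np
import pandas as pd
import pytest

from jellybloom import outbreak_model as om
from jellybloom import synthetic_data as sd

from conftest import STRONG_SLOPES, strong_truth


def manual_fit(beta_names, beta_mean, covariates=None):
    """Hand-built plug-in FitResult for prediction arithmetic tests."""
    beta_mean = np.asarray(beta_mean, dtype=float)
    spec = om.ModelSpec(
        covariates=covariates if covariates is not None else
        [n for n in beta_names if n != "intercept"],
        include_latent=False, include_iid_effect=False,
    )
    return om.FitResult(
        params=pd.DataFrame(), beta_mean=beta_mean,
        beta_sd=np.full(len(beta_mean), np.nan), beta_names=list(beta_names),
        theta_hat={"kappa": np.nan, "sigma_w2": np.nan, "a": np.nan,
                   "sigma_t2": np.nan},
        latent_mean=None,
        time_index=pd.DataFrame({"t": [], "year": [], "month": []}),
        spec=spec, mesh=None, projector=None, standardize_stats={},
        log_marginal=np.nan, diagnostics={},
    )


class TestAggregateOutbreakDays:
    def test_threshold_is_inclusive(self):
        dates = pd.date_range("2007-05-01", periods=31, freq="D")
        dens = np.zeros(31)
        dens[:4] = [0.5, 1.0, 2.3, 0.0]
        daily = pd.DataFrame({"site_id": 1, "date": dates, "density": dens})
        out = om.aggregate_outbreak_days(daily)
        assert out["count"].iloc[0] == 2  # 1.0 and 2.3 count, 0.5 does not

    def test_all_zero_month(self):
        dates = pd.date_range("2007-06-01", periods=30, freq="D")
        daily = pd.DataFrame({"site_id": 1, "date": dates, "density": 0.0})
        assert om.aggregate_outbreak_days(daily)["count"].iloc[0] == 0

    def test_full_design_yields_20_rows_per_site(self):
        frames = []
        for year in range(2007, 2011):
            dates = pd.date_range(f"{year}-05-01", f"{year}-09-30", freq="D")
            for site in range(3):
                frames.append(pd.DataFrame(
                    {"site_id": site, "date": dates, "density": 0.4}
                ))
        out = om.aggregate_outbreak_days(pd.concat(frames, ignore_index=True))
        assert (out.groupby("site_id").size() == 20).all()

    def test_duplicate_site_day_rejected(self):
        daily = pd.DataFrame({
            "site_id": [1, 1], "date": ["2007-05-01", "2007-05-01"],
            "density": [0.0, 1.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            om.aggregate_outbreak_days(daily)


class TestVIF:
    def test_orthogonal_covariates(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        vif = om.compute_vif(pd.DataFrame({"a": x, "b": y}))
        np.testing.assert_allclose(vif, 1.0, atol=1e-12)

    def test_known_correlation_closed_form(self):
        # corr(a, b) = 0.6 exactly by construction from orthonormal parts
        u = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        v = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
        a, b = u, 0.6 * u + 0.8 * v
        vif = om.compute_vif(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(vif, 1.0 / (1.0 - 0.36), rtol=1e-10)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=list("abcde"))
        vif = om.compute_vif(X)
        for col in X.columns:
            others = np.column_stack(
                [np.ones(len(X))] + [X[c] for c in X.columns if c != col]
            )
            coef, *_ = np.linalg.lstsq(others, X[col].to_numpy(), rcond=None)
            resid = X[col].to_numpy() - others @ coef
            r2 = 1.0 - resid.var() / X[col].to_numpy().var()
            assert vif[col] == pytest.approx(1.0 / (1.0 - r2), abs=1e-8)

    def test_exact_collinearity_reports_infinity(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="collinear"):
            vif = om.compute_vif(pd.DataFrame({"a": x, "b": 2 * x, "c": x**2}))
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            om.compute_vif(pd.DataFrame({"a": np.ones(5), "b": np.arange(5.0)}))


class TestSplitSites:
    def test_sizes_union_disjoint_deterministic(self):
        sites = pd.DataFrame({"site_id": np.arange(10)})
        cal, val = om.split_sites(sites, 0.7, seed=3)
        assert len(cal) == 7 and len(val) == 3
        assert set(cal) | set(val) == set(range(10))
        assert set(cal) & set(val) == set()
        cal2, val2 = om.split_sites(sites, 0.7, seed=3)
        np.testing.assert_array_equal(cal, cal2)

    def test_empty_side_rejected(self):
        sites = pd.DataFrame({"site_id": [0, 1]})
        with pytest.raises(ValueError):
            om.split_sites(sites, 0.01, seed=0)


class TestFitModel:
    def test_intercept_only_matches_poisson_mle(self):
        counts = pd.DataFrame({
            "site_id": np.arange(500), "year": 2007, "month": 5, "count": 4,
        })
        spec = om.ModelSpec(covariates=[], include_latent=False,
                            include_iid_effect=False)
        fit = om.fit_model(counts, spec)
        assert fit.beta_mean[0] == pytest.approx(np.log(4.0), abs=0.02)

    def test_beta_mode_matches_glm_oracle(self):
        """With latent and iid effects off and a flat-ish prior, the posterior
        mode equals the Poisson GLM maximum likelihood estimate."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 400
        df = pd.DataFrame({
            "site_id": np.arange(n), "year": 2007, "month": 5,
            "sst": rng.normal(20, 2, n), "chl": rng.normal(0.5, 0.2, n),
        })
        eta = 0.2 - 0.1 * (df["sst"] - 20) + 0.8 * df["chl"]
        df["count"] = rng.poisson(np.exp(eta))
        spec = om.ModelSpec(covariates=["sst", "chl"], include_latent=False,
                            include_iid_effect=False, beta_prior_var=1e8)
        fit = om.fit_model(df, spec)
        X = sm.add_constant(df[["sst", "chl"]].to_numpy())
        glm = sm.GLM(df["count"].to_numpy(), X,
                     family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta_mean, glm.params, atol=1e-3)

    def test_recovery_with_latent_field(self):
        """Strong-signal recovery: every coefficient within 3 posterior SDs."""
        study = sd.simulate_study(
            truth=strong_truth(), n_sites=60,
            env_years=range(2007, 2011), sampling_years=range(2007, 2011),
            seed=31, intercept_target=0.5,
        )
        spec = om.ModelSpec(include_iid_effect=False,
                            compute_hyper_posterior=False)
        fit = om.fit_model(study["counts"], spec, study["mesh"],
                           study["projector"])
        truth_vec = np.array(
            [study["beta"]["intercept"]]
            + [study["beta"][c] for c in spec.covariates]
        )
        z = (fit.beta_mean - truth_vec) / fit.beta_sd
        assert np.abs(z).max() < 3.0

    def test_temporal_coefficient_interval_covers_zero_truth(self):
        """With a = 0 in the generator, the 95% interval for a includes 0."""
        truth = strong_truth(sigma_w2=0.3, a=0.0)
        study = sd.simulate_study(
            truth=truth, n_sites=40,
            env_years=range(2007, 2011), sampling_years=range(2007, 2011),
            seed=32, intercept_target=0.5,
        )
        spec = om.ModelSpec(include_iid_effect=False, n_hyper_draws=2000)
        fit = om.fit_model(study["counts"], spec, study["mesh"],
                           study["projector"])
        lo, hi = fit.params.loc["a", ["q025", "q975"]]
        assert lo < 0.0 < hi
        # stored rho is consistent with the fitted kappa
        assert fit.rho == pytest.approx(np.sqrt(8.0) / fit.theta_hat["kappa"])

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            om.fit_model(pd.DataFrame(), om.ModelSpec(backend="mcmc"))


class TestPredict:
    def test_intercept_only_exponentiates(self):
        fit = manual_fit(["intercept"], [-0.4683], covariates=[])
        cov = pd.DataFrame({"site_id": [0], "year": [2007], "month": [5]})
        pred = om.predict(fit, cov, include_latent=False)
        assert pred["lambda"].iloc[0] == pytest.approx(np.exp(-0.4683))
        assert pred["lambda"].iloc[0] == pytest.approx(0.626, abs=5e-4)

    def test_zero_everything_gives_unit_rate(self):
        fit = manual_fit(["intercept", "sst"], [0.0, 0.0])
        cov = pd.DataFrame({"site_id": [0], "year": [2007], "month": [5],
                            "sst": [17.0]})
        assert om.predict(fit, cov, include_latent=False)["lambda"].iloc[0] == 1.0

    def test_monotone_in_positive_coefficient(self):
        fit = manual_fit(["intercept", "u_cur"], [0.1, 0.5])
        cov = pd.DataFrame({"site_id": 0, "year": 2007, "month": 5,
                            "u_cur": np.linspace(-2, 2, 9)})
        lam = om.predict(fit, cov, include_latent=False)["lambda"].to_numpy()
        assert (np.diff(lam) > 0).all()

    def test_latent_unit_shift_multiplies_rate_by_e(self, small_study):
        spec = om.ModelSpec(include_iid_effect=False,
                            compute_hyper_posterior=False,
                            optimizer_maxiter=15)
        fit = om.fit_model(small_study["counts"], spec, small_study["mesh"],
                           small_study["projector"])
        cov = small_study["counts"].head(30)
        base = om.predict(fit, cov, include_latent=True)["lambda"].to_numpy()
        fit.latent_mean = fit.latent_mean + 1.0
        bumped = om.predict(fit, cov, include_latent=True)["lambda"].to_numpy()
        np.testing.assert_allclose(bumped / base, np.e, rtol=1e-9)

    def test_missing_covariate_column_named(self):
        fit = manual_fit(["intercept", "sst"], [0.0, 1.0])
        cov = pd.DataFrame({"site_id": [0], "year": [2007], "month": [5]})
        with pytest.raises(KeyError, match="sst"):
            om.predict(fit, cov, include_latent=False)


class TestValidate:
    def test_perfect_predictions(self):
        # rate = count exactly: log-link fit with covariate log(count)
        counts = pd.DataFrame({
            "site_id": np.arange(6), "year": 2007, "month": 5,
            "count": [1, 2, 3, 4, 5, 6],
        })
        counts["logc"] = np.log(counts["count"])
        fit = manual_fit(["intercept", "logc"], [0.0, 1.0])
        metrics = om.validate(fit, counts)
        assert metrics["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert metrics["correlation"] == pytest.approx(1.0)
        assert metrics["actual_coverage"] == 1.0

    def test_constant_offset_rmse(self):
        counts = pd.DataFrame({
            "site_id": np.arange(5), "year": 2007, "month": 5,
            "count": [1, 2, 3, 4, 5],
        })
        counts["logc1"] = np.log(counts["count"] + 1.0)
        fit = manual_fit(["intercept", "logc1"], [0.0, 1.0])
        metrics = om.validate(fit, counts)
        assert metrics["rmse"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_reported_not_crashed(self):
        counts = pd.DataFrame({
            "site_id": np.arange(4), "year": 2007, "month": 5, "count": 2,
        })
        fit = manual_fit(["intercept"], [np.log(2.0)], covariates=[])
        metrics = om.validate(fit, counts)
        assert np.isnan(metrics["correlation"])
        assert "zero variance" in metrics["note"]

    def test_held_out_coverage_near_nominal(self, small_study):
        """Well-specified model: 95% predictive intervals cover ~95% of
        held-out observations."""
        counts = small_study["counts"]
        cal, val = om.split_sites(small_study["sites"], 0.7, seed=5)
        spec = om.ModelSpec(include_iid_effect=False,
                            compute_hyper_posterior=False)
        fit = om.fit_model(counts[counts.site_id.isin(cal)], spec,
                           small_study["mesh"], small_study["projector"])
        metrics = om.validate(fit, counts[counts.site_id.isin(val)], seed=6)
        assert metrics["actual_coverage"] >= 0.90
        assert metrics["rmse"] > 0
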