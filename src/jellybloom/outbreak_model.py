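"""Latent-Gaussian spatio-temporal Poisson model of monthly outbreak-day counts.

The response y_it (number of outbreak days at site i in month t, with t
enumerating (year, month) combinations) is modelled as

    y_it ~ Poisson(λ_it),   log λ_it = z_itᵀβ + Σ_j B_ij ζ_t(j) [+ ε_it]

where z_it holds the covariates (distance to canyon, SST, primary
production, chlorophyll, current components, and linear month/year terms),
B is the sparse site→vertex projector, ζ_t is a Matérn GMRF on the mesh
vertices evolving as a first-order autoregression

    ζ_t = a ζ_{t−1} + ω_t,  ω_t ~ N(0, Q_s⁻¹),  ζ_1 ~ N(0, Q_s⁻¹/(1−a²)),

with Q_s the SPDE precision (constant over time), and ε_it an optional iid
Gaussian extra-variation term with variance σ_t².

Inference is an empirical-Bayes Laplace approximation in the spirit of
integrated nested Laplace approximation: for hyperparameters θ = (κ, σ_w²,
a, σ_t²) the Gaussian-approximated marginal likelihood is maximized by a
derivative-free search; the latent vector (β, ζ, ε) gets a Gaussian
posterior at the mode, and hyperparameter uncertainty is summarized by a
Gaussian (Laplace) approximation on internal scales, sampled and
back-transformed.  Priors are proper but weak: N(0, 100) on each β and wide
Gaussians on log κ, log σ_w², log σ_t² and atanh(a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .mesh_spde import Mesh, Projector, _fem_matrices, ar1_time_precision

__all__ = [
    "DEFAULT_COVARIATES",
    "ModelSpec",
    "FitResult",
    "ConvergenceError",
    "aggregate_outbreak_days",
    "compute_vif",
    "split_sites",
    "fit_model",
    "predict",
    "validate",
]

DEFAULT_COVARIATES = [
    "dist_canyon", "sst", "pp", "chl", "u_cur", "v_cur", "month", "year",
]


class ConvergenceError(RuntimeError):
    """Raised when the inner Newton optimization fails to converge."""


@dataclass
class ModelSpec:
    """Model structure, priors and inference settings."""

    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    include_latent: bool = True
    include_iid_effect: bool = True
    beta_prior_var: float = 100.0
    standardize: bool = False
    backend: str = "laplace"
    #: hyperparameters held fixed (not optimized), e.g. {"kappa": 0.05}
    fixed_hypers: dict = field(default_factory=dict)
    hyper_init: dict = field(default_factory=dict)
    compute_hyper_posterior: bool = True
    n_hyper_draws: int = 4000
    optimizer_maxiter: int = 120
    seed: int = 0
    # weak priors on internal hyperparameter scales (mean, sd)
    prior_log_kappa_sd: float = 2.0
    prior_log_sigma_w2: tuple = (0.0, 3.0)
    prior_atanh_a: tuple = (0.0, 2.0)
    prior_log_sigma_t2: tuple = (-2.3, 3.0)


@dataclass
class FitResult:
    """Posterior summaries and everything needed to predict from the fit."""

    params: pd.DataFrame            # mean, sd, q025, q50, q975 per parameter
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    beta_names: list
    theta_hat: dict                 # kappa, sigma_w2, a, sigma_t2 at the mode
    latent_mean: np.ndarray | None  # (T, G) posterior mean of ζ
    time_index: pd.DataFrame        # columns t, year, month
    spec: ModelSpec
    mesh: Mesh | None
    projector: Projector | None
    standardize_stats: dict
    log_marginal: float
    diagnostics: dict
    _u: np.ndarray = field(repr=False, default=None)
    _factor: object = field(repr=False, default=None)
    _A: sp.spmatrix = field(repr=False, default=None)

    @property
    def rho(self) -> float:
        """Matérn correlation range √8/κ̂ implied by the fitted scale."""
        return float(np.sqrt(8.0) / self.theta_hat["kappa"])


# ---------------------------------------------------------------------------
# data preparation helpers

def aggregate_outbreak_days(
    daily_density_table: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Count, per (site, year, month), the days with density ≥ threshold.

    An outbreak day is a site-day with at least ``threshold`` stranded
    animals per m² (default one).
    """
    df = daily_density_table
    if df.duplicated(subset=["site_id", "date"]).any():
        dup = df[df.duplicated(subset=["site_id", "date"], keep=False)]
        key = dup.iloc[0]
        raise ValueError(
            f"duplicate (site, date) rows, e.g. site {key['site_id']} "
            f"on {pd.Timestamp(key['date']).date()}"
        )
    if (df["density"] < 0).any():
        raise ValueError("densities must be >= 0")
    tmp = df.assign(
        year=pd.DatetimeIndex(df["date"]).year,
        month=pd.DatetimeIndex(df["date"]).month,
        outbreak=(df["density"] >= threshold).astype(int),
    )
    out = (
        tmp.groupby(["site_id", "year", "month"], as_index=False)["outbreak"]
        .sum()
        .rename(columns={"outbreak": "count"})
    )
    return out.sort_values(["site_id", "year", "month"], ignore_index=True)


def compute_vif(covariate_table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: VIF_j = 1/(1 − R²_j)."""
    import statsmodels.api as sm

    X = covariate_table.select_dtypes(include=[np.number])
    if X.shape[1] < 2:
        raise ValueError("need at least 2 covariates for VIF")
    if (X.std(ddof=0) == 0).any():
        bad = X.columns[(X.std(ddof=0) == 0)].tolist()
        raise ValueError(f"constant covariate column(s): {bad}")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(float))
        r2 = sm.OLS(X[col].to_numpy(float), others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"covariate {col!r} is exactly collinear; VIF = inf")
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def split_sites(sites: pd.DataFrame, calibration_fraction: float = 0.7, seed=0):
    """Seeded disjoint calibration/validation split of the site ids."""
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must be in (0, 1)")
    ids = sites["site_id"].to_numpy()
    n_cal = int(round(calibration_fraction * len(ids)))
    if n_cal == 0 or n_cal == len(ids):
        raise ValueError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return np.sort(ids[perm[:n_cal]]), np.sort(ids[perm[n_cal:]])


# ---------------------------------------------------------------------------
# Laplace backend internals

def _splu_logdet(Q: sp.csc_matrix):
    lu = spla.splu(
        Q.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )
    return float(np.sum(np.log(np.abs(lu.U.diagonal())))), lu


class _Design:
    """Fixed data structures of one fit: response, design, latent layout."""

    def __init__(self, counts, spec: ModelSpec, mesh, projector):
        df = counts.copy()
        if df.duplicated(subset=["site_id", "year", "month"]).any():
            raise ValueError("duplicate (site, year, month) rows in counts")
        for c in spec.covariates + ["count"]:
            if c not in df.columns:
                raise KeyError(f"counts table missing column {c!r}")
        df = df.sort_values(["year", "month", "site_id"], ignore_index=True)
        self.counts = df
        self.y = df["count"].to_numpy(float)
        n = len(df)

        Zcols = [np.ones(n)]
        self.standardize_stats = {}
        for c in spec.covariates:
            v = df[c].to_numpy(float)
            if spec.standardize and c not in ("month", "year"):
                mu, sd = v.mean(), v.std(ddof=0)
                sd = sd if sd > 0 else 1.0
                self.standardize_stats[c] = (mu, sd)
                v = (v - mu) / sd
            Zcols.append(v)
        self.Z = np.column_stack(Zcols)
        self.beta_names = ["intercept"] + list(spec.covariates)
        self.p = self.Z.shape[1]

        times = (
            df[["year", "month"]].drop_duplicates().sort_values(["year", "month"])
        )
        times = times.reset_index(drop=True)
        times["t"] = np.arange(len(times))
        self.time_index = times[["t", "year", "month"]]
        self.T = len(times)
        tmap = {(r.year, r.month): r.t for r in times.itertuples()}
        self.t_of_obs = np.array(
            [tmap[(y, m)] for y, m in zip(df["year"], df["month"])]
        )

        self.include_latent = spec.include_latent and mesh is not None
        self.include_iid = spec.include_iid_effect
        blocks = [sp.csr_matrix(self.Z)]
        if self.include_latent:
            if projector is None:
                raise ValueError("latent field requires a projector")
            sid_to_row = {s: r for r, s in enumerate(projector.site_ids)}
            try:
                rows = np.array([sid_to_row[s] for s in df["site_id"]])
            except KeyError as exc:
                raise KeyError(f"site {exc.args[0]!r} missing from projector")
            Bsel = projector.B[rows].tocoo()
            self.G = projector.B.shape[1]
            cols = Bsel.col + self.t_of_obs[Bsel.row] * self.G
            blocks.append(
                sp.csr_matrix(
                    (Bsel.data, (Bsel.row, cols)), shape=(n, self.G * self.T)
                )
            )
            self.C_fem, self.G_fem = _fem_matrices(mesh)
            self.GCG = (
                self.G_fem
                @ sp.diags(1.0 / self.C_fem.diagonal())
                @ self.G_fem
            ).tocsc()
        else:
            self.G = 0
        if self.include_iid:
            blocks.append(sp.identity(n, format="csr"))
        self.A = sp.hstack(blocks, format="csr")
        self.n_obs = n
        self.n_latent = self.A.shape[1]

    def q_spatial(self, kappa, sigma_w2) -> sp.csc_matrix:
        Q0 = (
            kappa**4 * self.C_fem
            + 2.0 * kappa**2 * self.G_fem
            + self.GCG
        )
        return (Q0 / (4.0 * np.pi * kappa**2 * sigma_w2)).tocsc()

    def prior_precision(self, theta, spec: ModelSpec):
        """Block prior precision and its log-determinant."""
        blocks = [sp.identity(self.p) / spec.beta_prior_var]
        logdet = -self.p * np.log(spec.beta_prior_var)
        if self.include_latent:
            Qs = self.q_spatial(theta["kappa"], theta["sigma_w2"])
            ld_qs, _ = _splu_logdet(Qs)
            M = ar1_time_precision(theta["a"], self.T)
            blocks.append(sp.kron(M, Qs, format="csc"))
            logdet += self.G * np.log(1.0 - theta["a"] ** 2) + self.T * ld_qs
        if self.include_iid:
            blocks.append(sp.identity(self.n_obs) / theta["sigma_t2"])
            logdet += -self.n_obs * np.log(theta["sigma_t2"])
        return sp.block_diag(blocks, format="csc"), logdet


def _newton_mode(y, A, P, u0, max_iter=60, tol=1e-7):
    """Mode of the Poisson log-posterior with Gaussian prior precision P."""

    def objective(u, eta):
        return float(y @ eta - np.exp(eta).sum() - 0.5 * (u @ (P @ u)))

    u = u0.copy()
    eta = np.clip(A @ u, -30.0, 30.0)
    f = objective(u, eta)
    lu = None
    for _ in range(max_iter):
        lam = np.exp(eta)
        grad = A.T @ (y - lam) - P @ u
        Qpost = (P + (A.T @ sp.diags(lam) @ A)).tocsc()
        lu = spla.splu(
            Qpost, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        step = lu.solve(grad)
        gnorm = np.max(np.abs(grad))
        if gnorm < tol * max(1.0, np.abs(y).max()):
            return u, eta, lu, Qpost
        t = 1.0
        while t > 1e-6:
            u_new = u + t * step
            eta_new = np.clip(A @ u_new, -30.0, 30.0)
            f_new = objective(u_new, eta_new)
            if f_new > f - 1e-12:
                u, eta, f = u_new, eta_new, f_new
                break
            t *= 0.5
        else:
            break
    lam = np.exp(eta)
    grad = A.T @ (y - lam) - P @ u
    if np.max(np.abs(grad)) > 1e-3 * max(1.0, np.abs(y).max()):
        raise ConvergenceError(
            f"inner Newton failed: |grad|_inf = {np.max(np.abs(grad)):.3g}"
        )
    Qpost = (P + (A.T @ sp.diags(lam) @ A)).tocsc()
    lu = spla.splu(
        Qpost, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )
    return u, eta, lu, Qpost


_THETA_ORDER = ["kappa", "sigma_w2", "a", "sigma_t2"]


def _to_internal(name, value):
    return np.arctanh(value) if name == "a" else np.log(value)


def _from_internal(name, value):
    return np.tanh(value) if name == "a" else np.exp(value)


class _LaplaceFitter:
    def __init__(self, design: _Design, spec: ModelSpec):
        self.d = design
        self.spec = spec
        active = []
        if design.include_latent:
            active += ["kappa", "sigma_w2", "a"]
        if design.include_iid:
            active += ["sigma_t2"]
        self.active = [p for p in active if p not in spec.fixed_hypers]
        self.fixed = dict(spec.fixed_hypers)
        self._warm = np.zeros(design.n_latent)
        self._cache = {}

    def default_init(self):
        init = {"sigma_w2": 1.0, "a": 0.3, "sigma_t2": 0.1, "kappa": 0.05}
        init.update(self.spec.hyper_init)
        return init

    def theta_from_vec(self, vec):
        theta = dict(self.fixed)
        for name, v in zip(self.active, vec):
            theta[name] = _from_internal(name, v)
        return theta

    def log_prior_theta(self, vec):
        lp = 0.0
        s = self.spec
        pri = {
            "kappa": (self._kappa_prior_mean, s.prior_log_kappa_sd),
            "sigma_w2": s.prior_log_sigma_w2,
            "a": s.prior_atanh_a,
            "sigma_t2": s.prior_log_sigma_t2,
        }
        for name, v in zip(self.active, vec):
            m, sd = pri[name]
            lp += -0.5 * ((v - m) / sd) ** 2
        return lp

    def laplace_ll(self, theta):
        P, ld_prior = self.d.prior_precision(theta, self.spec)
        u, eta, lu, Qpost = _newton_mode(self.d.y, self.d.A, P, self._warm)
        self._warm = u
        lam = np.exp(eta)
        loglik = float(self.d.y @ eta - lam.sum())
        ld_post = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        ll = loglik - 0.5 * float(u @ (P @ u)) + 0.5 * ld_prior - 0.5 * ld_post
        return ll, (u, eta, lu, Qpost, P)

    def penalized(self, vec):
        key = tuple(np.round(vec, 10))
        if key in self._cache:
            return self._cache[key]
        theta = self.theta_from_vec(vec)
        try:
            ll, _ = self.laplace_ll(theta)
        except (ConvergenceError, RuntimeError):
            self._cache[key] = -1e10
            return -1e10
        val = ll + self.log_prior_theta(vec)
        self._cache[key] = val
        return val

    def fit(self):
        init = self.default_init()
        self._kappa_prior_mean = np.log(init.get("kappa", 0.05))
        if not self.active:
            theta = dict(self.fixed)
            ll, art = self.laplace_ll(theta)
            return theta, np.zeros(0), None, ll, art
        x0 = np.array(
            [_to_internal(n, init[n]) for n in self.active]
        )
        # explicit initial simplex: Nelder-Mead's default perturbation is
        # proportional to |x0| and degenerates for coordinates near zero
        simplex = np.vstack([x0, x0 + 0.6 * np.eye(len(x0))])
        res = minimize(
            lambda v: -self.penalized(v),
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": self.spec.optimizer_maxiter,
                "xatol": 2e-3,
                "fatol": 2e-3,
                "initial_simplex": simplex,
            },
        )
        vec = res.x
        theta = self.theta_from_vec(vec)
        ll, art = self.laplace_ll(theta)
        hess = None
        if self.spec.compute_hyper_posterior:
            hess = self._numeric_hessian(vec)
        return theta, vec, hess, ll, art

    def _numeric_hessian(self, vec, h=0.08):
        k = len(vec)
        f0 = self.penalized(vec)
        H = np.zeros((k, k))
        for i in range(k):
            ei = np.zeros(k); ei[i] = h
            fpp = self.penalized(vec + ei)
            fmm = self.penalized(vec - ei)
            H[i, i] = (fpp - 2 * f0 + fmm) / h**2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h
                fp = self.penalized(vec + ei + ej)
                fm = self.penalized(vec - ei - ej)
                H[i, j] = H[j, i] = (
                    fp - self.penalized(vec + ei - ej)
                    - self.penalized(vec - ei + ej) + fm
                ) / (4 * h**2)
        return H


def _gaussian_summary(mean, sd):
    z = 1.959963984540054
    return {
        "mean": mean, "sd": sd,
        "q025": mean - z * sd, "q50": mean, "q975": mean + z * sd,
    }


def _draw_summary(draws):
    return {
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)),
        "q025": float(np.quantile(draws, 0.025)),
        "q50": float(np.quantile(draws, 0.5)),
        "q975": float(np.quantile(draws, 0.975)),
    }


def _fit_laplace(counts, spec, mesh, projector) -> FitResult:
    d = _Design(counts, spec, mesh, projector)
    fitter = _LaplaceFitter(d, spec)
    theta, vec, hess, ll, art = fitter.fit()
    u, eta, lu, Qpost, P = art

    # marginal SDs of beta from columns of Qpost^{-1}
    beta_sd = np.empty(d.p)
    for j in range(d.p):
        e = np.zeros(d.n_latent); e[j] = 1.0
        beta_sd[j] = np.sqrt(max(lu.solve(e)[j], 0.0))
    beta_mean = u[: d.p]

    rows = {}
    for name, m, s in zip(d.beta_names, beta_mean, beta_sd):
        rows[name] = _gaussian_summary(float(m), float(s))

    theta_full = {
        "kappa": theta.get("kappa", np.nan),
        "sigma_w2": theta.get("sigma_w2", np.nan),
        "a": theta.get("a", np.nan),
        "sigma_t2": theta.get("sigma_t2", np.nan),
    }

    diagnostics = {"hyper_opt_evals": len(fitter._cache), "converged": True}
    if fitter.active and spec.compute_hyper_posterior and hess is not None:
        cov = -np.linalg.pinv(hess)
        # guard: force PD by clipping eigenvalues
        w, V = np.linalg.eigh((cov + cov.T) / 2)
        w = np.clip(w, 1e-8, None)
        cov = V @ np.diag(w) @ V.T
        rng = np.random.default_rng(spec.seed + 7919)
        draws_int = rng.multivariate_normal(vec, cov, size=spec.n_hyper_draws)
        tdraws = {
            n: np.array([_from_internal(n, v) for v in draws_int[:, i]])
            for i, n in enumerate(fitter.active)
        }
        if "sigma_t2" in tdraws:
            rows["sigma_t2"] = _draw_summary(tdraws["sigma_t2"])
        if "sigma_w2" in tdraws:
            rows["sigma_w2"] = _draw_summary(tdraws["sigma_w2"])
        if "kappa" in tdraws:
            rows["rho"] = _draw_summary(np.sqrt(8.0) / tdraws["kappa"])
        if "a" in tdraws:
            rows["a"] = _draw_summary(tdraws["a"])
        diagnostics["hyper_cov_internal"] = cov
        diagnostics["hyper_active"] = list(fitter.active)
    else:
        for name in fitter.active or []:
            label = "rho" if name == "kappa" else name
            val = np.sqrt(8.0) / theta[name] if name == "kappa" else theta[name]
            rows[label] = _gaussian_summary(float(val), np.nan)

    params = pd.DataFrame(rows).T[["mean", "sd", "q025", "q50", "q975"]]
    params.index.name = "parameter"

    latent_mean = None
    if d.include_latent:
        latent_mean = u[d.p: d.p + d.G * d.T].reshape(d.T, d.G)

    return FitResult(
        params=params,
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        beta_names=d.beta_names,
        theta_hat=theta_full,
        latent_mean=latent_mean,
        time_index=d.time_index.copy(),
        spec=spec,
        mesh=mesh,
        projector=projector,
        standardize_stats=d.standardize_stats,
        log_marginal=float(ll),
        diagnostics=diagnostics,
        _u=u,
        _factor=lu,
        _A=d.A,
    )


_BACKENDS = {"laplace": _fit_laplace}


def fit_model(
    counts: pd.DataFrame,
    spec: ModelSpec | None = None,
    mesh: Mesh | None = None,
    projector: Projector | None = None,
) -> FitResult:
    """Fit the spatio-temporal Poisson outbreak model.

    ``counts`` must hold one row per (site, year, month) with a ``count``
    column and every covariate named in the ModelSpec.  With
    ``spec.include_latent`` (the default) a mesh and projector are required.
    """
    spec = spec or ModelSpec()
    if spec.backend not in _BACKENDS:
        raise ValueError(
            f"unknown backend {spec.backend!r}; available: {sorted(_BACKENDS)}"
        )
    if spec.include_latent and mesh is None:
        raise ValueError("include_latent=True requires a mesh and projector")
    return _BACKENDS[spec.backend](counts, spec, mesh, projector)


# ---------------------------------------------------------------------------
# prediction and validation

def _build_eta(fit: FitResult, covariates: pd.DataFrame, include_latent: bool):
    spec = fit.spec
    for c in spec.covariates:
        if c not in covariates.columns:
            raise KeyError(f"prediction covariates missing column {c!r}")
    n = len(covariates)
    Z = [np.ones(n)]
    for c in spec.covariates:
        v = covariates[c].to_numpy(float)
        if c in fit.standardize_stats:
            mu, sd = fit.standardize_stats[c]
            v = (v - mu) / sd
        Z.append(v)
    Z = np.column_stack(Z)
    eta = Z @ fit.beta_mean
    if include_latent and fit.latent_mean is not None:
        tmap = {
            (r.year, r.month): r.t for r in fit.time_index.itertuples()
        }
        sid_to_row = {s: r for r, s in enumerate(fit.projector.site_ids)}
        lat = np.zeros(n)
        site_arr = covariates["site_id"].to_numpy()
        year_arr = covariates["year"].to_numpy()
        month_arr = covariates["month"].to_numpy()
        for i in range(n):
            key = (year_arr[i], month_arr[i])
            if key not in tmap:
                raise KeyError(f"(year, month) {key} not in the fitted period")
            if site_arr[i] not in sid_to_row:
                raise KeyError(f"site {site_arr[i]!r} not in the projector")
            row = fit.projector.B[sid_to_row[site_arr[i]]]
            lat[i] = (row @ fit.latent_mean[tmap[key]]).item()
        eta = eta + lat
    return eta, Z


def _eta_sd(fit: FitResult, covariates: pd.DataFrame, Z, include_latent: bool):
    """Posterior SD of each linear predictor via solves against Q_post.

    A fit reloaded for plug-in prediction carries no posterior factor; its
    linear-predictor uncertainty is reported as zero (intervals then carry
    Poisson and iid variability only).
    """
    if getattr(fit, "_factor", None) is None or getattr(fit, "_A", None) is None:
        return np.zeros(len(covariates))
    d_cols = fit._A.shape[1]
    p = len(fit.beta_names)
    tmap = {(r.year, r.month): r.t for r in fit.time_index.itertuples()}
    sid_to_row = {s: r for r, s in enumerate(fit.projector.site_ids)} \
        if fit.projector is not None else {}
    G = fit.latent_mean.shape[1] if fit.latent_mean is not None else 0
    sds = np.empty(len(covariates))
    site_arr = covariates["site_id"].to_numpy() if "site_id" in covariates else None
    year_arr = covariates["year"].to_numpy() if "year" in covariates else None
    month_arr = covariates["month"].to_numpy() if "month" in covariates else None
    for i in range(len(covariates)):
        a = np.zeros(d_cols)
        a[:p] = Z[i]
        if include_latent and fit.latent_mean is not None:
            t = tmap[(year_arr[i], month_arr[i])]
            row = fit.projector.B[sid_to_row[site_arr[i]]].tocoo()
            a[p + t * G + row.col] = row.data
        sds[i] = np.sqrt(max(float(a @ fit._factor.solve(a)), 0.0))
    return sds


def predict(
    fit: FitResult,
    covariates: pd.DataFrame,
    include_latent: bool = True,
    include_residual_draws: bool = False,
    intervals: bool = False,
    level: float = 0.95,
    n_draws: int = 2000,
    seed=0,
) -> pd.DataFrame:
    """Predicted outbreak rates λ = exp(zβ̂ + Bζ̂), optionally with
    predictive intervals combining posterior and Poisson uncertainty."""
    eta, Z = _build_eta(fit, covariates, include_latent)
    out = covariates.copy()
    out["eta"] = eta
    out["lambda"] = np.exp(np.clip(eta, -30, 30))
    if intervals:
        sds = _eta_sd(fit, covariates, Z, include_latent)
        rng = np.random.default_rng(seed)
        alpha = (1.0 - level) / 2.0
        lo = np.empty(len(out)); hi = np.empty(len(out))
        for i in range(len(out)):
            e = eta[i] + sds[i] * rng.standard_normal(n_draws)
            if include_residual_draws and np.isfinite(fit.theta_hat["sigma_t2"]):
                e = e + np.sqrt(fit.theta_hat["sigma_t2"]) * rng.standard_normal(
                    n_draws
                )
            ydraw = rng.poisson(np.exp(np.clip(e, -30, 30)))
            lo[i] = np.quantile(ydraw, alpha)
            hi[i] = np.quantile(ydraw, 1.0 - alpha)
        out["pi_low"] = lo
        out["pi_high"] = hi
    return out


def validate(fit: FitResult, validation_counts: pd.DataFrame, seed=0) -> dict:
    """RMSE, Pearson correlation and actual 95% predictive-interval coverage
    of the fit on held-out counts (latent contribution excluded for sites
    the model never saw)."""
    include_latent = (
        fit.projector is not None
        and set(validation_counts["site_id"]).issubset(set(fit.projector.site_ids))
    )
    pred = predict(
        fit,
        validation_counts,
        include_latent=include_latent,
        include_residual_draws=fit.spec.include_iid_effect,
        intervals=True,
        seed=seed,
    )
    obs = validation_counts["count"].to_numpy(float)
    lam = pred["lambda"].to_numpy()
    rmse = float(np.sqrt(np.mean((lam - obs) ** 2)))
    if np.std(obs) == 0 or np.std(lam) == 0:
        corr = np.nan
        note = "correlation undefined (zero variance)"
    else:
        corr = float(np.corrcoef(lam, obs)[0, 1])
        note = ""
    coverage = float(
        np.mean((obs >= pred["pi_low"].to_numpy()) & (obs <= pred["pi_high"].to_numpy()))
    )
    return {"rmse": rmse, "correlation": corr, "actual_coverage": coverage,
            "note": note, "n": len(obs)}
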