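"""The environmental bootstrap: separating deterministic signal from anomalies.

Each daily environmental series is decomposed into a deterministic
climatology — for every calendar day of the season, the mean and SD of a
15-day window pooled across all available years — and standardized
residuals (observed − mean)/SD.  Residuals are then randomized in blocks
whose length is the longest decorrelation time among the variables, with
one block permutation per replicate applied identically to every variable
and site, so same-day cross-variable and cross-site correlations are
preserved exactly.  Adding the permuted residuals back onto the climatology
(rescaled by the SD of the receiving calendar position) yields hypothetical
environmental histories with anomalies reallocated in time; feeding their
monthly means through a fitted outbreak model measures how much prediction
variability the stochastic component carries.  The mirrored variant
randomizes the deterministic (climatological-mean) component instead,
leaving residuals in place, to measure the deterministic contribution.

Seasons of different years are disjoint islands of days; blocks are built
within a single year's season and never span the winter gap.  Trailing
partial blocks are kept as short blocks and permuted with the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ENV_VARS

__all__ = [
    "EnvArrays",
    "SmoothedSeries",
    "ResidualSeries",
    "BlockScheme",
    "BootstrapOutput",
    "env_to_arrays",
    "smooth_series",
    "standardize_residuals",
    "acf",
    "decorrelation_time",
    "skewness_diagnostic",
    "build_block_scheme",
    "permuted_day_index",
    "block_randomize",
    "reconstruct",
    "run_bootstrap",
]


@dataclass
class EnvArrays:
    """Daily environmental values as a dense array [var, site, year, day]."""

    values: np.ndarray            # (V, S, Y, D)
    variables: list
    site_ids: np.ndarray
    years: np.ndarray
    dates: pd.DatetimeIndex       # length Y*D, chronological

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SmoothedSeries:
    """Per-calendar-day deterministic mean and SD, pooled across years."""

    mean: np.ndarray              # (V, S, D)
    sd: np.ndarray                # (V, S, D)
    window_days: int
    variables: list
    site_ids: np.ndarray


@dataclass
class ResidualSeries:
    """Standardized residuals aligned with the source EnvArrays."""

    values: np.ndarray            # (V, S, Y, D)
    variables: list
    site_ids: np.ndarray
    years: np.ndarray
    n_zero_sd: int = 0


@dataclass
class BlockScheme:
    """Within-season block segmentation shared by all variables and sites."""

    block_length_days: int
    season_length: int
    n_years: int
    #: (year_index, start_day, stop_day) per block, in season-day coordinates
    blocks: list = field(default_factory=list)

    def __post_init__(self):
        if self.block_length_days < 1:
            raise ValueError("block length must be >= 1")
        if not self.blocks:
            for y in range(self.n_years):
                for s in range(0, self.season_length, self.block_length_days):
                    self.blocks.append(
                        (y, s, min(s + self.block_length_days, self.season_length))
                    )


@dataclass
class BootstrapOutput:
    """Per-replicate predictions and per-month maxima from one bootstrap run."""

    predictions: np.ndarray       # (n_iter, S, T) predicted rates λ
    maxima: pd.DataFrame          # columns iteration, month, maximum
    mode: str
    site_ids: np.ndarray
    time_index: pd.DataFrame      # columns t, year, month
    n_iter: int
    block_length_days: int


# ---------------------------------------------------------------------------
# decomposition

def env_to_arrays(env_daily: pd.DataFrame, variables=None) -> EnvArrays:
    """Pivot the long daily table to [var, site, year, season-day] arrays.

    Every (site, year) must cover the same number of season days.
    """
    variables = list(variables) if variables is not None else [
        v for v in ENV_VARS if v in env_daily.columns
    ]
    df = env_daily.sort_values(["site_id", "date"])
    dates = pd.DatetimeIndex(df["date"])
    df = df.assign(year=dates.year)
    site_ids = np.array(sorted(df["site_id"].unique()))
    years = np.array(sorted(df["year"].unique()))
    all_dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    per_year = df.groupby("year")["date"].nunique()
    if per_year.nunique() != 1:
        raise ValueError("years cover unequal numbers of season days")
    D = int(per_year.iloc[0])
    Y, S, V = len(years), len(site_ids), len(variables)
    if len(df) != S * Y * D:
        raise ValueError("environmental table is not complete (one row per site-day)")
    # order rows site-major, then chronological
    vals = df.sort_values(["site_id", "date"])[variables].to_numpy(float)
    arr = vals.reshape(S, Y, D, V).transpose(3, 0, 1, 2).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError("environmental values must be finite")
    return EnvArrays(
        values=arr, variables=variables, site_ids=site_ids, years=years,
        dates=all_dates,
    )


def smooth_series(env_daily, window_days: int = 15) -> SmoothedSeries:
    """Climatology by a sliding window pooled across years.

    For focal season-day d the window spans d−w//2 .. d+w//2; at the season
    edges the outermost days are repeated to keep the pooled sample size at
    ``window_days × n_years``.  Mean and sample SD (ddof=1) are taken over
    the pooled values.
    """
    env = env_daily if isinstance(env_daily, EnvArrays) else env_to_arrays(env_daily)
    if window_days % 2 == 0 or window_days < 1:
        raise ValueError("window_days must be odd and positive")
    V, S, Y, D = env.values.shape
    if window_days > D:
        raise ValueError("smoothing window longer than the season")
    if Y < 2:
        raise ValueError("need at least 2 years to pool a climatology")
    half = window_days // 2
    mean = np.empty((V, S, D))
    sd = np.empty((V, S, D))
    for d in range(D):
        idx = np.clip(np.arange(d - half, d + half + 1), 0, D - 1)
        pool = env.values[:, :, :, idx].reshape(V, S, Y * window_days)
        mean[:, :, d] = pool.mean(axis=2)
        sd[:, :, d] = pool.std(axis=2, ddof=1)
    return SmoothedSeries(
        mean=mean, sd=sd, window_days=window_days,
        variables=env.variables, site_ids=env.site_ids,
    )


def standardize_residuals(env_daily, smoothed: SmoothedSeries) -> ResidualSeries:
    """r = (x − mean)/SD per site, variable and day; zero-SD days yield 0."""
    env = env_daily if isinstance(env_daily, EnvArrays) else env_to_arrays(env_daily)
    V, S, Y, D = env.values.shape
    if smoothed.mean.shape != (V, S, D):
        raise ValueError("smoothed series does not cover the environmental table")
    sd = smoothed.sd[:, :, None, :]
    diff = env.values - smoothed.mean[:, :, None, :]
    zero = sd == 0
    n_zero = int(np.broadcast_to(zero, diff.shape).sum())
    r = np.where(np.broadcast_to(zero, diff.shape), 0.0, diff / np.where(zero, 1.0, sd))
    if n_zero:
        warnings.warn(f"{n_zero} site-days with zero climatological SD; residual set to 0")
    return ResidualSeries(
        values=r, variables=env.variables, site_ids=env.site_ids,
        years=env.years, n_zero_sd=n_zero,
    )


# ---------------------------------------------------------------------------
# decorrelation time and diagnostics

def acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Empirical autocorrelation with the biased (1/n) covariance estimator."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    c0 = np.mean(x * x)
    if c0 == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    return np.array(
        [1.0] + [np.sum(x[:-k] * x[k:]) / n / c0 for k in range(1, max_lag + 1)]
    )


def _pooled_acf(values: np.ndarray, max_lag: int) -> np.ndarray:
    """ACF from autocovariances averaged over (site, year) season segments."""
    segs = values.reshape(-1, values.shape[-1])
    segs = segs - segs.mean(axis=1, keepdims=True)
    n = segs.shape[1]
    c0 = np.mean(segs * segs)
    if c0 == 0:
        raise ValueError("zero-variance residuals")
    out = [1.0]
    for k in range(1, max_lag + 1):
        out.append(np.mean(np.sum(segs[:, :-k] * segs[:, k:], axis=1) / n) / c0)
    return np.array(out)


def decorrelation_time(residuals, max_lag: int | None = None):
    """Smallest lag at which the autocorrelation reaches zero.

    For a 1-D series returns a single integer.  For a ResidualSeries returns
    a dict {variable: days} using the segment-pooled autocorrelation; the
    bootstrap block length is the max over variables.
    """
    if isinstance(residuals, ResidualSeries):
        D = residuals.values.shape[-1]
        lag = max_lag or min(60, D - 2)
        out = {}
        for i, v in enumerate(residuals.variables):
            a = _pooled_acf(residuals.values[i], lag)
            hit = np.flatnonzero(a[1:] <= 0)
            if hit.size == 0:
                warnings.warn(
                    f"{v}: autocorrelation never reached zero within {lag} lags"
                )
                out[v] = lag
            else:
                out[v] = int(hit[0] + 1)
        return out
    x = np.asarray(residuals, dtype=float)
    lag = max_lag or min(60, len(x) // 2 - 1)
    if len(x) <= 2 * lag:
        warnings.warn("short series: decorrelation time may be unreliable")
    a = acf(x, lag)
    hit = np.flatnonzero(a[1:] <= 0)
    if hit.size == 0:
        warnings.warn(f"autocorrelation never reached zero within {lag} lags")
        return lag
    return int(hit[0] + 1)


def skewness_diagnostic(
    residuals: ResidualSeries, smoothed: SmoothedSeries, window_days: int = 15
):
    """Windowed skewness index m₃/m₂ vs the windowed deterministic mean.

    The index is the ratio of the third central moment to the variance
    (1/n moments) over non-overlapping in-season windows; a correlation of
    the index with the smoothed mean would violate the interchangeability
    assumption behind the residual randomization.  Zero-variance windows
    are skipped.  Returns (per-window table, per-variable summary).
    """
    V, S, Y, D = residuals.values.shape
    rows = []
    skipped = 0
    for vi, var in enumerate(residuals.variables):
        for si in range(S):
            for yi in range(Y):
                for start in range(0, D, window_days):
                    w = residuals.values[vi, si, yi, start:start + window_days]
                    if len(w) < 3:
                        continue
                    m = w.mean()
                    m2 = np.mean((w - m) ** 2)
                    if m2 == 0:
                        skipped += 1
                        continue
                    m3 = np.mean((w - m) ** 3)
                    rows.append(
                        {
                            "variable": var,
                            "site_id": residuals.site_ids[si],
                            "year": residuals.years[yi],
                            "window_start": start,
                            "skew_index": m3 / m2,
                            "smoothed_mean": smoothed.mean[
                                vi, si, start:start + window_days
                            ].mean(),
                        }
                    )
    table = pd.DataFrame(rows)
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance windows")
    summary = []
    for var, grp in table.groupby("variable"):
        if grp["smoothed_mean"].std() == 0 or grp["skew_index"].std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(grp["skew_index"], grp["smoothed_mean"])[0, 1])
        summary.append(
            {"variable": var, "pearson_r": r, "flagged": bool(abs(r) > 0.3)
             if np.isfinite(r) else False}
        )
    return table, pd.DataFrame(summary)


# ---------------------------------------------------------------------------
# block randomization and reconstruction

def build_block_scheme(
    residuals: ResidualSeries, block_length_days: int
) -> BlockScheme:
    V, S, Y, D = residuals.values.shape
    return BlockScheme(
        block_length_days=int(block_length_days), season_length=D, n_years=Y
    )


def permuted_day_index(scheme: BlockScheme, rng: np.random.Generator) -> np.ndarray:
    """Global-day source indices after permuting the block order.

    Day positions are laid out year-major (g = year·D + day); the permuted
    blocks are concatenated into a sequence of the same total length.
    """
    order = rng.permutation(len(scheme.blocks))
    D = scheme.season_length
    pieces = [
        np.arange(scheme.blocks[b][0] * D + scheme.blocks[b][1],
                  scheme.blocks[b][0] * D + scheme.blocks[b][2])
        for b in order
    ]
    return np.concatenate(pieces)


def block_randomize(residuals: ResidualSeries, scheme: BlockScheme, seed=0):
    """One joint block permutation of the residuals.

    The same permutation of block indices is applied to every variable and
    site; within-block day order is untouched.  Returns (permuted
    ResidualSeries, day index map).
    """
    V, S, Y, D = residuals.values.shape
    if scheme.season_length != D or scheme.n_years != Y:
        raise ValueError("block scheme does not match the residual layout")
    rng = np.random.default_rng(seed)
    idx = permuted_day_index(scheme, rng)
    flat = residuals.values.reshape(V, S, Y * D)
    permuted = flat[:, :, idx].reshape(V, S, Y, D)
    return (
        ResidualSeries(
            values=permuted, variables=residuals.variables,
            site_ids=residuals.site_ids, years=residuals.years,
            n_zero_sd=residuals.n_zero_sd,
        ),
        idx,
    )


def reconstruct(permuted_residuals: ResidualSeries, smoothed: SmoothedSeries):
    """x*_t = r*_t · SD_t + mean_t with SD/mean from the receiving calendar
    position t, as EnvArrays-shaped values [V, S, Y, D]."""
    V, S, Y, D = permuted_residuals.values.shape
    if smoothed.mean.shape != (V, S, D):
        raise ValueError("smoothed series does not match the residual layout")
    return (
        permuted_residuals.values * smoothed.sd[:, :, None, :]
        + smoothed.mean[:, :, None, :]
    )


# ---------------------------------------------------------------------------
# the full bootstrap loop

def _monthly_aggregator(env: EnvArrays, time_index: pd.DataFrame) -> np.ndarray:
    """(T, Y*D) row-normalized matrix averaging days into fitted months."""
    Y, D = len(env.years), env.values.shape[-1]
    dates = env.dates
    years = np.array([d.year for d in dates])
    months = np.array([d.month for d in dates])
    M = np.zeros((len(time_index), Y * D))
    for row in time_index.itertuples():
        mask = (years == row.year) & (months == row.month)
        if not mask.any():
            raise ValueError(
                f"no environmental days for fitted month {row.year}-{row.month}"
            )
        M[row.t, mask] = 1.0 / mask.sum()
    return M


def run_bootstrap(
    fit,
    env_history: pd.DataFrame,
    sites: pd.DataFrame,
    mode: str = "stochastic",
    n_iter: int = 500,
    seed=0,
    window_days: int = 15,
    block_length: int | None = None,
    max_lag: int = 60,
    response_draws: bool = True,
    identity_permutation: bool = False,
) -> BootstrapOutput:
    """Drive the fitted model over bootstrapped environmental histories.

    Per iteration: randomize the designated component (``stochastic``:
    residual blocks; ``deterministic``: climatological-mean blocks, with
    residuals and the SD profile staying in place), reconstruct the daily
    series, average them into the fitted (year, month) grid, and predict
    outbreak rates λ per (site, month) by the plug-in linear predictor plus
    the fitted latent field.  Per-month maxima over sites and years are
    taken on Poisson draws of λ (``response_draws=True``), matching the
    integer nature of observed monthly outbreak-day maxima.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    env_vars = [v for v in ENV_VARS if v in fit.spec.covariates]
    env = env_to_arrays(env_history, variables=env_vars)
    site_ids = np.array(sorted(sites["site_id"]))
    if not np.array_equal(env.site_ids, site_ids):
        raise ValueError("environmental history and site table cover different sites")

    smoothed = smooth_series(env, window_days=window_days)
    residuals = standardize_residuals(env, smoothed)
    if block_length is None:
        per_var = decorrelation_time(residuals, max_lag=max_lag)
        block_length = max(per_var.values())
    scheme = build_block_scheme(residuals, block_length)

    V, S, Y, D = env.values.shape
    time_index = fit.time_index
    T = len(time_index)
    M = _monthly_aggregator(env, time_index)          # (T, Y*D)

    # static part of the linear predictor: intercept, dist_canyon, month,
    # year, plus the fitted latent field projected to sites
    beta = dict(zip(fit.beta_names, fit.beta_mean))
    extra = set(fit.spec.covariates) - set(env_vars) - {"dist_canyon", "month", "year"}
    if extra:
        raise ValueError(f"covariates without an environmental series: {sorted(extra)}")
    dist = (
        sites.set_index("site_id").loc[site_ids, "dist_canyon"].to_numpy(float)
        if "dist_canyon" in fit.spec.covariates else np.zeros(S)
    )
    eta_static = np.full((S, T), beta["intercept"])
    if "dist_canyon" in beta:
        eta_static += np.outer(beta["dist_canyon"] * dist, np.ones(T))
    for row in time_index.itertuples():
        if "month" in beta:
            eta_static[:, row.t] += beta["month"] * row.month
        if "year" in beta:
            eta_static[:, row.t] += beta["year"] * row.year
    if fit.latent_mean is not None:
        order = np.argsort(fit.projector.site_ids)
        pos = order[np.searchsorted(fit.projector.site_ids[order], site_ids)]
        lat = (fit.projector.B[pos] @ fit.latent_mean.T)  # (S, T)
        eta_static += lat

    def standardized(name, arr):
        if name in fit.standardize_stats:
            mu, sd = fit.standardize_stats[name]
            return (arr - mu) / sd
        return arr

    r_flat = residuals.values.reshape(V, S, Y * D)
    mean_flat = np.broadcast_to(
        smoothed.mean[:, :, None, :], (V, S, Y, D)
    ).reshape(V, S, Y * D)
    sd_flat = np.broadcast_to(
        smoothed.sd[:, :, None, :], (V, S, Y, D)
    ).reshape(V, S, Y * D)

    rng = np.random.default_rng(seed)
    predictions = np.empty((n_iter, S, T))
    months = time_index["month"].to_numpy()
    max_rows = []
    for it in range(n_iter):
        if identity_permutation:
            idx = np.arange(Y * D)
        else:
            idx = permuted_day_index(scheme, rng)
        if mode == "stochastic":
            x = r_flat[:, :, idx] * sd_flat + mean_flat
        else:
            x = r_flat * sd_flat + mean_flat[:, :, idx]
        monthly = x @ M.T                              # (V, S, T)
        eta = eta_static.copy()
        for vi, name in enumerate(env_vars):
            eta += beta[name] * standardized(name, monthly[vi])
        lam = np.exp(np.clip(eta, -30.0, 30.0))
        predictions[it] = lam
        vals = rng.poisson(lam) if response_draws else lam
        for m in np.unique(months):
            sel = vals[:, months == m]
            max_rows.append(
                {"iteration": it, "month": int(m), "maximum": float(sel.max())}
            )

    return BootstrapOutput(
        predictions=predictions,
        maxima=pd.DataFrame(max_rows),
        mode=mode,
        site_ids=site_ids,
        time_index=time_index.copy(),
        n_iter=n_iter,
        block_length_days=int(block_length),
    )
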