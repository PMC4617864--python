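"""End-to-end pipeline: simulate → fit → bootstrap ×2 → extremes → compare.

Each stage persists its outputs as CSV/YAML under its own subdirectory and
drops a ``.done`` marker; a rerun with ``resume=True`` skips completed
stages and reloads their outputs, so a full run and a resumed run produce
identical final tables.  The resolved configuration and a plain-text log
are written next to the outputs of every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import env_bootstrap as eb
from . import extremes as ext
from . import io as jio
from . import mesh_spde as ms
from . import outbreak_model as om
from . import synthetic_data as sd
from .config import Config, stage_seed

__all__ = ["run_pipeline", "load_fit_for_prediction", "PredictiveFit"]

log = logging.getLogger("jellybloom.pipeline")


@dataclass
class PredictiveFit:
    """The slice of a fit needed for prediction, reloadable from disk."""

    beta_names: list
    beta_mean: np.ndarray
    latent_mean: np.ndarray | None
    time_index: pd.DataFrame
    projector: object
    standardize_stats: dict
    theta_hat: dict
    spec: SimpleNamespace = field(default=None)


def _done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path):
    (stage_dir / ".done").write_text("ok\n")


def _build_mesh_projector(cfg: Config, sites: pd.DataFrame):
    mesh = ms.build_mesh(
        sites,
        max_edge_interior=cfg.mesh_max_edge,
        max_edge_outer=cfg.mesh_outer_edge,
        buffer_width=cfg.mesh_buffer,
    )
    proj = ms.build_projector(mesh, sites, weight_mode=cfg.projector_weights)
    return mesh, proj


def stage_simulate(cfg: Config, out: Path) -> dict:
    stage = out / "simulate"
    if _done(stage):
        log.info("simulate: resuming from %s", stage)
        return {
            "sites": jio.read_sites(stage / "sites.csv"),
            "env": jio.read_env_daily(stage / "env_daily.csv"),
            "counts": jio.read_counts(stage / "counts.csv"),
        }
    stage.mkdir(parents=True, exist_ok=True)
    truth = sd.TrueParams(seed=cfg.master_seed)
    truth.validate()
    sites = sd.generate_sites(
        n_sites=cfg.n_sites,
        coast_length_km=cfg.coast_length_km,
        canyon_positions_km=cfg.canyon_positions_km,
        seed=stage_seed(cfg.master_seed, "sites"),
    )
    env = sd.generate_environment(
        sites, cfg.env_years, truth.env,
        seed=stage_seed(cfg.master_seed, "environment"),
    )
    mesh, proj = _build_mesh_projector(cfg, sites)
    cov = sd.monthly_mean_covariates(env, sites, years=cfg.sampling_years)
    T = cov[["year", "month"]].drop_duplicates().shape[0]
    spde = ms.build_spde_precision(mesh, truth.kappa, truth.sigma_w2)
    zeta = ms.sample_st_field(
        spde, truth.a, T, seed=stage_seed(cfg.master_seed, "latent")
    )
    # align latent values with covariate rows
    times = cov[["year", "month"]].drop_duplicates().sort_values(["year", "month"])
    tmap = {tuple(r): i for i, r in enumerate(times.to_numpy())}
    site_row = {s: i for i, s in enumerate(proj.site_ids)}
    lat_site = proj.B @ zeta.T  # (S, T)
    latent_obs = np.array(
        [
            lat_site[site_row[s], tmap[(y, m)]]
            for s, y, m in zip(cov["site_id"], cov["year"], cov["month"])
        ]
    )
    counts = sd.simulate_outbreak_counts(
        cov, latent_obs, truth.beta,
        seed=stage_seed(cfg.master_seed, "counts"),
    )
    jio.write_table(sites, stage / "sites.csv")
    jio.write_table(env, stage / "env_daily.csv")
    jio.write_table(counts, stage / "counts.csv")
    (stage / "truth.yml").write_text(
        yaml.safe_dump(
            {
                "beta": truth.beta, "kappa": truth.kappa,
                "sigma_w2": truth.sigma_w2, "a": truth.a,
                "sigma_t2": truth.sigma_t2,
            }
        )
    )
    _mark_done(stage)
    log.info("simulate: %d sites, %d env rows, %d count rows",
             len(sites), len(env), len(counts))
    # hand downstream stages the persisted form, so fresh and resumed runs
    # consume identical inputs
    return {
        "sites": jio.read_sites(stage / "sites.csv"),
        "env": jio.read_env_daily(stage / "env_daily.csv"),
        "counts": jio.read_counts(stage / "counts.csv"),
    }


def save_fit(fit: om.FitResult, stage: Path):
    fit.params.to_csv(stage / "params.csv")
    if fit.latent_mean is not None:
        T, G = fit.latent_mean.shape
        lat = pd.DataFrame(
            {
                "t": np.repeat(np.arange(T), G),
                "vertex": np.tile(np.arange(G), T),
                "value": fit.latent_mean.ravel(),
            }
        )
        lat.to_csv(stage / "latent.csv", index=False)
    meta = {
        "beta_names": list(fit.beta_names),
        "beta_mean": [float(b) for b in fit.beta_mean],
        "theta_hat": {k: (None if not np.isfinite(v) else float(v))
                      for k, v in fit.theta_hat.items()},
        "covariates": list(fit.spec.covariates),
        "standardize_stats": {
            k: [float(a), float(b)] for k, (a, b) in fit.standardize_stats.items()
        },
        "time_index": fit.time_index.to_dict("list"),
    }
    (stage / "fit_meta.yml").write_text(yaml.safe_dump(meta))


def load_fit_for_prediction(stage: Path, projector) -> PredictiveFit:
    meta = yaml.safe_load((stage / "fit_meta.yml").read_text())
    latent = None
    if (stage / "latent.csv").exists():
        lat = pd.read_csv(stage / "latent.csv")
        T = int(lat["t"].max()) + 1
        G = int(lat["vertex"].max()) + 1
        latent = lat["value"].to_numpy().reshape(T, G)
    spec_like = SimpleNamespace(covariates=list(meta["covariates"]))
    return PredictiveFit(
        beta_names=meta["beta_names"],
        beta_mean=np.array(meta["beta_mean"]),
        latent_mean=latent,
        time_index=pd.DataFrame(meta["time_index"]),
        projector=projector,
        standardize_stats={
            k: tuple(v) for k, v in meta["standardize_stats"].items()
        },
        theta_hat={k: (np.nan if v is None else v)
                   for k, v in meta["theta_hat"].items()},
        spec=spec_like,
    )


def stage_fit(cfg: Config, out: Path, data: dict) -> PredictiveFit:
    stage = out / "fit"
    mesh, proj = _build_mesh_projector(cfg, data["sites"])
    if _done(stage):
        log.info("fit: resuming from %s", stage)
        return load_fit_for_prediction(stage, proj)
    stage.mkdir(parents=True, exist_ok=True)

    cal_ids, val_ids = om.split_sites(
        data["sites"], cfg.calibration_fraction,
        seed=stage_seed(cfg.master_seed, "split"),
    )
    counts = data["counts"]
    vif = om.compute_vif(counts[list(cfg.covariates)])
    vif.to_csv(stage / "vif.csv", header=["vif"])

    spec = om.ModelSpec(
        covariates=list(cfg.covariates),
        include_latent=cfg.include_latent,
        include_iid_effect=cfg.include_iid_effect,
        standardize=cfg.standardize,
        seed=stage_seed(cfg.master_seed, "fit"),
    )
    fit = om.fit_model(
        counts[counts["site_id"].isin(cal_ids)], spec, mesh, proj
    )
    metrics = om.validate(
        fit, counts[counts["site_id"].isin(val_ids)],
        seed=stage_seed(cfg.master_seed, "validate"),
    )
    save_fit(fit, stage)
    (stage / "validation.yml").write_text(yaml.safe_dump(
        {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
         for k, v in metrics.items()}
    ))
    pd.DataFrame({"site_id": cal_ids}).to_csv(stage / "calibration_sites.csv",
                                              index=False)
    _mark_done(stage)
    log.info("fit: RMSE %.3f corr %.3f coverage %.3f",
             metrics["rmse"], metrics["correlation"], metrics["actual_coverage"])
    return load_fit_for_prediction(stage, proj)


def stage_bootstrap(cfg: Config, out: Path, data: dict, fit: PredictiveFit,
                    mode: str) -> dict:
    stage = out / f"boot_{mode}"
    if _done(stage):
        log.info("bootstrap[%s]: resuming", mode)
        return {
            "maxima": pd.read_csv(stage / "maxima.csv"),
            "site_sd": pd.read_csv(stage / "site_sd.csv"),
        }
    stage.mkdir(parents=True, exist_ok=True)
    boot = eb.run_bootstrap(
        fit, data["env"], data["sites"], mode=mode,
        n_iter=cfg.n_iter,
        seed=stage_seed(cfg.master_seed, f"boot_{mode}"),
        window_days=cfg.window_days,
        response_draws=cfg.response_draws,
    )
    sd_table = cmp.per_site_sd(boot)
    jio.write_table(boot.maxima, stage / "maxima.csv")
    jio.write_table(sd_table, stage / "site_sd.csv")
    _mark_done(stage)
    log.info("bootstrap[%s]: %d iterations, block length %d days",
             mode, boot.n_iter, boot.block_length_days)
    return {"maxima": boot.maxima, "site_sd": sd_table}


def stage_extremes(cfg: Config, out: Path, maxima: pd.DataFrame) -> dict:
    stage = out / "extremes"
    if _done(stage):
        return {
            "gev": pd.read_csv(stage / "gev_params.csv"),
            "curves": pd.read_csv(stage / "return_curves.csv"),
        }
    stage.mkdir(parents=True, exist_ok=True)
    rows, curves = [], []
    for month in cfg.months_report:
        vals = maxima.loc[maxima["month"] == month, "maximum"].to_numpy()
        try:
            params = ext.fit_gev(vals, jitter=0.5,
                                 seed=stage_seed(cfg.master_seed, "extremes"))
        except (ValueError, RuntimeError) as exc:
            log.warning("extremes: month %d skipped (%s)", month, exc)
            continue
        rows.append(
            {"month": month, "mu": params.mu, "sigma": params.sigma,
             "xi": params.xi, "loglik": params.loglik, "n": params.n}
        )
        curves.append(ext.return_curve(params, month=month).to_frame())
    gev = pd.DataFrame(rows)
    curve_df = (
        pd.concat(curves, ignore_index=True) if curves
        else pd.DataFrame(columns=["month", "return_period", "return_level"])
    )
    jio.write_table(gev, stage / "gev_params.csv")
    jio.write_table(curve_df, stage / "return_curves.csv")
    _mark_done(stage)
    return {"gev": gev, "curves": curve_df}


def stage_compare(cfg: Config, out: Path, sd_s: pd.DataFrame,
                  sd_d: pd.DataFrame) -> dict:
    stage = out / "compare"
    if _done(stage):
        return {
            "paired": pd.read_csv(stage / "paired_sd.csv"),
            "wilcoxon": yaml.safe_load((stage / "wilcoxon.yml").read_text()),
        }
    stage.mkdir(parents=True, exist_ok=True)
    paired = cmp.pair_sd_tables(sd_s, sd_d)
    result = cmp.wilcoxon_signed_rank(paired)
    report = cmp.mode_contrast_report(paired, result)
    jio.write_table(paired, stage / "paired_sd.csv")
    (stage / "wilcoxon.yml").write_text(yaml.safe_dump(
        {
            "W": result.statistic, "p_value": result.p_value,
            "n_used": result.n_used, "n_zero_dropped": result.n_zero_dropped,
            "method": result.method,
            "median_stochastic": report["median_stochastic"],
            "median_deterministic": report["median_deterministic"],
            "direction": report["direction"],
        }
    ))
    hist = pd.DataFrame(
        {
            "bin_left": report["bin_edges"][:-1],
            "bin_right": report["bin_edges"][1:],
            "stochastic": report["hist_stochastic"],
            "deterministic": report["hist_deterministic"],
        }
    )
    jio.write_table(hist, stage / "histogram.csv")
    _mark_done(stage)
    log.info("compare: %s (W=%.0f, p=%.3g)", report["direction"],
             result.statistic, result.p_value)
    return {"paired": paired, "wilcoxon": result, "report": report}


def run_pipeline(cfg: Config, out_dir, resume: bool = True) -> dict:
    """Run every stage; with ``resume`` (default) completed stages are
    reloaded from disk instead of recomputed."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not resume:
        for marker in out.glob("*/.done"):
            marker.unlink()
    handler = logging.FileHandler(out / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg.to_yaml(out / "resolved_config.yml")
        data = stage_simulate(cfg, out)
        fit = stage_fit(cfg, out, data)
        boot_s = stage_bootstrap(cfg, out, data, fit, "stochastic")
        boot_d = stage_bootstrap(cfg, out, data, fit, "deterministic")
        extremes_out = stage_extremes(cfg, out, boot_s["maxima"])
        compare_out = stage_compare(cfg, out, boot_s["site_sd"], boot_d["site_sd"])
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return {
        "data": data, "fit": fit, "boot_stochastic": boot_s,
        "boot_deterministic": boot_d, "extremes": extremes_out,
        "compare": compare_out, "out_dir": out,
    }
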