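"""Deterministic vs stochastic forcing: paired per-site variability contrast.

For each (site, year, month) cell, the sample SD of predicted outbreak
rates across bootstrap replicates measures how strongly the randomized
component drives predictions there: randomizing a weak component barely
moves the predictions, a strong one spreads them out.  Cells are matched by
site, year and month between the two randomization schemes and compared
with the Wilcoxon signed-rank test.

The signed-rank statistic reported is W⁺, the rank sum of the positive
differences.  The exact null distribution (all 2ⁿ sign assignments equally
likely) is computed by the standard rank-sum recursion when the absolute
differences are tie-free and n ≤ 25; otherwise the normal approximation
with continuity and tie corrections is used.  Zero differences are dropped
and their count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "per_site_sd",
    "pair_sd_tables",
    "wilcoxon_signed_rank",
    "mode_contrast_report",
]


@dataclass
class WilcoxonResult:
    statistic: float          # W⁺, rank sum of positive differences
    p_value: float
    n_used: int
    n_zero_dropped: int
    method: str               # "exact" or "normal"
    alternative: str = "two-sided"


def per_site_sd(bootstrap_output) -> pd.DataFrame:
    """Sample SD (ddof=1) of predicted rates across replicates per cell."""
    preds = bootstrap_output.predictions
    if preds.shape[0] < 2:
        raise ValueError("need at least 2 replicates to compute an SD")
    sds = preds.std(axis=0, ddof=1)          # (S, T)
    ti = bootstrap_output.time_index
    rows = []
    for s_i, sid in enumerate(bootstrap_output.site_ids):
        for row in ti.itertuples():
            rows.append(
                {"site_id": sid, "year": int(row.year), "month": int(row.month),
                 "sd": float(sds[s_i, row.t])}
            )
    return pd.DataFrame(rows)


def pair_sd_tables(sd_stochastic: pd.DataFrame, sd_deterministic: pd.DataFrame) -> pd.DataFrame:
    """Match the two per-site SD tables by (site, year, month)."""
    merged = sd_stochastic.merge(
        sd_deterministic,
        on=["site_id", "year", "month"],
        suffixes=("_stochastic", "_deterministic"),
        how="inner",
        validate="one_to_one",
    )
    if len(merged) == 0:
        raise ValueError("no matching (site, year, month) cells between tables")
    return merged.rename(
        columns={"sd_stochastic": "sd_stochastic", "sd_deterministic": "sd_deterministic"}
    )


def _exact_sf_cdf(ranks: np.ndarray, w: int):
    """P(W⁺ ≤ w) and P(W⁺ ≥ w) under the exact signed-rank null.

    ``ranks`` must be the integers 1..n in some order (no ties).  Uses the
    generating-function recursion: each rank contributes (1 + x^r)/2.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= 2.0 ** len(ranks)
    cdf = float(counts[: w + 1].sum())
    sf = float(counts[w:].sum())
    return cdf, sf


def wilcoxon_signed_rank(paired, alternative: str = "two-sided") -> WilcoxonResult:
    """Signed-rank test on paired SDs (or a precomputed difference vector).

    Accepts a PairedSDTable-style DataFrame (columns ``sd_stochastic``,
    ``sd_deterministic``; differences are deterministic − stochastic) or a
    1-D array of differences.
    """
    if isinstance(paired, pd.DataFrame):
        d = (
            paired["sd_deterministic"].to_numpy(float)
            - paired["sd_stochastic"].to_numpy(float)
        )
    else:
        d = np.asarray(paired, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    if n < 5:
        # exact machinery still works; warn-level smallness is the caller's concern
        pass
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())

    ties = len(np.unique(absd)) < n
    if not ties and n <= 25:
        cdf, sf = _exact_sf_cdf(np.sort(ranks), int(round(w_plus)))
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(absd, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        if var <= 0:
            raise ValueError("zero variance in the signed-rank null (all ties)")
        # continuity correction toward the mean
        if alternative == "greater":
            z = (w_plus - mean - 0.5) / np.sqrt(var)
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mean + 0.5) / np.sqrt(var)
            p = float(stats.norm.cdf(z))
        else:
            z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / np.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(
        statistic=w_plus, p_value=float(max(p, np.finfo(float).tiny)),
        n_used=n, n_zero_dropped=n_zero, method=method, alternative=alternative,
    )


def mode_contrast_report(
    paired: pd.DataFrame, wilcoxon: WilcoxonResult | None = None, n_bins: int = 30
) -> dict:
    """Histograms, medians and dominance direction of the paired SDs."""
    s = paired["sd_stochastic"].to_numpy(float)
    dd = paired["sd_deterministic"].to_numpy(float)
    lo = min(s.min(), dd.min())
    hi = max(s.max(), dd.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    med_s, med_d = float(np.median(s)), float(np.median(dd))
    if med_d > med_s:
        direction = "deterministic > stochastic"
    elif med_d < med_s:
        direction = "stochastic > deterministic"
    else:
        direction = "none"
    report = {
        "bin_edges": edges,
        "hist_stochastic": np.histogram(s, bins=edges)[0],
        "hist_deterministic": np.histogram(dd, bins=edges)[0],
        "median_stochastic": med_s,
        "median_deterministic": med_d,
        "direction": direction,
        "n_pairs": len(paired),
    }
    if wilcoxon is not None:
        report["wilcoxon"] = wilcoxon
    return report
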