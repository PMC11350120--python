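"""Early-warning-signal (critical slowing down) diagnostics for tree growth.

A system losing resilience recovers more slowly from perturbations, which
shows up in its fluctuations as rising lag-1 autocorrelation (AR1) and rising
variance.  Per tree, the BAI series is detrended with a Gaussian-kernel
smoother, AR1 and SD are computed in a moving window (default 15 years, i.e.
30% of a 50-year record, labelled by the window's last year), and the trend
of each metric over time is summarised by the nonparametric Mann-Kendall tau.
At the site level the per-tree tau values are averaged and a one-sided
one-sample t-test asks whether the mean trend is positive (rising AR1/SD, a
warning) or negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EWSResult",
    "SiteEwsSummary",
    "gaussian_detrend",
    "moving_window_metrics",
    "mann_kendall",
    "sens_slope",
    "site_ews",
]


class MannKendallResult(NamedTuple):
    s: int
    var_s: float
    z: float
    tau: float
    p: float


@dataclass
class EWSResult:
    """Per-tree moving-window AR1/SD trajectories and their MK trends."""

    tree_id: str
    window_end_years: np.ndarray
    ar1: np.ndarray
    sd: np.ndarray
    tau_ar1: float
    tau_sd: float
    p_ar1: float
    p_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "window_end_year": self.window_end_years,
                "ar1": self.ar1,
                "sd": self.sd,
            }
        )


@dataclass
class SiteEwsSummary:
    """Across-tree mean +/- SE of the tau trends with one-sided t-tests.

    ``p_onesided_*`` is the p-value for mean tau > 0 (rising metric); the
    symmetric test for a falling metric is its complement 1 - p.
    """

    site_id: str
    n_trees: int
    mean_tau_ar1: float
    se_tau_ar1: float
    mean_tau_sd: float
    se_tau_sd: float
    p_onesided_ar1: float
    p_onesided_sd: float


def gaussian_detrend(series, bandwidth: float) -> np.ndarray:
    """Residuals after removing a Gaussian-kernel local mean (the
    low-frequency signal).  ``bandwidth`` is the kernel SD in years.

    Weights are renormalised at the edges (no padding), so a constant series
    gives exactly zero residuals.
    """
    y = np.asarray(series, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if y.size < 3:
        raise ValueError("series shorter than 3")
    t = np.arange(y.size)
    w = np.exp(-0.5 * ((t[:, None] - t[None, :]) / bandwidth) ** 2)
    smooth = (w @ y) / w.sum(axis=1)
    return y - smooth


def moving_window_metrics(
    residuals, window: int = 15, years: np.ndarray | None = None
) -> pd.DataFrame:
    """Lag-1 autocorrelation and SD in a right-aligned moving window.

    Returns one row per window, labelled by the window's last year (so a
    1965-2014 series with window 15 has 36 windows, the first labelled 1979).
    AR1 is the lag-1 sample autocorrelation within the window (shift- and
    scale-invariant); SD uses the n-1 denominator.  A constant window leaves
    AR1 undefined (NaN, with a warning).
    """
    x = np.asarray(residuals, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    if x.size < window:
        raise ValueError("series shorter than the window")
    if years is None:
        years = np.arange(x.size)
    years = np.asarray(years)
    n_win = x.size - window + 1
    ar1 = np.full(n_win, np.nan)
    sd = np.full(n_win, np.nan)
    n_const = 0
    for i in range(n_win):
        w = x[i : i + window]
        sd[i] = np.std(w, ddof=1)
        a, b = w[:-1], w[1:]
        if np.std(a) == 0 or np.std(b) == 0:
            n_const += 1
            continue
        ar1[i] = np.corrcoef(a, b)[0, 1]
    if n_const:
        warnings.warn(
            f"{n_const} constant window(s): AR1 undefined, emitted as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {"window_end_year": years[window - 1 :], "ar1": ar1, "sd": sd}
    )


def mann_kendall(series) -> MannKendallResult:
    """Mann-Kendall trend test with tie correction.

    S = sum_{i<j} sign(x_j - x_i); var(S) carries the usual tie term; tau is
    the tau-b form S / sqrt((n0 - T) * n0) with n0 = n(n-1)/2 and T the number
    of tied pairs (time itself is never tied).  The p-value uses the normal
    approximation with continuity correction, two-tailed.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.sum(np.triu(diff, k=1)))
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    n0 = n * (n - 1) / 2.0
    t_pairs = float(np.sum(ties * (ties - 1) / 2.0))
    denom = np.sqrt((n0 - t_pairs) * n0)
    tau = s / denom if denom > 0 else 0.0
    if var_s <= 0:
        return MannKendallResult(s, float(var_s), 0.0, float(tau), 1.0)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return MannKendallResult(s, float(var_s), float(z), float(tau), float(p))


def sens_slope(series, t=None) -> float:
    """Theil-Sen estimate: median of pairwise slopes (x_j - x_i)/(t_j - t_i).

    Robust companion to the Mann-Kendall test; exact for a noiseless line and
    unmoved by a symmetric outlier.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    i, j = np.triu_indices(n, k=1)
    dt = t[j] - t[i]
    ok = dt != 0
    return float(np.median((x[j] - x[i])[ok] / dt[ok]))


def _one_sided_greater(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, SE and one-sided p (H1: mean > 0) from a one-sample t-test."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 trees for the site-level t-test")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(n))
    if se == 0:
        return mean, se, 0.0 if mean > 0 else 1.0
    p = float(stats.t.sf(mean / se, n - 1))
    return mean, se, p


def site_ews(
    bai_by_tree: dict[str, pd.Series] | Sequence,
    window: int = 15,
    bandwidth: float | None = None,
    site_id: str = "site",
) -> tuple[list[EWSResult], SiteEwsSummary]:
    """Full per-site EWS procedure.

    ``bai_by_tree`` maps tree id -> annual pd.Series (year-indexed), or is a
    sequence of objects with ``series_id``/``years``/``bai`` attributes.  Each
    tree is Gaussian-detrended (default kernel SD = 10% of its series length),
    AR1/SD moving-window trajectories are computed, their Mann-Kendall tau
    trends extracted, and the across-tree mean tau tested one-sided against 0.
    """
    if not isinstance(bai_by_tree, dict):
        bai_by_tree = {
            b.series_id: pd.Series(b.bai, index=b.years) for b in bai_by_tree
        }
    results: list[EWSResult] = []
    for tree_id, ser in bai_by_tree.items():
        ser = ser.dropna()
        y = ser.to_numpy(dtype=float)
        bw = bandwidth if bandwidth is not None else max(0.1 * y.size, 1.0)
        res = gaussian_detrend(y, bw)
        metrics = moving_window_metrics(res, window, years=ser.index.to_numpy())
        def _trend(col: np.ndarray) -> tuple[float, float]:
            ok = np.isfinite(col)
            if ok.sum() < 3:
                return np.nan, np.nan
            mk = mann_kendall(col[ok])
            return mk.tau, mk.p
        tau_a, p_a = _trend(metrics["ar1"].to_numpy())
        tau_s, p_s = _trend(metrics["sd"].to_numpy())
        results.append(
            EWSResult(
                tree_id=str(tree_id),
                window_end_years=metrics["window_end_year"].to_numpy(),
                ar1=metrics["ar1"].to_numpy(),
                sd=metrics["sd"].to_numpy(),
                tau_ar1=tau_a,
                tau_sd=tau_s,
                p_ar1=p_a,
                p_sd=p_s,
            )
        )
    mean_a, se_a, p_a = _one_sided_greater(np.array([r.tau_ar1 for r in results]))
    mean_s, se_s, p_s = _one_sided_greater(np.array([r.tau_sd for r in results]))
    summary = SiteEwsSummary(
        site_id=site_id,
        n_trees=len(results),
        mean_tau_ar1=mean_a,
        se_tau_ar1=se_a,
        mean_tau_sd=mean_s,
        se_tau_sd=se_s,
        p_onesided_ar1=p_a,
        p_onesided_sd=p_s,
    )
    return results, summary
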