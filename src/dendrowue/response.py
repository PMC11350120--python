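"""Lagged monthly climate-growth correlation matrices.

An annual response (BAI chronology, delta13C or iWUE) is correlated with each
monthly climate variable over a 24-month window: January of the previous year
(labelled with a trailing ``*``) through December of the current year.
Significance uses the analytic two-tailed t threshold, |r| >= r_crit(n, alpha),
with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "align_lagged",
    "pearson_r",
    "critical_r",
    "correlation_matrix",
    "spei_scale_screen",
    "month_labels_24",
]

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def month_labels_24() -> list[str]:
    """24 lag labels: previous-year months carry a trailing ``*``."""
    return [m + "*" for m in _MONTHS] + list(_MONTHS)


@dataclass
class CorrelationMatrix:
    """One response x one monthly variable over 24 lag months."""

    response_name: str
    variable_name: str
    month_labels: list[str]
    r: np.ndarray
    n: np.ndarray
    p: np.ndarray
    r_crit: float
    alpha: float
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": self.response_name,
                "variable": self.variable_name,
                "month": self.month_labels,
                "r": self.r,
                "n": self.n,
                "p": self.p,
                "significant": self.significant,
            }
        )


def align_lagged(annual: pd.Series, monthly: pd.Series) -> pd.DataFrame:
    """Pair an annual series with 24 lagged monthly columns.

    ``annual`` is indexed by year; ``monthly`` by (year, month).  For response
    year t the columns hold Jan(t-1)..Dec(t-1), Jan(t)..Dec(t).  Rows are kept
    whenever the response exists (missing monthly cells stay NaN; correlation
    uses pairwise-complete deletion per column).  Requires >= 3 usable years.
    """
    monthly = monthly.copy()
    monthly.index = pd.MultiIndex.from_tuples(
        [(int(y), int(m)) for y, m in monthly.index], names=["year", "month"]
    )
    labels = month_labels_24()
    rows = {}
    for year, resp in annual.items():
        if not np.isfinite(resp):
            continue
        cells = []
        for lag_year in (year - 1, year):
            for m in range(1, 13):
                cells.append(monthly.get((lag_year, m), np.nan))
        if np.any(np.isfinite(cells)):
            rows[year] = cells
    if len(rows) < 3:
        raise ValueError("fewer than 3 overlapping years after lagging")
    out = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    out.index.name = "year"
    out["response"] = annual.loc[out.index].to_numpy(dtype=float)
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-tailed p-value from
    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt(n - 2) / np.sqrt(1.0 - r_**2)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r_, float(p)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` (two-tailed) for sample size n.

    Solves the t-test equality: r = t_{1-alpha/2, n-2} / sqrt(t^2 + n - 2).
    For n = 50 and alpha = 0.05 this is 0.279 (3 dp).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def correlation_matrix(
    response: pd.Series,
    variables: dict[str, pd.Series],
    alpha: float = 0.05,
    response_name: str = "response",
) -> dict[str, CorrelationMatrix]:
    """Lagged monthly Pearson correlation matrices, one per climate variable.

    Cells are flagged significant when the two-tailed p-value is <= alpha
    (equivalently |r| >= r_crit at that cell's pairwise-complete n).  The
    reported ``r_crit`` header value uses the modal cell n.
    """
    out: dict[str, CorrelationMatrix] = {}
    labels = month_labels_24()
    for name, monthly in variables.items():
        table = align_lagged(response, monthly)
        resp = table["response"].to_numpy()
        r = np.full(24, np.nan)
        p = np.full(24, np.nan)
        n = np.zeros(24, dtype=int)
        for j, lab in enumerate(labels):
            col = table[lab].to_numpy(dtype=float)
            ok = np.isfinite(col) & np.isfinite(resp)
            n[j] = int(ok.sum())
            if n[j] >= 3 and np.std(col[ok]) > 0 and np.std(resp[ok]) > 0:
                r[j], p[j] = pearson_r(resp[ok], col[ok])
        n_typical = int(np.bincount(n[n >= 4]).argmax()) if np.any(n >= 4) else 0
        rc = critical_r(n_typical, alpha) if n_typical >= 4 else np.nan
        sig = np.isfinite(p) & (p <= alpha)
        out[name] = CorrelationMatrix(
            response_name=response_name,
            variable_name=name,
            month_labels=labels,
            r=r,
            n=n,
            p=p,
            r_crit=rc,
            alpha=alpha,
            significant=sig,
        )
    return out


def spei_scale_screen(
    bai: pd.Series,
    spei_by_scale: dict[int, pd.DataFrame],
    end_month: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank SPEI time scales by |r| with an annual BAI chronology.

    For each scale k the screened predictor is the SPEI-k value at the
    growing-season endpoint month (October by default, so the k-month window
    covers the May-October season and the months leading into it).  Returns a
    table sorted by descending |r| with Pearson p-values.
    """
    if not spei_by_scale:
        raise ValueError("no SPEI scales supplied")
    rows = []
    for k, tab in sorted(spei_by_scale.items()):
        sel = tab[tab["month"] == end_month].set_index("year")["value"]
        joined = pd.concat([bai.rename("bai"), sel.rename("spei")], axis=1).dropna()
        if len(joined) < 3:
            raise ValueError(f"scale {k}: fewer than 3 paired years")
        r, p = pearson_r(joined["bai"], joined["spei"])
        rows.append({"scale": k, "r": r, "abs_r": abs(r), "p": p,
                     "n": len(joined), "significant": p <= alpha})
    out = pd.DataFrame(rows).sort_values("abs_r", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
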