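"""Long-term trend description: loess smoothing, linear/Theil-Sen trends and
a simplified additive growth model.

The additive model describes per-tree annual BAI as a sum of smooth effects

    BAI ~ f_year(year) + f_age(age) + f_spei(SPEI) + alpha_tree + eps

fitted by backfitting with penalized cubic B-spline smooths (small basis,
second-difference penalty, penalty strength by generalized cross-validation on
a fixed log-grid) and per-tree intercepts absorbing tree identity.  It plays
the inferential role of a generalized additive mixed model with smoothing
basis dimension 4 per term, at desk scale: it is a deliberately simplified
stand-in, not a mixed-model smoother (no thin-plate bases, no formal random
effect variance).  Candidate models are compared with AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .ews import mann_kendall, sens_slope

__all__ = [
    "TrendFit",
    "AdditiveGrowthFit",
    "loess_trend",
    "linear_trend",
    "additive_growth_model",
    "aic_rank",
]


@dataclass
class TrendFit:
    """A fitted trend: loess, OLS or Theil-Sen."""

    method: str
    x: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    slope: float | None = None
    intercept: float | None = None
    p_value: float | None = None


def loess_trend(x, y, span: float = 0.75, degree: int = 2) -> TrendFit:
    """Local polynomial (loess) smooth with tricube weights and a pointwise
    95% band.

    For each target point the ``span`` fraction of nearest neighbours is
    locally fitted with a degree-``degree`` polynomial; the band is
    fit +/- 1.96 * sigma_hat * ||l_i|| from the equivalent-kernel rows, with
    sigma^2 estimated from the residuals and the smoother's effective df.
    Exactly reproduces a polynomial of degree <= ``degree``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 for loess")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted_s = np.empty(n)
    lev = np.empty(n)       # l_i at the target point (leverage)
    l_norm2 = np.empty(n)   # ||l_i||^2
    for i in range(n):
        d = np.abs(xs - xs[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(idx.size)
        else:
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-12)
        a = np.vander(xs[idx] - xs[i], degree + 1, increasing=True)
        aw = a * w[:, None]
        g = a.T @ aw
        # row of the hat matrix for the constant term at the target point
        li = np.linalg.solve(g, aw.T)[0]
        fitted_s[i] = li @ ys[idx]
        pos = np.where(idx == i)[0]
        lev[i] = li[pos[0]] if pos.size else 0.0
        l_norm2[i] = float(li @ li)
    resid = ys - fitted_s
    edf = float(np.sum(lev))
    dof = max(n - edf, 1.0)
    sigma2 = float(resid @ resid) / dof
    half = 1.96 * np.sqrt(sigma2 * l_norm2)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return TrendFit(
        method="loess",
        x=x,
        fitted=fitted_s[inv],
        band_lower=(fitted_s - half)[inv],
        band_upper=(fitted_s + half)[inv],
    )


def linear_trend(x, y) -> tuple[TrendFit, TrendFit]:
    """OLS trend (two-sided slope t-test, 95% band) and a Theil-Sen variant
    (median pairwise slope, Mann-Kendall p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    n = x.size
    resid = y - fitted
    sigma2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_fit = np.sqrt(sigma2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.975, n - 2)
    ols = TrendFit(
        method="ols",
        x=x,
        fitted=fitted,
        band_lower=fitted - tcrit * se_fit,
        band_upper=fitted + tcrit * se_fit,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )
    order = np.argsort(x)
    ts_slope = sens_slope(y[order], t=x[order])
    ts_icept = float(np.median(y) - ts_slope * np.median(x))
    mk = mann_kendall(y[order])
    ts = TrendFit(
        method="theil_sen",
        x=x,
        fitted=ts_icept + ts_slope * x,
        slope=ts_slope,
        intercept=ts_icept,
        p_value=mk.p,
    )
    return ols, ts


# ---------------------------------------------------------------------------
# Additive growth model
# ---------------------------------------------------------------------------

_LAMBDA_GRID = 10.0 ** np.linspace(-4, 8, 25)


def _bspline_basis(x: np.ndarray, basis_dim: int, degree: int = 3
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with ``basis_dim`` functions on the range
    of x (equally spaced interior knots)."""
    if basis_dim < degree + 1:
        raise ValueError(f"basis_dim must be >= {degree + 1}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate covariate (constant)")
    pad = 1e-9 * (hi - lo)
    n_interior = basis_dim - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate(
        [[lo - pad] * (degree + 1), interior, [hi + pad] * (degree + 1)]
    )
    b = BSpline.design_matrix(x, t, degree).toarray()
    return b, t


class _PenalizedSmooth:
    """One penalized-spline smooth with GCV-chosen penalty (deterministic)."""

    def __init__(self, x: np.ndarray, basis_dim: int):
        self.x = x
        self.basis, self.knots = _bspline_basis(x, basis_dim)
        m = self.basis.shape[1]
        d = np.diff(np.eye(m), n=2, axis=0)
        self.penalty = d.T @ d
        self.coef = np.zeros(m)
        self.lam = np.nan
        self.edf = 0.0

    def fit(self, r: np.ndarray) -> np.ndarray:
        b = self.basis
        btb = b.T @ b
        btr = b.T @ r
        n = r.size
        best = (np.inf, None, None, None)
        for lam in _LAMBDA_GRID:
            try:
                m_inv = np.linalg.inv(btb + lam * self.penalty)
            except np.linalg.LinAlgError:
                continue
            coef = m_inv @ btr
            fit = b @ coef
            edf = float(np.trace(m_inv @ btb))
            rss = float(np.sum((r - fit) ** 2))
            gcv = n * rss / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, lam, coef, edf)
        _, self.lam, self.coef, tr = best
        # trace of the smoother = coefficients effectively estimated; the
        # reported edf removes the constant direction, which the per-tree
        # intercepts absorb after centering
        self.trace = tr
        self.edf = max(tr - 1.0, 0.0)
        fit = b @ self.coef
        return fit - fit.mean()

    def values(self) -> np.ndarray:
        v = self.basis @ self.coef
        return v - v.mean()


@dataclass
class AdditiveGrowthFit:
    """Backfitted additive growth model."""

    term_names: list[str]
    components: dict[str, np.ndarray]      # centered, per observation
    covariates: dict[str, np.ndarray]
    intercepts: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    residual_var: float
    edf: dict[str, float]
    aic: float
    converged: bool
    n_iter: int

    def component_frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.covariates[name], "f": self.components[name]}
        ).sort_values("x")


def additive_growth_model(
    bai,
    year=None,
    age=None,
    spei=None,
    tree_ids=None,
    basis_dim: int = 4,
    max_iter: int = 200,
    tol: float = 1e-6,
    init_rng: np.random.Generator | None = None,
) -> AdditiveGrowthFit:
    """Fit BAI ~ s(year) + s(age) + s(SPEI) + tree intercepts by backfitting.

    Any of the smooth covariates may be omitted (``None``); with all omitted
    the model is intercepts-only.  Each smooth uses ``basis_dim`` cubic
    B-spline functions with a second-difference penalty whose strength is
    chosen by GCV on a fixed log-grid (seedless and deterministic).
    Components are centered each sweep, so they are identifiable up to
    additive constants absorbed by the intercepts.  Convergence: max change
    in any component below ``tol``; non-convergence is signalled with a
    warning and the partial fit returned flagged.

    AIC = n*log(RSS/n) + 2*(sum of smooth edf + number of intercepts),
    comparable across candidate term sets on the same data.
    """
    y = np.asarray(bai, dtype=float)
    n = y.size
    smooth_x = {}
    for name, arr in (("year", year), ("age", age), ("spei", spei)):
        if arr is not None:
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValueError(f"covariate {name} length mismatch")
            smooth_x[name] = arr
    if tree_ids is None:
        tree_ids = np.zeros(n, dtype=int)
    tree_ids = np.asarray(tree_ids)
    groups = pd.Series(np.arange(n)).groupby(pd.Series(tree_ids)).groups
    n_groups = len(groups)
    if smooth_x and n < 20:
        raise ValueError("need >= 20 observations to fit smooths")

    smooths = {k: _PenalizedSmooth(v, basis_dim) for k, v in smooth_x.items()}
    # components start at zero; a supplied generator randomises the start so
    # identifiability (components unique up to constants) can be exercised
    if init_rng is None:
        comp = {k: np.zeros(n) for k in smooths}
    else:
        comp = {}
        for k in smooths:
            c = init_rng.normal(0.0, np.std(y) if np.std(y) > 0 else 1.0, n)
            comp[k] = c - c.mean()
    alpha = np.zeros(n)
    for _, idx in groups.items():
        ii = np.asarray(idx)
        alpha[ii] = y[ii].mean()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_change = 0.0
        for name, sm in smooths.items():
            partial = y - alpha - sum(comp[k] for k in comp if k != name)
            new = sm.fit(partial)
            max_change = max(max_change, float(np.max(np.abs(new - comp[name]))))
            comp[name] = new
        resid_for_alpha = y - sum(comp.values()) if comp else y.copy()
        new_alpha = np.empty(n)
        for _, idx in groups.items():
            ii = np.asarray(idx)
            new_alpha[ii] = resid_for_alpha[ii].mean()
        max_change = max(max_change, float(np.max(np.abs(new_alpha - alpha))))
        alpha = new_alpha
        if max_change < tol:
            converged = True
            break
    if not converged and smooths:
        warnings.warn(
            f"backfitting did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    fitted = alpha + (sum(comp.values()) if comp else 0.0)
    resid = y - fitted
    rss = float(resid @ resid)
    edf = {k: sm.edf for k, sm in smooths.items()}
    # the AIC penalty counts every coefficient actually estimated (smoother
    # traces + intercepts); the reported per-smooth edf is the identifiable
    # nonlinear df (trace minus the centered constant)
    total_edf = sum(sm.trace for sm in smooths.values()) + n_groups
    aic = n * np.log(max(rss, 1e-300) / n) + 2.0 * total_edf
    intercepts = {str(k): float(alpha[np.asarray(idx)[0]]) for k, idx in groups.items()}
    dof = max(n - total_edf, 1.0)
    return AdditiveGrowthFit(
        term_names=list(smooths),
        components=comp,
        covariates=smooth_x,
        intercepts=intercepts,
        fitted=fitted,
        residuals=resid,
        residual_var=rss / dof,
        edf=edf,
        aic=float(aic),
        converged=converged or not smooths,
        n_iter=it,
    )


def aic_rank(fits: dict[str, AdditiveGrowthFit] | list[tuple[str, float]]) -> pd.DataFrame:
    """Rank candidate fits by ascending AIC with a delta-AIC column.

    Accepts a mapping name -> fit (or name -> AIC value); ties keep input
    order, and the ranking is invariant to adding a constant to every AIC.
    """
    if isinstance(fits, dict):
        items = [(k, v.aic if hasattr(v, "aic") else float(v)) for k, v in fits.items()]
    else:
        items = [(k, float(v)) for k, v in fits]
    if not items:
        raise ValueError("no fits to rank")
    df = pd.DataFrame(items, columns=["model", "aic"])
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    return df
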