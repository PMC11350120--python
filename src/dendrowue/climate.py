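"""Drought and atmospheric-demand indices from daily climate.

From daily precipitation, temperature and relative humidity this module
derives:

* vapour pressure deficit (VPD, hPa) from the Tetens saturation curve;
* extraterrestrial solar radiation (FAO-56 solar geometry);
* potential evapotranspiration (PET) from a Hargreaves-type relation,
  PET = 0.0029 * Ra * (Tmean + 20) * TR**0.4  (the study form; the classical
  Hargreaves coefficients are available behind ``variant``);
* the bounded climate moisture index CMI in [-1, 1] contrasting P and PET;
* monthly aggregates and the climatic water balance D = P - PET;
* the multiscalar SPEI: k-month sums of D fitted per calendar month with a
  3-parameter log-logistic distribution (unbiased probability-weighted
  moments) and mapped to standard-normal units.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

__all__ = [
    "vpd_tetens",
    "extraterrestrial_radiation",
    "pet_hargreaves",
    "cmi",
    "monthly_aggregate",
    "spei",
    "growing_season_cmi",
    "GROWING_SEASON_MONTHS",
]

#: May-October growing season used throughout.
GROWING_SEASON_MONTHS = (5, 6, 7, 8, 9, 10)


def vpd_tetens(t, rh):
    """Vapour pressure deficit (hPa) from temperature (degC) and RH (%).

    es = 6.1078 * exp(17.27*T / (T + 237.3));  vpd = es * (1 - RH/100).
    RH must lie in (0, 100]; at saturation the deficit is exactly 0.
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh <= 0) | (rh > 100)):
        raise ValueError("relative humidity must be in (0, 100]")
    es = 6.1078 * np.exp(17.27 * t / (t + 237.3))
    return es * (1.0 - rh / 100.0)


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily extraterrestrial solar radiation Ra (MJ m-2 day-1), FAO-56.

    Standard solar geometry: inverse relative Earth-Sun distance, solar
    declination and sunset hour angle; polar-night days return exactly 0.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude must be within [-90, 90] degrees")
    doy = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def pet_hargreaves(tmean, tmax, tmin, ra, variant: str = "modified_hargreaves"):
    """Potential evapotranspiration (mm day-1) from a Hargreaves-type relation.

    ``modified_hargreaves``:  PET = 0.0029 * Ra * (Tmean + 20) * TR**0.4  (study form,
    taken verbatim; whether 0.0029 absorbs the MJ->mm conversion is an open
    unit convention, see docs).  ``classic_hargreaves``:
    0.0023 * Ra * (Tmean + 17.8) * sqrt(TR).  Negative values are clamped
    to 0; requires tmax >= tmin.
    """
    tmean = np.asarray(tmean, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    ra = np.asarray(ra, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    tr = tmax - tmin
    if variant == "modified_hargreaves":
        pet = 0.0029 * ra * (tmean + 20.0) * tr**0.4
    elif variant == "classic_hargreaves":
        pet = 0.0023 * ra * (tmean + 17.8) * np.sqrt(tr)
    else:
        raise ValueError(f"unknown PET variant {variant!r}")
    return np.maximum(pet, 0.0)


def cmi(p, pet):
    """Climate moisture index, bounded to (-1, 1).

    CMI = P/PET - 1 when P < PET, 1 - PET/P when P > PET, and 0 at P = PET;
    antisymmetric under swapping P and PET.  Undefined (error) when both are
    zero.
    """
    p_arr = np.asarray(p, dtype=float)
    pet_arr = np.asarray(pet, dtype=float)
    if np.any(p_arr < 0) or np.any(pet_arr < 0):
        raise ValueError("P and PET must be nonnegative")
    if np.any((p_arr == 0) & (pet_arr == 0)):
        raise ValueError("CMI undefined when P = PET = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        dry = p_arr / pet_arr - 1.0
        wet = 1.0 - pet_arr / p_arr
    out = np.where(p_arr < pet_arr, dry, np.where(p_arr > pet_arr, wet, 0.0))
    if np.ndim(p) == 0 and np.ndim(pet) == 0:
        return float(out)
    return out


def _prepare_daily(daily: pd.DataFrame, latitude: float, variant: str) -> pd.DataFrame:
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in daily climate table")
    if np.any(df["tmin"] > df["tmean"]) or np.any(df["tmean"] > df["tmax"]):
        raise ValueError("temperature ordering tmin <= tmean <= tmax violated")
    if np.any(df["p"] < 0):
        raise ValueError("negative precipitation")
    df["vpd"] = vpd_tetens(df["tmean"].to_numpy(), df["rh"].to_numpy())
    if "ra" not in df.columns:
        df["ra"] = extraterrestrial_radiation(latitude, df["date"].dt.dayofyear.to_numpy())
    df["pet"] = pet_hargreaves(
        df["tmean"].to_numpy(),
        df["tmax"].to_numpy(),
        df["tmin"].to_numpy(),
        df["ra"].to_numpy(),
        variant=variant,
    )
    return df


def monthly_aggregate(
    daily: pd.DataFrame, latitude: float, variant: str = "modified_hargreaves"
) -> pd.DataFrame:
    """Aggregate a daily climate table to monthly values.

    Input columns: date, p, tmin, tmean, tmax, rh (and optionally ra).
    Output columns: year, month, p_sum (mm), tmean_avg (degC), vpd_avg (hPa),
    pet_sum (mm), d (= p_sum - pet_sum, mm) and a ``complete`` flag marking
    months with every calendar day present (leap Februaries included).
    """
    df = _prepare_daily(daily, latitude, variant)
    grp = df.groupby([df["date"].dt.year, df["date"].dt.month])
    out = grp.agg(
        p_sum=("p", "sum"),
        tmean_avg=("tmean", "mean"),
        vpd_avg=("vpd", "mean"),
        pet_sum=("pet", "sum"),
        n_days=("p", "size"),
    )
    out.index.names = ["year", "month"]
    out = out.reset_index()
    out["d"] = out["p_sum"] - out["pet_sum"]
    out["complete"] = [
        n == calendar.monthrange(y, m)[1]
        for y, m, n in zip(out["year"], out["month"], out["n_days"])
    ]
    return out.drop(columns="n_days")


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

_AS_C = (2.515517, 0.802853, 0.010328)
_AS_D = (1.432788, 0.189269, 0.001308)


def _norm_ppf_as(p: np.ndarray) -> np.ndarray:
    """Standard-normal quantile via the Abramowitz-Stegun rational
    approximation (26.2.23), the transform conventionally used for SPEI."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for mask, sign, prob in (((p > 0) & (p <= 0.5), -1.0, p),
                                 ((p > 0.5) & (p < 1), 1.0, 1.0 - p)):
            w = np.sqrt(-2.0 * np.log(prob[mask]))
            num = _AS_C[0] + _AS_C[1] * w + _AS_C[2] * w**2
            den = 1.0 + _AS_D[0] * w + _AS_D[1] * w**2 + _AS_D[2] * w**3
            out[mask] = sign * (w - num / den)
    return out


def _loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float, float]:
    """Fit a 3-parameter log-logistic distribution by unbiased PWMs.

    Returns (alpha, beta, gamma, sign) = (scale, shape, origin, orientation)
    in the standard SPEI parameterisation.  The parameterisation requires a
    right-skewed sample (shape beta > 1); a left-skewed sample is fitted on
    its mirror image (sign = -1), with the CDF flipped accordingly, so both
    skew directions standardize cleanly.  Raises for degenerate samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        raise ValueError("degenerate sample for log-logistic fit")
    for sign in (1.0, -1.0):
        xs = np.sort(sign * x)
        n = xs.size
        # unbiased PWMs a_s = E[(1-F)^s X] from the ascending order sample
        i = np.arange(1, n + 1)
        a0 = xs.mean()
        a1 = np.sum((n - i) * xs) / (n * (n - 1))
        a2 = np.sum((n - i) * (n - i - 1) * xs) / (n * (n - 1) * (n - 2))
        beta = (2 * a1 - a0) / (6 * a1 - a0 - 6 * a2)
        if not np.isfinite(beta) or beta <= 1.0:
            continue
        g1g2 = _gamma_fn(1 + 1 / beta) * _gamma_fn(1 - 1 / beta)
        alpha = (a0 - 2 * a1) * beta / g1g2
        gamma = a0 - alpha * g1g2
        if np.isfinite(alpha) and alpha > 0:
            return alpha, beta, gamma, sign
    raise ValueError("log-logistic fit failed in both orientations")


def _loglogistic_cdf(
    x: np.ndarray, alpha: float, beta: float, gamma: float, sign: float = 1.0
) -> np.ndarray:
    xx = sign * np.asarray(x, dtype=float)
    out = np.zeros_like(xx)
    z = xx - gamma
    pos = z > 0
    out[pos] = (1.0 + (alpha / z[pos]) ** beta) ** -1.0
    return out if sign > 0 else 1.0 - out


def spei(d_monthly: pd.DataFrame, scale: int, min_years: int = 25) -> pd.DataFrame:
    """Standardized precipitation-evapotranspiration index at a k-month scale.

    ``d_monthly`` needs columns year, month, d (climatic water balance, mm);
    months must be consecutive.  X_k(t) is the sum of d over the k months
    ending at t; for each calendar month separately a 3-parameter
    log-logistic distribution is fitted to the X_k values by unbiased
    probability-weighted moments and SPEI = Phi^-1(F(X_k)) through the
    Abramowitz-Stegun approximation.  The full series is its own calibration
    period, so per-calendar-month mean ~ 0 and SD ~ 1.  Values where the
    window is incomplete are NaN; non-finite transforms are flagged with a
    warning, never clamped.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1 month")
    df = d_monthly.sort_values(["year", "month"]).reset_index(drop=True)
    idx = df["year"] * 12 + (df["month"] - 1)
    if not np.all(np.diff(idx) == 1):
        raise ValueError("monthly series must be consecutive")
    n_years = df["year"].nunique()
    if n_years < min_years:
        raise ValueError(f"need >= {min_years} years of monthly data, got {n_years}")
    d = df["d"].to_numpy(dtype=float)
    xk = pd.Series(d).rolling(scale).sum().to_numpy()
    value = np.full(d.size, np.nan)
    months = df["month"].to_numpy()
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(xk)
        if not np.any(sel):
            continue
        alpha, beta, gamma, sign = _loglogistic_pwm(xk[sel])
        f = _loglogistic_cdf(xk[sel], alpha, beta, gamma, sign)
        value[sel] = _norm_ppf_as(f)
    bad = np.isfinite(xk) & ~np.isfinite(value)
    if np.any(bad):
        warnings.warn(
            f"SPEI-{scale}: {int(bad.sum())} non-finite transform(s) flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    out = df[["year", "month"]].copy()
    out["value"] = value
    out.attrs["scale_months"] = scale
    return out


def growing_season_cmi(
    daily: pd.DataFrame, latitude: float, variant: str = "modified_hargreaves"
) -> pd.DataFrame:
    """Per-year CMI with P and PET summed over the May-October growing season."""
    df = _prepare_daily(daily, latitude, variant)
    gs = df[df["date"].dt.month.isin(GROWING_SEASON_MONTHS)]
    ann = gs.groupby(gs["date"].dt.year).agg(p=("p", "sum"), pet=("pet", "sum"))
    ann["cmi"] = cmi(ann["p"].to_numpy(), ann["pet"].to_numpy())
    ann.index.name = "year"
    return ann.reset_index()[["year", "cmi", "p", "pet"]]
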