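"""Synthetic multi-site climate, ring-width and wood-delta13C generator.

The study system is four mature European beech stands along the Italian
peninsula (TRE, LAZ, CAM, CAL: ~900 km latitudinal transect, mean annual
temperature 9.0-14.3 degC, annual precipitation 825-1003 mm, contrasting soil
water holding capacity).  No field data ship with the package, so every
downstream stage is exercised on synthetic data with *known, configurable*
structure:

* daily climate: sinusoidal seasonal temperature around the site mean plus a
  linear warming trend, daily Gaussian noise and a year-scale anomaly (real
  weather is coherent within a year, which is what lets monthly climate
  correlate with annual growth); precipitation as a seasonal wet-day
  occurrence process with gamma amounts whose expectation matches the
  configured annual total; bounded RH noise;
* tree rings: multiplicative log-linear growth — a negative-exponential age
  trend times exp of standardized growing-season (May-Oct) temperature, VPD
  and precipitation anomalies scaled by per-SD coefficients, plus AR(1) noise
  whose coefficient can drift upward after a chosen year (the
  critical-slowing-down signal the EWS module must detect);
* isotopes: wood delta13C tracking atmospheric delta13C minus a site
  discrimination offset, plus a summer-VPD response, so the iWUE chain has
  recoverable ground truth.

Identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import GROWING_SEASON_MONTHS, vpd_tetens
from .isotopes import AtmHistory, IsotopeSeries, bundled_atm_table
from .rings import RingWidthSeries, write_rwl

__all__ = [
    "SiteConfig",
    "GrowthParams",
    "IsotopeParams",
    "ClimateNoise",
    "StudyFixture",
    "gen_daily_climate",
    "gen_tree_rings",
    "gen_isotopes",
    "default_study_fixture",
    "default_site_configs",
    "write_fixture",
]

_SWHC_LEVELS = ("low", "moderate", "high")
#: Drought-sensitivity multiplier applied to the VPD coefficient: stands on
#: soil with low water holding capacity feel atmospheric drought harder.
SWHC_SENSITIVITY = {"low": 1.3, "moderate": 1.0, "high": 0.7}


@dataclass(frozen=True)
class SiteConfig:
    """Geographic and climatic description of one stand.

    Trends are linear, in units per decade; ``swhc_class`` is an ordinal soil
    water holding capacity level scaling the growth model's drought
    sensitivity.
    """

    site_id: str
    latitude: float
    elevation: float
    mean_annual_t: float
    annual_p: float
    t_trend: float = 0.0
    p_trend: float = 0.0
    rh_mean: float = 75.0
    rh_trend: float = 0.0
    swhc_class: str = "moderate"

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude outside [-90, 90]")
        if self.annual_p <= 0:
            raise ValueError("annual_p must be > 0")
        if self.swhc_class not in _SWHC_LEVELS:
            raise ValueError(f"swhc_class must be one of {_SWHC_LEVELS}")


@dataclass(frozen=True)
class GrowthParams:
    """Multiplicative log-linear growth model parameters.

    ``beta_*`` are effects per standard deviation of the growing-season
    (May-Oct) anomaly on log ring width; ``phi`` is the AR(1) coefficient of
    the noise, optionally drifting by ``phi_drift_rate`` per year after
    ``phi_drift_start`` (capped below 1).
    """

    w0: float = 1.0
    age_decay: float = 0.008
    beta_t: float = 0.0
    beta_vpd: float = 0.0
    beta_p: float = 0.0
    phi: float = 0.3
    sigma: float = 0.15
    phi_drift_start: int | None = None
    phi_drift_rate: float = 0.0
    phi_cap: float = 0.98

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def phi_at(self, year: np.ndarray) -> np.ndarray:
        phi = np.full(np.shape(year), self.phi, dtype=float)
        if self.phi_drift_start is not None:
            extra = self.phi_drift_rate * np.maximum(
                0, np.asarray(year) - self.phi_drift_start
            )
            phi = phi + extra
        return np.clip(phi, -self.phi_cap, self.phi_cap)


@dataclass(frozen=True)
class IsotopeParams:
    """Wood delta13C model: baseline discrimination offset (permil), response
    to the standardized summer VPD anomaly (permil per SD) and noise SD."""

    delta_offset: float = 18.4
    gamma_vpd: float = 0.0
    sigma_iso: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_iso < 0:
            raise ValueError("sigma_iso must be >= 0")


@dataclass(frozen=True)
class ClimateNoise:
    """Noise/shape constants of the daily weather process (degC, %, unitless)."""

    t_amplitude: float = 9.0       # seasonal half-amplitude of Tmean
    diurnal_range: float = 8.0     # Tmax - Tmin
    sigma_t_daily: float = 2.0
    sigma_t_annual: float = 0.6    # year-scale temperature anomaly
    sigma_hr: float = 0.15         # lognormal jitter of the half diurnal range
    sigma_rh_daily: float = 4.0
    sigma_rh_annual: float = 2.0
    wet_prob: float = 0.35         # mean wet-day probability
    wet_seasonality: float = 0.4   # winter-peaking modulation of wet_prob
    gamma_shape: float = 0.7       # shape of wet-day amounts

    def any_noise(self) -> bool:
        return any(
            s > 0
            for s in (
                self.sigma_t_daily,
                self.sigma_t_annual,
                self.sigma_hr,
                self.sigma_rh_daily,
                self.sigma_rh_annual,
            )
        )


def gen_daily_climate(
    site: SiteConfig,
    years: tuple[int, int],
    seed: int | None,
    noise: ClimateNoise = ClimateNoise(),
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Generate a daily climate table (date, p, tmin, tmean, tmax, rh).

    The per-year mean of the seasonal temperature component is removed, so
    each year's annual mean Tmean is exactly ``mean_annual_t`` plus the
    linear trend plus the year/day noise; expected annual precipitation is
    exactly ``annual_p`` plus its trend.  With a seed of ``None`` every
    stochastic component must be switched off (noise SDs zero), in which case
    precipitation is emitted as its deterministic daily expectation.

    Trends are anchored at ``reference_year`` (default: the first generated
    year): the configured site means hold exactly there, so a run that
    extends far into the past should anchor at the study period instead.
    """
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0 + 1:
        raise ValueError("need at least 2 full calendar years")
    deterministic = seed is None
    if deterministic and noise.any_noise():
        raise ValueError("seed is required when any noise SD is > 0")
    rng = None if deterministic else np.random.default_rng(seed)

    # second resolution keeps multi-century ranges inside datetime bounds
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D", unit="s")
    year = dates.year.to_numpy()
    doy = dates.dayofyear.to_numpy()
    n = dates.size
    n_years = y1 - y0 + 1
    yidx = year - y0
    ref = y0 if reference_year is None else int(reference_year)
    yr_offset = np.arange(y0, y1 + 1) - ref  # per-year trend offset

    # temperature: seasonal sinusoid (peak mid-July), per-year mean removed
    seasonal = noise.t_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
    seas_mean = np.bincount(yidx, seasonal) / np.bincount(yidx)
    seasonal = seasonal - seas_mean[yidx]
    trend = site.t_trend / 10.0 * yr_offset[yidx]
    if deterministic:
        t_anom = np.zeros(n)
        hr = np.full(n, noise.diurnal_range / 2.0)
        rh_noise = np.zeros(n)
    else:
        t_yr = rng.normal(0.0, noise.sigma_t_annual, n_years)
        t_anom = t_yr[yidx] + rng.normal(0.0, noise.sigma_t_daily, n)
        hr = noise.diurnal_range / 2.0 * np.exp(rng.normal(0.0, noise.sigma_hr, n))
        rh_yr = rng.normal(0.0, noise.sigma_rh_annual, n_years)
        rh_noise = rh_yr[yidx] + rng.normal(0.0, noise.sigma_rh_daily, n)
    tmean = site.mean_annual_t + seasonal + trend + t_anom
    tmin = tmean - hr
    tmax = tmean + hr

    rh = np.clip(
        site.rh_mean + site.rh_trend / 10.0 * yr_offset[yidx] + rh_noise, 1.0, 100.0
    )

    # precipitation: winter-peaking occurrence, gamma amounts; expectation of
    # each year's total equals the configured annual total plus trend
    p_wet = np.clip(
        noise.wet_prob
        * (1.0 + noise.wet_seasonality * np.cos(2 * np.pi * (doy - 15) / 365.25)),
        0.01,
        0.99,
    )
    pwet_sum = np.bincount(yidx, p_wet)
    target = site.annual_p + site.p_trend / 10.0 * yr_offset
    if np.any(target <= 0):
        raise ValueError("precipitation trend drives the annual total below zero")
    mean_amt = (target / pwet_sum)[yidx]
    if deterministic:
        p = p_wet * mean_amt
    else:
        wet = rng.random(n) < p_wet
        amounts = rng.gamma(noise.gamma_shape, mean_amt / noise.gamma_shape)
        p = np.where(wet, amounts, 0.0)

    return pd.DataFrame(
        {"date": dates, "p": p, "tmin": tmin, "tmean": tmean, "tmax": tmax, "rh": rh}
    )


def growing_season_anomalies(climate: pd.DataFrame) -> pd.DataFrame:
    """Standardized May-Oct mean T, mean VPD and total P per year."""
    df = climate.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["vpd"] = vpd_tetens(df["tmean"].to_numpy(), df["rh"].to_numpy())
    gs = df[df["date"].dt.month.isin(GROWING_SEASON_MONTHS)]
    ann = gs.groupby(gs["date"].dt.year).agg(
        t=("tmean", "mean"), vpd=("vpd", "mean"), p=("p", "sum")
    )
    for col in ("t", "vpd", "p"):
        sd = ann[col].std(ddof=1)
        ann[col + "_std"] = (ann[col] - ann[col].mean()) / (sd if sd > 0 else 1.0)
    ann.index.name = "year"
    return ann


def gen_tree_rings(
    climate: pd.DataFrame,
    gp: GrowthParams,
    n_trees: int,
    germination_years: list[int],
    seed: int | None,
    site_id: str = "SYN",
) -> list[RingWidthSeries]:
    """Generate ring-width series driven by growing-season climate anomalies.

    width(t) = w0 * exp(-age_decay * age)
             * exp(beta_t*T~ + beta_vpd*V~ + beta_p*P~ + eps_t)

    with standardized May-Oct anomalies and eps an AR(1) process (stationary
    start, coefficient possibly drifting after ``phi_drift_start``).  All
    widths are positive by construction.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(germination_years) != n_trees:
        raise ValueError("one germination year per tree required")
    if seed is None and gp.sigma > 0:
        raise ValueError("seed is required when sigma > 0")
    ann = growing_season_anomalies(climate)
    first_clim, last_clim = int(ann.index.min()), int(ann.index.max())
    rng = np.random.default_rng(seed) if seed is not None else None
    out: list[RingWidthSeries] = []
    for i, germ in enumerate(germination_years):
        germ = int(germ)
        if germ > last_clim:
            raise ValueError(f"germination year {germ} after climate range")
        if germ < first_clim:
            raise ValueError(f"germination year {germ} before climate range")
        yrs = np.arange(germ, last_clim + 1)
        ages = yrs - germ + 1
        sub = ann.loc[yrs]
        signal = (
            gp.beta_t * sub["t_std"].to_numpy()
            + gp.beta_vpd * sub["vpd_std"].to_numpy()
            + gp.beta_p * sub["p_std"].to_numpy()
        )
        eps = np.zeros(yrs.size)
        if gp.sigma > 0:
            phi_t = gp.phi_at(yrs)
            e = rng.normal(0.0, gp.sigma / np.sqrt(1.0 - gp.phi**2))
            for j in range(yrs.size):
                e = phi_t[j] * e + rng.normal(0.0, gp.sigma)
                eps[j] = e
        logw = np.log(gp.w0) - gp.age_decay * ages + signal + eps
        out.append(
            RingWidthSeries(
                series_id=f"{site_id[:4].upper()}{i + 1:03d}",
                site_id=site_id,
                first_year=germ,
                widths=np.exp(logw),
            )
        )
    return out


def gen_isotopes(
    climate: pd.DataFrame,
    atm: AtmHistory,
    ip: IsotopeParams,
    seed: int | None,
    site_id: str = "SYN",
) -> IsotopeSeries:
    """Annual wood delta13C: atmospheric delta13C minus the discrimination
    offset, plus a summer (Jun-Aug) VPD response and Gaussian noise.

    Every climate year must be covered by the atmospheric table.
    """
    if seed is None and ip.sigma_iso > 0:
        raise ValueError("seed is required when sigma_iso > 0")
    df = climate.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["vpd"] = vpd_tetens(df["tmean"].to_numpy(), df["rh"].to_numpy())
    summer = df[df["date"].dt.month.isin((6, 7, 8))]
    vpd_ann = summer.groupby(summer["date"].dt.year)["vpd"].mean()
    sd = vpd_ann.std(ddof=1)
    vpd_std = (vpd_ann - vpd_ann.mean()) / (sd if sd > 0 else 1.0)
    years = vpd_ann.index.to_numpy(dtype=int)
    _, d13c_atm = atm.lookup(years)  # raises if a year is missing
    noise = 0.0
    if ip.sigma_iso > 0:
        noise = np.random.default_rng(seed).normal(0.0, ip.sigma_iso, years.size)
    d13c = d13c_atm - ip.delta_offset + ip.gamma_vpd * vpd_std.to_numpy() + noise
    return IsotopeSeries(site_id=site_id, years=years, d13c_tree=d13c)


# ---------------------------------------------------------------------------
# Default four-site study fixture
# ---------------------------------------------------------------------------

#: Per-site fixture constants: geography/climate, stand structure, growth and
#: isotope targets.  Latitudes, elevations, temperatures, precipitation and
#: tree counts/ages follow the modelled stands; trend signs
#: follow the reported climate trends (warming everywhere, VPD rising in the
#: north and falling in the south, precipitation rising at TRE/CAM and
#: falling at LAZ).
_SITE_TABLE = {
    #          lat    elev  T     P     Ttr   Ptr  RH  RHtr  swhc       n   age  sd  trw   d13c
    "TRE": (46.20, 1276, 9.0, 929, 0.35, 30, 78, -1.5, "low", 40, 78, 15, 1.01, -25.9),
    "LAZ": (42.40, 1000, 14.3, 829, 0.30, -20, 72, -0.5, "high", 20, 53, 8, 2.05, -25.1),
    "CAM": (41.40, 1140, 9.8, 825, 0.30, 30, 76, 0.0, "high", 65, 102, 20, 0.98, -26.4),
    "CAL": (39.32, 1601, 11.0, 1003, 0.25, 0, 74, 1.5, "moderate", 50, 63, 7, 1.43, -24.8),
}

#: Growth-model extras per site: base VPD sensitivity (before the SWHC
#: multiplier) and the AR(1) drift injected to emulate the reported
#: early-warning behaviour (AR1 rising at TRE after 2003 and at LAZ from the
#: 1990s, falling at CAM, flat at CAL).
_GROWTH_TABLE = {
    "TRE": (-0.10, 2003, 0.050),
    "LAZ": (-0.12, 1985, 0.030),
    "CAM": (-0.14, 1980, -0.008),
    "CAL": (-0.16, None, 0.0),
}

STUDY_PERIOD = (1965, 2014)


@dataclass
class StudyFixture:
    """Bundle of synthetic inputs for the four-site study."""

    sites: dict[str, SiteConfig]
    climate: dict[str, pd.DataFrame]
    rings: dict[str, list[RingWidthSeries]]
    isotopes: dict[str, IsotopeSeries]
    growth_params: dict[str, GrowthParams]
    isotope_params: dict[str, IsotopeParams]
    atm: AtmHistory
    period: tuple[int, int] = STUDY_PERIOD


def default_site_configs() -> dict[str, SiteConfig]:
    """The four stand configurations (TRE, LAZ, CAM, CAL)."""
    out = {}
    for sid, row in _SITE_TABLE.items():
        lat, elev, t, p, ttr, ptr, rh, rhtr, swhc = row[:9]
        out[sid] = SiteConfig(
            site_id=sid,
            latitude=lat,
            elevation=elev,
            mean_annual_t=t,
            annual_p=p,
            t_trend=ttr,
            p_trend=ptr,
            rh_mean=rh,
            rh_trend=rhtr,
            swhc_class=swhc,
        )
    return out


def _w0_for_target(trw: float, age_decay: float, mean_age: int) -> float:
    """Initial width giving the requested lifetime-mean ring width under the
    negative-exponential age trend (climate and noise average out)."""
    ages = np.arange(1, mean_age + 1)
    return trw / float(np.mean(np.exp(-age_decay * ages)))


def default_study_fixture(
    seed: int,
    tree_fraction: float = 1.0,
    atm: AtmHistory | None = None,
) -> StudyFixture:
    """Generate the full four-site synthetic study (1965-2014 analysis period).

    Tree counts default to 40/20/65/50; ``tree_fraction``
    scales them down proportionally (minimum 3 per site) for quick runs.
    Stand ages are drawn around the per-site mean ages, so climate is generated
    from each site's oldest germination year through 2014; the per-site
    delta13C offset is chosen so the fixture's mean wood delta13C over
    1965-2014 lands on the configured site means.
    """
    if atm is None:
        atm = bundled_atm_table()
    in_period = (atm.years >= STUDY_PERIOD[0]) & (atm.years <= STUDY_PERIOD[1])
    mean_datm = float(np.mean(atm.d13c_atm[in_period]))
    rng = np.random.default_rng(seed)
    sites = default_site_configs()
    climate: dict[str, pd.DataFrame] = {}
    rings: dict[str, list[RingWidthSeries]] = {}
    isotopes: dict[str, IsotopeSeries] = {}
    gparams: dict[str, GrowthParams] = {}
    iparams: dict[str, IsotopeParams] = {}
    for sid, row in _SITE_TABLE.items():
        n_trees, age_mean, age_sd, trw_target, d13c_target = row[9:]
        n_trees = max(3, int(round(n_trees * tree_fraction)))
        beta_vpd_base, drift_start, drift_rate = _GROWTH_TABLE[sid]
        cfg = sites[sid]
        ages = np.clip(
            np.round(rng.normal(age_mean, age_sd, n_trees)).astype(int), 35, 160
        )
        germination = (STUDY_PERIOD[1] + 1 - ages).tolist()
        clim_start = min(germination)
        clim = gen_daily_climate(
            cfg,
            (clim_start, STUDY_PERIOD[1]),
            seed=int(rng.integers(2**31 - 1)),
            # anchor trends mid-study so the configured site means hold over
            # the 1965-2014 analysis period, not at the oldest tree's birth
            reference_year=(STUDY_PERIOD[0] + STUDY_PERIOD[1]) // 2,
        )
        gp = GrowthParams(
            w0=_w0_for_target(trw_target, 0.008, int(age_mean)),
            age_decay=0.008,
            beta_t=0.08,
            beta_vpd=beta_vpd_base * SWHC_SENSITIVITY[cfg.swhc_class],
            beta_p=0.04,
            phi=0.30,
            sigma=0.15,
            phi_drift_start=drift_start,
            phi_drift_rate=drift_rate,
        )
        rw = gen_tree_rings(
            clim, gp, n_trees, germination, seed=int(rng.integers(2**31 - 1)),
            site_id=sid,
        )
        ip = IsotopeParams(
            delta_offset=mean_datm - d13c_target, gamma_vpd=0.3, sigma_iso=0.15
        )
        clim_iso = clim[
            pd.to_datetime(clim["date"]).dt.year.between(*STUDY_PERIOD)
        ].reset_index(drop=True)
        iso = gen_isotopes(
            clim_iso, atm, ip, seed=int(rng.integers(2**31 - 1)), site_id=sid
        )
        climate[sid], rings[sid], isotopes[sid] = clim, rw, iso
        gparams[sid], iparams[sid] = gp, ip
    return StudyFixture(
        sites=sites,
        climate=climate,
        rings=rings,
        isotopes=isotopes,
        growth_params=gparams,
        isotope_params=iparams,
        atm=atm,
    )


def write_fixture(fx: StudyFixture, outdir: str | Path) -> dict[str, list[str]]:
    """Write a fixture to disk: per-site Tucson .rwl and daily-climate CSV,
    a combined isotope CSV, the atmospheric CSV and key:value site configs.

    Returns the written paths grouped by kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"rwl": [], "climate": [], "config": []}
    iso_rows = []
    for sid, cfg in fx.sites.items():
        rwl = outdir / f"{sid}.rwl"
        write_rwl(fx.rings[sid], rwl, precision=0.01)
        written["rwl"].append(str(rwl))
        clim_path = outdir / f"{sid}_climate_daily.csv"
        clim = fx.climate[sid].copy()
        clim["date"] = pd.to_datetime(clim["date"]).dt.strftime("%Y-%m-%d")
        clim.to_csv(clim_path, index=False, float_format="%.4f")
        written["climate"].append(str(clim_path))
        iso = fx.isotopes[sid]
        iso_rows.append(
            pd.DataFrame(
                {"site": sid, "year": iso.years, "d13c_permil": iso.d13c_tree}
            )
        )
        cfg_path = outdir / f"{sid}_site.cfg"
        cfg_lines = [
            f"site_id: {cfg.site_id}",
            f"latitude: {cfg.latitude}",
            f"elevation: {cfg.elevation}",
            f"mean_annual_t: {cfg.mean_annual_t}",
            f"annual_p: {cfg.annual_p}",
            f"t_trend: {cfg.t_trend}",
            f"p_trend: {cfg.p_trend}",
            f"rh_mean: {cfg.rh_mean}",
            f"rh_trend: {cfg.rh_trend}",
            f"swhc_class: {cfg.swhc_class}",
        ]
        cfg_path.write_text("\n".join(cfg_lines) + "\n")
        written["config"].append(str(cfg_path))
    iso_path = outdir / "isotopes.csv"
    pd.concat(iso_rows).to_csv(iso_path, index=False, float_format="%.4f")
    written["isotopes"] = [str(iso_path)]
    atm_path = outdir / "atm.csv"
    pd.DataFrame(
        {
            "year": fx.atm.years,
            "co2_ppm": fx.atm.ca,
            "d13c_atm_permil": fx.atm.d13c_atm,
        }
    ).to_csv(atm_path, index=False, float_format="%.4f")
    written["atm"] = [str(atm_path)]
    return written
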