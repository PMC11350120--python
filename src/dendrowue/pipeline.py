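"""End-to-end orchestration of the study pipeline.

Stages mirror the analysis order: simulate (or validate supplied inputs) ->
BAI chronologies -> iWUE -> monthly climate + SPEI + CMI -> lagged
climate-growth correlation matrices -> growth trends -> early-warning
signals -> manifest.  Every intermediate artifact is plain CSV/JSON under the
configured output directory, so any stage can be inspected or re-run in
isolation, and the manifest records everything needed to reproduce the run
bit-identically (config, seed, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import growing_season_cmi, monthly_aggregate, spei
from .ews import site_ews
from .isotopes import read_atm_csv, read_isotope_csv, wue_series
from .response import correlation_matrix, critical_r, spei_scale_screen
from .rings import bai_from_widths, read_rwl, series_summary, site_mean_bai, truncate_series
from .synthetic import default_study_fixture, write_fixture
from .trends import additive_growth_model, aic_rank, linear_trend, loess_trend

__all__ = ["RunConfig", "run_full_study", "validate_inputs", "STAGES"]

log = logging.getLogger("dendrowue")

STAGES = ("simulate", "bai", "iwue", "climate", "correlate", "trends", "ews", "report")


@dataclass
class RunConfig:
    """Study configuration with the study defaults.

    period: analysis years (inclusive); alpha: significance level for the
    correlation matrices; spei_scales: SPEI aggregation scales in months;
    ews_window: moving-window length in years; bandwidth_frac: Gaussian
    detrending kernel SD as a fraction of series length.
    """

    outdir: str = "dendrowue_run"
    seed: int = 0
    simulate: bool = True
    tree_fraction: float = 1.0
    period: tuple[int, int] = (1965, 2014)
    alpha: float = 0.05
    spei_scales: tuple[int, ...] = (1, 3, 6, 9, 12, 18, 24)
    spei_screen_scale: int = 18
    ews_window: int = 15
    bandwidth_frac: float = 0.10
    pet_variant: str = "modified_hargreaves"
    min_depth: int = 3

    def __post_init__(self) -> None:
        self.period = (int(self.period[0]), int(self.period[1]))
        if self.period[0] >= self.period[1]:
            raise ValueError("period start must precede period end")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.ews_window > self.period[1] - self.period[0] + 1:
            raise ValueError("EWS window longer than the analysis period")
        self.spei_scales = tuple(int(k) for k in self.spei_scales)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period"] = list(self.period)
        d["spei_scales"] = list(self.spei_scales)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @property
    def root(self) -> Path:
        return Path(self.outdir)

    @property
    def inputs(self) -> Path:
        return self.root / "inputs"


def _timed(name):
    def deco(fn):
        def wrapper(cfg: RunConfig, *a, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(cfg, *a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


def _site_ids(cfg: RunConfig) -> list[str]:
    return sorted(p.stem for p in cfg.inputs.glob("*.rwl"))


@_timed("simulate")
def stage_simulate(cfg: RunConfig) -> None:
    fx = default_study_fixture(cfg.seed, tree_fraction=cfg.tree_fraction)
    write_fixture(fx, cfg.inputs)


@_timed("bai")
def stage_bai(cfg: RunConfig) -> None:
    rows, chron_rows, all_series = [], [], []
    for sid in _site_ids(cfg):
        series = read_rwl(cfg.inputs / f"{sid}.rwl", site_id=sid)
        all_series.extend(series)
        bais = []
        for s in series:
            t = truncate_series(s, *cfg.period)
            if t is None or t.n_rings < 2:
                continue
            b = bai_from_widths(t)
            bais.append(b)
            rows.append(
                pd.DataFrame(
                    {"site": sid, "tree": b.series_id, "year": b.years, "bai_mm2": b.bai}
                )
            )
        chron = site_mean_bai(bais, min_depth=cfg.min_depth, site_id=sid)
        cf = chron.to_frame()
        cf.insert(0, "site", sid)
        chron_rows.append(cf)
    pd.concat(rows).to_csv(cfg.root / "bai_per_tree.csv", index=False)
    pd.concat(chron_rows).to_csv(cfg.root / "bai_chronology.csv", index=False)
    series_summary(all_series).to_csv(cfg.root / "series_summary.csv", index=False)


@_timed("iwue")
def stage_iwue(cfg: RunConfig) -> None:
    iso_path = cfg.inputs / "isotopes.csv"
    if not iso_path.exists():
        log.warning("no isotope inputs found; skipping the iWUE stage")
        return
    atm = read_atm_csv(cfg.inputs / "atm.csv")
    frames = []
    for iso in read_isotope_csv(iso_path):
        keep = (iso.years >= cfg.period[0]) & (iso.years <= cfg.period[1])
        iso.years, iso.d13c_tree = iso.years[keep], iso.d13c_tree[keep]
        w = wue_series(iso, atm)
        f = w.to_frame()
        f["d13c_tree"] = iso.d13c_tree
        frames.append(f)
    pd.concat(frames).to_csv(cfg.root / "iwue.csv", index=False)


def _read_site_climate(cfg: RunConfig, sid: str) -> tuple[pd.DataFrame, float]:
    clim = pd.read_csv(cfg.inputs / f"{sid}_climate_daily.csv")
    lat = None
    cfg_path = cfg.inputs / f"{sid}_site.cfg"
    if cfg_path.exists():
        for line in cfg_path.read_text().splitlines():
            k, _, v = line.partition(":")
            if k.strip() == "latitude":
                lat = float(v)
    if lat is None:
        raise ValueError(f"no latitude found for site {sid}")
    return clim, lat


@_timed("climate")
def stage_climate(cfg: RunConfig) -> None:
    monthly_frames, spei_frames, cmi_frames = [], [], []
    for sid in _site_ids(cfg):
        clim, lat = _read_site_climate(cfg, sid)
        monthly = monthly_aggregate(clim, lat, variant=cfg.pet_variant)
        monthly = monthly[monthly["complete"]]
        mf = monthly.copy()
        mf.insert(0, "site", sid)
        monthly_frames.append(mf)
        for k in cfg.spei_scales:
            sp = spei(monthly[["year", "month", "d"]], k)
            sp = sp[sp["year"].between(*cfg.period)]
            sp.insert(0, "scale", k)
            sp.insert(0, "site", sid)
            spei_frames.append(sp)
        gs = growing_season_cmi(clim, lat, variant=cfg.pet_variant)
        gs = gs[gs["year"].between(*cfg.period)]
        gs.insert(0, "site", sid)
        cmi_frames.append(gs)
    pd.concat(monthly_frames).to_csv(cfg.root / "monthly_climate.csv", index=False)
    pd.concat(spei_frames).to_csv(cfg.root / "spei.csv", index=False)
    pd.concat(cmi_frames).to_csv(cfg.root / "cmi_growing_season.csv", index=False)


def _monthly_series(monthly: pd.DataFrame, col: str) -> pd.Series:
    return monthly.set_index(["year", "month"])[col]


def _load_responses(cfg: RunConfig, sid: str) -> dict[str, pd.Series]:
    out = {}
    chron = pd.read_csv(cfg.root / "bai_chronology.csv")
    sub = chron[chron["site"] == sid]
    out["BAI"] = pd.Series(sub["mean"].to_numpy(), index=sub["year"].to_numpy())
    iwue_path = cfg.root / "iwue.csv"
    if iwue_path.exists():
        iw = pd.read_csv(iwue_path)
        sub = iw[iw["site_id"] == sid]
        if len(sub):
            out["iWUE"] = pd.Series(
                sub["iwue_umol_mol"].to_numpy(), index=sub["year"].to_numpy()
            )
    return out


@_timed("correlate")
def stage_correlate(cfg: RunConfig) -> None:
    monthly_all = pd.read_csv(cfg.root / "monthly_climate.csv")
    spei_all = pd.read_csv(cfg.root / "spei.csv")
    mat_rows, screen_rows = [], []
    for sid in _site_ids(cfg):
        monthly = monthly_all[monthly_all["site"] == sid]
        sp1 = spei_all[(spei_all["site"] == sid) & (spei_all["scale"] == 1)]
        variables = {
            "P": _monthly_series(monthly, "p_sum"),
            "Tmean": _monthly_series(monthly, "tmean_avg"),
            "VPD": _monthly_series(monthly, "vpd_avg"),
            "SPEI1": _monthly_series(sp1, "value"),
        }
        for rname, resp in _load_responses(cfg, sid).items():
            resp = resp[resp.index.to_series().between(*cfg.period)]
            mats = correlation_matrix(resp, variables, cfg.alpha, response_name=rname)
            for m in mats.values():
                f = m.to_frame()
                f.insert(0, "site", sid)
                f["r_crit"] = m.r_crit
                mat_rows.append(f)
        bai = _load_responses(cfg, sid)["BAI"]
        by_scale = {
            k: g.reset_index(drop=True)
            for k, g in spei_all[spei_all["site"] == sid].groupby("scale")
        }
        scr = spei_scale_screen(bai, by_scale, alpha=cfg.alpha)
        scr.insert(0, "site", sid)
        screen_rows.append(scr)
    pd.concat(mat_rows).to_csv(cfg.root / "correlation_matrices.csv", index=False)
    pd.concat(screen_rows).to_csv(cfg.root / "spei_scale_screen.csv", index=False)


@_timed("trends")
def stage_trends(cfg: RunConfig) -> None:
    chron = pd.read_csv(cfg.root / "bai_chronology.csv")
    loess_rows, lin_rows = [], []
    for sid, sub in chron.groupby("site"):
        fit = loess_trend(sub["year"].to_numpy(float), sub["mean"].to_numpy())
        loess_rows.append(
            pd.DataFrame(
                {
                    "site": sid,
                    "year": sub["year"].to_numpy(),
                    "bai_mean": sub["mean"].to_numpy(),
                    "loess": fit.fitted,
                    "lo95": fit.band_lower,
                    "hi95": fit.band_upper,
                }
            )
        )
    iwue_path = cfg.root / "iwue.csv"
    if iwue_path.exists():
        iw = pd.read_csv(iwue_path)
        for sid, sub in iw.groupby("site_id"):
            for col in ("d13c_tree", "iwue_umol_mol"):
                ols, ts = linear_trend(sub["year"].to_numpy(float), sub[col].to_numpy())
                lin_rows.append(
                    {
                        "site": sid,
                        "variable": col,
                        "ols_slope_per_yr": ols.slope,
                        "ols_p": ols.p_value,
                        "sen_slope_per_yr": ts.slope,
                        "mk_p": ts.p_value,
                    }
                )
    pd.concat(loess_rows).to_csv(cfg.root / "bai_loess.csv", index=False)
    pd.DataFrame(lin_rows).to_csv(cfg.root / "linear_trends.csv", index=False)

    # additive growth model per site: BAI ~ s(year)+s(age)+s(SPEI-k) + tree
    per_tree = pd.read_csv(cfg.root / "bai_per_tree.csv")
    spei_all = pd.read_csv(cfg.root / "spei.csv")
    rwl_ages = {}
    for sid in _site_ids(cfg):
        for s in read_rwl(cfg.inputs / f"{sid}.rwl", site_id=sid):
            rwl_ages[(sid, s.series_id)] = (s.first_year, s.last_year)
    gamm_out = {}
    for sid, sub in per_tree.groupby("site"):
        sp = spei_all[
            (spei_all["site"] == sid)
            & (spei_all["scale"] == cfg.spei_screen_scale)
            & (spei_all["month"] == 10)
        ].set_index("year")["value"]
        sub = sub.copy()
        sub["age"] = [
            y - rwl_ages[(sid, t)][0] + 1 for t, y in zip(sub["tree"], sub["year"])
        ]
        sub["spei"] = sub["year"].map(sp)
        sub = sub.dropna(subset=["spei"])
        y = sub["bai_mm2"].to_numpy()
        kw = dict(tree_ids=sub["tree"].to_numpy())
        candidates = {
            "year+age+spei": additive_growth_model(
                y, year=sub["year"].to_numpy(float), age=sub["age"].to_numpy(float),
                spei=sub["spei"].to_numpy(float), **kw),
            "year+age": additive_growth_model(
                y, year=sub["year"].to_numpy(float), age=sub["age"].to_numpy(float), **kw),
            "intercepts_only": additive_growth_model(y, **kw),
        }
        rank = aic_rank(candidates)
        best = rank.iloc[0]["model"]
        gamm_out[sid] = {
            "ranking": rank.to_dict(orient="records"),
            "best": best,
            "edf": candidates[best].edf,
            "converged": bool(candidates[best].converged),
        }
    (cfg.root / "additive_model.json").write_text(json.dumps(gamm_out, indent=2))


@_timed("ews")
def stage_ews(cfg: RunConfig) -> None:
    per_tree = pd.read_csv(cfg.root / "bai_per_tree.csv")
    traj_rows, site_rows = [], []
    for sid, sub in per_tree.groupby("site"):
        series = {
            t: pd.Series(g["bai_mm2"].to_numpy(), index=g["year"].to_numpy())
            for t, g in sub.groupby("tree")
        }
        n_years = cfg.period[1] - cfg.period[0] + 1
        results, summary = site_ews(
            series,
            window=cfg.ews_window,
            bandwidth=cfg.bandwidth_frac * n_years,
            site_id=sid,
        )
        for r in results:
            f = r.to_frame()
            f["tau_ar1"], f["tau_sd"] = r.tau_ar1, r.tau_sd
            f.insert(0, "site", sid)
            traj_rows.append(f)
        site_rows.append(dataclasses.asdict(summary))
    pd.concat(traj_rows).to_csv(cfg.root / "ews_per_tree.csv", index=False)
    pd.DataFrame(site_rows).to_csv(cfg.root / "ews_site_summary.csv", index=False)


@_timed("report")
def stage_report(cfg: RunConfig) -> dict:
    n_years = cfg.period[1] - cfg.period[0] + 1
    manifest = {
        "package": "dendrowue",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "sites": _site_ids(cfg),
        "critical_r": round(critical_r(n_years, cfg.alpha), 6),
        "ews_window_fraction": cfg.ews_window / n_years,
        "artifacts": sorted(p.name for p in cfg.root.glob("*.csv"))
        + sorted(p.name for p in cfg.root.glob("*.json") if p.name != "manifest.json"),
    }
    (cfg.root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_full_study(cfg: RunConfig) -> dict:
    """Run every stage in order and return the manifest.

    With ``cfg.simulate`` the four-site synthetic fixture is generated first;
    otherwise the input files must already sit under ``<outdir>/inputs``.
    The isotope stage is skipped (with a log message) when no isotope CSV is
    present; all other stages require their inputs.
    """
    cfg.root.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        stage_simulate(cfg)
    diagnostics = validate_inputs(cfg)
    fatal = [d for d in diagnostics if d[0] == "error"]
    if fatal:
        raise ValueError("input validation failed: " + "; ".join(m for _, m in fatal))
    stage_bai(cfg)
    stage_iwue(cfg)
    stage_climate(cfg)
    stage_correlate(cfg)
    stage_trends(cfg)
    stage_ews(cfg)
    return stage_report(cfg)


def validate_inputs(cfg: RunConfig) -> list[tuple[str, str]]:
    """Schema/unit/invariant checks on the input files.

    Returns (level, message) diagnostics; level is "error" (fatal) or
    "warning".  Fatal: RH outside (0, 100], non-positive ring widths, gap
    years inside a ring series, temperature ordering violations.
    """
    diags: list[tuple[str, str]] = []
    sids = _site_ids(cfg)
    if not sids:
        diags.append(("error", f"no .rwl files under {cfg.inputs}"))
        return diags
    for sid in sids:
        try:
            read_rwl(cfg.inputs / f"{sid}.rwl", site_id=sid)
        except ValueError as exc:  # gap years / non-positive widths
            diags.append(("error", f"{sid}.rwl: {exc}"))
        clim_path = cfg.inputs / f"{sid}_climate_daily.csv"
        if not clim_path.exists():
            diags.append(("error", f"missing climate table for {sid}"))
            continue
        clim = pd.read_csv(clim_path)
        if clim["rh"].le(0).any() or clim["rh"].gt(100).any():
            diags.append(("error", f"{sid}: RH outside (0, 100]"))
        if clim["p"].lt(0).any():
            diags.append(("error", f"{sid}: negative precipitation"))
        if (clim["tmin"] > clim["tmean"]).any() or (clim["tmean"] > clim["tmax"]).any():
            diags.append(("error", f"{sid}: temperature ordering violated"))
        years = pd.to_datetime(clim["date"]).dt.year
        if years.max() < cfg.period[1] or years.min() > cfg.period[0]:
            diags.append(
                ("warning", f"{sid}: climate does not span the analysis period")
            )
    if not (cfg.inputs / "isotopes.csv").exists():
        diags.append(("warning", "no isotope CSV: the iWUE stage will be skipped"))
    return diags
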