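"""Synthetic climate / ring / isotope generator: determinism, physicality and
recoverable injected structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendrowue.ews import mann_kendall
from dendrowue.isotopes import AtmHistory
from dendrowue.response import critical_r
from dendrowue.synthetic import (
    GrowthParams,
    IsotopeParams,
    SiteConfig,
    default_study_fixture,
    gen_daily_climate,
    gen_isotopes,
    gen_tree_rings,
    growing_season_anomalies,
)
from tests.conftest import NOISELESS


class TestDailyClimate:
    def test_bit_identical_under_same_seed(self, site):
        a = gen_daily_climate(site, (1990, 1999), seed=5)
        b = gen_daily_climate(site, (1990, 1999), seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = gen_daily_climate(site, (1990, 1999), seed=6)
        assert not a["p"].equals(c["p"])

    def test_physicality_invariants(self, climate_50y):
        assert (climate_50y["tmin"] <= climate_50y["tmean"]).all()
        assert (climate_50y["tmean"] <= climate_50y["tmax"]).all()
        assert (climate_50y["p"] >= 0).all()
        assert climate_50y["rh"].gt(0).all() and climate_50y["rh"].le(100).all()

    def test_noise_free_annual_mean_is_exact(self):
        clim = gen_daily_climate(
            SiteConfig("D", 45, 1000, 9.0, 900), (2000, 2004), seed=None,
            noise=NOISELESS,
        )
        ann = clim.groupby(pd.to_datetime(clim["date"]).dt.year)["tmean"].mean()
        np.testing.assert_allclose(ann, 9.0, atol=1e-12)

    def test_noise_free_warming_trend_is_exact(self):
        clim = gen_daily_climate(
            SiteConfig("D", 45, 1000, 9.0, 900, t_trend=0.5), (1965, 2014),
            seed=None, noise=NOISELESS,
        )
        ann = clim.groupby(pd.to_datetime(clim["date"]).dt.year)["tmean"].mean()
        slope = stats.linregress(ann.index, ann.to_numpy()).slope
        assert slope == pytest.approx(0.05, abs=1e-12)  # 0.5 degC per decade

    def test_annual_precipitation_hits_configured_mean(self, climate_50y):
        ann = climate_50y.groupby(pd.to_datetime(climate_50y["date"]).dt.year)["p"].sum()
        se = ann.std(ddof=1) / np.sqrt(ann.size)
        assert abs(ann.mean() - 900.0) < 3 * se

    def test_errors(self, site):
        with pytest.raises(ValueError, match="2 full"):
            gen_daily_climate(site, (2000, 2000), seed=1)
        with pytest.raises(ValueError, match="seed"):
            gen_daily_climate(site, (2000, 2005), seed=None)


class TestTreeRings:
    def test_deterministic_limit_constant_width(self, site):
        clim = gen_daily_climate(site, (1990, 2010), seed=2)
        gp = GrowthParams(w0=1.7, age_decay=0.0, sigma=0.0, phi=0.0)
        trees = gen_tree_rings(clim, gp, 3, [1990, 1995, 2000], seed=None)
        for t in trees:
            np.testing.assert_allclose(t.widths, 1.7, rtol=1e-12)

    def test_injected_vpd_effect_recovered_in_log_widths(self, site):
        clim = gen_daily_climate(site, (1965, 2014), seed=3)
        gp = GrowthParams(beta_vpd=-0.2, sigma=0.02, phi=0.0, age_decay=0.0)
        (tree,) = gen_tree_rings(clim, gp, 1, [1965], seed=4)
        vpd = growing_season_anomalies(clim)["vpd_std"].to_numpy()
        r = np.corrcoef(np.log(tree.widths), vpd)[0, 1]
        assert r < -critical_r(vpd.size, 0.05)

    def test_ar1_coefficient_recovered_at_long_horizon(self, site):
        clim = gen_daily_climate(site, (1015, 2014), seed=5)
        gp = GrowthParams(phi=0.8, sigma=1.0, age_decay=0.0)
        (tree,) = gen_tree_rings(clim, gp, 1, [1015], seed=6)
        logw = np.log(tree.widths)
        phi_hat = np.corrcoef(logw[:-1], logw[1:])[0, 1]
        assert phi_hat == pytest.approx(0.8, abs=0.05)

    def test_widths_positive_and_deterministic_under_seed(self, stand_20):
        clim, trees = stand_20
        assert all(np.all(t.widths > 0) for t in trees)
        gp = GrowthParams(beta_t=0.08, beta_vpd=-0.13, beta_p=0.04, phi=0.3, sigma=0.15)
        again = gen_tree_rings(clim, gp, 20, [1945] * 20, seed=12)
        for a, b in zip(trees, again):
            np.testing.assert_array_equal(a.widths, b.widths)

    def test_errors(self, site):
        clim = gen_daily_climate(site, (1990, 2000), seed=7)
        gp = GrowthParams()
        with pytest.raises(ValueError):
            gen_tree_rings(clim, gp, 0, [], seed=1)
        with pytest.raises(ValueError, match="after climate range"):
            gen_tree_rings(clim, gp, 1, [2005], seed=1)
        with pytest.raises(ValueError, match="seed"):
            gen_tree_rings(clim, gp, 1, [1990], seed=None)


class TestIsotopes:
    @staticmethod
    def _flat_atm(years):
        years = np.asarray(years)
        # slightly declining to satisfy history invariants; constant ca
        return AtmHistory(years, np.full(years.size, 400.0), -7.5 - 1e-6 * (years - years[0]))

    def test_offset_construction(self, climate_50y):
        atm = self._flat_atm(np.arange(1965, 2015))
        iso = gen_isotopes(
            climate_50y, atm, IsotopeParams(delta_offset=18.4), seed=None
        )
        np.testing.assert_allclose(iso.d13c_tree, -25.9, atol=1e-4)

    def test_rising_vpd_trend_gives_positive_mk_tau(self):
        cfg = SiteConfig("D", 45, 1000, 9.0, 900, t_trend=0.6, rh_trend=-3.0)
        clim = gen_daily_climate(cfg, (1965, 2014), seed=8)
        atm = self._flat_atm(np.arange(1965, 2015))
        iso = gen_isotopes(clim, atm, IsotopeParams(gamma_vpd=1.0, sigma_iso=0.05), seed=9)
        mk = mann_kendall(iso.d13c_tree)
        assert mk.tau > 0
        assert mk.p < 0.05

    def test_uncovered_year_is_an_error(self, climate_50y):
        atm = self._flat_atm(np.arange(1980, 2015))
        with pytest.raises(KeyError):
            gen_isotopes(climate_50y, atm, IsotopeParams(), seed=None)


class TestDefaultFixture:
    @pytest.fixture(scope="class")
    def fixture(self):
        return default_study_fixture(seed=0, tree_fraction=0.5)

    def test_analysis_period_and_site_roster(self, fixture):
        assert fixture.period == (1965, 2014)
        assert fixture.period[1] - fixture.period[0] + 1 == 50
        assert list(fixture.sites) == ["TRE", "LAZ", "CAM", "CAL"]
        assert fixture.sites["CAL"].annual_p == 1003

    def test_full_scale_tree_counts(self):
        fx = default_study_fixture(seed=1)
        assert [len(fx.rings[s]) for s in ("TRE", "LAZ", "CAM", "CAL")] == [40, 20, 65, 50]

    def test_stand_ages_near_configured_means(self):
        fx = default_study_fixture(seed=2)
        configured = {"TRE": (78, 15), "LAZ": (53, 8), "CAM": (102, 20), "CAL": (63, 7)}
        for sid, (mean, sd) in configured.items():
            ages = np.array([t.n_rings for t in fx.rings[sid]])
            se = sd / np.sqrt(ages.size)
            assert abs(ages.mean() - mean) < 2 * se + 1  # +1 for the integer clip

    def test_site_mean_iwue_ordering(self, fixture):
        from dendrowue.isotopes import wue_series

        means = {
            sid: wue_series(iso, fixture.atm).iwue.mean()
            for sid, iso in fixture.isotopes.items()
        }
        assert means["CAL"] > means["LAZ"] > means["TRE"] > means["CAM"]

    def test_determinism(self):
        a = default_study_fixture(seed=3, tree_fraction=0.2)
        b = default_study_fixture(seed=3, tree_fraction=0.2)
        for sid in a.rings:
            for ta, tb in zip(a.rings[sid], b.rings[sid]):
                np.testing.assert_array_equal(ta.widths, tb.widths)
            np.testing.assert_array_equal(
                a.isotopes[sid].d13c_tree, b.isotopes[sid].d13c_tree
            )
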