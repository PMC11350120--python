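"""Tree-ring delta13C to intercellular CO2 and intrinsic water-use efficiency.

The Farquhar "simple" discrimination model links wood delta13C to the
intercellular-to-ambient CO2 ratio:

    d13C_tree = d13C_atm - a - (b - a) * ci / ca

with a = 4.4 permil (diffusion through stomata) and b = 27 permil (Rubisco
carboxylation).  Solving for ci and applying Fick's law with the 1.6
diffusivity ratio of water vapour to CO2 gives

    ci   = ca * (d13C_atm - d13C_tree - a) / (b - a)
    iWUE = (ca - ci) / 1.6        [umol CO2 per mol H2O]

Mesophyll-conductance and photorespiration terms are deliberately excluded
(the simple form).  Because atmospheric d13C declines through the industrial
era (Suess effect), d13C_atm must be supplied per year; a packaged annual
CO2/d13C_atm table is provided and can be overridden with a user CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FractionationConstants",
    "IsotopeSeries",
    "AtmHistory",
    "WueSeries",
    "ci_from_delta",
    "iwue_from_delta",
    "wue_series",
    "bundled_atm_table",
    "read_atm_csv",
    "read_isotope_csv",
]


@dataclass(frozen=True)
class FractionationConstants:
    """Carbon isotope fractionation factors (permil): diffusion ``a`` and
    carboxylation ``b``; requires b > a > 0."""

    a: float = 4.4
    b: float = 27.0

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0):
            raise ValueError("require b > a > 0")


DEFAULT_CONSTANTS = FractionationConstants()


@dataclass
class IsotopeSeries:
    """Annual wood delta13C (permil vs VPDB) for one site."""

    site_id: str
    years: np.ndarray
    d13c_tree: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.d13c_tree = np.asarray(self.d13c_tree, dtype=float)
        if self.years.size != self.d13c_tree.size:
            raise ValueError("years and d13c_tree must have equal length")
        if np.unique(self.years).size != self.years.size:
            raise ValueError("years must be unique")
        if np.any((self.d13c_tree <= -40) | (self.d13c_tree >= -10)):
            raise ValueError("d13C outside the (-40, -10) permil sanity band")

    def to_series(self) -> pd.Series:
        return pd.Series(self.d13c_tree, index=self.years, name=self.site_id)


@dataclass
class AtmHistory:
    """Annual atmospheric CO2 (ppm) and d13C_atm (permil)."""

    years: np.ndarray
    ca: np.ndarray
    d13c_atm: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ca = np.asarray(self.ca, dtype=float)
        self.d13c_atm = np.asarray(self.d13c_atm, dtype=float)
        if not (self.years.size == self.ca.size == self.d13c_atm.size):
            raise ValueError("column length mismatch")
        if np.any(self.ca <= 0):
            raise ValueError("ca must be positive")

    def lookup(self, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (ca, d13c_atm) for the requested years; KeyError if any
        year is missing from the table."""
        idx = pd.Index(self.years)
        pos = idx.get_indexer(np.asarray(years, dtype=int))
        if np.any(pos < 0):
            missing = np.asarray(years)[pos < 0]
            raise KeyError(f"years missing from atmospheric table: {missing.tolist()}")
        return self.ca[pos], self.d13c_atm[pos]


@dataclass
class WueSeries:
    """Annual intercellular CO2 (ppm) and iWUE (umol mol-1) for one site.

    ``out_of_range`` flags years whose implied ci falls outside (0, ca) —
    implausible inputs are flagged, never silently dropped.
    """

    site_id: str
    years: np.ndarray
    ci: np.ndarray
    iwue: np.ndarray
    out_of_range: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "year": self.years,
                "ci_ppm": self.ci,
                "iwue_umol_mol": self.iwue,
                "out_of_range": self.out_of_range,
            }
        )


def ci_from_delta(d13c_tree, d13c_atm, ca, k: FractionationConstants = DEFAULT_CONSTANTS):
    """Intercellular CO2, ci = ca*(d13C_atm - d13C_tree - a)/(b - a), in ppm."""
    d13c_tree = np.asarray(d13c_tree, dtype=float)
    d13c_atm = np.asarray(d13c_atm, dtype=float)
    ca = np.asarray(ca, dtype=float)
    return ca * (d13c_atm - d13c_tree - k.a) / (k.b - k.a)


def iwue_from_delta(d13c_tree, d13c_atm, ca, k: FractionationConstants = DEFAULT_CONSTANTS):
    """Intrinsic water-use efficiency, iWUE = (ca - ci)/1.6, in umol mol-1.

    Derived from the discrimination relation so it is algebraically consistent
    with :func:`ci_from_delta` by construction (linear in ca at fixed deltas).
    """
    ca = np.asarray(ca, dtype=float)
    return (ca - ci_from_delta(d13c_tree, d13c_atm, ca, k)) / 1.6


def wue_series(
    iso: IsotopeSeries, atm: AtmHistory, k: FractionationConstants = DEFAULT_CONSTANTS
) -> WueSeries:
    """Year-wise ci and iWUE for an isotope series under an atmospheric history.

    Every isotope year must be present in ``atm``; years whose ci falls
    outside (0, ca) are flagged via ``out_of_range``.
    """
    ca, datm = atm.lookup(iso.years)
    ci = ci_from_delta(iso.d13c_tree, datm, ca, k)
    iwue = (ca - ci) / 1.6
    flag = (ci <= 0) | (ci >= ca)
    return WueSeries(iso.site_id, iso.years.copy(), ci, iwue, flag)


# ---------------------------------------------------------------------------
# Tables and CSV I/O
# ---------------------------------------------------------------------------

def bundled_atm_table() -> AtmHistory:
    """Packaged annual CO2/d13C_atm table for 1965-2014.

    The packaged file is a documented smooth approximation of the well-known
    Mauna Loa CO2 record and the industrial-era atmospheric d13C decline (see
    the header comments in ``data/atm_co2_d13c_synthetic.csv``); downstream
    results depend on its invariants (rising ca, falling d13C_atm), not on
    the exact digits.  Override with :func:`read_atm_csv` for real data.
    """
    ref = importlib.resources.files("dendrowue.data") / "atm_co2_d13c_synthetic.csv"
    with importlib.resources.as_file(ref) as p:
        return read_atm_csv(p)


def read_atm_csv(path: str | Path) -> AtmHistory:
    """Read an atmospheric table CSV: year, co2_ppm, d13c_atm_permil."""
    df = pd.read_csv(path, comment="#")
    return AtmHistory(
        df["year"].to_numpy(), df["co2_ppm"].to_numpy(), df["d13c_atm_permil"].to_numpy()
    )


def read_isotope_csv(path: str | Path) -> list[IsotopeSeries]:
    """Read an isotope CSV (site, year, d13c_permil, optional tree_id).

    Multiple trees per (site, year) are averaged into one annual site value.
    """
    df = pd.read_csv(path, comment="#")
    out = []
    for site, grp in df.groupby("site", sort=True):
        ann = grp.groupby("year")["d13c_permil"].mean().sort_index()
        out.append(IsotopeSeries(str(site), ann.index.to_numpy(), ann.to_numpy()))
    return out
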