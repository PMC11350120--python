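"""Tucson ring-width I/O, cross-dating agreement (GLK) and basal area increment.

Ring widths are annual radial increments in mm.  Basal area increment (BAI)
converts them to the annual cross-sectional area added by the stem,

    BAI_t = pi * (R_t**2 - R_{t-1}**2)   [mm^2]

where R_t is the cumulative radius through year t (optionally offset by the
distance from the pith to the innermost measured ring).  Unlike raw ring
width, BAI is free of the geometric decline imposed by a growing
circumference, so long-term BAI trends can be read as growth trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthSeries",
    "BAISeries",
    "SiteChronology",
    "read_rwl",
    "write_rwl",
    "glk",
    "bai_from_widths",
    "site_mean_bai",
    "series_summary",
    "truncate_series",
]

#: Tucson stop markers and the measurement unit (mm) each implies.
_STOP_UNITS = {999: 0.01, -9999: 0.001}


@dataclass
class RingWidthSeries:
    """One tree's dated annual ring widths.

    Parameters
    ----------
    series_id : str
        Core/tree label, at most 8 characters (Tucson field width).
    site_id : str
        Stand the tree belongs to.
    first_year : int
        Calendar year of the innermost ring; years are strictly consecutive.
    widths : array of float
        Ring widths in mm, all strictly positive.
    pith_offset : float
        Distance (mm) from the pith to the innermost measured ring; 0 for a
        full pith-to-bark core.
    """

    series_id: str
    site_id: str
    first_year: int
    widths: np.ndarray
    pith_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.series_id) > 8:
            raise ValueError(f"series_id {self.series_id!r} longer than 8 characters")
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError("widths must be a non-empty 1-d array")
        if np.any(self.widths <= 0):
            raise ValueError(f"series {self.series_id}: all ring widths must be > 0")
        if self.pith_offset < 0:
            raise ValueError("pith_offset must be >= 0")
        self.first_year = int(self.first_year)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def n_rings(self) -> int:
        return self.widths.size


@dataclass
class BAISeries:
    """Per-tree annual basal area increment (mm^2) with cumulative radius."""

    series_id: str
    site_id: str
    first_year: int
    bai: np.ndarray
    cumulative_radius: np.ndarray

    def __post_init__(self) -> None:
        self.bai = np.asarray(self.bai, dtype=float)
        self.cumulative_radius = np.asarray(self.cumulative_radius, dtype=float)
        if np.any(self.bai <= 0):
            raise ValueError("BAI must be positive elementwise")
        if np.any(np.diff(self.cumulative_radius) <= 0):
            raise ValueError("cumulative radius must be strictly increasing")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.bai.size)

    def to_series(self) -> pd.Series:
        return pd.Series(self.bai, index=self.years, name=self.series_id)


@dataclass
class SiteChronology:
    """Site-level mean chronology with sample depth (trees per year)."""

    site_id: str
    years: np.ndarray
    mean_value: np.ndarray
    sd_value: np.ndarray
    sample_depth: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "mean": self.mean_value,
                "sd": self.sd_value,
                "depth": self.sample_depth,
            }
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.mean_value, index=self.years, name=self.site_id)


# ---------------------------------------------------------------------------
# Tucson (.rwl) I/O
# ---------------------------------------------------------------------------

def read_rwl(path: str | Path, site_id: str | None = None) -> list[RingWidthSeries]:
    """Read a Tucson decadal ring-width file.

    Both common dialects are supported: data in units of 0.01 mm terminated by
    the stop marker ``999``, and 0.001 mm terminated by ``-9999``.  The stop
    marker itself is not data.
    """
    path = Path(path)
    if site_id is None:
        site_id = path.stem[:8]
    out: list[RingWidthSeries] = []
    cur_id: str | None = None
    cur_first: int | None = None
    cur_vals: list[int] = []
    expected_next: int | None = None

    def _finish(marker: int) -> None:
        nonlocal cur_id, cur_first, cur_vals, expected_next
        unit = _STOP_UNITS[marker]
        widths = np.asarray(cur_vals, dtype=float) * unit
        if np.any(widths <= 0):
            raise ValueError(f"series {cur_id}: non-positive width after scaling")
        out.append(RingWidthSeries(cur_id, site_id, cur_first, widths))
        cur_id, cur_first, cur_vals, expected_next = None, None, [], None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not rest:
                continue
            year = int(rest[0])
            vals = [int(v) for v in rest[1:]]
            if cur_id is None:
                cur_id, cur_first = sid, year
            elif sid != cur_id:
                raise ValueError(
                    f"{path}:{lineno}: series {cur_id!r} not terminated by a stop marker"
                )
            elif expected_next is not None and year != expected_next:
                raise ValueError(
                    f"{path}:{lineno}: non-consecutive decade line "
                    f"(expected {expected_next}, got {year})"
                )
            done = False
            for v in vals:
                if v in _STOP_UNITS:
                    _finish(v)
                    done = True
                    break
                cur_vals.append(v)
            if not done:
                expected_next = (year // 10 + 1) * 10
    if cur_id is not None:
        raise ValueError(f"{path}: series {cur_id!r} has no stop marker")
    return out


def write_rwl(
    series: Sequence[RingWidthSeries], path: str | Path, precision: float = 0.01
) -> None:
    """Write series in Tucson decadal layout at 0.01 or 0.001 mm precision.

    Widths are rounded to the nearest unit (lossy within half a unit when the
    data carry more precision than requested); round-trips with
    :func:`read_rwl` at the chosen precision.
    """
    if not series:
        raise ValueError("empty series collection")
    if math.isclose(precision, 0.01):
        marker = 999
    elif math.isclose(precision, 0.001):
        marker = -9999
    else:
        raise ValueError("precision must be 0.01 or 0.001 mm")
    lines: list[str] = []
    for s in series:
        if len(s.series_id) > 8:
            raise ValueError(f"series_id {s.series_id!r} longer than 8 characters")
        ints = np.rint(s.widths / precision).astype(int)
        if np.any(ints <= 0):
            raise ValueError(
                f"series {s.series_id}: width rounds to <= 0 at precision {precision}"
            )
        tokens = list(ints) + [marker]
        year = s.first_year
        row: list[str] = []
        row_year = year
        for tok in tokens:
            if not row:
                row_year = year
            row.append(f"{tok:>6d}")
            year += 1
            if year % 10 == 0:  # decade boundary: flush the row
                lines.append(f"{s.series_id:<8}{row_year:>4}" + "".join(row))
                row = []
        if row:
            lines.append(f"{s.series_id:<8}{row_year:>4}" + "".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def truncate_series(
    s: RingWidthSeries, first: int, last: int
) -> RingWidthSeries | None:
    """Restrict a series to [first, last], folding earlier growth into the
    pith offset so BAI computed on the truncated series keeps the true radii.

    Returns ``None`` when the series does not overlap the interval.
    """
    lo = max(first, s.first_year)
    hi = min(last, s.last_year)
    if hi < lo:
        return None
    i0 = lo - s.first_year
    i1 = hi - s.first_year + 1
    offset = s.pith_offset + float(np.sum(s.widths[:i0]))
    return RingWidthSeries(s.series_id, s.site_id, lo, s.widths[i0:i1].copy(), offset)


# ---------------------------------------------------------------------------
# Cross-dating agreement
# ---------------------------------------------------------------------------

def glk(a: RingWidthSeries, b: RingWidthSeries) -> float:
    """Gleichlaeufigkeit: sign agreement of year-to-year changes over the
    common interval.

    For each consecutive pair of overlapping years the score is 1 when both
    series move in the same nonzero direction, 0 when they move in opposite
    directions, and 0.5 when either change is zero (classical tie handling).
    Returns the mean score in [0, 1]; requires an overlap of at least 3 years.
    """
    lo = max(a.first_year, b.first_year)
    hi = min(a.last_year, b.last_year)
    if hi - lo + 1 < 3:
        raise ValueError("insufficient overlap (need >= 3 common years)")
    wa = a.widths[lo - a.first_year : hi - a.first_year + 1]
    wb = b.widths[lo - b.first_year : hi - b.first_year + 1]
    da = np.sign(np.diff(wa))
    db = np.sign(np.diff(wb))
    score = np.where((da == 0) | (db == 0), 0.5, (da == db).astype(float))
    return float(np.mean(score))


# ---------------------------------------------------------------------------
# Basal area increment
# ---------------------------------------------------------------------------

def bai_from_widths(s: RingWidthSeries) -> BAISeries:
    """Convert ring widths to basal area increment, pi*(R_t^2 - R_{t-1}^2).

    R_t is the pith offset plus the cumulative width through year t, assuming
    a circular cross-section.  The transform is exactly invertible and, for a
    zero pith offset, conserves total basal area:
    sum(BAI) = pi * (sum(widths))**2.
    """
    radius = s.pith_offset + np.cumsum(s.widths)
    prev = np.concatenate(([s.pith_offset], radius[:-1]))
    bai = np.pi * (radius**2 - prev**2)
    return BAISeries(s.series_id, s.site_id, s.first_year, bai, radius)


def widths_from_bai(b: BAISeries, pith_offset: float = 0.0) -> np.ndarray:
    """Invert :func:`bai_from_widths` (widths from cumulative radii)."""
    prev = np.concatenate(([pith_offset], b.cumulative_radius[:-1]))
    return b.cumulative_radius - prev


def site_mean_bai(
    collection: Sequence[BAISeries], min_depth: int = 1, site_id: str | None = None
) -> SiteChronology:
    """Arithmetic mean BAI chronology over trees, with SD and sample depth.

    No standardization/detrending is applied (long-term cumulative climate
    effects are deliberately preserved).  Years with fewer than ``min_depth``
    trees are dropped.
    """
    if not collection:
        raise ValueError("empty BAI collection")
    if site_id is None:
        site_id = collection[0].site_id
    frame = pd.DataFrame({b.series_id: b.to_series() for b in collection})
    depth = frame.notna().sum(axis=1)
    keep = depth >= min_depth
    frame = frame.loc[keep]
    depth = depth.loc[keep]
    return SiteChronology(
        site_id=site_id,
        years=frame.index.to_numpy(dtype=int),
        mean_value=frame.mean(axis=1).to_numpy(),
        sd_value=frame.std(axis=1, ddof=1).to_numpy(),
        sample_depth=depth.to_numpy(dtype=int),
    )


def series_summary(collection: Iterable[RingWidthSeries]) -> pd.DataFrame:
    """Per-site biometric summary: grand mean ring width +/- SD across trees
    (each tree contributing its lifetime mean) and mean ring-count age +/- SD.
    """
    rows = [
        {
            "site_id": s.site_id,
            "series_id": s.series_id,
            "mean_trw": float(np.mean(s.widths)),
            "age": s.n_rings,
        }
        for s in collection
    ]
    if not rows:
        raise ValueError("empty series collection")
    df = pd.DataFrame(rows)
    out = df.groupby("site_id").agg(
        n_trees=("series_id", "size"),
        trw_mean=("mean_trw", "mean"),
        trw_sd=("mean_trw", "std"),
        age_mean=("age", "mean"),
        age_sd=("age", "std"),
    )
    return out.reset_index()
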