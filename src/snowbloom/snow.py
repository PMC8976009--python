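"""Snow-season estimation from buried soil-temperature loggers.

A plot under snow sits at the 0 °C isothermal point: the logger reads ~0 °C
with essentially no diurnal variation. Once the plot melts out, radiative
heating produces a daily temperature swing well above 1 °C. A day is
therefore classified *snow-covered* when its diurnal range is below a
threshold (default 1 °C) **and** its mean temperature is within a small band
around 0 °C — the second condition keeps stable warm (or cold) spells from
masquerading as snow.

"Consistent snow cover" is operationalised as runs of at least ``min_run``
consecutive snow days: the snow-appearance date is the first day of the first
qualifying run, the disappearance date the last day of the last qualifying
run (so a brief melt followed by re-burial does not end the season), and the
snow-disappearance date (SDD) is the day-of-year of the disappearance date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: expected logger cadence: 8 samples/day at 3-hour intervals
SAMPLES_PER_DAY = 8
LOW_COVERAGE_MIN = 4


@dataclass
class SnowSeason:
    """Derived snow-season quantities for one plot-year."""

    snow_appearance_date: dt.date | None
    snow_disappearance_date: dt.date | None
    snow_cover_duration: int
    minimum_soil_temp: float | None
    sdd: int | None  # DOY of the disappearance date
    notes: str = ""
    predicted: bool = False  # True when sdd was imputed, not measured

    def to_row(self) -> dict:
        return {
            "Snow_appearance_date": self.snow_appearance_date or pd.NA,
            "Snow_disappearance_date": self.snow_disappearance_date or pd.NA,
            "Snow_cover_duration": self.snow_cover_duration,
            "Minimum_soil_temp": self.minimum_soil_temp if self.minimum_soil_temp is not None else pd.NA,
            "SDD": self.sdd if self.sdd is not None else pd.NA,
            "Notes": self.notes or pd.NA,
        }


def daily_stats(series: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day min/max/mean/range of a logger series.

    Parameters
    ----------
    series : DataFrame with columns ``timestamp`` (datetime-like, strictly
        increasing) and ``temp_c``.

    Returns a DataFrame indexed by date with columns ``tmin, tmax, tmean,
    trange, n_obs, low_coverage``; days with fewer than half the expected
    3-hourly samples are flagged low-coverage.
    """
    if len(series) == 0:
        raise ValueError("empty logger series")
    ts = pd.to_datetime(series["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("logger timestamps must be strictly increasing")
    temp = pd.to_numeric(series["temp_c"])
    g = temp.groupby(ts.dt.date.values)
    out = pd.DataFrame(
        {
            "tmin": g.min(),
            "tmax": g.max(),
            "tmean": g.mean(),
            "n_obs": g.size(),
        }
    )
    out["trange"] = out["tmax"] - out["tmin"]
    out["low_coverage"] = out["n_obs"] < LOW_COVERAGE_MIN
    out.index = pd.Index(out.index, name="date")
    return out


def classify_snow_day(
    stats: pd.DataFrame,
    range_threshold: float = 1.0,
    zero_band: float = 1.0,
) -> pd.Series:
    """Classify each day as snow-covered (True) or snow-free (False).

    Snow iff the diurnal range is below ``range_threshold`` °C *and* the
    daily mean lies within ``zero_band`` °C of 0 °C.
    """
    snow = (stats["trange"] < range_threshold) & (stats["tmean"].abs() <= zero_band)
    snow.name = "snow"
    return snow


def _runs(flags: list[bool | None], max_gap: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of True, letting up to ``max_gap`` consecutive None days
    inside a run inherit its class. Returns (start, end) index pairs, inclusive."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(flags)
    while i < n:
        if flags[i] is True:
            start = i
            j = i
            last_true = i
            while j + 1 < n:
                nxt = flags[j + 1]
                if nxt is True:
                    j += 1
                    last_true = j
                elif nxt is None:
                    # look ahead: a short missing gap inside snow is bridged
                    k = j + 1
                    while k < n and flags[k] is None:
                        k += 1
                    if k < n and flags[k] is True and (k - j - 1) <= max_gap:
                        j = k
                        last_true = j
                    else:
                        break
                else:
                    break
            runs.append((start, last_true))
            i = last_true + 1
        else:
            i += 1
    return runs


def estimate_snow_season(
    series: pd.DataFrame,
    min_run: int = 5,
    range_threshold: float = 1.0,
    zero_band: float = 1.0,
    max_gap: int = 2,
) -> SnowSeason:
    """Estimate the snow season of one plot-year from its logger series.

    Appearance = first day of the first run of >= ``min_run`` snow days;
    disappearance = last day of the last such run; duration = total days
    inside qualifying runs (bridged short gaps included); SDD = DOY of the
    disappearance date. Gaps longer than ``max_gap`` days break runs and are
    recorded in the notes.
    """
    stats = daily_stats(series)
    snow = classify_snow_day(stats, range_threshold, zero_band)

    days = pd.date_range(stats.index.min(), stats.index.max(), freq="D").date
    by_day = dict(zip(stats.index, snow))
    flags: list[bool | None] = [by_day.get(d) for d in days]

    notes: list[str] = []
    n_missing = sum(f is None for f in flags)
    if n_missing:
        notes.append(f"{n_missing} day(s) without logger data")
    n_low = int(stats["low_coverage"].sum())
    if n_low:
        notes.append(f"{n_low} low-coverage day(s) (<{LOW_COVERAGE_MIN} samples)")

    runs = [r for r in _runs(flags, max_gap) if (r[1] - r[0] + 1) >= min_run]
    tmin = float(stats["tmin"].min())

    if not runs:
        if all(f is not False for f in flags) and any(f is True for f in flags):
            notes.append("snow cover too fragmented for a consistent run")
        elif any(f is True for f in flags):
            notes.append("no run of consistent snow cover")
        else:
            notes.append("no snow-covered days detected")
        return SnowSeason(None, None, 0, tmin, None, "; ".join(notes))

    first_start, _ = runs[0]
    _, last_end = runs[-1]
    appearance = days[first_start]
    disappearance = days[last_end]
    if flags[last_end] is True and last_end == len(flags) - 1:
        notes.append("no melt observed; season ends snow-covered")
        sdd = None
        disappearance_out = None
    else:
        sdd = disappearance.timetuple().tm_yday
        disappearance_out = disappearance
    duration = sum(e - s + 1 for s, e in runs)
    if len(runs) > 1:
        notes.append(f"{len(runs)} separate snow runs (re-burial)")
    return SnowSeason(appearance, disappearance_out, duration, tmin, sdd, "; ".join(notes))


def seasons_to_sdd_table(
    seasons: dict[tuple[str, int], SnowSeason],
    site_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble SnowSeason results into the MW_SDDall schema.

    ``seasons`` maps (site_code, year) to a SnowSeason; site metadata
    (transect) is pulled from the site table.
    """
    from snowbloom.schemas import SITE_CODE_RE, _coerce_dtypes

    site_transect = dict(zip(site_table["Site_Loc"], site_table["Transect"]))
    rows = []
    for (site_code, year), season in sorted(seasons.items()):
        m = SITE_CODE_RE.match(site_code)
        if m is None:
            raise ValueError(f"malformed site code {site_code!r}")
        row = {
            "Year": year,
            "Transect": site_transect.get(site_code, pd.NA),
            "Site_Num": int(m.group(2)),
            "Site_Code": site_code,
            "Site_Loc": site_code,
            "Calibration": pd.NA,
            "predSDD": pd.NA,
        }
        row.update(season.to_row())
        rows.append(row)
    cols = ["Year", "Transect", "Site_Num", "Site_Code", "Site_Loc", "Calibration",
            "Snow_appearance_date", "Snow_disappearance_date", "Snow_cover_duration",
            "Minimum_soil_temp", "SDD", "Notes", "predSDD"]
    return _coerce_dtypes(pd.DataFrame(rows, columns=cols), "sdd")
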