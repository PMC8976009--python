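"""Dataset-descriptive summaries: temporal resolution, report tallies, species shares.

A *trail report* is one datasheet-level unit — a distinct (date, transect,
observer party) submission covering every plot the party visited — not an
individual species row. Temporal resolution for a trail-year is the mean gap
in days between consecutive distinct report dates, the growing season being
bounded by the first and last report.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as dt

import numpy as np
import pandas as pd

from snowbloom.schemas import PHENO_OBSERVER_COLS


@dataclass
class TemporalResolution:
    transect: str
    year: int
    n_report_days: int
    mean_gap_days: float | None
    season_start: dt.date | None
    season_end: dt.date | None
    reason: str = ""


def _with_date_parts(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    dates = pd.to_datetime(df["Date"].astype("object"))
    df["_date"] = dates.dt.date
    df["_year"] = dates.dt.year
    df["_month"] = dates.dt.month
    return df


def mean_report_interval(records: pd.DataFrame, transect: str, year: int,
                         role: str | None = None) -> TemporalResolution:
    """Mean days between consecutive distinct report dates for a trail-year.

    ``role`` optionally restricts to Scientist or Volunteer submissions.
    Undefined (with a reason) when fewer than two distinct dates exist.
    """
    df = _with_date_parts(records)
    sel = (df["Transect"] == transect) & (df["_year"] == year)
    if role is not None:
        sel &= df["Scientist_or_volunteer"] == role
    dates = sorted(set(df.loc[sel, "_date"]))
    if len(dates) < 2:
        return TemporalResolution(
            transect, year, len(dates), None,
            dates[0] if dates else None, dates[-1] if dates else None,
            reason=f"only {len(dates)} distinct report date(s)",
        )
    gaps = np.diff([d.toordinal() for d in dates])
    return TemporalResolution(
        transect, year, len(dates), float(gaps.mean()), dates[0], dates[-1]
    )


def temporal_resolution_table(records: pd.DataFrame, role: str | None = None) -> pd.DataFrame:
    """Table-style mean inter-report interval per transect and year."""
    df = _with_date_parts(records)
    rows = []
    for (transect, year), _ in df.groupby(["Transect", "_year"], sort=True):
        tr = mean_report_interval(records, transect, int(year), role=role)
        rows.append(
            {
                "Transect": transect,
                "Year": tr.year,
                "n_report_days": tr.n_report_days,
                "mean_gap_days": tr.mean_gap_days,
                "season_start": tr.season_start,
                "season_end": tr.season_end,
            }
        )
    return pd.DataFrame(rows)


def _report_units(df: pd.DataFrame) -> pd.DataFrame:
    """Distinct datasheet submissions: (date, transect, observer set)."""
    obs = df[PHENO_OBSERVER_COLS].astype("object")
    party = obs.apply(
        lambda r: "|".join(sorted(str(v) for v in r if not pd.isna(v))), axis=1
    )
    units = df.assign(_party=party)[["_date", "_year", "_month", "Transect", "_party"]]
    return units.drop_duplicates()


def report_counts(records: pd.DataFrame, by: str = "year") -> pd.DataFrame:
    """Trail-report tallies per transect, by year or by (year, month)."""
    if by not in ("year", "month"):
        raise ValueError(f"by must be 'year' or 'month', got {by!r}")
    df = _with_date_parts(records)
    if len(df) == 0:
        return pd.DataFrame(columns=["Transect", "Year"] + (["Month"] if by == "month" else []) + ["n_reports"])
    units = _report_units(df)
    keys = ["Transect", "_year"] + (["_month"] if by == "month" else [])
    out = units.groupby(keys, sort=True).size().reset_index(name="n_reports")
    out = out.rename(columns={"_year": "Year", "_month": "Month"})
    return out


def species_report_share(records: pd.DataFrame, transect: str) -> pd.Series:
    """Fraction of a transect's species-level observation rows per species.

    Shares sum to 1 and are invariant to record order.
    """
    sub = records[records["Transect"] == transect]
    if len(sub) == 0:
        raise ValueError(f"no records for transect {transect!r}")
    counts = sub["Species"].value_counts().sort_index()
    share = counts / counts.sum()
    share.name = "share"
    return share
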