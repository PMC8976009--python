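"""Read, validate, and write the six project CSV schemas.

Each table has a fixed column layout and its own conventions; two details are
easy to get wrong and are enforced here:

* **Date dialects differ per file.** The phenology-report table uses
  day-first dates (DD/MM/YYYY); the snow-season table uses month-first
  dates (MM/DD/YYYY).
* **Missing values** are written as the literal token ``NA``; both ``NA``
  and the empty string read back as missing. Missing cells never silently
  become zeros.

Readers return a typed :class:`pandas.DataFrame` together with a
:class:`ViolationReport` pinpointing every offending row and field. In
non-strict mode offending rows are excluded; in strict mode the first
violation raises :class:`SchemaError`.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from snowbloom.species import SPECIES_BY_CODE, TRANSECTS, TRANSECT_CODES

MISSING_TOKENS = ("", "NA")
NA_TOKEN = "NA"

FILENAMES = {
    "site": "MW_SiteInfo_2013_2020.csv",
    "pheno": "MW_Phenodat_2013_2019.csv",
    "sdd": "MW_SDDall.csv",
    "curves": "MW_Phenocurves.csv",
    "volunteers": "MW_Volunteer_info_2013_2019.csv",
    "species": "MW_SpeciesInfo.csv",
}

HABITATS = ("Forest", "Low meadows", "High meadows")
OBSERVER_GROUPS = ("single", "pair", "group")
ROLES = ("Scientist", "Volunteer")
TRAINING_TYPES = ("Traditional", "Online")
SITE_CODE_RE = re.compile(r"^(GB|RL)(\d+)$")


class SchemaError(ValueError):
    """Raised in strict mode on the first schema violation."""


@dataclass(frozen=True)
class Violation:
    row: int  # 1-based data-row number (header not counted)
    field: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, field {self.field}: {self.reason}"


@dataclass
class ViolationReport:
    filename: str
    violations: list[Violation] = field(default_factory=list)

    def add(self, row: int, fieldname: str, reason: str, strict: bool) -> None:
        v = Violation(row, fieldname, reason)
        if strict:
            raise SchemaError(f"{self.filename}: {v}")
        self.violations.append(v)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.row, v.field, v.reason) for v in self.violations],
            columns=["row", "field", "reason"],
        )


# ---------------------------------------------------------------------------
# cell-level parsers / formatters

def _parse_date(token: str, fmt: str) -> dt.date:
    try:
        return dt.datetime.strptime(token, fmt).date()
    except ValueError:
        raise ValueError(f"unparseable date {token!r} (expected {fmt})")


def _parse_int(token: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"not an integer: {token!r}")


def _parse_float(token: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"not numeric: {token!r}")


def _parse_snow(token: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ValueError(f"snow code not numeric: {token!r}")
    if v not in (0.0, 0.5, 1.0):
        raise ValueError(f"snow code {token!r} outside {{0, 0.5, 1}}")
    return v


def _parse_binary(token: str) -> int:
    v = _parse_int(token)
    if v not in (0, 1):
        raise ValueError(f"value {token!r} outside {{0, 1}}")
    return v


def _parse_rank(token: str) -> int:
    v = _parse_int(token)
    if v not in (1, 2, 3, 4):
        raise ValueError(f"rank {token!r} outside {{1, 2, 3, 4}}")
    return v


def _enum_parser(allowed: tuple[str, ...], label: str) -> Callable[[str], str]:
    def parse(token: str) -> str:
        if token not in allowed:
            raise ValueError(f"{label} {token!r} not in {allowed}")
        return token

    return parse


def _parse_species(token: str) -> str:
    if token not in SPECIES_BY_CODE:
        raise ValueError(f"unknown species code {token!r}")
    return token


def _fmt_float(v: Any) -> str:
    return repr(float(v))


def _fmt_snow(v: Any) -> str:
    return {0.0: "0", 0.5: "0.5", 1.0: "1"}[float(v)]


def _fmt_date(fmt: str) -> Callable[[Any], str]:
    def f(v: Any) -> str:
        if isinstance(v, pd.Timestamp):
            v = v.date()
        return v.strftime(fmt)

    return f


@dataclass(frozen=True)
class Column:
    name: str
    parse: Callable[[str], Any]
    fmt: Callable[[Any], str] = str
    allow_missing: bool = False


# ---------------------------------------------------------------------------
# file specifications

PHENO_DATE_FMT = "%d/%m/%Y"  # day-first
SDD_DATE_FMT = "%m/%d/%Y"  # month-first

SITE_COLUMNS = (
    Column("Site_Loc", str),
    Column("Transect", _enum_parser(tuple(TRANSECTS.values()), "transect")),
    Column("Latitude", _parse_float, _fmt_float),
    Column("Longitude", _parse_float, _fmt_float),
    Column("Elevation", _parse_float, _fmt_float),
    Column("Forest_type", _enum_parser(HABITATS, "habitat")),
)

PHENO_COLUMNS = (
    Column("Transect", _enum_parser(tuple(TRANSECTS.values()), "transect")),
    Column("Date", lambda t: _parse_date(t, PHENO_DATE_FMT), _fmt_date(PHENO_DATE_FMT)),
    Column("Observer1", str),
    Column("Observer2", str, allow_missing=True),
    Column("Observer3", str, allow_missing=True),
    Column("Observer4", str, allow_missing=True),
    Column("Observer5", str, allow_missing=True),
    Column("Observer6", str, allow_missing=True),
    Column("Observer_group", _enum_parser(OBSERVER_GROUPS, "observer group")),
    Column("Scientist_or_volunteer", _enum_parser(ROLES, "role")),
    Column("Site_Code", str),
    Column("Species", _parse_species),
    Column("Snow", _parse_snow, _fmt_snow),
    Column("Bud", _parse_binary),
    Column("Bud_rank", _parse_rank, allow_missing=True),
    Column("Flower", _parse_binary),
    Column("Flower_rank", _parse_rank, allow_missing=True),
    Column("Fruit", _parse_binary),
    Column("Fruit_rank", _parse_rank, allow_missing=True),
    Column("Disperse", _parse_binary),
    Column("Disperse_rank", _parse_rank, allow_missing=True),
    Column("Herb", _parse_binary, allow_missing=True),
)

SDD_COLUMNS = (
    Column("Year", _parse_int),
    Column("Transect", _enum_parser(tuple(TRANSECTS.values()), "transect")),
    Column("Site_Num", _parse_int),
    Column("Site_Code", str),
    Column("Site_Loc", str),
    Column("Calibration", _parse_float, _fmt_float, allow_missing=True),
    Column("Snow_appearance_date", lambda t: _parse_date(t, SDD_DATE_FMT),
           _fmt_date(SDD_DATE_FMT), allow_missing=True),
    Column("Snow_disappearance_date", lambda t: _parse_date(t, SDD_DATE_FMT),
           _fmt_date(SDD_DATE_FMT), allow_missing=True),
    Column("Snow_cover_duration", _parse_int, allow_missing=True),
    Column("Minimum_soil_temp", _parse_float, _fmt_float, allow_missing=True),
    Column("SDD", _parse_int, allow_missing=True),
    Column("Notes", str, allow_missing=True),
    Column("predSDD", _parse_float, _fmt_float, allow_missing=True),
)

CURVES_COLUMNS = (
    Column("Year", _parse_int),
    Column("transect", _enum_parser(tuple(TRANSECTS.values()), "transect")),
    Column("site_code", str),
    Column("plot", _parse_int),
    Column("SDD", _parse_float, _fmt_float, allow_missing=True),
    Column("species", _parse_species),
    Column("Peak", _parse_float, _fmt_float),
    Column("Duration", _parse_float, _fmt_float),
    Column("Maximum", _parse_float, _fmt_float),
)

VOLUNTEER_COLUMNS = (
    Column("Observer", str),
    Column("First_participation", _parse_int),
    Column("Year_of_first_training", _parse_int, allow_missing=True),
    Column("Training_type", _enum_parser(TRAINING_TYPES, "training type"), allow_missing=True),
)

SPECIES_COLUMNS = (
    Column("Species", _parse_species),
    Column("Botanical_name", str),
    Column("Common_name", str),
    Column("Trails", str),
    Column("First_year", _parse_int),
    Column("Last_year", _parse_int),
)

_SPECS: dict[str, tuple[Column, ...]] = {
    "site": SITE_COLUMNS,
    "pheno": PHENO_COLUMNS,
    "sdd": SDD_COLUMNS,
    "curves": CURVES_COLUMNS,
    "volunteers": VOLUNTEER_COLUMNS,
    "species": SPECIES_COLUMNS,
}

PHENO_OBSERVER_COLS = [f"Observer{i}" for i in range(1, 7)]


# ---------------------------------------------------------------------------
# row-level checks

def _check_site_row(row: dict[str, Any]) -> list[tuple[str, str]]:
    issues = []
    if not pd.isna(row["Elevation"]) and not (1000 <= row["Elevation"] <= 2500):
        issues.append(("Elevation", f"elevation {row['Elevation']} outside [1000, 2500] m"))
    return issues


def _check_pheno_row(row: dict[str, Any]) -> list[tuple[str, str]]:
    issues = []
    n_obs = sum(not pd.isna(row[c]) for c in PHENO_OBSERVER_COLS)
    group = row["Observer_group"]
    expected = "single" if n_obs == 1 else "pair" if n_obs == 2 else "group"
    if not pd.isna(group) and n_obs >= 1 and group != expected:
        issues.append(
            ("Observer_group", f"group {group!r} inconsistent with {n_obs} observer id(s)")
        )
    m = SITE_CODE_RE.match(str(row["Site_Code"]))
    if m is None:
        issues.append(("Site_Code", f"malformed site code {row['Site_Code']!r}"))
    elif not pd.isna(row["Transect"]) and TRANSECT_CODES.get(row["Transect"]) != m.group(1):
        issues.append(
            ("Site_Code", f"site code {row['Site_Code']!r} does not match transect {row['Transect']!r}")
        )
    return issues


def _check_volunteer_row(row: dict[str, Any]) -> list[tuple[str, str]]:
    issues = []
    y = row["Year_of_first_training"]
    if not pd.isna(y) and y < 2013:
        issues.append(("Year_of_first_training", f"training year {y} precedes 2013"))
    return issues


_ROW_CHECKS: dict[str, Callable[[dict[str, Any]], list[tuple[str, str]]]] = {
    "site": _check_site_row,
    "pheno": _check_pheno_row,
    "volunteers": _check_volunteer_row,
}


# ---------------------------------------------------------------------------
# generic engine

def _read_table(path: str | Path, kind: str, strict: bool = False
                ) -> tuple[pd.DataFrame, ViolationReport]:
    path = Path(path)
    spec = _SPECS[kind]
    report = ViolationReport(path.name)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    expected = [c.name for c in spec]
    if list(raw.columns) != expected:
        missing = set(expected) - set(raw.columns)
        extra = set(raw.columns) - set(expected)
        raise SchemaError(
            f"{path.name}: header mismatch (missing {sorted(missing)}, unexpected {sorted(extra)})"
        )

    rows: list[dict[str, Any]] = []
    for i, raw_row in enumerate(raw.itertuples(index=False), start=1):
        parsed: dict[str, Any] = {}
        ok = True
        for col, token in zip(spec, raw_row):
            token = str(token).strip()
            if token in MISSING_TOKENS:
                if col.allow_missing:
                    parsed[col.name] = pd.NA
                else:
                    report.add(i, col.name, "missing value in required field", strict)
                    ok = False
                continue
            try:
                parsed[col.name] = col.parse(token)
            except ValueError as exc:
                report.add(i, col.name, str(exc), strict)
                ok = False
        if not ok:
            continue
        check = _ROW_CHECKS.get(kind)
        if check is not None:
            issues = check(parsed)
            for fieldname, reason in issues:
                report.add(i, fieldname, reason, strict)
            if issues:
                continue
        rows.append(parsed)

    df = pd.DataFrame(rows, columns=expected)
    df = _coerce_dtypes(df, kind)

    if kind == "site" and len(df):
        dup = df["Site_Loc"][df["Site_Loc"].duplicated()]
        for idx in dup.index:
            report.add(int(idx) + 1, "Site_Loc", f"duplicate site id {df.at[idx, 'Site_Loc']!r}", strict)
        if not dup.empty:
            df = df[~df["Site_Loc"].duplicated(keep=False) | ~df["Site_Loc"].isin(dup)]
            df = df.reset_index(drop=True)
    return df, report


_INT_COLS = {
    "pheno": ["Bud", "Flower", "Fruit", "Disperse", "Bud_rank", "Flower_rank",
              "Fruit_rank", "Disperse_rank", "Herb"],
    "sdd": ["Year", "Site_Num", "Snow_cover_duration", "SDD"],
    "curves": ["Year", "plot"],
    "volunteers": ["First_participation", "Year_of_first_training"],
    "species": ["First_year", "Last_year"],
}
_FLOAT_COLS = {
    "site": ["Latitude", "Longitude", "Elevation"],
    "pheno": ["Snow"],
    "sdd": ["Calibration", "Minimum_soil_temp", "predSDD"],
    "curves": ["SDD", "Peak", "Duration", "Maximum"],
}


def _coerce_dtypes(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    for c in _INT_COLS.get(kind, []):
        df[c] = pd.array(df[c], dtype="Int64")
    for c in _FLOAT_COLS.get(kind, []):
        df[c] = pd.array(df[c], dtype="Float64")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    spec = _SPECS[kind]
    out = pd.DataFrame(index=df.index)
    for col in spec:
        if col.name not in df.columns:
            raise SchemaError(f"cannot write {Path(path).name}: column {col.name!r} absent")
        values = df[col.name]
        out[col.name] = [
            NA_TOKEN if pd.isna(v) else col.fmt(v) for v in values
        ]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# public API

def read_site_table(path, strict: bool = False):
    """Read the plot-location table (id, transect, WGS84 coords, elevation, habitat)."""
    return _read_table(path, "site", strict)


def read_pheno_table(path, strict: bool = False):
    """Read raw phenology reports. Dates are day-first; snow codes in {0, 0.5, 1}."""
    return _read_table(path, "pheno", strict)


def read_sdd_table(path, strict: bool = False):
    """Read the per-plot-year snow-season table. Dates are month-first."""
    return _read_table(path, "sdd", strict)


def read_curves_table(path, strict: bool = False):
    """Read fitted flowering-curve parameters (Peak=rho, Duration=delta, Maximum=mu)."""
    return _read_table(path, "curves", strict)


def read_volunteer_table(path, strict: bool = False):
    """Read the anonymized volunteer roster."""
    return _read_table(path, "volunteers", strict)


def read_species_table(path, strict: bool = False):
    """Read the species-code equivalency table; unknown codes are violations."""
    return _read_table(path, "species", strict)


_READERS = {
    "site": read_site_table,
    "pheno": read_pheno_table,
    "sdd": read_sdd_table,
    "curves": read_curves_table,
    "volunteers": read_volunteer_table,
    "species": read_species_table,
}


def read_tables(directory, strict: bool = False
                ) -> tuple[dict[str, pd.DataFrame], dict[str, ViolationReport]]:
    """Read every schema file present in *directory*.

    Returns (tables, reports), keyed by schema kind. Missing files are simply
    absent from the result.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    reports: dict[str, ViolationReport] = {}
    for kind, fname in FILENAMES.items():
        p = directory / fname
        if p.exists():
            tables[kind], reports[kind] = _READERS[kind](p, strict)
    if not tables:
        raise FileNotFoundError(f"no schema files found in {directory}")
    return tables, reports


def write_tables(tables: dict[str, pd.DataFrame], directory) -> dict[str, Path]:
    """Write tables under their canonical filenames; round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for kind, df in tables.items():
        if kind not in _SPECS:
            raise SchemaError(f"unknown table kind {kind!r}")
        p = directory / FILENAMES[kind]
        _write_table(df, p, kind)
        written[kind] = p
    return written


def species_table_frame() -> pd.DataFrame:
    """The canonical species table as a schema-shaped DataFrame."""
    from snowbloom.species import SPECIES_TABLE

    rows = [
        {
            "Species": s.code,
            "Botanical_name": s.botanical_name,
            "Common_name": s.common_name,
            "Trails": ";".join(sorted(s.trails)),
            "First_year": s.first_year,
            "Last_year": s.last_year,
        }
        for s in SPECIES_TABLE
    ]
    df = pd.DataFrame(rows).sort_values("Species").reset_index(drop=True)
    return _coerce_dtypes(df, "species")
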