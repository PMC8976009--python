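"""Synthetic two-transect phenology studies with known ground truth.

The generator emulates the field design end to end: plots along two trail
transects spanning a ~400 m elevation gradient; buried loggers recording
soil temperature every 3 hours (isothermal ~0 °C under snow, diurnally
cycling when snow-free); per-plot snowmelt-keyed phenophase schedules
(bud -> flower -> fruit -> seed) for each hosted species; and trail reports
filed several times a week by volunteer parties plus roughly weekly by
scientists, each observer reading the latent plot state through a
configurable sensitivity/specificity filter.

Flowering is special: the latent flowering state on a given day is a
Bernoulli draw from the same Gaussian-bump curve the fitting module
estimates, so fitted parameters can be compared against the exact generating
(delta*, mu*, rho*). Bud/fruit/seed are deterministic window indicators
observed with error. One latent state is drawn per (date, plot, species), so
observers who visit on the same day see the same plants.

Everything is deterministic given the seed: the same configuration and seed
produce byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snowbloom.curves import flowering_probability
from snowbloom.schemas import _coerce_dtypes, species_table_frame, write_tables
from snowbloom.species import (
    PHENOPHASES,
    SPECIES_BY_CODE,
    TRANSECTS,
    species_for_trail,
)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ErrorProfile:
    """Per species x phenophase (sensitivity, specificity) for one observer role."""

    rates: dict[tuple[str, str], tuple[float, float]]

    @classmethod
    def uniform(cls, sensitivity: float, specificity: float,
                species: list[str] | None = None) -> "ErrorProfile":
        codes = species if species is not None else sorted(SPECIES_BY_CODE)
        rates = {
            (sp, ph): (sensitivity, specificity)
            for sp in codes
            for ph in PHENOPHASES
        }
        return cls(rates)

    def get(self, species: str, phase: str) -> tuple[float, float]:
        try:
            return self.rates[(species, phase)]
        except KeyError:
            raise KeyError(
                f"error profile has no entry for species {species!r}, phenophase {phase!r}"
            )

    def validate(self) -> None:
        for (sp, ph), (sens, spec) in self.rates.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise ValueError(
                    f"error rates for ({sp}, {ph}) outside [0, 1]: ({sens}, {spec})"
                )


@dataclass
class SpeciesCurve:
    """True flowering-curve parameters for one species, keyed to snowmelt."""

    rho_offset: float  # days between SDD and peak flowering
    delta: float  # duration (width) parameter, days
    mu: float  # maximum flowering probability


def default_species_curves() -> dict[str, SpeciesCurve]:
    """Deterministic per-species true parameters spanning realistic ranges:
    peaks 3-9 weeks after melt, widths 8-14 days, maxima 0.65-0.97."""
    out = {}
    for i, code in enumerate(sorted(SPECIES_BY_CODE)):
        out[code] = SpeciesCurve(
            rho_offset=22.0 + 2.4 * i,
            delta=8.0 + 1.5 * (i % 5),
            mu=round(0.65 + 0.02 * i, 3),
        )
    return out


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the field design: 14 plots per transect (28 total) over
    the published elevation ranges, Reflection Lakes monitored from 2013 and
    Glacier Basin from 2015, 4-5 trail reports per week in a May-October
    season, ~once-weekly scientist sampling, a fifth of plot-years losing
    their logger, and volunteers reading phenophases with sensitivity ~0.75
    and specificity ~0.90 against near-perfect (0.98) scientists.
    """

    n_plots_gb: int = 14
    n_plots_rl: int = 14
    elevation_gb: tuple[float, float] = (1460.0, 1831.0)
    elevation_rl: tuple[float, float] = (1490.0, 1889.0)
    years_gb: tuple[int, int] = (2015, 2019)
    years_rl: tuple[int, int] = (2013, 2019)
    season: tuple[int, int] = (120, 280)  # DOY window for trail reports
    reports_per_week: float = 4.0  # volunteer submissions
    scientist_weekday: int = 2  # Wednesday; ~weekly expert sampling
    species_per_plot: int = 3
    # observer error rates (scalar defaults; per-species/phase overrides below)
    volunteer_sensitivity: float = 0.75
    volunteer_specificity: float = 0.90
    scientist_sensitivity: float = 0.98
    scientist_specificity: float = 0.98
    volunteer_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    # loggers
    logger_noise_sd: float = 0.05  # deg C
    diurnal_amplitude: float = 6.0  # deg C daily range when snow-free; must be > 1
    missing_sdd_fraction: float = 0.20
    # snow / phenology structure
    sdd_base: float = 135.0  # DOY at the lowest plot
    sdd_elev_slope: float = 3.5  # days per 100 m
    sdd_year_sd: float = 6.0
    sdd_plot_sd: float = 3.0
    snow_appearance_doy: float = 305.0  # previous fall
    partial_snow_window: float = 7.0  # days of snow code 0.5 before melt-out
    pheno_jitter_sd: float = 2.0  # plot-level jitter of windows/peaks
    herbivory_rate: float = 0.08
    n_volunteers: int = 160
    n_scientists: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 3.0 <= self.reports_per_week + 1.0 <= 9.0:
            raise ValueError(
                "total reports/week (volunteer + ~1 scientist) must lie in [3, 9]; "
                f"got volunteer rate {self.reports_per_week}"
            )
        if self.diurnal_amplitude <= 1.0:
            raise ValueError(
                f"diurnal amplitude must exceed 1 deg C (got {self.diurnal_amplitude}); "
                "snow detection is ill-posed otherwise"
            )
        if not 0.0 <= self.missing_sdd_fraction < 1.0:
            raise ValueError("missing_sdd_fraction must be in [0, 1)")
        for name in ("volunteer_sensitivity", "volunteer_specificity",
                     "scientist_sensitivity", "scientist_specificity",
                     "herbivory_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.volunteer_profile().validate()

    # -- observer profiles --------------------------------------------------

    def volunteer_profile(self) -> ErrorProfile:
        prof = ErrorProfile.uniform(self.volunteer_sensitivity, self.volunteer_specificity)
        for key, (sens, spec) in self.volunteer_overrides.items():
            sp, ph = key.split(":")
            if sp not in SPECIES_BY_CODE or ph not in PHENOPHASES:
                raise ValueError(f"bad override key {key!r} (expected 'CODE:phenophase')")
            prof.rates[(sp, ph)] = (float(sens), float(spec))
        return prof

    def scientist_profile(self) -> ErrorProfile:
        return ErrorProfile.uniform(self.scientist_sensitivity, self.scientist_specificity)

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("elevation_gb", "elevation_rl", "years_gb", "years_rl", "season"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "volunteer_overrides" in raw:
            raw["volunteer_overrides"] = {
                k: tuple(v) for k, v in raw["volunteer_overrides"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("elevation_gb", "elevation_rl", "years_gb", "years_rl", "season"):
            d[key] = list(d[key])
        d["volunteer_overrides"] = {k: list(v) for k, v in d["volunteer_overrides"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# ground truth containers

@dataclass
class GroundTruth:
    """Latent truth behind a synthetic study.

    ``plot_years``: one row per plot-year with the true SDD (DOY), the
    previous-fall snow-appearance DOY, and whether the logger survived.
    ``species_truth``: one row per species x plot x year with the true curve
    (delta*, mu*, rho*) and the four phenophase windows (DOY, inclusive).
    """

    plot_years: pd.DataFrame
    species_truth: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.plot_years.to_csv(directory / "ground_truth_plot_years.csv", index=False)
        self.species_truth.to_csv(directory / "ground_truth_curves.csv", index=False)


@dataclass
class StudyData:
    """A complete synthetic study: the six schema tables, the raw logger
    series keyed by (site_code, year), and the generating ground truth."""

    tables: dict[str, pd.DataFrame]
    loggers: dict[tuple[str, int], pd.DataFrame]
    truth: GroundTruth
    config: SimulationConfig
    seed: int

    def write(self, directory) -> None:
        directory = Path(directory)
        write_tables(self.tables, directory)
        logger_dir = directory / "loggers"
        logger_dir.mkdir(parents=True, exist_ok=True)
        for (site, year), series in sorted(self.loggers.items()):
            out = series.copy()
            out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
            out["temp_c"] = out["temp_c"].map(lambda v: f"{v:.4f}")
            out.to_csv(logger_dir / f"{site}_{year}.csv", index=False)
        self.truth.write(directory)


# ---------------------------------------------------------------------------
# component simulators

def _doy_to_date(year: int, doy: float) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(round(doy)) - 1)


def seasonal_mean_temp(doy: np.ndarray) -> np.ndarray:
    """Smooth snow-free soil temperature trend (deg C), peaking mid-July and
    staying comfortably above the near-zero band year-round."""
    return 8.0 + 4.0 * np.cos(2.0 * np.pi * (doy - 193.0) / 365.0)


def simulate_logger_series(
    true_sdd: int,
    snow_appearance: int,
    year: int,
    amplitude: float = 6.0,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> pd.DataFrame:
    """Simulate a 3-hour soil-temperature series for one plot-year.

    The series runs from *start* (default Sep 1 of the previous year, when
    sensors are placed) to *end* (default Aug 1 of *year*). Days from the
    snow-appearance date (DOY of the previous fall) through the true SDD
    inclusive read ~0 deg C with no diurnal cycle; snow-free days follow a
    seasonal trend plus a sinusoidal diurnal cycle whose daily range equals
    ``amplitude``.
    """
    if amplitude <= 1.0:
        raise ValueError(f"amplitude must exceed 1 deg C, got {amplitude}")
    rng = rng if rng is not None else np.random.default_rng(0)
    start = start or dt.date(year - 1, 9, 1)
    end = end or dt.date(year, 8, 1)
    appearance_date = _doy_to_date(year - 1, snow_appearance)
    sdd_date = _doy_to_date(year, true_sdd)
    if not (start < appearance_date < sdd_date < end):
        raise ValueError(
            f"snow season [{appearance_date}, {sdd_date}] must fall inside the "
            f"logger window [{start}, {end}]"
        )

    stamps = pd.date_range(
        dt.datetime.combine(start, dt.time(0)),
        dt.datetime.combine(end, dt.time(21)),
        freq="3h",
    )
    dates = stamps.date
    doy = stamps.dayofyear.to_numpy(dtype=float)
    hours = stamps.hour.to_numpy(dtype=float)
    snow = (dates >= appearance_date) & (dates <= sdd_date)

    temp = np.empty(len(stamps))
    diurnal = (amplitude / 2.0) * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
    temp[~snow] = seasonal_mean_temp(doy[~snow]) + diurnal[~snow]
    temp[snow] = 0.0
    if noise_sd > 0:
        temp += rng.normal(0.0, noise_sd, size=len(temp))
    return pd.DataFrame({"timestamp": stamps, "temp_c": temp})


def simulate_phenology(
    plot_years: pd.DataFrame,
    assignment: dict[str, list[str]],
    curves: dict[str, SpeciesCurve],
    jitter_sd: float = 2.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent phenophase windows and flowering curves per species x plot x year.

    Windows are keyed to each plot-year's true SDD: peak flowering sits
    ``rho_offset`` days after melt (plus plot-level jitter), the flowering
    window spans rho +/- 2 delta, buds lead flowering by ~10 days, and fruit
    and seed lag by delta and 2 delta. Onsets are clamped at the SDD, which
    preserves the bud <= flower <= fruit <= seed onset ordering.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for pr in plot_years.sort_values(["Site_Code", "Year"]).itertuples(index=False):
        sdd = float(pr.true_sdd)
        for code in assignment[pr.Site_Code]:
            sp = SPECIES_BY_CODE[code]
            if not sp.active_in(int(pr.Year)):
                continue
            c = curves[code]
            jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            rho = sdd + c.rho_offset + jitter
            flower_on, flower_off = rho - 2 * c.delta, rho + 2 * c.delta
            bud_on, bud_off = flower_on - 10.0, rho
            fruit_on, fruit_off = rho + c.delta, rho + 3 * c.delta
            seed_on, seed_off = rho + 2 * c.delta, rho + 4 * c.delta
            clamp = lambda x: max(x, sdd)
            rows.append(
                {
                    "Site_Code": pr.Site_Code,
                    "Transect": pr.Transect,
                    "Year": int(pr.Year),
                    "Species": code,
                    "delta": c.delta,
                    "mu": c.mu,
                    "rho": rho,
                    "bud_on": clamp(bud_on),
                    "bud_off": bud_off,
                    "flower_on": clamp(flower_on),
                    "flower_off": flower_off,
                    "fruit_on": clamp(fruit_on),
                    "fruit_off": fruit_off,
                    "seed_on": clamp(seed_on),
                    "seed_off": seed_off,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Submission:
    """One scheduled trail report: a party walking a transect on a date."""

    date: dt.date
    transect: str  # full transect name
    role: str  # Scientist / Volunteer
    observers: tuple[str, ...]


def simulate_schedules(
    transect: str,
    year: int,
    season: tuple[int, int],
    reports_per_week: float,
    volunteers: list[str],
    scientists: list[str],
    rng: np.random.Generator,
    scientist_weekday: int = 2,
) -> list[Submission]:
    """Volunteer and scientist trail-report schedules for one transect-year.

    Volunteers file ~``reports_per_week`` submissions on dates drawn with a
    weekend bias (the pattern the parallel expert sampling corrects);
    scientists walk the trail weekly on a fixed weekday.
    """
    d0 = _doy_to_date(year, season[0])
    d1 = _doy_to_date(year, season[1])
    days = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]

    subs: list[Submission] = []
    sci_party_pool = list(scientists)
    for d in days:
        if d.weekday() == scientist_weekday:
            k = 1 + int(rng.random() < 0.3)
            party = tuple(rng.choice(sci_party_pool, size=k, replace=False))
            subs.append(Submission(d, transect, "Scientist", party))

    n_weeks = len(days) / 7.0
    n_vol = int(round(reports_per_week * n_weeks))
    weights = np.array(
        [2.5 if d.weekday() >= 5 else 1.5 if d.weekday() == 4 else 1.0 for d in days]
    )
    weights = weights / weights.sum()
    picks = rng.choice(len(days), size=n_vol, replace=True, p=weights)
    for i in sorted(picks):
        size = int(rng.choice([1, 2, 3], p=[0.5, 0.35, 0.15]))
        party = tuple(rng.choice(volunteers, size=size, replace=False))
        subs.append(Submission(days[i], transect, "Volunteer", party))
    subs.sort(key=lambda s: (s.date, s.role, s.observers))
    return subs


def _observer_group(n: int) -> str:
    return "single" if n == 1 else "pair" if n == 2 else "group"


def simulate_reports(
    truth: GroundTruth,
    assignment: dict[str, list[str]],
    submissions: list[Submission],
    volunteer_profile: ErrorProfile,
    scientist_profile: ErrorProfile,
    season: tuple[int, int],
    partial_snow_window: float,
    herbivory_rate: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Turn latent truth plus a schedule into a phenology-report table.

    One latent state per (date, plot, species) is drawn (flowering is a
    Bernoulli draw from the true curve; the other phases are window
    indicators); every party that day reads that state through its own
    sensitivity/specificity filter. Snow codes derive from the true SDD:
    1 (covered) until ``partial_snow_window`` days before melt-out, 0.5
    through the SDD, 0 after. Submissions outside the season window are
    excluded and tallied.
    """
    stats = {"submissions": 0, "excluded_out_of_season": 0, "rows": 0}
    py = {
        (r.Site_Code, int(r.Year)): r
        for r in truth.plot_years.itertuples(index=False)
    }
    st = {
        (r.Site_Code, int(r.Year), r.Species): r
        for r in truth.species_truth.itertuples(index=False)
    }
    plots_by_transect: dict[str, list[str]] = {}
    for (site, year_), r in py.items():
        plots_by_transect.setdefault(r.Transect, [])
        if site not in plots_by_transect[r.Transect]:
            plots_by_transect[r.Transect].append(site)
    for v in plots_by_transect.values():
        v.sort()

    latent_flower: dict[tuple[dt.date, str, str], int] = {}
    latent_herb: dict[tuple[dt.date, str], int] = {}
    rows: list[dict] = []

    for sub in submissions:
        doy = sub.date.timetuple().tm_yday
        if not season[0] <= doy <= season[1]:
            stats["excluded_out_of_season"] += 1
            continue
        stats["submissions"] += 1
        profile = scientist_profile if sub.role == "Scientist" else volunteer_profile
        year = sub.date.year
        obs_cells = {f"Observer{i + 1}": pd.NA for i in range(6)}
        for i, o in enumerate(sub.observers):
            obs_cells[f"Observer{i + 1}"] = o

        for site in plots_by_transect.get(sub.transect, []):
            key_py = (site, year)
            if key_py not in py:
                continue
            sdd = float(py[key_py].true_sdd)
            if doy > sdd:
                snow = 0.0
            elif doy >= sdd - partial_snow_window:
                snow = 0.5
            else:
                snow = 1.0

            hk = (sub.date, site)
            if hk not in latent_herb:
                latent_herb[hk] = int(rng.random() < herbivory_rate)
            herb: object
            if year < 2017:
                herb = pd.NA  # herbivory only recorded from 2017 on
            elif sub.role == "Volunteer" and rng.random() < 0.10:
                herb = pd.NA  # occasional unfilled cell
            else:
                herb = latent_herb[hk]

            for code in assignment[site]:
                tkey = (site, year, code)
                if tkey not in st:
                    continue  # species not active this year
                t = st[tkey]
                fk = (sub.date, site, code)
                if fk not in latent_flower:
                    p = flowering_probability(doy, t.delta, t.mu, t.rho)
                    latent_flower[fk] = int(rng.random() < p)
                latent = {
                    "bud": int(t.bud_on <= doy <= t.bud_off),
                    "flower": latent_flower[fk],
                    "fruit": int(t.fruit_on <= doy <= t.fruit_off),
                    "disperse": int(t.seed_on <= doy <= t.seed_off),
                }
                recorded = {}
                for phase, lat in latent.items():
                    sens, spec = profile.get(code, phase)
                    if lat == 1:
                        recorded[phase] = int(rng.random() < sens)
                    else:
                        recorded[phase] = int(rng.random() >= spec)
                ranks = {}
                for phase in PHENOPHASES:
                    col = f"{phase.capitalize()}_rank" if phase != "disperse" else "Disperse_rank"
                    if 2013 <= year <= 2015 and recorded[phase] == 1:
                        ranks[col] = int(rng.integers(1, 5))
                    else:
                        ranks[col] = pd.NA
                rows.append(
                    {
                        "Transect": sub.transect,
                        "Date": sub.date,
                        **obs_cells,
                        "Observer_group": _observer_group(len(sub.observers)),
                        "Scientist_or_volunteer": sub.role,
                        "Site_Code": site,
                        "Species": code,
                        "Snow": snow,
                        "Bud": recorded["bud"],
                        "Bud_rank": ranks["Bud_rank"],
                        "Flower": recorded["flower"],
                        "Flower_rank": ranks["Flower_rank"],
                        "Fruit": recorded["fruit"],
                        "Fruit_rank": ranks["Fruit_rank"],
                        "Disperse": recorded["disperse"],
                        "Disperse_rank": ranks["Disperse_rank"],
                        "Herb": herb,
                    }
                )
                stats["rows"] += 1
    cols = ["Transect", "Date"] + [f"Observer{i}" for i in range(1, 7)] + [
        "Observer_group", "Scientist_or_volunteer", "Site_Code", "Species", "Snow",
        "Bud", "Bud_rank", "Flower", "Flower_rank", "Fruit", "Fruit_rank",
        "Disperse", "Disperse_rank", "Herb",
    ]
    pheno = _coerce_dtypes(pd.DataFrame(rows, columns=cols), "pheno")
    return pheno, stats


# ---------------------------------------------------------------------------
# full-study generator

def _make_sites(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    specs = [
        ("GB", "Glacier Basin", config.n_plots_gb, config.elevation_gb, 46.90, -121.68),
        ("RL", "Reflection Lakes", config.n_plots_rl, config.elevation_rl, 46.77, -121.73),
    ]
    for code, name, n, (e0, e1), lat0, lon0 in specs:
        elevs = np.linspace(e0, e1, n)
        for i, elev in enumerate(elevs, start=1):
            habitat = "Forest" if elev < 1550 else "Low meadows" if elev < 1700 else "High meadows"
            rows.append(
                {
                    "Site_Loc": f"{code}{i:02d}",
                    "Transect": name,
                    "Latitude": round(lat0 + 0.0008 * i, 6),
                    "Longitude": round(lon0 + 0.0005 * i, 6),
                    "Elevation": round(float(elev), 1),
                    "Forest_type": habitat,
                }
            )
    return _coerce_dtypes(pd.DataFrame(rows), "site")


def generate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> StudyData:
    """Generate a complete synthetic study (six tables + loggers + truth).

    Deterministic given (config, seed); *seed* overrides ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    sites = _make_sites(config)
    elev = dict(zip(sites["Site_Loc"], sites["Elevation"].astype(float)))
    transect_of = dict(zip(sites["Site_Loc"], sites["Transect"]))

    years_of = {
        "Glacier Basin": range(config.years_gb[0], config.years_gb[1] + 1),
        "Reflection Lakes": range(config.years_rl[0], config.years_rl[1] + 1),
    }
    all_years = sorted(
        set(years_of["Glacier Basin"]) | set(years_of["Reflection Lakes"])
    )
    year_eff = {y: rng.normal(0.0, config.sdd_year_sd) for y in all_years}
    e_min = min(elev.values())

    # --- plot-year truth ----------------------------------------------------
    pr_rows = []
    for site in sorted(elev):
        for year in years_of[transect_of[site]]:
            sdd = (
                config.sdd_base
                + config.sdd_elev_slope * (elev[site] - e_min) / 100.0
                + year_eff[year]
                + rng.normal(0.0, config.sdd_plot_sd)
            )
            appearance = config.snow_appearance_doy + rng.normal(0.0, 5.0)
            pr_rows.append(
                {
                    "Site_Code": site,
                    "Transect": transect_of[site],
                    "Year": year,
                    "Elevation": elev[site],
                    "true_sdd": int(round(sdd)),
                    "snow_appearance_doy": int(round(appearance)),
                }
            )
    plot_years = pd.DataFrame(pr_rows)
    n_missing = int(round(config.missing_sdd_fraction * len(plot_years)))
    missing_idx = rng.choice(len(plot_years), size=n_missing, replace=False)
    plot_years["logger_available"] = True
    plot_years.loc[sorted(missing_idx), "logger_available"] = False

    # --- species assignment and latent phenology ---------------------------
    curves = default_species_curves()
    assignment: dict[str, list[str]] = {}
    for site in sorted(elev):
        trail = "GB" if site.startswith("GB") else "RL"
        pool = sorted(s.code for s in species_for_trail(trail))
        k = min(config.species_per_plot, len(pool))
        assignment[site] = sorted(rng.choice(pool, size=k, replace=False))
    species_truth = simulate_phenology(
        plot_years, assignment, curves, config.pheno_jitter_sd, rng
    )

    # --- loggers and the snow-season table ---------------------------------
    loggers: dict[tuple[str, int], pd.DataFrame] = {}
    sdd_rows = []
    for pr in plot_years.itertuples(index=False):
        site, year = pr.Site_Code, int(pr.Year)
        row = {
            "Year": year,
            "Transect": pr.Transect,
            "Site_Num": int(site[2:]),
            "Site_Code": site,
            "Site_Loc": site,
            "Calibration": pd.NA,
            "predSDD": pd.NA,
        }
        if pr.logger_available:
            series = simulate_logger_series(
                int(pr.true_sdd),
                int(pr.snow_appearance_doy),
                year,
                amplitude=config.diurnal_amplitude,
                noise_sd=config.logger_noise_sd,
                rng=rng,
            )
            loggers[(site, year)] = series
            appearance = _doy_to_date(year - 1, pr.snow_appearance_doy)
            disappearance = _doy_to_date(year, pr.true_sdd)
            row.update(
                {
                    "Snow_appearance_date": appearance,
                    "Snow_disappearance_date": disappearance,
                    "Snow_cover_duration": (disappearance - appearance).days + 1,
                    "Minimum_soil_temp": round(float(series["temp_c"].min()), 4),
                    "SDD": int(pr.true_sdd),
                    "Notes": pd.NA,
                }
            )
        else:
            row.update(
                {
                    "Snow_appearance_date": pd.NA,
                    "Snow_disappearance_date": pd.NA,
                    "Snow_cover_duration": pd.NA,
                    "Minimum_soil_temp": pd.NA,
                    "SDD": pd.NA,
                    "Notes": "logger lost; SDD to be imputed",
                }
            )
        sdd_rows.append(row)
    sdd_cols = ["Year", "Transect", "Site_Num", "Site_Code", "Site_Loc", "Calibration",
                "Snow_appearance_date", "Snow_disappearance_date", "Snow_cover_duration",
                "Minimum_soil_temp", "SDD", "Notes", "predSDD"]
    sdd_table = _coerce_dtypes(pd.DataFrame(sdd_rows, columns=sdd_cols), "sdd")

    # --- observers and schedules -------------------------------------------
    volunteers = [f"V{1000 + i}" for i in range(config.n_volunteers)]
    scientists = [f"S{100 + i}" for i in range(config.n_scientists)]
    submissions: list[Submission] = []
    for transect in ("Glacier Basin", "Reflection Lakes"):
        for year in years_of[transect]:
            submissions += simulate_schedules(
                transect, year, config.season, config.reports_per_week,
                volunteers, scientists, rng, config.scientist_weekday,
            )

    pheno, _ = simulate_reports(
        GroundTruth(plot_years, species_truth),
        assignment,
        submissions,
        config.volunteer_profile(),
        config.scientist_profile(),
        config.season,
        config.partial_snow_window,
        config.herbivory_rate,
        rng,
    )

    # --- volunteer roster ---------------------------------------------------
    first_seen: dict[str, int] = {}
    for sub in submissions:
        if sub.role != "Volunteer":
            continue
        for o in sub.observers:
            y = sub.date.year
            first_seen[o] = min(first_seen.get(o, y), y)
    vol_rows = [
        {
            "Observer": o,
            "First_participation": y,
            "Year_of_first_training": y,
            "Training_type": "Traditional",
        }
        for o, y in sorted(first_seen.items())
    ]
    vol_table = _coerce_dtypes(
        pd.DataFrame(vol_rows, columns=["Observer", "First_participation",
                                        "Year_of_first_training", "Training_type"]),
        "volunteers",
    )

    # --- true curves in the phenocurves layout ------------------------------
    cv_rows = [
        {
            "Year": int(r.Year),
            "transect": r.Transect,
            "site_code": r.Site_Code,
            "plot": int(r.Site_Code[2:]),
            "SDD": float(
                plot_years.set_index(["Site_Code", "Year"]).loc[
                    (r.Site_Code, int(r.Year)), "true_sdd"
                ]
            ),
            "species": r.Species,
            "Peak": round(float(r.rho), 3),
            "Duration": float(r.delta),
            "Maximum": float(r.mu),
        }
        for r in species_truth.itertuples(index=False)
    ]
    curves_table = _coerce_dtypes(
        pd.DataFrame(cv_rows, columns=["Year", "transect", "site_code", "plot",
                                       "SDD", "species", "Peak", "Duration", "Maximum"]),
        "curves",
    )

    tables = {
        "site": sites,
        "pheno": pheno,
        "sdd": sdd_table,
        "curves": curves_table,
        "volunteers": vol_table,
        "species": species_table_frame(),
    }
    return StudyData(tables, loggers, GroundTruth(plot_years, species_truth), config, seed)
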