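import numpy as np
import pandas as pd
import pytest

from snowbloom.simulate import SimulationConfig, generate_study


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down study design for fast tests: 4+4 plots, two seasons."""
    base = dict(
        n_plots_gb=4,
        n_plots_rl=4,
        years_gb=(2017, 2018),
        years_rl=(2017, 2018),
        season=(140, 240),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def study():
    """One shared small synthetic study."""
    return generate_study(small_config(), seed=42)


@pytest.fixture(scope="session")
def inversion_study():
    """A study sized for error-rate inversion: error-free scientist reference,
    dense volunteer sampling, strata of well over 200 pairs per phenophase."""
    cfg = small_config(
        n_plots_gb=8, n_plots_rl=8,
        years_gb=(2016, 2018), years_rl=(2016, 2018),
        reports_per_week=8.0,
        scientist_sensitivity=1.0, scientist_specificity=1.0,
        volunteer_sensitivity=0.75, volunteer_specificity=0.90,
    )
    return generate_study(cfg, seed=2024)


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    study.write(d)
    return d


def make_pheno(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal phenology-report frame from sparse row dicts."""
    import datetime as dt

    from snowbloom.schemas import _coerce_dtypes

    defaults = {
        "Transect": "Glacier Basin",
        "Date": dt.date(2018, 7, 1),
        "Observer1": "V1",
        "Observer2": pd.NA,
        "Observer3": pd.NA,
        "Observer4": pd.NA,
        "Observer5": pd.NA,
        "Observer6": pd.NA,
        "Observer_group": "single",
        "Scientist_or_volunteer": "Volunteer",
        "Site_Code": "GB01",
        "Species": "LUAR",
        "Snow": 0.0,
        "Bud": 0,
        "Bud_rank": pd.NA,
        "Flower": 0,
        "Flower_rank": pd.NA,
        "Fruit": 0,
        "Fruit_rank": pd.NA,
        "Disperse": 0,
        "Disperse_rank": pd.NA,
        "Herb": pd.NA,
    }
    out = [dict(defaults, **r) for r in rows]
    return _coerce_dtypes(pd.DataFrame(out, columns=list(defaults)), "pheno")
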