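"""Synthetic-data generator: construction rules, determinism, calibration."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from snowbloom.curves import flowering_probability
from snowbloom.simulate import (
    ErrorProfile,
    GroundTruth,
    SimulationConfig,
    Submission,
    default_species_curves,
    generate_study,
    simulate_logger_series,
    simulate_phenology,
    simulate_reports,
)

from conftest import small_config


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    def test_amplitude_at_or_below_one_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            SimulationConfig(diurnal_amplitude=1.0).validate()

    def test_report_rate_outside_band_rejected(self):
        with pytest.raises(ValueError, match="3, 9"):
            SimulationConfig(reports_per_week=12.0).validate()

    def test_probability_fields_bounded(self):
        with pytest.raises(ValueError, match="volunteer_sensitivity"):
            SimulationConfig(volunteer_sensitivity=1.2).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(volunteer_overrides={"CAPA:flower": (0.8, 0.95)})
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_plots_gb: 3\nbogus_knob: 1\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            SimulationConfig.from_yaml(p)

    def test_missing_profile_entry_raises(self):
        prof = ErrorProfile({("LUAR", "flower"): (0.9, 0.9)})
        with pytest.raises(KeyError, match="VASI"):
            prof.get("VASI", "bud")


class TestLoggerSeries:
    def test_range_zero_under_snow_and_amplitude_after(self):
        s = simulate_logger_series(166, 300, 2018, amplitude=6.0, noise_sd=0.0)
        ts = pd.to_datetime(s["timestamp"])
        daily = s.groupby(ts.dt.date.values)["temp_c"].agg(["min", "max"])
        rng_by_day = daily["max"] - daily["min"]
        for day, r in rng_by_day.items():
            doy = day.timetuple().tm_yday
            if day.year == 2018 and doy <= 166:
                assert r == pytest.approx(0.0, abs=1e-12)
            elif day.year == 2018 and doy > 166:
                assert r == pytest.approx(6.0, abs=1e-9)

    def test_three_hour_cadence_sample_count(self):
        start, end = dt.date(2017, 9, 1), dt.date(2018, 8, 1)
        s = simulate_logger_series(166, 300, 2018, start=start, end=end)
        n_days = (end - start).days + 1
        assert len(s) == 8 * n_days

    def test_snow_day_ranges_stay_below_threshold_under_noise(self):
        """0.2 degC sensor noise keeps nearly all snow-day diurnal ranges
        under the 1 degC detection threshold (checked over ~1000 days)."""
        rng = np.random.default_rng(0)
        ranges = []
        for k in range(5):
            s = simulate_logger_series(170, 290, 2018, amplitude=5.0,
                                       noise_sd=0.2, rng=rng)
            ts = pd.to_datetime(s["timestamp"])
            daily = s.groupby(ts.dt.date.values)["temp_c"].agg(["min", "max"])
            for day, row in daily.iterrows():
                doy = day.timetuple().tm_yday
                snow = (day.year == 2017 and doy >= 290) or (day.year == 2018 and doy <= 170)
                if snow:
                    ranges.append(row["max"] - row["min"])
        ranges = np.asarray(ranges)
        assert len(ranges) >= 1000
        assert (ranges < 1.0).mean() >= 0.99

    def test_snow_season_must_fit_logger_window(self):
        with pytest.raises(ValueError, match="logger window"):
            simulate_logger_series(400, 300, 2018)

    def test_amplitude_validation(self):
        with pytest.raises(ValueError, match="amplitude"):
            simulate_logger_series(166, 300, 2018, amplitude=0.8)


def _plot_years(entries):
    return pd.DataFrame(
        [{"Site_Code": s, "Transect": "Glacier Basin", "Year": y,
          "Elevation": 1600.0, "true_sdd": sdd, "snow_appearance_doy": 300,
          "logger_available": True} for s, y, sdd in entries]
    )


class TestPhenologySchedules:
    def test_flower_peak_offset_from_snowmelt(self):
        curves = default_species_curves()
        py = _plot_years([("GB01", 2018, 150)])
        truth = simulate_phenology(py, {"GB01": ["LUAR"]}, curves, jitter_sd=0.0)
        row = truth.iloc[0]
        assert row["rho"] == pytest.approx(150 + curves["LUAR"].rho_offset)
        assert row["flower_on"] == pytest.approx(row["rho"] - 2 * row["delta"])

    def test_windows_translate_with_sdd(self):
        curves = default_species_curves()
        t1 = simulate_phenology(_plot_years([("GB01", 2018, 150)]),
                                {"GB01": ["LUAR"]}, curves, jitter_sd=0.0)
        t2 = simulate_phenology(_plot_years([("GB01", 2018, 160)]),
                                {"GB01": ["LUAR"]}, curves, jitter_sd=0.0)
        for col in ("rho", "bud_on", "flower_on", "fruit_on", "seed_on", "seed_off"):
            assert t2.iloc[0][col] - t1.iloc[0][col] == pytest.approx(10.0)

    def test_zero_jitter_is_deterministic(self):
        curves = default_species_curves()
        py = _plot_years([("GB01", 2018, 150), ("GB02", 2018, 162)])
        frames = [
            simulate_phenology(py, {"GB01": ["LUAR"], "GB02": ["LUAR"]}, curves,
                               jitter_sd=0.0, rng=np.random.default_rng(k))
            for k in range(5)
        ]
        for f in frames[1:]:
            pd.testing.assert_frame_equal(f, frames[0])

    def test_onsets_ordered_and_after_snowmelt(self, study):
        t = study.truth.species_truth
        assert (t["bud_on"] <= t["flower_on"]).all()
        assert (t["flower_on"] <= t["fruit_on"]).all()
        assert (t["fruit_on"] <= t["seed_on"]).all()
        sdd = study.truth.plot_years.set_index(["Site_Code", "Year"])["true_sdd"]
        keys = list(zip(t["Site_Code"], t["Year"]))
        assert (t["bud_on"].to_numpy() >= sdd.loc[keys].to_numpy()).all()
        # the peak sits inside the flowering window
        assert ((t["flower_on"] <= t["rho"]) & (t["rho"] <= t["flower_off"])).all()


class TestReports:
    def _setup(self, n_sites=1, sens=1.0, spec=1.0, dates=(dt.date(2018, 7, 10),)):
        curves = default_species_curves()
        sites = [f"GB{i:02d}" for i in range(1, n_sites + 1)]
        py = _plot_years([(s, 2018, 150) for s in sites])
        assignment = {s: ["LUAR"] for s in sites}
        truth = simulate_phenology(py, assignment, curves, jitter_sd=0.0)
        gt = GroundTruth(py, truth)
        subs = []
        for d in dates:
            subs.append(Submission(d, "Glacier Basin", "Scientist", ("S1",)))
            subs.append(Submission(d, "Glacier Basin", "Volunteer", ("V1",)))
        profile = ErrorProfile.uniform(sens, spec)
        perfect = ErrorProfile.uniform(1.0, 1.0)
        return gt, assignment, subs, profile, perfect

    def test_error_free_volunteers_match_scientists(self):
        gt, assignment, subs, _, perfect = self._setup(
            n_sites=3, dates=[dt.date(2018, 6, 20) + dt.timedelta(days=7 * i)
                              for i in range(6)]
        )
        pheno, _ = simulate_reports(
            gt, assignment, subs, perfect, perfect, (120, 280), 7.0, 0.0,
            np.random.default_rng(0),
        )
        phases = ["Bud", "Flower", "Fruit", "Disperse"]
        for key, g in pheno.groupby(["Date", "Site_Code"]):
            sci = g[g["Scientist_or_volunteer"] == "Scientist"][phases].reset_index(drop=True)
            vol = g[g["Scientist_or_volunteer"] == "Volunteer"][phases].reset_index(drop=True)
            pd.testing.assert_frame_equal(sci, vol)

    def test_false_positive_rate_matches_specificity(self):
        """Latent absence + specificity 0.9: recorded presences ~ Binomial(n, 0.1)."""
        dates = [dt.date(2018, 5, 1)]  # DOY 121, long before any phenophase
        gt, assignment, subs, profile, perfect = self._setup(
            n_sites=40, sens=1.0, spec=0.9, dates=dates
        )
        subs = [s for s in subs if s.role == "Volunteer"]
        reps = []
        for k in range(250):
            pheno, _ = simulate_reports(
                gt, assignment, subs, profile, perfect, (120, 280), 7.0, 0.0,
                np.random.default_rng(k),
            )
            reps.append(pheno[["Bud", "Flower", "Fruit", "Disperse"]].to_numpy())
        draws = np.concatenate(reps).ravel()
        n = draws.size
        assert n == 250 * 40 * 4
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(draws.mean() - 0.10) <= 3 * se

    def test_out_of_season_submission_excluded_and_logged(self):
        gt, assignment, subs, _, perfect = self._setup(dates=[dt.date(2018, 3, 1)])
        pheno, stats = simulate_reports(
            gt, assignment, subs, perfect, perfect, (120, 280), 7.0, 0.0,
            np.random.default_rng(0),
        )
        assert len(pheno) == 0
        assert stats["excluded_out_of_season"] == len(subs)

    def test_snow_code_tracks_melt_date(self):
        days = [dt.date(2018, 5, 20), dt.date(2018, 5, 28), dt.date(2018, 6, 10)]
        # DOYs 140, 148, 161 against SDD=150, partial window 7
        gt, assignment, subs, _, perfect = self._setup(dates=days)
        pheno, _ = simulate_reports(
            gt, assignment, subs, perfect, perfect, (120, 280), 7.0, 0.0,
            np.random.default_rng(0),
        )
        codes = pheno.groupby("Date")["Snow"].first()
        assert codes[days[0]] == 1.0  # before the partial window
        assert codes[days[1]] == 0.5  # within 7 days of melt-out
        assert codes[days[2]] == 0.0  # after melt

    def test_empirical_flowering_frequency_matches_curve(self):
        """Across many replicate plots with identical truth, the fraction of
        error-free reports recording flowering at DOY t converges on
        mu* exp(-(t-rho*)^2 / (2 delta*^2)) - the generator and the fitted
        model share one curve definition."""
        curves = default_species_curves()
        c = curves["LUAR"]
        for offset in (0.0, c.delta, 2.5 * c.delta):
            t_doy = 150 + c.rho_offset + offset
            date = dt.date(2018, 1, 1) + dt.timedelta(days=int(round(t_doy)) - 1)
            gt, assignment, subs, _, perfect = self._setup(n_sites=60, dates=[date])
            subs = [s for s in subs if s.role == "Scientist"]
            draws = []
            for k in range(40):
                pheno, _ = simulate_reports(
                    gt, assignment, subs, perfect, perfect, (120, 280), 7.0, 0.0,
                    np.random.default_rng(300 + k),
                )
                draws.append(pheno["Flower"].to_numpy())
            draws = np.concatenate(draws)
            doy = date.timetuple().tm_yday
            expected = float(flowering_probability(doy, c.delta, c.mu, 150 + c.rho_offset))
            se = np.sqrt(max(expected * (1 - expected), 1e-6) / draws.size)
            assert abs(draws.mean() - expected) <= max(3 * se, 0.01), offset


class TestFullStudy:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config(n_plots_gb=2, n_plots_rl=2, years_gb=(2018, 2018),
                           years_rl=(2018, 2018), season=(150, 200))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_study(cfg, seed=5).write(d1)
        generate_study(cfg, seed=5).write(d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_different_seeds_differ(self, tmp_path):
        cfg = small_config(n_plots_gb=2, n_plots_rl=2, years_gb=(2018, 2018),
                           years_rl=(2018, 2018), season=(150, 200))
        a = generate_study(cfg, seed=1).tables["pheno"]
        b = generate_study(cfg, seed=2).tables["pheno"]
        assert not a.equals(b)

    def test_default_design_has_two_transects_28_plots(self):
        study = generate_study(seed=0)
        sites = study.tables["site"]
        assert len(sites) == 28
        assert set(sites["Transect"]) == {"Glacier Basin", "Reflection Lakes"}

    def test_missing_sdd_fraction_respected(self, study):
        py = study.truth.plot_years
        expected = round(0.20 * len(py))
        assert (~py["logger_available"]).sum() == expected
        assert study.tables["sdd"]["SDD"].isna().sum() == expected

    def test_loggers_withheld_for_missing_plot_years(self, study):
        py = study.truth.plot_years
        have = set(study.loggers)
        for r in py.itertuples(index=False):
            assert ((r.Site_Code, int(r.Year)) in have) == bool(r.logger_available)

    def test_ranks_only_populated_2013_to_2015(self):
        cfg = small_config(years_rl=(2014, 2016), years_gb=(2015, 2016))
        study = generate_study(cfg, seed=3)
        pheno = study.tables["pheno"]
        years = pd.to_datetime(pheno["Date"].astype("object")).dt.year
        early = pheno[years <= 2015]
        late = pheno[years > 2015]
        assert late["Flower_rank"].isna().all()
        flowering_early = early[early["Flower"] == 1]
        assert flowering_early["Flower_rank"].notna().all()
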