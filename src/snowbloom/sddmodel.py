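"""Imputation of missing snow-disappearance dates.

Logger loss (sensor failure, removal by visitors) leaves roughly a fifth of
plot-years without a measured snow-disappearance date (SDD). Missing values
are filled with predictions from an additive fixed-effects linear model

    SDD(site, year) = intercept + site_effect + year_effect  (+ calibration)

fitted by least squares to the observed plot-years under sum-to-zero
constraints on both effect sets. The model is deliberately additive (no
site x year interaction): with one observation per plot-year an interaction
would be saturated and could never predict an unobserved cell. Year enters
as a categorical code, not a linear trend.

``calibration`` is an optional additive adjustment (days), default 0,
mirroring the per-row calibration column of the snow-season table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


class DesignError(ValueError):
    """The site/year design cannot support an additive fit."""


def _connected_components(pairs: list[tuple[str, str]]) -> int:
    """Number of connected components of the bipartite site-year graph."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(x) for x in parent})


class SnowDisappearanceModel:
    """Additive site + year model of snow-disappearance day of year.

    Parameters
    ----------
    data : DataFrame holding one row per plot-year with columns for the
        site code, the year, and the (possibly missing) measured SDD.
        Rows with missing SDD are kept aside for imputation; the fit uses
        the observed rows only.
    site_col, year_col, sdd_col : column names (defaults match the
        snow-season table schema).
    """

    def __init__(self, data: pd.DataFrame, site_col: str = "Site_Code",
                 year_col: str = "Year", sdd_col: str = "SDD"):
        self.data = data
        self.site_col, self.year_col, self.sdd_col = site_col, year_col, sdd_col
        d = pd.DataFrame(
            {
                "site": data[site_col].astype(str),
                "year": data[year_col].astype(int).astype(str),
                "sdd": pd.to_numeric(data[sdd_col].astype("object"), errors="coerce"),
            }
        )
        self._all = d
        self._obs = d.dropna(subset=["sdd"]).reset_index(drop=True)
        self._validate_design()

    def _validate_design(self) -> None:
        obs, full = self._obs, self._all
        if len(obs) == 0:
            raise DesignError("no observed SDD values: nothing to fit")
        if obs["site"].nunique() < 2 or obs["year"].nunique() < 2:
            raise DesignError(
                "need at least 2 sites and 2 years with observed SDD "
                f"(got {obs['site'].nunique()} site(s), {obs['year'].nunique()} year(s))"
            )
        for level in sorted(set(full["site"]) - set(obs["site"])):
            raise DesignError(f"site {level!r} has no observed SDD; cannot estimate its effect")
        for level in sorted(set(full["year"]) - set(obs["year"])):
            raise DesignError(f"year {level} has no observed SDD; cannot estimate its effect")
        pairs = [("s:" + s, "y:" + y) for s, y in zip(obs["site"], obs["year"])]
        if _connected_components(pairs) > 1:
            raise DesignError("site-year design is disconnected; effects are not identifiable")

    def fit(self, calibration: float = 0.0) -> "SnowDisappearanceResults":
        """Least-squares fit under sum-to-zero constraints on both effect sets."""
        obs = self._obs
        ols = smf.ols("sdd ~ C(site, Sum) + C(year, Sum)", data=obs).fit()
        n_params = 1 + (obs["site"].nunique() - 1) + (obs["year"].nunique() - 1)
        if np.linalg.matrix_rank(ols.model.exog) < n_params:
            raise DesignError("rank-deficient design matrix")

        site_levels = sorted(obs["site"].unique())
        year_levels = sorted(obs["year"].unique())
        site_eff = self._sum_effects(ols.params, "site", site_levels)
        year_eff = self._sum_effects(ols.params, "year", year_levels)
        resid_sd = float(np.sqrt(ols.scale)) if ols.df_resid > 0 else 0.0
        return SnowDisappearanceResults(
            model=self,
            intercept=float(ols.params["Intercept"]),
            site_effects=site_eff,
            year_effects=year_eff,
            calibration=float(calibration),
            nobs=int(ols.nobs),
            resid_sd=resid_sd,
            llf=float(ols.llf),
        )

    @staticmethod
    def _sum_effects(params: pd.Series, name: str, levels: list[str]) -> pd.Series:
        vals = {}
        for lv in levels[:-1]:
            vals[lv] = float(params[f"C({name}, Sum)[S.{lv}]"])
        vals[levels[-1]] = -sum(vals.values())
        return pd.Series(vals, name=f"{name}_effect")


@dataclass
class SnowDisappearanceResults:
    """Fitted additive SDD model: intercept, effect estimates, diagnostics."""

    model: SnowDisappearanceModel
    intercept: float
    site_effects: pd.Series
    year_effects: pd.Series
    calibration: float
    nobs: int
    resid_sd: float
    llf: float

    def predict(self, site, year) -> float:
        """predSDD = intercept + site effect + year effect + calibration.

        Raises ``KeyError`` for a site or year absent from the training data:
        the model never extrapolates to unknown plots or years.
        """
        site, year = str(site), str(int(year))
        if site not in self.site_effects.index:
            raise KeyError(f"site {site!r} was not in the training data")
        if year not in self.year_effects.index:
            raise KeyError(f"year {year} was not in the training data")
        return (
            self.intercept
            + float(self.site_effects[site])
            + float(self.year_effects[year])
            + self.calibration
        )

    def impute(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        """Attach predictions and fill missing SDD values.

        Every row gets ``predSDD``; rows whose measured SDD is missing get
        ``predicted=True``. Observed SDD values are never overwritten.
        """
        m = self.model
        out = (table if table is not None else m.data).copy()
        pred = [
            self.predict(s, y)
            for s, y in zip(out[m.site_col].astype(str), out[m.year_col].astype(int))
        ]
        out["predSDD"] = pd.array(pred, dtype="Float64")
        out["predicted"] = out[m.sdd_col].isna()
        return out

    def summary(self) -> str:
        lines = [
            "Snow-disappearance model (additive site + year, sum-to-zero)",
            "-" * 60,
            f"n observed plot-years   {self.nobs}",
            f"intercept (grand mean)  {self.intercept:8.2f}  DOY",
            f"residual sd             {self.resid_sd:8.2f}  days",
            f"calibration             {self.calibration:8.2f}  days",
            "",
            "site effects (days):",
        ]
        lines += [f"  {s:10s} {v:+7.2f}" for s, v in self.site_effects.items()]
        lines.append("year effects (days):")
        lines += [f"  {y:10s} {v:+7.2f}" for y, v in self.year_effects.items()]
        return "\n".join(lines)


def fit_sdd_model(table: pd.DataFrame, calibration: float = 0.0,
                  **cols) -> SnowDisappearanceResults:
    """Convenience wrapper: build and fit in one call."""
    return SnowDisappearanceModel(table, **cols).fit(calibration=calibration)


def impute_table(table: pd.DataFrame, results: SnowDisappearanceResults | None = None,
                 calibration: float = 0.0, **cols) -> pd.DataFrame:
    """Fill missing SDD values in a snow-season table.

    Fits the additive model on the observed rows of *table* (unless a fitted
    ``results`` is supplied) and returns the completed table with ``predSDD``
    and a ``predicted`` flag column.
    """
    if results is None:
        results = fit_sdd_model(table, calibration=calibration, **cols)
    return results.impute(table)
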