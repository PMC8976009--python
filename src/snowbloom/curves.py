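"""Maximum-likelihood unimodal flowering curves.

For one species x plot x year cell, the probability that a report on
day-of-year *t* records the species in flower is modelled as a Gaussian bump

    p(t) = mu * exp(-(t - rho)^2 / (2 * delta^2))

with three parameters: ``mu`` the maximum flowering probability (0 < mu <= 1),
``rho`` the peak flowering day (DOY), and ``delta`` the duration (width)
parameter in days. Binary flowering observations y_t in {0, 1} are treated
as independent Bernoulli draws and the parameters are estimated by bounded
multi-start maximum likelihood.

`FloweringCurveModel` / `FloweringCurveResults` follow the familiar
model-object idiom: build the model from data, call :meth:`fit`, read
estimates and diagnostics off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

PROB_EPS = 1e-10

DEFAULT_BOUNDS = {
    "delta": (1.0, 60.0),
    "mu": (0.01, 1.0),
    "rho_margin": 15.0,  # rho may sit this many days outside the observed season
}


class UnfittableDataError(ValueError):
    """Raised when a cell has too little data to support a curve fit."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def flowering_probability(doy, delta: float, mu: float, rho: float):
    """Gaussian-bump flowering probability p(t) = mu * exp(-(t-rho)^2 / (2 delta^2))."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if not 0 < mu <= 1:
        raise ValueError(f"mu must be in (0, 1], got {mu}")
    doy = np.asarray(doy, dtype=float)
    return mu * np.exp(-((doy - rho) ** 2) / (2.0 * delta**2))


def bernoulli_nll(params, doy, y) -> float:
    """Negative Bernoulli log-likelihood of (delta, mu, rho) given binary data.

    Probabilities are clipped to [eps, 1-eps] (eps = 1e-10) so the value is
    always finite.
    """
    delta, mu, rho = params
    p = np.clip(flowering_probability(doy, delta, mu, rho), PROB_EPS, 1.0 - PROB_EPS)
    y = np.asarray(y, dtype=float)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


class FloweringCurveModel:
    """Bernoulli MLE of a Gaussian-bump flowering curve for one cell.

    Parameters
    ----------
    doy : array-like of int
        Day of year of each report (1..366).
    flowering : array-like of {0, 1}
        Whether the species was recorded in flower.
    season : (float, float), optional
        Season bounds for the peak parameter; defaults to the observed
        DOY range. The peak may wander ``rho_margin`` days beyond them.
    min_obs : int
        Minimum number of reports required to attempt a fit.
    """

    def __init__(self, doy, flowering, season=None, min_obs: int = 5):
        doy = np.asarray(doy, dtype=float)
        y = np.asarray(flowering, dtype=float)
        if doy.shape != y.shape or doy.ndim != 1:
            raise ValueError("doy and flowering must be 1-d arrays of equal length")
        if len(doy) and (doy.min() < 1 or doy.max() > 366):
            raise ValueError("doy values must lie in [1, 366]")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("flowering values must be 0 or 1")
        self.doy = doy
        self.y = y
        self.min_obs = int(min_obs)
        if season is None:
            season = (doy.min(), doy.max()) if len(doy) else (1.0, 366.0)
        self.season = (float(season[0]), float(season[1]))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, doy_col: str = "DOY",
                       flower_col: str = "Flower", **kwargs) -> "FloweringCurveModel":
        return cls(df[doy_col].to_numpy(), df[flower_col].to_numpy(), **kwargs)

    # -- likelihood ---------------------------------------------------------

    def nll(self, params) -> float:
        return bernoulli_nll(params, self.doy, self.y)

    def _bounds(self):
        lo, hi = self.season
        m = DEFAULT_BOUNDS["rho_margin"]
        return [DEFAULT_BOUNDS["delta"], DEFAULT_BOUNDS["mu"], (lo - m, hi + m)]

    def _initial_guess(self):
        pos = self.doy[self.y == 1]
        rho0 = float(np.median(pos))
        mu0 = float(np.clip(self.y.mean(), 0.05, 0.95))
        delta0 = float(max((pos.max() - pos.min()) / 2.0, 5.0))
        return np.array([delta0, mu0, rho0])

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 10, seed: int = 0) -> "FloweringCurveResults":
        """Fit by bounded multi-start L-BFGS-B; deterministic given *seed*.

        Raises
        ------
        UnfittableDataError
            Fewer than ``min_obs`` reports, or no positive observation.
        """
        n = len(self.doy)
        if n < self.min_obs:
            raise UnfittableDataError(f"only {n} observations (minimum {self.min_obs})")
        n_pos = int(self.y.sum())
        if n_pos == 0:
            raise UnfittableDataError("no positive observations")

        rng = np.random.default_rng(seed)
        bounds = self._bounds()
        x0 = self._initial_guess()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        x0 = np.clip(x0, lo, hi)

        best = None
        converged = False
        for k in range(n_starts):
            if k == 0:
                start = x0
            else:
                jitter = rng.normal(0.0, [5.0, 0.15, 10.0])
                start = np.clip(x0 + jitter, lo, hi)
            res = minimize(self.nll, start, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        delta, mu, rho = best.x
        return FloweringCurveResults(
            model=self,
            delta=float(delta),
            mu=float(mu),
            rho=float(rho),
            llf=-float(best.fun),
            n_obs=n,
            n_positive=n_pos,
            converged=converged,
        )


@dataclass
class FloweringCurveResults:
    """Fitted flowering curve: estimates, likelihood, and diagnostics."""

    model: FloweringCurveModel
    delta: float
    mu: float
    rho: float
    llf: float  # log-likelihood at the optimum (<= 0)
    n_obs: int
    n_positive: int
    converged: bool

    @property
    def params(self) -> dict[str, float]:
        return {"delta": self.delta, "mu": self.mu, "rho": self.rho}

    def predict(self, doy):
        """Flowering probability at the given day(s) of year."""
        return flowering_probability(doy, self.delta, self.mu, self.rho)

    def at_bound(self) -> dict[str, bool]:
        """Which parameters sit on a box bound (e.g. mu pinned at 1 for
        degenerate all-positive data)."""
        b = self.model._bounds()
        vals = (self.delta, self.mu, self.rho)
        names = ("delta", "mu", "rho")
        return {
            n: bool(np.isclose(v, lo) or np.isclose(v, hi))
            for n, v, (lo, hi) in zip(names, vals, b)
        }

    def summary(self) -> str:
        lines = [
            "Flowering curve fit (Bernoulli MLE, Gaussian bump)",
            "-" * 50,
            f"n_obs        {self.n_obs:>10d}",
            f"n_positive   {self.n_positive:>10d}",
            f"peak rho     {self.rho:>10.2f}  DOY",
            f"duration d   {self.delta:>10.2f}  days",
            f"maximum mu   {self.mu:>10.3f}",
            f"log-lik      {self.llf:>10.3f}",
            f"converged    {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# table-level driver and derived products

def fit_phenocurves(
    pheno: pd.DataFrame,
    sdd: pd.DataFrame | None = None,
    seed: int = 0,
    min_obs: int = 5,
    n_starts: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit a flowering curve per species x plot x year from a report table.

    Parameters
    ----------
    pheno : phenology-report table (schemas_io layout).
    sdd : optional snow-season table; when given, the measured-or-imputed
        SDD is attached to each fitted row (predSDD fills missing SDD).
    seed : base seed; each cell gets a deterministic sub-seed.

    Returns
    -------
    curves : DataFrame in the MW_Phenocurves layout.
    skipped : DataFrame of unfittable cells and the reason each was skipped.
    """
    from snowbloom.schemas import SITE_CODE_RE, _coerce_dtypes

    df = pheno.copy()
    dates = pd.to_datetime(df["Date"].astype("object"))
    df["_doy"] = dates.dt.dayofyear
    df["_year"] = dates.dt.year

    sdd_lookup: dict[tuple[str, int], float] = {}
    if sdd is not None:
        for r in sdd.itertuples(index=False):
            val = r.SDD if not pd.isna(r.SDD) else r.predSDD
            if not pd.isna(val):
                sdd_lookup[(r.Site_Code, int(r.Year))] = float(val)

    rows, skipped = [], []
    groups = df.groupby(["_year", "Transect", "Site_Code", "Species"], sort=True)
    for i, ((year, transect, site_code, species), g) in enumerate(groups):
        model = FloweringCurveModel(
            g["_doy"].to_numpy(), g["Flower"].to_numpy(dtype=float), min_obs=min_obs
        )
        try:
            res = model.fit(n_starts=n_starts, seed=seed + i)
        except UnfittableDataError as exc:
            skipped.append(
                {"Year": year, "Site_Code": site_code, "Species": species,
                 "reason": exc.reason}
            )
            continue
        m = SITE_CODE_RE.match(site_code)
        rows.append(
            {
                "Year": int(year),
                "transect": transect,
                "site_code": site_code,
                "plot": int(m.group(2)) if m else pd.NA,
                "SDD": sdd_lookup.get((site_code, int(year)), pd.NA),
                "species": species,
                "Peak": res.rho,
                "Duration": res.delta,
                "Maximum": res.mu,
            }
        )
    cols = ["Year", "transect", "site_code", "plot", "SDD", "species",
            "Peak", "Duration", "Maximum"]
    curves = _coerce_dtypes(pd.DataFrame(rows, columns=cols), "curves")
    skipped_df = pd.DataFrame(skipped, columns=["Year", "Site_Code", "Species", "reason"])
    return curves, skipped_df


def flowering_richness(
    curves: pd.DataFrame,
    doy,
    threshold: float | None = None,
) -> pd.Series | int:
    """Number of species predicted in flower on day(s) *doy*.

    A species counts as flowering when its maximum-over-plots predicted
    probability reaches the threshold: by default half that species' fitted
    maximum (0.5 * mu), or an absolute probability if *threshold* is given.
    """
    if len(curves) == 0:
        raise ValueError("no fitted curves supplied")
    doy_arr = np.atleast_1d(np.asarray(doy, dtype=float))
    counts = np.zeros(len(doy_arr), dtype=int)
    for species, g in curves.groupby("species"):
        p = np.zeros(len(doy_arr))
        mu_max = 0.0
        for r in g.itertuples(index=False):
            p = np.maximum(
                p, flowering_probability(doy_arr, float(r.Duration), float(r.Maximum), float(r.Peak))
            )
            mu_max = max(mu_max, float(r.Maximum))
        thr = 0.5 * mu_max if threshold is None else threshold
        counts += (p >= thr).astype(int)
    if np.isscalar(doy) or np.asarray(doy).ndim == 0:
        return int(counts[0])
    return pd.Series(counts, index=doy_arr, name="flowering_richness")
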