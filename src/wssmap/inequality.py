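"""Geographical inequality: Lorenz curves, GINI coefficients, RGI scores.

For each country, administrative areas are ranked by per-capita coverage
and the cumulative share of national "use" (population × coverage) is
plotted against the cumulative population share — the Lorenz curve. The
geographical GINI coefficient is twice the area between the curve and the
diagonal of equality (0 = perfect equality, 1 = total inequality).

Coverage is bounded in [0, 1], so GINI falls mechanically as national
coverage rises. The relative geographic inequality (RGI) score corrects for
this: a linear regression of GINI on national coverage across countries
gives the inequality *expected* at a given coverage level, and
RGI = observed GINI − expected GINI. Positive RGI means more sub-national
inequality than expected at that coverage; significance is judged by the
95% credible interval of the per-draw RGI excluding zero.

For open defecation, GINI/RGI are computed on its complement (households
with access to any type of sanitation) so the indicator points the same
way as the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LorenzCurve",
    "GiniRegression",
    "GiniRgiResult",
    "lorenz_curve",
    "gini",
    "gini_from_values",
    "fit_gini_coverage_regression",
    "rgi_scores",
    "od_to_any_sanitation",
]


@dataclass
class LorenzCurve:
    """Cumulative population share q vs cumulative use share L, both
    starting at (0, 0) and ending at (1, 1)."""

    q: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.q[0] != 0 or self.L[0] != 0:
            raise ValueError("Lorenz curve must start at (0, 0)")
        if abs(self.q[-1] - 1) > 1e-9 or abs(self.L[-1] - 1) > 1e-9:
            raise ValueError("Lorenz curve must end at (1, 1)")
        if np.any(np.diff(self.q) < -1e-12) or np.any(np.diff(self.L) < -1e-12):
            raise ValueError("Lorenz curve must be non-decreasing")

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.q, self.L, **kwargs)
        ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
        ax.set_xlabel("cumulative population share")
        ax.set_ylabel("cumulative share of use")
        return ax


def lorenz_curve(
    coverage: np.ndarray,
    population: np.ndarray,
    area_ids=None,
    rank_by: str = "per_capita",
) -> LorenzCurve:
    """Population-weighted Lorenz curve of coverage across areas.

    Areas are ranked ascending by per-capita coverage (ties broken by area
    id for determinism); ``rank_by='use_share'`` ranks by raw share of
    national use instead (sensitivity option). Raises on zero national use.
    """
    coverage = np.asarray(coverage, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("populations must be positive")
    if np.any((coverage < 0) | (coverage > 1)):
        raise ValueError("coverage must lie in [0, 1]")
    use = population * coverage
    if use.sum() <= 0:
        raise ValueError("zero national use: Lorenz curve undefined")
    if area_ids is None:
        area_ids = np.arange(len(coverage))
    if rank_by == "per_capita":
        key = coverage
    elif rank_by == "use_share":
        key = use / use.sum()
    else:
        raise ValueError("rank_by must be 'per_capita' or 'use_share'")
    order = np.lexsort((np.asarray(area_ids), key))
    q = np.concatenate([[0.0], np.cumsum(population[order]) / population.sum()])
    L = np.concatenate([[0.0], np.cumsum(use[order]) / use.sum()])
    q[-1] = 1.0
    L[-1] = 1.0
    return LorenzCurve(q=q, L=L)


def gini(curve: LorenzCurve) -> float:
    """Twice the area between the diagonal and the Lorenz curve.

    Trapezoid rule: G = 1 − Σ (q_i − q_{i−1})(L_i + L_{i−1}).
    """
    dq = np.diff(curve.q)
    return float(1.0 - np.sum(dq * (curve.L[1:] + curve.L[:-1])))


def gini_from_values(coverage, population, **kwargs) -> float:
    """Convenience: Lorenz + GINI in one call."""
    return gini(lorenz_curve(coverage, population, **kwargs))


def od_to_any_sanitation(p_open_defecation):
    """Complement an open-defecation proportion into 'any sanitation'."""
    p = np.asarray(p_open_defecation, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = 1.0 - p
    return float(out) if np.isscalar(p_open_defecation) else out


@dataclass
class GiniRegression:
    """OLS fit of GINI on national coverage across countries."""

    slope: float
    intercept: float
    residual_se: float
    countries: list[str]
    expected: dict[str, float]    # fitted values, unclipped
    observed: dict[str, float]

    def predict(self, coverage: float, clip: bool = False) -> float:
        val = self.intercept + self.slope * coverage
        return float(np.clip(val, 0.0, 1.0)) if clip else float(val)


def fit_gini_coverage_regression(
    gini_by_country: dict[str, float],
    coverage_by_country: dict[str, float],
) -> GiniRegression:
    """Ordinary least squares of GINI against national coverage.

    Needs at least three countries and non-degenerate coverage spread.
    Fitted values are reported unclipped (clipping to [0, 1] is available
    for display via :meth:`GiniRegression.predict`); residuals are always
    computed on the unclipped line.
    """
    countries = sorted(gini_by_country)
    if sorted(coverage_by_country) != countries:
        raise ValueError("gini and coverage tables cover different countries")
    if len(countries) < 3:
        raise ValueError("need at least 3 countries for the regression")
    x = np.array([coverage_by_country[c] for c in countries], dtype=float)
    y = np.array([gini_by_country[c] for c in countries], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in national coverage")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = max(len(countries) - 2, 1)
    residual_se = float(np.sqrt(np.sum(resid ** 2) / dof))
    fitted = intercept + slope * x
    return GiniRegression(
        slope=slope, intercept=intercept, residual_se=residual_se,
        countries=countries,
        expected=dict(zip(countries, fitted.astype(float))),
        observed=dict(zip(countries, y.astype(float))),
    )


@dataclass
class GiniRgiResult:
    country: str
    indicator: str
    gini_median: float
    gini_lower: float
    gini_upper: float
    expected_gini: float
    rgi: float
    rgi_lower: float
    rgi_upper: float
    significant: str      # lower | higher | none

    def arrow(self) -> int:
        return {"lower": -1, "none": 0, "higher": +1}[self.significant]


def rgi_scores(
    gini_draws_by_country: dict[str, np.ndarray],
    regression: GiniRegression,
    indicator: str = "",
) -> list[GiniRgiResult]:
    """Relative geographic inequality per country.

    Per draw, RGI = GINI(draw) − expected GINI at the country's (point
    estimate) national coverage; significance is read off the central 95%
    interval of the RGI draws ('higher' = significantly above 0, i.e.
    greater than expected inequality). Point-mass draws (an array of one
    value, or a scalar) give the point-estimate mode.
    """
    results = []
    for country in sorted(gini_draws_by_country):
        if country not in regression.expected:
            raise ValueError(f"country {country!r} absent from the regression")
        g = np.atleast_1d(np.asarray(gini_draws_by_country[country], dtype=float))
        expected = regression.expected[country]
        rgi_draws = g - expected
        med_g, lo_g, hi_g = np.quantile(g, (0.5, 0.025, 0.975))
        rgi_med, lo, hi = np.quantile(rgi_draws, (0.5, 0.025, 0.975))
        # epsilon guards the degenerate point-mass case against round-off
        if hi < -1e-9:
            sig = "lower"
        elif lo > 1e-9:
            sig = "higher"
        else:
            sig = "none"
        results.append(GiniRgiResult(
            country=country, indicator=indicator,
            gini_median=float(med_g), gini_lower=float(lo_g),
            gini_upper=float(hi_g), expected_gini=float(expected),
            rgi=float(rgi_med), rgi_lower=float(lo), rgi_upper=float(hi),
            significant=sig,
        ))
    return results


def rgi_table(results: list[GiniRgiResult]) -> pd.DataFrame:
    rows = [{
        "country": r.country, "indicator": r.indicator,
        "gini": r.gini_median, "gini_lower": r.gini_lower,
        "gini_upper": r.gini_upper, "expected_gini": r.expected_gini,
        "rgi": r.rgi, "rgi_lower": r.rgi_lower, "rgi_upper": r.rgi_upper,
        "significant": r.arrow(),
    } for r in results]
    return pd.DataFrame(rows)
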