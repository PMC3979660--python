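"""Posterior prediction of coverage and significance flagging.

Turns posterior draws into per-admin2 × stratum coverage for a target year
(default 2012), completing the spatial field for admin2 without data by
sampling the ICAR conditional given the observed effects, aggregating with
urban/rural population weights to overall and national coverage per draw,
and flagging areas whose coverage differs significantly from the national
mean (95% credible interval of the per-draw difference excluding zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .hierarchy import AdminHierarchy, PopulationTable, laplacian
from .model import PosteriorDraws
from .synthetic import STRATA

logger = logging.getLogger(__name__)

__all__ = [
    "icar_conditional",
    "impute_unsampled_effects",
    "predict_coverage",
    "aggregate_population",
    "flag_significant_areas",
    "coverage_table",
    "ImputedSpatialEffects",
    "PredictedCoverage",
]


def icar_conditional(
    lap: np.ndarray,
    obs_idx: np.ndarray,
    miss_idx: np.ndarray,
    u_obs: np.ndarray,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditional of missing ICAR effects given observed ones.

    With ICAR precision ``Q = L / sigma**2`` (graph Laplacian ``L``), the
    missing block given the observed block is
    ``N(-Q_mm^-1 Q_mo u_obs, Q_mm^-1)``; for a single missing node this is
    the familiar full conditional N(mean of neighbours, sigma^2 / m).
    ``Q_mm`` is nonsingular whenever every component containing a missing
    node also contains an observed node.

    Returns ``(mean, cov)`` for the missing nodes in ``miss_idx`` order.
    """
    L_mm = lap[np.ix_(miss_idx, miss_idx)]
    L_mo = lap[np.ix_(miss_idx, obs_idx)]
    mean = -np.linalg.solve(L_mm, L_mo @ u_obs)
    cov = sigma ** 2 * np.linalg.inv(L_mm)
    return mean, cov


@dataclass
class ImputedSpatialEffects:
    """Completed spatial field: per-draw u over every admin2 of the modelled
    countries, with the prediction basis of each area."""

    admin2: list[str]
    u: np.ndarray                 # (n_total_draws, n_admin2)
    basis: dict[str, str]         # admin2 -> sampled | imputed | admin1-level


def impute_unsampled_effects(
    draws: PosteriorDraws,
    hierarchy: AdminHierarchy,
    seed: int = 0,
) -> ImputedSpatialEffects:
    """Complete the spatial field for admin2 without data.

    Per posterior draw, missing effects are sampled jointly from the ICAR
    conditional given the observed effects of their graph component (exact
    block solve, not single-site sweeps). Components containing no observed
    admin2 fall back to u = 0 with basis ``imputed`` and a warning. A
    country with no admin2-located data at all contributes its admin2 with
    basis ``admin1-level`` (spatial effect omitted, i.e. zero).
    """
    rng = np.random.default_rng(seed)
    observed = draws.labels["admin2"]
    obs_pos = {a: i for i, a in enumerate(observed)}
    u_obs_all = draws.stacked("u")                    # (ndraw, n_obs)
    sigma_u_all = draws.stacked("sigma_u")            # (ndraw, C)
    ndraw = u_obs_all.shape[0]
    countries = draws.labels["countries"]

    admin2_out: list[str] = []
    cols: list[np.ndarray] = []
    basis: dict[str, str] = {}

    for ci, country in enumerate(countries):
        members = hierarchy.admin2_in_country(country)
        obs_in_c = [a for a in members if a in obs_pos]
        if not obs_in_c:
            # no admin2-located data: predictions fall back to admin1 level
            for a in members:
                admin2_out.append(a)
                cols.append(np.zeros(ndraw))
                basis[a] = "admin1-level"
            continue
        sigma_c = sigma_u_all[:, ci]
        for comp in hierarchy.components(country):
            comp_nodes = sorted(comp)
            comp_obs = [a for a in comp_nodes if a in obs_pos]
            comp_miss = [a for a in comp_nodes if a not in obs_pos]
            for a in comp_obs:
                admin2_out.append(a)
                cols.append(u_obs_all[:, obs_pos[a]])
                basis[a] = "sampled"
            if not comp_miss:
                continue
            if not comp_obs:
                logger.warning(
                    "component %s of %s has no observed admin2; imputing 0",
                    comp_nodes[:3], country,
                )
                for a in comp_miss:
                    admin2_out.append(a)
                    cols.append(np.zeros(ndraw))
                    basis[a] = "imputed"
                continue
            lap = laplacian(hierarchy.graph(nodes=comp_nodes), comp_nodes)
            pos = {a: i for i, a in enumerate(comp_nodes)}
            oi = np.array([pos[a] for a in comp_obs], dtype=np.intp)
            mi = np.array([pos[a] for a in comp_miss], dtype=np.intp)
            L_mm = lap[np.ix_(mi, mi)]
            L_mo = lap[np.ix_(mi, oi)]
            uo = u_obs_all[:, [obs_pos[a] for a in comp_obs]]  # (ndraw, nobs)
            mean = -np.linalg.solve(L_mm, L_mo @ uo.T)          # (nmiss, ndraw)
            upper = sla.cholesky(L_mm, lower=False)
            z = rng.standard_normal((len(mi), ndraw))
            noise = sla.solve_triangular(upper, z, lower=False)  # cov L_mm^-1
            u_miss = mean + sigma_c[None, :] * noise             # (nmiss, ndraw)
            for row, a in enumerate(comp_miss):
                admin2_out.append(a)
                cols.append(u_miss[row])
                basis[a] = "imputed"

    order = np.argsort(admin2_out)
    admin2_sorted = [admin2_out[i] for i in order]
    u_full = np.column_stack([cols[i] for i in order]) if cols else np.zeros((ndraw, 0))
    return ImputedSpatialEffects(admin2=admin2_sorted, u=u_full, basis=basis)


@dataclass
class PredictedCoverage:
    """Per-draw coverage by admin2 and stratum for one target year."""

    admin2: list[str]
    country_of: list[str]
    p: dict[str, np.ndarray]      # stratum -> (n_draws, n_admin2)
    basis: dict[str, str]
    year: int


def predict_coverage(
    draws: PosteriorDraws,
    hierarchy: AdminHierarchy,
    year: int = 2012,
    seed: int = 0,
    imputed: ImputedSpatialEffects | None = None,
) -> PredictedCoverage:
    """Coverage p = expit(alpha + beta (year - t0) + u + v) per draw.

    Admin1 effects for admin1 that contributed no data are drawn from their
    N(0, sigma_v^2) prior per draw (posterior predictive).
    """
    from scipy.special import expit

    if imputed is None:
        imputed = impute_unsampled_effects(draws, hierarchy, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    t0 = draws.meta["t0"]
    alpha = draws.stacked("alpha")      # (ndraw, C, 2)
    beta = draws.stacked("beta")
    v = draws.stacked("v")              # (ndraw, K)
    sigma_v = draws.stacked("sigma_v")  # (ndraw,)
    ndraw = alpha.shape[0]
    c_idx = {c: i for i, c in enumerate(draws.labels["countries"])}
    a1_idx = {a: i for i, a in enumerate(draws.labels["admin1"])}
    u_pos = {a: i for i, a in enumerate(imputed.admin2)}

    admin2 = imputed.admin2
    country_of = [hierarchy.country_of_admin2(a) for a in admin2]
    # predictive draw per unobserved admin1, shared across its admin2
    unobserved_a1 = sorted({hierarchy.admin2_of[a] for a in admin2}
                           - set(a1_idx))
    v_new = {a1: sigma_v * rng.standard_normal(ndraw) for a1 in unobserved_a1}

    p: dict[str, np.ndarray] = {}
    for r, stratum in enumerate(STRATA):
        eta = np.empty((ndraw, len(admin2)))
        for col, a2 in enumerate(admin2):
            c = c_idx[country_of[col]]
            a1 = hierarchy.admin2_of[a2]
            v_col = v[:, a1_idx[a1]] if a1 in a1_idx else v_new[a1]
            u_col = (imputed.u[:, u_pos[a2]]
                     if imputed.basis[a2] != "admin1-level" else 0.0)
            eta[:, col] = (alpha[:, c, r] + beta[:, c, r] * (year - t0)
                           + u_col + v_col)
        p[stratum] = expit(eta)
    return PredictedCoverage(admin2=admin2, country_of=country_of, p=p,
                             basis=imputed.basis, year=year)


def aggregate_population(
    pred: PredictedCoverage, populations: PopulationTable
) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]]]:
    """Population-weighted overall coverage per admin2 and national coverage.

    Returns ``(overall, national)`` where ``overall`` is an
    ``(n_draws, n_admin2)`` array (NaN for admin2 with zero total
    population, which are excluded from the national sums with a warning)
    and ``national[country][stratum]`` gives per-draw national coverage for
    stratum ∈ {rural, urban, overall}.
    """
    ndraw = next(iter(pred.p.values())).shape[0]
    n2 = len(pred.admin2)
    pu = np.array([populations.p_urban.get(a, 0.0) for a in pred.admin2])
    pr = np.array([populations.p_rural.get(a, 0.0) for a in pred.admin2])
    tot = pu + pr
    overall = np.full((ndraw, n2), np.nan)
    pos = tot > 0
    if not pos.all():
        logger.warning("admin2 with zero total population excluded: %s",
                       [a for a, ok in zip(pred.admin2, pos) if not ok])
    overall[:, pos] = (pred.p["urban"][:, pos] * pu[pos]
                       + pred.p["rural"][:, pos] * pr[pos]) / tot[pos]

    national: dict[str, dict[str, np.ndarray]] = {}
    countries = sorted(set(pred.country_of))
    carr = np.array(pred.country_of)
    for country in countries:
        mask = (carr == country) & pos
        nat: dict[str, np.ndarray] = {}
        for stratum, weights in (("rural", pr), ("urban", pu), ("overall", tot)):
            wsum = weights[mask].sum()
            if wsum <= 0:
                nat[stratum] = np.full(ndraw, np.nan)
                continue
            parr = overall if stratum == "overall" else pred.p[stratum]
            nat[stratum] = (parr[:, mask] * weights[mask]).sum(axis=1) / wsum
        national[country] = nat
    return overall, national


def flag_significant_areas(
    area_draws: np.ndarray, national_draws: np.ndarray
) -> list[str]:
    """Flag areas whose coverage differs credibly from the national mean.

    Per area, the per-draw difference d = area − national is summarized;
    ``low`` if its 97.5% quantile is below 0, ``high`` if its 2.5% quantile
    is above 0, else ``none``.
    """
    if area_draws.shape[0] != national_draws.shape[0]:
        raise ValueError("draw counts differ between area and national draws")
    d = area_draws - national_draws[:, None]
    lo = np.nanquantile(d, 0.025, axis=0)
    hi = np.nanquantile(d, 0.975, axis=0)
    out = []
    for l, h in zip(lo, hi):
        if np.isnan(l) or np.isnan(h):
            out.append("none")
        elif h < 0:
            out.append("low")
        elif l > 0:
            out.append("high")
        else:
            out.append("none")
    return out


def coverage_table(
    draws: PosteriorDraws,
    hierarchy: AdminHierarchy,
    populations: PopulationTable,
    year: int = 2012,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior coverage summaries per admin2 × stratum.

    One row per admin2 and stratum ∈ {rural, urban, overall}: posterior
    median, central 95% interval, significance flag against the matching
    national aggregate, and the prediction basis of the area.
    """
    pred = predict_coverage(draws, hierarchy, year=year, seed=seed)
    overall, national = aggregate_population(pred, populations)
    rows = []
    carr = np.array(pred.country_of)
    stratum_draws = {"rural": pred.p["rural"], "urban": pred.p["urban"],
                     "overall": overall}
    for stratum, parr in stratum_draws.items():
        for country in sorted(set(pred.country_of)):
            mask = carr == country
            flags = flag_significant_areas(parr[:, mask],
                                           national[country][stratum])
            idxs = np.where(mask)[0]
            for flag, col in zip(flags, idxs):
                a2 = pred.admin2[col]
                vals = parr[:, col]
                if np.all(np.isnan(vals)):
                    med = lo = hi = np.nan
                else:
                    med, lo, hi = np.nanquantile(vals, (0.5, 0.025, 0.975))
                rows.append({
                    "admin2": a2,
                    "country": country,
                    "stratum": stratum,
                    "indicator": draws.meta.get("indicator", ""),
                    "median": med,
                    "lower": lo,
                    "upper": hi,
                    "flag": flag,
                    "basis": pred.basis[a2],
                })
    df = pd.DataFrame(rows)
    return df.sort_values(["admin2", "stratum"]).reset_index(drop=True)


def national_table(
    draws: PosteriorDraws,
    hierarchy: AdminHierarchy,
    populations: PopulationTable,
    year: int = 2012,
    seed: int = 0,
) -> pd.DataFrame:
    """National coverage summaries per country × stratum."""
    pred = predict_coverage(draws, hierarchy, year=year, seed=seed)
    _, national = aggregate_population(pred, populations)
    rows = []
    for country, strata in national.items():
        for stratum, arr in strata.items():
            med, lo, hi = np.nanquantile(arr, (0.5, 0.025, 0.975))
            rows.append({
                "country": country, "stratum": stratum,
                "indicator": draws.meta.get("indicator", ""),
                "median": med, "lower": lo, "upper": hi,
            })
    return pd.DataFrame(rows)
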