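"""Synthetic survey-data generator.

Emulates the structure of DHS/MICS-style national cluster-sample surveys so
the whole pipeline is testable without licensed microdata: a nested
admin hierarchy with within-country rook-lattice adjacency, urban/rural
strata with country-level logit intercepts and linear time trends drawn
around grand means, spatially correlated admin2 effects (intrinsic CAR on
the adjacency graph), unstructured admin1 effects, and binomial cluster
sampling of ~25 households per site over multiple survey years. Configurable
fractions of admin2 receive no sites, and of sites are emitted located to
admin1 only.

The generator inverts the analysis model exactly: site counts are
``k ~ Binomial(n, expit(alpha[c,r] + beta[c,r]*(t - t0) + u[j] + v[a1]))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .hierarchy import AdminHierarchy, PopulationTable, laplacian
from .indicators import INDICATORS, SurveySiteRecord

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "build_admin_hierarchy",
    "make_populations",
    "sample_icar_effects",
    "sample_true_parameters",
    "simulate_survey",
    "demo_scenario",
]

STRATA = ("rural", "urban")


@dataclass
class SimulationConfig:
    """Scenario description: geography, sampling design and seed.

    Each admin1 holds a ``lattice_rows x lattice_cols`` rook-contiguity grid
    of admin2; the admin1 blocks of one country are stacked vertically into a
    single connected country lattice. ``sites_per_admin2_per_year`` clusters
    are drawn in every sampled admin2 for every survey year, each of
    ``households_per_site`` households (a typical DHS cluster take ~25).
    """

    n_countries: int = 3
    admin1_per_country: int = 2
    lattice_rows: int = 3
    lattice_cols: int = 3
    sites_per_admin2_per_year: int = 2
    households_per_site: int = 25
    survey_years: Sequence[int] = (1998, 2005, 2011)
    fraction_unsampled_admin2: float = 0.0
    fraction_admin1_only: float = 0.0
    contiguity: str = "rook"
    t0: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_countries", "admin1_per_country", "lattice_rows",
                     "lattice_cols", "sites_per_admin2_per_year",
                     "households_per_site"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_unsampled_admin2", "fraction_admin1_only"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.contiguity not in ("rook", "queen"):
            raise ValueError("contiguity must be 'rook' or 'queen'")
        if not self.survey_years:
            raise ValueError("survey_years must be non-empty")


@dataclass
class TrueParameters:
    """Ground-truth parameters of the data-generating model (one indicator).

    All effects are on the logit scale; ``t0`` centres the time trend so
    intercepts are logit coverage at the reference year.
    """

    mu_alpha: dict[str, float]
    mu_beta: dict[str, float]
    sigma_alpha: dict[str, float]
    sigma_beta: dict[str, float]
    alpha: dict[tuple[str, str], float]   # (country, stratum) -> intercept
    beta: dict[tuple[str, str], float]    # (country, stratum) -> slope /yr
    sigma_u: dict[str, float]             # country -> ICAR SD
    u: dict[str, float]                   # admin2 -> spatial effect
    sigma_v: float
    v: dict[str, float]                   # admin1 -> unstructured effect
    t0: int = 2012

    def validate(self, hierarchy: AdminHierarchy, atol: float = 1e-8) -> None:
        for d in (self.sigma_alpha, self.sigma_beta, self.sigma_u):
            for s in d.values():
                if s < 0:
                    raise ValueError("standard deviations must be >= 0")
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be >= 0")
        for country in hierarchy.countries:
            for comp in hierarchy.components(country):
                total = sum(self.u.get(a2, 0.0) for a2 in comp)
                if abs(total) > atol * max(1, len(comp)):
                    raise ValueError(
                        f"spatial effects in component {sorted(comp)[:3]}... "
                        f"of {country} do not sum to zero ({total:g})"
                    )

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return float(obj)
            return obj

        d = clean(asdict(self))
        d["alpha"] = {f"{c}|{r}": float(v) for (c, r), v in self.alpha.items()}
        d["beta"] = {f"{c}|{r}": float(v) for (c, r), v in self.beta.items()}
        return d

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def build_admin_hierarchy(config: SimulationConfig) -> AdminHierarchy:
    """Construct the nested hierarchy and its within-country lattice graph.

    Admin2 of country ``C{i}`` are laid out on a
    ``(admin1_per_country * lattice_rows) x lattice_cols`` grid; rook
    contiguity joins edge-sharing cells (queen additionally joins corners).
    Deterministic (no randomness is involved in the geography).
    """
    countries = [f"C{i}" for i in range(config.n_countries)]
    admin1_of: dict[str, str] = {}
    admin2_of: dict[str, str] = {}
    adjacency: set[tuple[str, str]] = set()
    rows_total = config.admin1_per_country * config.lattice_rows
    cols = config.lattice_cols
    for c in countries:
        def name(r: int, col: int) -> str:
            return f"{c}A{r // config.lattice_rows}D{r % config.lattice_rows * cols + col:02d}"

        for a1 in range(config.admin1_per_country):
            admin1_of[f"{c}A{a1}"] = c
        for r in range(rows_total):
            for col in range(cols):
                admin2_of[name(r, col)] = f"{c}A{r // config.lattice_rows}"
        for r in range(rows_total):
            for col in range(cols):
                here = name(r, col)
                steps = [(1, 0), (0, 1)]
                if config.contiguity == "queen":
                    steps += [(1, 1), (1, -1)]
                for dr, dc in steps:
                    rr, cc = r + dr, col + dc
                    if 0 <= rr < rows_total and 0 <= cc < cols:
                        adjacency.add(tuple(sorted((here, name(rr, cc)))))
    return AdminHierarchy(
        countries=countries, admin1_of=admin1_of, admin2_of=admin2_of,
        adjacency=adjacency,
    )


def make_populations(
    hierarchy: AdminHierarchy,
    seed: int | np.random.Generator = 0,
    mean_total: float = 200_000.0,
) -> PopulationTable:
    """Random urban/rural person counts per admin2.

    Totals are log-normal around ``mean_total`` (the order of magnitude of a
    typical district) with an urban share drawn Beta(2, 3).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p_urban: dict[str, float] = {}
    p_rural: dict[str, float] = {}
    for a2 in hierarchy.admin2_ids:
        total = float(rng.lognormal(mean=np.log(mean_total), sigma=0.5))
        share = float(rng.beta(2.0, 3.0))
        p_urban[a2] = round(total * share)
        p_rural[a2] = round(total * (1.0 - share))
    return PopulationTable(p_urban=p_urban, p_rural=p_rural)


def sample_icar_effects(
    hierarchy: AdminHierarchy,
    sigma_u_per_country: Mapping[str, float] | float,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Draw intrinsic-CAR spatial effects on the admin2 graph.

    The intrinsic CAR is improper; draws are realised from its proper
    representative — a zero-mean Gaussian with covariance
    ``sigma_u**2 * pinv(L)`` (graph-Laplacian pseudo-inverse) — which is
    supported on the per-component sum-to-zero subspace. Effects are
    re-centred per connected component; islands receive exactly 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u: dict[str, float] = {}
    for country in hierarchy.countries:
        sigma = (
            sigma_u_per_country if np.isscalar(sigma_u_per_country)
            else sigma_u_per_country[country]
        )
        if sigma < 0:
            raise ValueError("sigma_u must be >= 0")
        nodes = hierarchy.admin2_in_country(country)
        graph = hierarchy.graph(country)
        lap = laplacian(graph, nodes)
        evals, evecs = np.linalg.eigh(lap)
        keep = evals > 1e-9
        z = rng.standard_normal(int(keep.sum()))
        draw = float(sigma) * evecs[:, keep] @ (z / np.sqrt(evals[keep]))
        vals = dict(zip(nodes, draw))
        # re-centre per component (a no-op up to round-off; imposed exactly)
        for comp in hierarchy.components(country):
            comp = sorted(comp)
            if len(comp) == 1:
                vals[comp[0]] = 0.0
                continue
            mean = sum(vals[a] for a in comp) / len(comp)
            for a in comp:
                vals[a] -= mean
        u.update(vals)
    return u


_INDICATOR_DEFAULTS: dict[str, dict[str, dict[str, float]]] = {
    # 2012 logit-scale grand intercepts and per-year slopes, by stratum;
    # chosen to land in the coverage ranges typical of the region in 2012
    # (water ~60%, sanitation ~40%, open defecation ~25% overall, urban
    # consistently better served, slow secular improvement).
    "improved_water": {
        "mu_alpha": {"rural": 0.2, "urban": 1.5},
        "mu_beta": {"rural": 0.05, "urban": 0.03},
    },
    "improved_sanitation": {
        "mu_alpha": {"rural": -0.8, "urban": 0.3},
        "mu_beta": {"rural": 0.04, "urban": 0.03},
    },
    "open_defecation": {
        "mu_alpha": {"rural": -0.3, "urban": -2.0},
        "mu_beta": {"rural": -0.05, "urban": -0.03},
    },
}


def sample_true_parameters(
    hierarchy: AdminHierarchy,
    seed: int | np.random.Generator = 0,
    *,
    mu_alpha: Mapping[str, float] | None = None,
    mu_beta: Mapping[str, float] | None = None,
    sigma_alpha: float = 0.75,
    sigma_beta: float = 0.02,
    sigma_u: float = 0.5,
    sigma_v: float = 0.3,
    t0: int = 2012,
    indicator: str = "improved_water",
) -> TrueParameters:
    """Draw a full ground-truth parameter set for one indicator.

    Country intercepts/slopes are normal around the grand means with
    between-country SDs ``sigma_alpha``/``sigma_beta``; spatial effects come
    from :func:`sample_icar_effects`; admin1 effects are iid normal.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    defaults = _INDICATOR_DEFAULTS[indicator]
    ma = dict(defaults["mu_alpha"] if mu_alpha is None else mu_alpha)
    mb = dict(defaults["mu_beta"] if mu_beta is None else mu_beta)
    alpha = {}
    beta = {}
    for c in hierarchy.countries:
        for r in STRATA:
            alpha[(c, r)] = float(ma[r] + sigma_alpha * rng.standard_normal())
            beta[(c, r)] = float(mb[r] + sigma_beta * rng.standard_normal())
    u = sample_icar_effects(hierarchy, sigma_u, rng)
    v = {a1: float(sigma_v * rng.standard_normal()) for a1 in hierarchy.admin1_ids}
    truth = TrueParameters(
        mu_alpha=ma,
        mu_beta=mb,
        sigma_alpha={r: sigma_alpha for r in STRATA},
        sigma_beta={r: sigma_beta for r in STRATA},
        alpha=alpha,
        beta=beta,
        sigma_u={c: sigma_u for c in hierarchy.countries},
        u=u,
        sigma_v=sigma_v,
        v=v,
        t0=t0,
    )
    truth.validate(hierarchy)
    return truth


def simulate_survey(
    hierarchy: AdminHierarchy,
    populations: PopulationTable,
    truth: Mapping[str, TrueParameters] | TrueParameters,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> list[SurveySiteRecord]:
    """Generate cluster-level survey records from known truth.

    ``truth`` maps indicator name → :class:`TrueParameters` (a bare
    TrueParameters is taken as the ``improved_water`` truth with the other
    indicator counts omitted). Per sampled admin2 and survey year,
    ``config.sites_per_admin2_per_year`` sites are drawn; each site's
    stratum is Bernoulli in the admin2's urban population share (a stratum
    with zero population is never selected). A ``fraction_unsampled_admin2``
    of admin2 per country receives no sites at all; a ``fraction_admin1_only``
    of emitted sites loses its admin2 label. Deterministic given the seed.
    """
    if isinstance(truth, TrueParameters):
        truth = {"improved_water": truth}
    for t in truth.values():
        t.validate(hierarchy)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    records: list[SurveySiteRecord] = []
    site_counter = 0
    for country in hierarchy.countries:
        admin2s = hierarchy.admin2_in_country(country)
        n_unsampled = int(round(config.fraction_unsampled_admin2 * len(admin2s)))
        n_unsampled = min(n_unsampled, len(admin2s) - 1)  # keep >=1 sampled
        unsampled = set(
            rng.choice(admin2s, size=n_unsampled, replace=False)
        ) if n_unsampled else set()
        for a2 in admin2s:
            if a2 in unsampled:
                continue
            a1 = hierarchy.admin2_of[a2]
            urban_share = populations.urban_share(a2)
            if populations.total(a2) <= 0:
                continue
            for year in config.survey_years:
                for _ in range(config.sites_per_admin2_per_year):
                    if urban_share <= 0:
                        urban = False
                    elif urban_share >= 1:
                        urban = True
                    else:
                        urban = bool(rng.random() < urban_share)
                    stratum = "urban" if urban else "rural"
                    n = config.households_per_site
                    k: dict[str, int] = {}
                    nn: dict[str, int] = {}
                    for ind, tp in truth.items():
                        eta = (
                            tp.alpha[(country, stratum)]
                            + tp.beta[(country, stratum)] * (year - tp.t0)
                            + tp.u.get(a2, 0.0)
                            + tp.v.get(a1, 0.0)
                        )
                        k[ind] = int(rng.binomial(n, expit(eta)))
                        nn[ind] = n
                    hide_admin2 = rng.random() < config.fraction_admin1_only
                    records.append(
                        SurveySiteRecord(
                            country=country,
                            admin1=a1,
                            admin2=None if hide_admin2 else a2,
                            urban=urban,
                            year=int(year),
                            n=nn,
                            k=k,
                            weight=1.0,
                            site_id=f"S{site_counter:06d}",
                        )
                    )
                    site_counter += 1
    return records


def demo_scenario(seed: int = 0, config: SimulationConfig | None = None):
    """Small end-to-end scenario: hierarchy, populations, truths, records.

    Returns ``(hierarchy, populations, truths, config, records)`` where
    ``truths`` maps each of the three main indicators to its ground truth.
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_truth, s_survey = ss.spawn(3)
    if config is None:
        config = SimulationConfig(seed=seed)
    hierarchy = build_admin_hierarchy(config)
    populations = make_populations(hierarchy, np.random.default_rng(s_pop))
    rng_truth = np.random.default_rng(s_truth)
    truths = {
        ind: sample_true_parameters(hierarchy, rng_truth, indicator=ind, t0=config.t0)
        for ind in INDICATORS
    }
    records = simulate_survey(
        hierarchy, populations, truths, config, np.random.default_rng(s_survey)
    )
    return hierarchy, populations, truths, config, records
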