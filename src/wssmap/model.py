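"""Bayesian hierarchical spatially-explicit binomial logistic model.

One indicator at a time, the proportion of households at survey site *s*
(in admin2 *j*, admin1 *a*, country *c*, stratum *r* ∈ {rural, urban},
survey year *t*) reporting use is modelled as

    k_s ~ Binomial(n_s, p_s),
    logit(p_s) = alpha[c,r] + beta[c,r] * (t - t0) + u[j] + v[a],

with country intercepts and slopes drawn around stratum grand means,

    alpha[c,r] ~ N(mu_alpha[r], sigma_alpha[r]^2),
    beta[c,r]  ~ N(mu_beta[r],  sigma_beta[r]^2),

an intrinsic CAR (ICAR) prior on the admin2 effects over the within-country
adjacency graph with country-specific spatial SD,

    p(u | sigma_u[c]) ∝ sigma_u[c]^-rank_c
                        * exp( -1/(2 sigma_u[c]^2) * sum_{i~j} (u_i - u_j)^2 ),

subject to a per-component sum-to-zero constraint (islands are fixed at 0),
and iid unstructured admin1 effects v[a] ~ N(0, sigma_v^2). The spatial and
admin1 effects are shared across strata. Record weights (from admin1-only
allocation) enter as powers on the binomial likelihood contributions.

Hyperpriors: grand means ~ N(0, 5^2); all SDs ~ half-normal(1) on the logit
scale (configurable).

Inference is by adaptive Metropolis-within-Gibbs: conjugate Gibbs draws for
the grand means; element-wise random-walk Metropolis, vectorised over
conditionally independent blocks, for everything else. The admin2 effects
are updated by graph colouring (chromatic blocking): within one colour class
no two areas are adjacent and none share a likelihood record, so their full
conditionals are independent and the whole class is updated in one
vectorised step. Proposal scales adapt during warmup toward an acceptance
rate of 0.4 and are frozen afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit, gammaln

from .hierarchy import AdminHierarchy
from .indicators import SurveySiteRecord, allocate_admin1_only
from .synthetic import STRATA

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperpriors",
    "ModelData",
    "ParameterState",
    "PosteriorDraws",
    "build_model_data",
    "log_unnormalized_posterior",
    "run_mcmc",
    "CoverageModel",
    "CoverageResults",
]


@dataclass
class Hyperpriors:
    """Prior scales, all on the logit scale."""

    mu_sd: float = 5.0
    sigma_alpha_scale: float = 1.0
    sigma_beta_scale: float = 1.0
    sigma_u_scale: float = 1.0
    sigma_v_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_sd", "sigma_alpha_scale", "sigma_beta_scale",
                     "sigma_u_scale", "sigma_v_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelData:
    """Design arrays for one indicator, with the observed-admin2 graph."""

    # per-record arrays
    k: np.ndarray
    n: np.ndarray
    w: np.ndarray
    cr: np.ndarray        # dense country*2 + stratum index
    c: np.ndarray
    a1: np.ndarray        # dense admin1 index
    j: np.ndarray         # dense admin2 index (observed admin2 only)
    t: np.ndarray         # centred year
    # labels
    countries: list[str]
    admin1_labels: list[str]
    admin2_labels: list[str]
    # graph structure on observed admin2 (induced subgraph)
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_country: np.ndarray
    degree: np.ndarray
    comp_label: np.ndarray        # per observed admin2
    node_country: np.ndarray      # per observed admin2
    rank_per_country: np.ndarray  # n_nodes_c - n_components_c
    colors: list[np.ndarray]      # chromatic classes of observed admin2
    indicator: str = "improved_water"
    t0: int = 2012
    hierarchy: AdminHierarchy | None = None
    logC: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def n_admin1(self) -> int:
        return len(self.admin1_labels)

    @property
    def n_admin2(self) -> int:
        return len(self.admin2_labels)

    @property
    def n_records(self) -> int:
        return len(self.k)


def build_model_data(
    records: Iterable[SurveySiteRecord],
    hierarchy: AdminHierarchy,
    indicator: str = "improved_water",
    t0: int = 2012,
) -> ModelData:
    """Encode located survey records into dense design arrays.

    Records with ``n == 0`` for the indicator are dropped (logged). Records
    must carry an admin2 (apply :func:`allocate_admin1_only` first);
    admin2 unknown to the hierarchy raise a validation error listing the
    offenders.
    """
    recs = list(records)
    bad = sorted({r.admin2 for r in recs
                  if r.admin2 is not None and r.admin2 not in hierarchy.admin2_of})
    if bad:
        raise ValueError(f"records reference unknown admin2: {bad}")
    if any(r.admin2 is None for r in recs):
        raise ValueError(
            "records with unknown admin2 present; run allocate_admin1_only first"
        )
    kept = [r for r in recs if r.n.get(indicator, 0) > 0]
    if len(kept) < len(recs):
        logger.info("dropped %d records with n=0 for %s", len(recs) - len(kept), indicator)
    if not kept:
        raise ValueError(f"no records with data for indicator {indicator!r}")

    countries = sorted({r.country for r in kept})
    admin1_labels = sorted({r.admin1 for r in kept})
    admin2_labels = sorted({r.admin2 for r in kept})  # type: ignore[type-var]
    c_idx = {c: i for i, c in enumerate(countries)}
    a1_idx = {a: i for i, a in enumerate(admin1_labels)}
    a2_idx = {a: i for i, a in enumerate(admin2_labels)}

    k = np.array([r.k[indicator] for r in kept], dtype=float)
    n = np.array([r.n[indicator] for r in kept], dtype=float)
    w = np.array([r.weight for r in kept], dtype=float)
    c = np.array([c_idx[r.country] for r in kept], dtype=np.intp)
    rr = np.array([int(r.urban) for r in kept], dtype=np.intp)
    a1 = np.array([a1_idx[r.admin1] for r in kept], dtype=np.intp)
    j = np.array([a2_idx[r.admin2] for r in kept], dtype=np.intp)
    t = np.array([r.year - t0 for r in kept], dtype=float)
    logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    # induced subgraph on observed admin2
    g = hierarchy.graph(nodes=admin2_labels)
    edge_i, edge_j, edge_country = [], [], []
    for a, b in sorted(g.edges()):
        edge_i.append(a2_idx[a])
        edge_j.append(a2_idx[b])
        edge_country.append(c_idx[hierarchy.country_of_admin2(a)])
    edge_i = np.array(edge_i, dtype=np.intp)
    edge_j = np.array(edge_j, dtype=np.intp)
    edge_country = np.array(edge_country, dtype=np.intp)
    degree = np.zeros(len(admin2_labels))
    np.add.at(degree, edge_i, 1.0)
    np.add.at(degree, edge_j, 1.0)

    comp_label = np.empty(len(admin2_labels), dtype=np.intp)
    node_country = np.array(
        [c_idx[hierarchy.country_of_admin2(a)] for a in admin2_labels], dtype=np.intp
    )
    n_comp_per_country = np.zeros(len(countries), dtype=np.intp)
    comp_counter = 0
    for comp in nx.connected_components(g):
        for a in comp:
            comp_label[a2_idx[a]] = comp_counter
        n_comp_per_country[c_idx[hierarchy.country_of_admin2(next(iter(comp)))]] += 1
        comp_counter += 1
    n_nodes_per_country = np.bincount(node_country, minlength=len(countries))
    rank = n_nodes_per_country - n_comp_per_country

    coloring = nx.coloring.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1 if coloring else 1
    colors = [
        np.array(sorted(a2_idx[a] for a, col in coloring.items() if col == color),
                 dtype=np.intp)
        for color in range(n_colors)
    ]

    return ModelData(
        k=k, n=n, w=w, cr=c * 2 + rr, c=c, a1=a1, j=j, t=t,
        countries=countries, admin1_labels=admin1_labels,
        admin2_labels=admin2_labels,
        edge_i=edge_i, edge_j=edge_j, edge_country=edge_country,
        degree=degree, comp_label=comp_label, node_country=node_country,
        rank_per_country=rank, colors=colors,
        indicator=indicator, t0=t0, hierarchy=hierarchy, logC=logC,
    )


@dataclass
class ParameterState:
    """One point in parameter space (arrays indexed like ModelData)."""

    mu_alpha: np.ndarray    # (2,)   rural, urban
    mu_beta: np.ndarray     # (2,)
    alpha: np.ndarray       # (C, 2)
    beta: np.ndarray        # (C, 2)
    sigma_alpha: np.ndarray  # (2,)
    sigma_beta: np.ndarray   # (2,)
    sigma_u: np.ndarray      # (C,)
    sigma_v: float
    u: np.ndarray            # (J,)
    v: np.ndarray            # (K,)

    def copy(self) -> "ParameterState":
        return ParameterState(
            mu_alpha=self.mu_alpha.copy(), mu_beta=self.mu_beta.copy(),
            alpha=self.alpha.copy(), beta=self.beta.copy(),
            sigma_alpha=self.sigma_alpha.copy(), sigma_beta=self.sigma_beta.copy(),
            sigma_u=self.sigma_u.copy(), sigma_v=float(self.sigma_v),
            u=self.u.copy(), v=self.v.copy(),
        )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _linear_predictor(data: ModelData, p: ParameterState) -> np.ndarray:
    return (p.alpha.ravel()[data.cr] + p.beta.ravel()[data.cr] * data.t
            + p.u[data.j] + p.v[data.a1])


def log_unnormalized_posterior(
    data: ModelData, params: ParameterState, hyper: Hyperpriors | None = None
) -> float:
    """Joint log density up to an additive constant.

    Returns ``-inf`` (a rejected state, not an exception) when any SD is
    non-positive. The binomial coefficient is included, scaled by the record
    weight, so that splitting one record into two half-weight copies leaves
    the value exactly unchanged.
    """
    hyper = hyper or Hyperpriors()
    sigs = np.concatenate([params.sigma_alpha, params.sigma_beta,
                           params.sigma_u, [params.sigma_v]])
    if np.any(sigs <= 0):
        return -np.inf
    eta = _linear_predictor(data, params)
    ll = float(np.sum(data.w * (data.logC + data.k * eta - data.n * _softplus(eta))))

    # ICAR pseudo-likelihood for u, per country
    du = params.u[data.edge_i] - params.u[data.edge_j]
    q = np.bincount(data.edge_country, weights=du * du, minlength=data.n_countries)
    icar = float(np.sum(
        -data.rank_per_country * np.log(params.sigma_u)
        - q / (2.0 * params.sigma_u ** 2)
    ))

    lp = ll + icar
    lp += float(np.sum(-np.log(params.sigma_v)
                       - params.v ** 2 / (2.0 * params.sigma_v ** 2)))
    for r in range(2):
        lp += float(np.sum(
            -np.log(params.sigma_alpha[r])
            - (params.alpha[:, r] - params.mu_alpha[r]) ** 2
            / (2.0 * params.sigma_alpha[r] ** 2)
        ))
        lp += float(np.sum(
            -np.log(params.sigma_beta[r])
            - (params.beta[:, r] - params.mu_beta[r]) ** 2
            / (2.0 * params.sigma_beta[r] ** 2)
        ))
    lp += float(np.sum(-params.mu_alpha ** 2 / (2.0 * hyper.mu_sd ** 2)))
    lp += float(np.sum(-params.mu_beta ** 2 / (2.0 * hyper.mu_sd ** 2)))
    lp += float(np.sum(-params.sigma_alpha ** 2 / (2.0 * hyper.sigma_alpha_scale ** 2)))
    lp += float(np.sum(-params.sigma_beta ** 2 / (2.0 * hyper.sigma_beta_scale ** 2)))
    lp += float(np.sum(-params.sigma_u ** 2 / (2.0 * hyper.sigma_u_scale ** 2)))
    lp += float(-params.sigma_v ** 2 / (2.0 * hyper.sigma_v_scale ** 2))
    return lp


@dataclass
class PosteriorDraws:
    """MCMC samples with chain structure and sampler metadata.

    Arrays in ``params`` carry a leading ``(chain, draw)`` pair of axes.
    """

    params: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    meta: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior=self.params)

    def scalar_table(self) -> dict[str, np.ndarray]:
        """Flatten every parameter into named scalar chains (chain, draw)."""
        out: dict[str, np.ndarray] = {}
        strata = self.labels["strata"]
        countries = self.labels["countries"]
        for r, s in enumerate(strata):
            out[f"mu_alpha[{s}]"] = self.params["mu_alpha"][:, :, r]
            out[f"mu_beta[{s}]"] = self.params["mu_beta"][:, :, r]
            out[f"sigma_alpha[{s}]"] = self.params["sigma_alpha"][:, :, r]
            out[f"sigma_beta[{s}]"] = self.params["sigma_beta"][:, :, r]
        for ci, cname in enumerate(countries):
            out[f"sigma_u[{cname}]"] = self.params["sigma_u"][:, :, ci]
            for r, s in enumerate(strata):
                out[f"alpha[{cname},{s}]"] = self.params["alpha"][:, :, ci, r]
                out[f"beta[{cname},{s}]"] = self.params["beta"][:, :, ci, r]
        out["sigma_v"] = self.params["sigma_v"]
        return out

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {"labels": self.labels, "meta": self.meta, "arrays": {}}
        for name, arr in self.params.items():
            np.save(d / f"{name}.npy", arr)
            manifest["arrays"][name] = {"file": f"{name}.npy", "shape": list(arr.shape)}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        import json
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        params = {
            name: np.load(d / info["file"])
            for name, info in manifest["arrays"].items()
        }
        return cls(params=params, labels=manifest["labels"], meta=manifest["meta"])


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

_ADAPT_TARGET = 0.4


class _Chain:
    """One chain of the adaptive Metropolis-within-Gibbs sampler.

    Internally the intercepts are reparameterised to the precision-weighted
    mean survey time of each (country, stratum) cell,
    ``alpha_int = alpha + beta * tbar``, which removes the strong
    intercept–slope posterior correlation induced by a reference year
    outside the data span; draws are transformed back before storage. An
    exact Gibbs "shift" move along the likelihood-invariant ridge
    ``alpha[c,:] += delta, v[admin1 in c] -= delta`` handles the weak
    identification between country intercepts and unstructured admin1
    effects.
    """

    def __init__(self, data: ModelData, hyper: Hyperpriors,
                 rng: np.random.Generator):
        self.data = data
        self.hyper = hyper
        self.rng = rng
        d = data
        C = d.n_countries
        # precision-weighted mean time per (country, stratum) cell
        wn = d.w * d.n
        num = np.bincount(d.cr, weights=wn * d.t, minlength=2 * C)
        den = np.bincount(d.cr, weights=wn, minlength=2 * C)
        self.tbar = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        self.tc = d.t - self.tbar[d.cr]
        # admin1 -> country index
        self.a1_country = np.full(d.n_admin1, -1, dtype=np.intp)
        for rec in range(d.n_records):
            self.a1_country[d.a1[rec]] = d.c[rec]
        # empirical-logit initial values with chain jitter
        p_pool = np.zeros(2)
        for r in range(2):
            mask = (d.cr % 2) == r
            tot_k = float(np.sum(d.w[mask] * d.k[mask])) if mask.any() else 0.0
            tot_n = float(np.sum(d.w[mask] * d.n[mask])) if mask.any() else 1.0
            p_pool[r] = (tot_k + 0.5) / (tot_n + 1.0)
        mu0 = np.log(p_pool / (1 - p_pool))
        self.state = ParameterState(
            mu_alpha=mu0 + 0.2 * rng.standard_normal(2),
            mu_beta=0.01 * rng.standard_normal(2),
            alpha=np.tile(mu0, (C, 1)) + 0.2 * rng.standard_normal((C, 2)),
            beta=0.01 * rng.standard_normal((C, 2)),
            sigma_alpha=np.full(2, 0.5) * np.exp(0.1 * rng.standard_normal(2)),
            sigma_beta=np.full(2, 0.02) * np.exp(0.1 * rng.standard_normal(2)),
            sigma_u=np.full(C, 0.5) * np.exp(0.1 * rng.standard_normal(C)),
            sigma_v=float(0.3 * np.exp(0.1 * rng.standard_normal())),
            u=np.zeros(d.n_admin2),
            v=np.zeros(d.n_admin1),
        )
        if not np.isfinite(log_unnormalized_posterior(data, self.state, hyper)):
            raise RuntimeError(
                "non-finite posterior at initialization; jitter starting values "
                "or re-seed the sampler"
            )
        # proposal scales (log-space random-walk for SDs)
        self.step_alpha = np.full(2 * C, 0.3)
        self.step_beta = np.full(2 * C, 0.02)
        self.step_u = np.full(d.n_admin2, 0.5)
        self.step_v = np.full(d.n_admin1, 0.3)
        self.eta = _linear_predictor(d, self.state)
        self.acc: dict[str, list[float]] = {k: [] for k in
                                            ("alpha", "beta", "u", "v",
                                             "sigma_alpha", "sigma_beta",
                                             "sigma_u", "sigma_v")}
        # component bookkeeping for re-centring
        self.n_comp = int(d.comp_label.max()) + 1 if d.n_admin2 else 0
        self.comp_size = np.bincount(d.comp_label, minlength=self.n_comp).astype(float)
        # neighbour-sum matrix
        import scipy.sparse as sp

        J = d.n_admin2
        rows = np.concatenate([d.edge_i, d.edge_j])
        cols = np.concatenate([d.edge_j, d.edge_i])
        self.adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(J, J)
        )

    # -- likelihood helpers ------------------------------------------------
    def _delta_ll_records(self, deta: np.ndarray) -> np.ndarray:
        d = self.data
        eta_new = self.eta + deta
        return d.w * (d.k * deta - d.n * (_softplus(eta_new) - _softplus(self.eta)))

    def _adapt(self, step: np.ndarray | float, accepted, gamma: float):
        acc = np.asarray(accepted, dtype=float)
        return step * np.exp(gamma * (acc - _ADAPT_TARGET))

    # -- block updates -----------------------------------------------------
    def update_alpha_beta(self, which: str, gamma: float | None) -> None:
        # "alpha" moves the data-centred intercept (equivalently the
        # reported intercept, slope fixed); "beta" moves the slope holding
        # the data-centred intercept fixed, so the reported intercept
        # co-moves by -dbeta * tbar.
        d, s = self.data, self.state
        ncell = 2 * d.n_countries
        step = self.step_alpha if which == "alpha" else self.step_beta
        dcell = step * self.rng.standard_normal(ncell)
        deta = dcell[d.cr] if which == "alpha" else dcell[d.cr] * self.tc
        dll = np.bincount(d.cr, weights=self._delta_ll_records(deta), minlength=ncell)
        mu_a = np.tile(s.mu_alpha, d.n_countries)
        sig_a = np.tile(s.sigma_alpha, d.n_countries)
        alpha_flat = s.alpha.ravel()
        if which == "alpha":
            new = alpha_flat + dcell
            dprior = ((alpha_flat - mu_a) ** 2 - (new - mu_a) ** 2) / (2 * sig_a ** 2)
        else:
            mu_b = np.tile(s.mu_beta, d.n_countries)
            sig_b = np.tile(s.sigma_beta, d.n_countries)
            beta_flat = s.beta.ravel()
            new_b = beta_flat + dcell
            new_a = alpha_flat - dcell * self.tbar
            dprior = (
                ((beta_flat - mu_b) ** 2 - (new_b - mu_b) ** 2) / (2 * sig_b ** 2)
                + ((alpha_flat - mu_a) ** 2 - (new_a - mu_a) ** 2) / (2 * sig_a ** 2)
            )
        accept = np.log(self.rng.random(ncell)) < dll + dprior
        if which == "alpha":
            alpha_flat[accept] = (alpha_flat + dcell)[accept]
            self.eta += np.where(accept[d.cr], dcell[d.cr], 0.0)
        else:
            beta_flat = s.beta.ravel()
            beta_flat[accept] = (beta_flat + dcell)[accept]
            alpha_flat[accept] = (alpha_flat - dcell * self.tbar)[accept]
            self.eta += np.where(accept[d.cr], dcell[d.cr] * self.tc, 0.0)
        self.acc[which].append(float(accept.mean()))
        if gamma is not None:
            if which == "alpha":
                self.step_alpha = self._adapt(step, accept, gamma)
            else:
                self.step_beta = self._adapt(step, accept, gamma)

    def update_shift(self) -> None:
        """Exact Gibbs move along the likelihood-invariant ridge
        alpha[c,:] += delta_c, v[admin1 in c] -= delta_c."""
        d, s = self.data, self.state
        C = d.n_countries
        k_per_c = np.bincount(self.a1_country, minlength=C)
        v_sum = np.bincount(self.a1_country, weights=s.v, minlength=C)
        prec = (1.0 / s.sigma_alpha ** 2).sum() + k_per_c / s.sigma_v ** 2
        num = (((s.mu_alpha - s.alpha) / s.sigma_alpha ** 2).sum(axis=1)
               + v_sum / s.sigma_v ** 2)
        delta = num / prec + self.rng.standard_normal(C) / np.sqrt(prec)
        s.alpha += delta[:, None]
        s.v -= delta[self.a1_country]
        # eta is invariant: the intercept shift cancels the admin1 shift

    def update_u(self, gamma: float | None) -> None:
        d, s = self.data, self.state
        if d.n_admin2 == 0:
            return
        acc_all = np.zeros(d.n_admin2, dtype=bool)
        for nodes in d.colors:
            if len(nodes) == 0:
                continue
            du_node = np.zeros(d.n_admin2)
            du_node[nodes] = self.step_u[nodes] * self.rng.standard_normal(len(nodes))
            deta = du_node[d.j]
            dll_node = np.bincount(d.j, weights=self._delta_ll_records(deta),
                                   minlength=d.n_admin2)[nodes]
            nbr_sum = self.adj @ s.u
            uc, un = s.u[nodes], s.u[nodes] + du_node[nodes]
            m = d.degree[nodes]
            sig2 = s.sigma_u[d.node_country[nodes]] ** 2
            dprior = -((m * un ** 2 - 2 * un * nbr_sum[nodes])
                       - (m * uc ** 2 - 2 * uc * nbr_sum[nodes])) / (2 * sig2)
            accept = np.log(self.rng.random(len(nodes))) < dll_node + dprior
            s.u[nodes[accept]] = un[accept]
            acc_all[nodes[accept]] = True
            if gamma is not None:
                self.step_u[nodes] = self._adapt(self.step_u[nodes], accept, gamma)
        # re-impose sum-to-zero per connected component, then refresh eta
        comp_mean = (np.bincount(d.comp_label, weights=s.u, minlength=self.n_comp)
                     / self.comp_size)
        s.u -= comp_mean[d.comp_label]
        # islands stay exactly 0
        s.u[d.degree == 0] = 0.0
        self.eta = _linear_predictor(d, s)
        self.acc["u"].append(float(acc_all.mean()))

    def update_v(self, gamma: float | None) -> None:
        d, s = self.data, self.state
        K = d.n_admin1
        dv = self.step_v * self.rng.standard_normal(K)
        deta = dv[d.a1]
        dll = np.bincount(d.a1, weights=self._delta_ll_records(deta), minlength=K)
        new = s.v + dv
        dprior = (s.v ** 2 - new ** 2) / (2 * s.sigma_v ** 2)
        accept = np.log(self.rng.random(K)) < dll + dprior
        s.v[accept] = new[accept]
        self.eta += np.where(accept[d.a1], dv[d.a1], 0.0)
        self.acc["v"].append(float(accept.mean()))
        if gamma is not None:
            self.step_v = self._adapt(self.step_v, accept, gamma)

    def update_grand_means(self) -> None:
        """Conjugate Gibbs draws for mu_alpha and mu_beta."""
        s, h = self.state, self.hyper
        C = self.data.n_countries
        for name, vals, sig in (("mu_alpha", s.alpha, s.sigma_alpha),
                                ("mu_beta", s.beta, s.sigma_beta)):
            prec = C / sig ** 2 + 1.0 / h.mu_sd ** 2
            mean = (vals.sum(axis=0) / sig ** 2) / prec
            draw = mean + self.rng.standard_normal(2) / np.sqrt(prec)
            setattr(s, name, draw)

    @staticmethod
    def _halfnormal_logpdf(sigma: np.ndarray, scale: float) -> np.ndarray:
        return -(sigma ** 2) / (2 * scale ** 2)

    def _slice_sd(self, sigma0: float, m: float, ssq: float, scale: float,
                  width: float = 1.0) -> float:
        """Slice-sample one SD whose full conditional is
        sigma^-m exp(-ssq / (2 sigma^2)) * halfnormal(sigma; scale),
        on the log scale (tuning-free)."""

        def f(l: float) -> float:
            sig2 = np.exp(2.0 * l)
            # +l is the Jacobian of the log transform
            return (-m * l - ssq / (2.0 * sig2) - sig2 / (2.0 * scale ** 2) + l)

        rng = self.rng
        l0 = float(np.log(sigma0))
        y = f(l0) - rng.exponential()
        left = l0 - width * rng.random()
        right = left + width
        for _ in range(50):
            if f(left) <= y:
                break
            left -= width
        for _ in range(50):
            if f(right) <= y:
                break
            right += width
        for _ in range(100):
            l1 = left + (right - left) * rng.random()
            if f(l1) >= y:
                return float(np.exp(l1))
            if l1 < l0:
                left = l1
            else:
                right = l1
        return sigma0

    def update_sigmas(self, gamma: float | None = None) -> None:
        del gamma  # slice sampling needs no adaptation
        d, s, h = self.data, self.state, self.hyper
        C = d.n_countries
        dev_a = ((s.alpha - s.mu_alpha) ** 2).sum(axis=0)
        dev_b = ((s.beta - s.mu_beta) ** 2).sum(axis=0)
        for r in range(2):
            s.sigma_alpha[r] = self._slice_sd(
                s.sigma_alpha[r], C, float(dev_a[r]), h.sigma_alpha_scale)
            s.sigma_beta[r] = self._slice_sd(
                s.sigma_beta[r], C, float(dev_b[r]), h.sigma_beta_scale)
        du = s.u[d.edge_i] - s.u[d.edge_j]
        q = np.bincount(d.edge_country, weights=du * du, minlength=C)
        for ci in range(C):
            s.sigma_u[ci] = self._slice_sd(
                s.sigma_u[ci], float(d.rank_per_country[ci]), float(q[ci]),
                h.sigma_u_scale)
        s.sigma_v = self._slice_sd(
            s.sigma_v, d.n_admin1, float(np.sum(s.v ** 2)), h.sigma_v_scale)
        for key in ("sigma_alpha", "sigma_beta", "sigma_u", "sigma_v"):
            self.acc[key].append(1.0)

    def update_sigmas_noncentered(self) -> None:
        """Interweaving (ASIS) moves: rescale u (per country) and v jointly
        with their SDs, holding the standardized effects fixed. Breaks the
        funnel coupling between small SDs and near-zero effects."""
        d, s, h = self.data, self.state, self.hyper
        C = d.n_countries
        # sigma_u per country
        z = 0.3 * self.rng.standard_normal(C)
        ratio = np.exp(z)
        deta = (ratio[d.c] - 1.0) * s.u[d.j]
        dll = np.bincount(d.c, weights=self._delta_ll_records(deta), minlength=C)
        new = s.sigma_u * ratio
        dlp = (dll + self._halfnormal_logpdf(new, h.sigma_u_scale)
               - self._halfnormal_logpdf(s.sigma_u, h.sigma_u_scale) + z)
        accept = np.log(self.rng.random(C)) < dlp
        if accept.any():
            scale_node = np.where(accept[d.node_country], ratio[d.node_country], 1.0)
            s.u *= scale_node
            s.sigma_u = np.where(accept, new, s.sigma_u)
            self.eta = _linear_predictor(d, s)
        # sigma_v (global)
        z = 0.3 * float(self.rng.standard_normal())
        ratio = float(np.exp(z))
        deta = (ratio - 1.0) * s.v[d.a1]
        dll = float(np.sum(self._delta_ll_records(deta)))
        new_sv = s.sigma_v * ratio
        dlp = (dll + float(self._halfnormal_logpdf(np.array(new_sv), h.sigma_v_scale))
               - float(self._halfnormal_logpdf(np.array(s.sigma_v), h.sigma_v_scale))
               + z)
        if np.log(self.rng.random()) < dlp:
            s.v *= ratio
            s.sigma_v = new_sv
            self.eta = _linear_predictor(d, s)

    def iterate(self, it: int, n_warmup: int) -> None:
        gamma = min(0.25, (it + 1.0) ** -0.6) if it < n_warmup else None
        self.update_alpha_beta("alpha", gamma)
        self.update_alpha_beta("beta", gamma)
        self.update_u(gamma)
        self.update_v(gamma)
        self.update_shift()
        self.update_grand_means()
        self.update_sigmas()
        self.update_sigmas_noncentered()


def run_mcmc(
    data: ModelData,
    hyper: Hyperpriors | None = None,
    n_chains: int = 2,
    n_iter: int = 4000,
    n_warmup: int = 2000,
    seed: int = 0,
    thin: int = 1,
) -> PosteriorDraws:
    """Sample the posterior; reproducible given ``seed``.

    ``n_iter`` counts total iterations per chain including the ``n_warmup``
    adaptation phase; post-warmup draws are stored every ``thin`` iterations.
    """
    if not (n_iter > n_warmup >= 0):
        raise ValueError("need n_iter > n_warmup >= 0")
    hyper = hyper or Hyperpriors()
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    n_keep = (n_iter - n_warmup) // thin
    store: dict[str, np.ndarray] = {
        "mu_alpha": np.empty((n_chains, n_keep, 2)),
        "mu_beta": np.empty((n_chains, n_keep, 2)),
        "alpha": np.empty((n_chains, n_keep, data.n_countries, 2)),
        "beta": np.empty((n_chains, n_keep, data.n_countries, 2)),
        "sigma_alpha": np.empty((n_chains, n_keep, 2)),
        "sigma_beta": np.empty((n_chains, n_keep, 2)),
        "sigma_u": np.empty((n_chains, n_keep, data.n_countries)),
        "sigma_v": np.empty((n_chains, n_keep)),
        "u": np.empty((n_chains, n_keep, data.n_admin2)),
        "v": np.empty((n_chains, n_keep, data.n_admin1)),
    }
    acc_rates = []
    for ch in range(n_chains):
        chain = _Chain(data, hyper, np.random.default_rng(seeds[ch]))
        kept = 0
        for it in range(n_iter):
            chain.iterate(it, n_warmup)
            if it >= n_warmup and (it - n_warmup) % thin == 0 and kept < n_keep:
                s = chain.state
                store["mu_alpha"][ch, kept] = s.mu_alpha
                store["mu_beta"][ch, kept] = s.mu_beta
                store["alpha"][ch, kept] = s.alpha
                store["beta"][ch, kept] = s.beta
                store["sigma_alpha"][ch, kept] = s.sigma_alpha
                store["sigma_beta"][ch, kept] = s.sigma_beta
                store["sigma_u"][ch, kept] = s.sigma_u
                store["sigma_v"][ch, kept] = s.sigma_v
                store["u"][ch, kept] = s.u
                store["v"][ch, kept] = s.v
                kept += 1
        acc_rates.append({k: float(np.mean(v[n_warmup:])) if len(v) > n_warmup
                          else float(np.mean(v)) for k, v in chain.acc.items()})
    labels = {
        "strata": list(STRATA),
        "countries": data.countries,
        "admin1": data.admin1_labels,
        "admin2": data.admin2_labels,
    }
    meta = {
        "seed": int(seed), "n_chains": int(n_chains), "n_iter": int(n_iter),
        "n_warmup": int(n_warmup), "thin": int(thin),
        "indicator": data.indicator, "t0": int(data.t0),
        "acceptance_rates": acc_rates,
    }
    return PosteriorDraws(params=store, labels=labels, meta=meta)


# --------------------------------------------------------------------------
# statsmodels-style front door
# --------------------------------------------------------------------------


class CoverageModel:
    """Spatial multilevel coverage model for one indicator.

    Build from located survey records (admin1-only records are spread over
    their admin2 with 1/m weights automatically) and fit by MCMC; ``fit``
    returns a :class:`CoverageResults`.
    """

    def __init__(self, data: ModelData, hyper: Hyperpriors | None = None):
        self.data = data
        self.hyper = hyper or Hyperpriors()

    @classmethod
    def from_records(
        cls,
        records: Iterable[SurveySiteRecord],
        hierarchy: AdminHierarchy,
        indicator: str = "improved_water",
        t0: int = 2012,
        hyper: Hyperpriors | None = None,
    ) -> "CoverageModel":
        recs = allocate_admin1_only(records, hierarchy)
        return cls(build_model_data(recs, hierarchy, indicator, t0), hyper)

    @classmethod
    def from_frame(cls, frame, hierarchy: AdminHierarchy, **kwargs) -> "CoverageModel":
        """Build from the canonical site-level table (see indicators module)."""
        import io

        from .indicators import read_sites_csv

        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        return cls.from_records(read_sites_csv(buf), hierarchy, **kwargs)

    def log_posterior(self, params: ParameterState) -> float:
        return log_unnormalized_posterior(self.data, params, self.hyper)

    def fit(self, n_chains: int = 2, n_iter: int = 4000, n_warmup: int = 2000,
            seed: int = 0, thin: int = 1) -> "CoverageResults":
        draws = run_mcmc(self.data, self.hyper, n_chains=n_chains,
                         n_iter=n_iter, n_warmup=n_warmup, seed=seed, thin=thin)
        return CoverageResults(self, draws)


class CoverageResults:
    """Fitted model: posterior draws plus prediction and diagnostics."""

    def __init__(self, model: CoverageModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    def diagnostics(self):
        from .diagnostics import diagnostics

        return diagnostics(self.draws)

    def impute_spatial_effects(self, seed: int = 0):
        from .predict import impute_unsampled_effects

        return impute_unsampled_effects(
            self.draws, self.model.data.hierarchy, seed=seed
        )

    def predict_coverage(self, year: int = 2012, seed: int = 0):
        from .predict import predict_coverage

        return predict_coverage(self.draws, self.model.data.hierarchy,
                                year=year, seed=seed)

    def coverage_table(self, populations, year: int = 2012, seed: int = 0):
        from .predict import coverage_table

        return coverage_table(self.draws, self.model.data.hierarchy,
                              populations, year=year, seed=seed)

    def summary(self) -> str:
        qs = (0.5, 0.025, 0.975)
        lines = [
            f"Coverage model: {self.model.data.indicator}",
            f"records: {self.model.data.n_records}  "
            f"admin2: {self.model.data.n_admin2}  "
            f"admin1: {self.model.data.n_admin1}  "
            f"countries: {self.model.data.n_countries}",
            f"chains: {self.draws.n_chains}  draws/chain: {self.draws.n_draws}",
            "",
            f"{'parameter':<24}{'median':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        scalars = self.draws.scalar_table()
        for name, arr in scalars.items():
            med, lo, hi = np.quantile(arr, qs)
            lines.append(f"{name:<24}{med:>10.3f}{lo:>10.3f}{hi:>10.3f}")
        return "\n".join(lines)
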