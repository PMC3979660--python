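import itertools

import numpy as np
import pytest

import wssmap as w
from wssmap.hierarchy import laplacian
from wssmap.synthetic import STRATA, SimulationConfig, TrueParameters


def flat_truth(hierarchy, mu_alpha=0.0, t0=2012):
    """Truth with all random effects zero and flat time trends."""
    return TrueParameters(
        mu_alpha={r: mu_alpha for r in STRATA},
        mu_beta={r: 0.0 for r in STRATA},
        sigma_alpha={r: 0.0 for r in STRATA},
        sigma_beta={r: 0.0 for r in STRATA},
        alpha={(c, r): mu_alpha for c in hierarchy.countries for r in STRATA},
        beta={(c, r): 0.0 for c in hierarchy.countries for r in STRATA},
        sigma_u={c: 0.0 for c in hierarchy.countries},
        u={a: 0.0 for a in hierarchy.admin2_ids},
        sigma_v=0.0,
        v={a: 0.0 for a in hierarchy.admin1_ids},
        t0=t0,
    )


class TestBuildHierarchy:
    def test_2x2_rook_lattice_every_node_has_two_neighbours(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=2, lattice_cols=2)
        h = w.build_admin_hierarchy(cfg)
        assert len(h.admin2_of) == 4
        assert all(len(h.neighbours(a)) == 2 for a in h.admin2_ids)

    def test_3x3_rook_lattice_centre_has_four_neighbours(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=3, lattice_cols=3)
        h = w.build_admin_hierarchy(cfg)
        # oracle: enumerate rook edges of a 3x3 grid directly
        edges = set()
        for r, c in itertools.product(range(3), range(3)):
            for dr, dc in ((1, 0), (0, 1)):
                if r + dr < 3 and c + dc < 3:
                    edges.add(((r, c), (r + dr, c + dc)))
        assert len(h.adjacency) == len(edges) == 12
        degrees = sorted(len(h.neighbours(a)) for a in h.admin2_ids)
        assert degrees == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_single_admin2_countries_are_islands(self):
        cfg = SimulationConfig(n_countries=2, admin1_per_country=1,
                               lattice_rows=1, lattice_cols=1)
        h = w.build_admin_hierarchy(cfg)
        assert h.adjacency == set()
        assert h.islands == set(h.admin2_ids)

    def test_queen_contiguity_adds_diagonals(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=2, lattice_cols=2,
                               contiguity="queen")
        h = w.build_admin_hierarchy(cfg)
        assert all(len(h.neighbours(a)) == 3 for a in h.admin2_ids)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_countries=0)
        with pytest.raises(ValueError, match="0, 1"):
            SimulationConfig(fraction_admin1_only=1.5)


class TestIcarEffects:
    def test_zero_sigma_gives_zero_effects(self):
        cfg = SimulationConfig(n_countries=1, lattice_rows=3, lattice_cols=3)
        h = w.build_admin_hierarchy(cfg)
        u = w.sample_icar_effects(h, 0.0, seed=5)
        assert all(v == 0.0 for v in u.values())

    def test_component_sums_are_zero(self):
        cfg = SimulationConfig(n_countries=2, admin1_per_country=2,
                               lattice_rows=2, lattice_cols=3)
        h = w.build_admin_hierarchy(cfg)
        u = w.sample_icar_effects(h, {"C0": 0.7, "C1": 1.3}, seed=9)
        for country in h.countries:
            for comp in h.components(country):
                assert abs(sum(u[a] for a in comp)) < 1e-10

    def test_islands_get_exactly_zero(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=1, lattice_cols=1)
        h = w.build_admin_hierarchy(cfg)
        assert w.sample_icar_effects(h, 2.0, seed=3) == {h.admin2_ids[0]: 0.0}

    def test_path_graph_covariance_matches_laplacian_pseudoinverse(self):
        # 5-node path: empirical covariance of draws must match the
        # centred pseudo-inverse oracle, and Var(u_i - u_j) must grow
        # with path distance.
        h = w.AdminHierarchy(
            countries=["P"], admin1_of={"PA": "P"},
            admin2_of={f"N{i}": "PA" for i in range(5)},
            adjacency={(f"N{i}", f"N{i+1}") for i in range(4)},
        )
        nodes = h.admin2_in_country("P")
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(10_000):
            u = w.sample_icar_effects(h, 1.0, rng)
            draws.append([u[a] for a in nodes])
        draws = np.array(draws)
        lap_pinv = np.linalg.pinv(laplacian(h.graph("P"), nodes))
        emp = np.cov(draws.T)
        assert np.allclose(emp, lap_pinv, atol=0.08)
        dist_var = {}
        for i in range(5):
            for j in range(i + 1, 5):
                dvar = lap_pinv[i, i] + lap_pinv[j, j] - 2 * lap_pinv[i, j]
                emp_var = np.var(draws[:, i] - draws[:, j])
                assert abs(emp_var - dvar) < 0.1
                dist_var.setdefault(j - i, []).append(emp_var)
        means = [np.mean(dist_var[d]) for d in sorted(dist_var)]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestSimulateSurvey:
    def small(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=2, lattice_cols=2,
                               survey_years=(2010,), seed=2)
        h = w.build_admin_hierarchy(cfg)
        pop = w.make_populations(h, seed=2)
        return cfg, h, pop

    def test_determinism_same_seed_identical_records(self):
        cfg, h, pop = self.small()
        truth = {"improved_water": flat_truth(h)}
        a = w.simulate_survey(h, pop, truth, cfg, seed=10)
        b = w.simulate_survey(h, pop, truth, cfg, seed=10)
        assert a == b
        c = w.simulate_survey(h, pop, truth, cfg, seed=11)
        assert a != c

    def test_total_households_exact(self):
        cfg, h, pop = self.small()
        truth = {"improved_water": flat_truth(h)}
        recs = w.simulate_survey(h, pop, truth, cfg, seed=1)
        total = sum(r.n["improved_water"] for r in recs)
        assert total == len(recs) * cfg.households_per_site

    def test_null_effects_give_half_coverage(self):
        cfg, h, pop = self.small()
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=3, lattice_cols=3,
                               survey_years=(2010,),
                               sites_per_admin2_per_year=40)
        h = w.build_admin_hierarchy(cfg)
        pop = w.make_populations(h, seed=3)
        recs = w.simulate_survey(h, pop, {"improved_water": flat_truth(h)},
                                 cfg, seed=4)
        k = sum(r.k["improved_water"] for r in recs)
        n = sum(r.n["improved_water"] for r in recs)
        assert abs(k / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_unit_intercept_gives_expit_one_mean_proportion(self):
        # 2,000 sites of n=25 at a logit intercept of 1: mean site
        # proportion within 0.731 +/- 0.01 (expit(1) = e/(1+e))
        cfg = SimulationConfig(n_countries=1, admin1_per_country=1,
                               lattice_rows=5, lattice_cols=5,
                               survey_years=(2012,),
                               sites_per_admin2_per_year=80)
        h = w.build_admin_hierarchy(cfg)
        pop = w.make_populations(h, seed=6)
        recs = w.simulate_survey(h, pop,
                                 {"improved_water": flat_truth(h, mu_alpha=1.0)},
                                 cfg, seed=8)
        assert len(recs) == 2000
        props = np.array([r.k["improved_water"] / r.n["improved_water"]
                          for r in recs])
        assert abs(props.mean() - 0.7311) < 0.01

    def test_unsampled_and_admin1_only_fractions(self):
        cfg = SimulationConfig(n_countries=1, admin1_per_country=2,
                               lattice_rows=3, lattice_cols=3,
                               fraction_unsampled_admin2=0.25,
                               fraction_admin1_only=0.3)
        h = w.build_admin_hierarchy(cfg)
        pop = w.make_populations(h, seed=1)
        truth = {"improved_water": flat_truth(h)}
        recs = w.simulate_survey(h, pop, truth, cfg, seed=5)
        sampled = {r.admin2 for r in recs if r.admin2 is not None}
        hidden = [r for r in recs if r.admin2 is None]
        n_unsampled_target = round(0.25 * 18)
        assert len(sampled) <= 18 - n_unsampled_target + len(hidden)
        assert 0 < len(hidden) < len(recs)

    def test_truth_sum_to_zero_invariant_enforced(self):
        cfg, h, pop = self.small()
        truth = flat_truth(h)
        truth.u[h.admin2_ids[0]] = 1.0  # breaks the component constraint
        with pytest.raises(ValueError, match="sum to zero"):
            w.simulate_survey(h, pop, {"improved_water": truth}, cfg, seed=1)
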