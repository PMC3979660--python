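import numpy as np
import pytest
from scipy.special import expit

import wssmap as w
from wssmap.hierarchy import laplacian
from wssmap.model import build_model_data, run_mcmc
from wssmap.predict import (aggregate_population, coverage_table,
                            flag_significant_areas, icar_conditional,
                            impute_unsampled_effects, predict_coverage)


def path_hierarchy(n=5, country="P"):
    return w.AdminHierarchy(
        countries=[country], admin1_of={f"{country}A": country},
        admin2_of={f"N{i}": f"{country}A" for i in range(n)},
        adjacency={(f"N{i}", f"N{i+1}") for i in range(n - 1)},
    )


class TestIcarConditional:
    def test_single_node_full_conditional_is_neighbour_mean(self):
        # node with two observed neighbours at 0.2 and 0.4, sigma^2 = 1:
        # conditional N(0.3, 0.5)
        h = path_hierarchy(3)
        lap = laplacian(h.graph("P"), ["N0", "N1", "N2"])
        mean, cov = icar_conditional(lap, np.array([0, 2]), np.array([1]),
                                     np.array([0.2, 0.4]), sigma=1.0)
        assert abs(mean[0] - 0.3) < 1e-12
        assert abs(cov[0, 0] - 0.5) < 1e-12

    def test_zero_neighbours_give_zero_mean(self):
        h = path_hierarchy(3)
        lap = laplacian(h.graph("P"), ["N0", "N1", "N2"])
        mean, _ = icar_conditional(lap, np.array([0, 2]), np.array([1]),
                                   np.zeros(2), sigma=2.0)
        assert mean[0] == 0.0

    def test_joint_conditional_mean_matches_harmonic_relaxation(self):
        # 5-node path with nodes 1 and 3 missing: the conditional mean is
        # the harmonic extension of the observed values, computed here by
        # an independent iterative neighbour-averaging oracle
        h = path_hierarchy(5)
        nodes = [f"N{i}" for i in range(5)]
        lap = laplacian(h.graph("P"), nodes)
        obs_idx, miss_idx = np.array([0, 2, 4]), np.array([1, 3])
        u_obs = np.array([0.5, -0.2, 0.9])
        mean, cov = icar_conditional(lap, obs_idx, miss_idx, u_obs, sigma=0.8)
        vals = dict(zip([nodes[i] for i in obs_idx], u_obs))
        guess = {nodes[i]: 0.0 for i in miss_idx}
        for _ in range(500):
            for node in list(guess):
                nbrs = h.neighbours(node)
                guess[node] = np.mean([vals.get(b, guess.get(b)) for b in nbrs])
        oracle = np.array([guess[nodes[i]] for i in miss_idx])
        assert np.allclose(mean, oracle, atol=1e-12)
        # covariance satisfies the defining identity cov @ (L_mm/sigma^2) = I
        L_mm = lap[np.ix_(miss_idx, miss_idx)]
        assert np.allclose(cov @ L_mm / 0.8 ** 2, np.eye(2), atol=1e-12)


class TestImputation:
    def fake_draws(self, u_vals, sigma_u=0.5, n=400, seed=0,
                   countries=("P",)):
        """Hand-built PosteriorDraws with observed admin2 N0, N2, N4."""
        nd = n
        C = len(countries)
        params = {
            "mu_alpha": np.zeros((1, nd, 2)), "mu_beta": np.zeros((1, nd, 2)),
            "alpha": np.zeros((1, nd, C, 2)), "beta": np.zeros((1, nd, C, 2)),
            "sigma_alpha": np.ones((1, nd, 2)), "sigma_beta": np.ones((1, nd, 2)),
            "sigma_u": np.full((1, nd, C), sigma_u),
            "sigma_v": np.full((1, nd), 0.3),
            "u": np.tile(np.asarray(u_vals), (1, nd, 1)),
            "v": np.zeros((1, nd, 1)),
        }
        labels = {"strata": ["rural", "urban"], "countries": list(countries),
                  "admin1": ["PA"], "admin2": ["N0", "N2", "N4"]}
        return w.PosteriorDraws(params=params, labels=labels,
                                meta={"t0": 2012, "indicator": "improved_water",
                                      "seed": seed})

    def test_imputed_moments_match_block_conditional(self):
        h = path_hierarchy(5)
        draws = self.fake_draws([0.5, -0.2, 0.9], sigma_u=0.5, n=40_000)
        imp = impute_unsampled_effects(draws, h, seed=1)
        assert imp.admin2 == ["N0", "N1", "N2", "N3", "N4"]
        assert imp.basis == {"N0": "sampled", "N2": "sampled", "N4": "sampled",
                             "N1": "imputed", "N3": "imputed"}
        nodes = [f"N{i}" for i in range(5)]
        lap = laplacian(h.graph("P"), nodes)
        mean, cov = icar_conditional(lap, np.array([0, 2, 4]),
                                     np.array([1, 3]),
                                     np.array([0.5, -0.2, 0.9]), sigma=0.5)
        got = imp.u[:, [1, 3]]
        assert np.allclose(got.mean(axis=0), mean, atol=0.01)
        assert np.allclose(np.cov(got.T), cov, atol=0.01)

    def test_component_without_observed_nodes_imputes_zero(self, caplog):
        h = w.AdminHierarchy(
            countries=["P"], admin1_of={"PA": "P"},
            admin2_of={"N0": "PA", "N2": "PA", "N4": "PA", "Z1": "PA",
                       "Z2": "PA", "N1": "PA", "N3": "PA"},
            adjacency={("N0", "N1"), ("N1", "N2"), ("N2", "N3"),
                       ("N3", "N4"), ("Z1", "Z2")},
        )
        draws = self.fake_draws([0.1, 0.0, -0.1], n=50)
        with caplog.at_level("WARNING"):
            imp = impute_unsampled_effects(draws, h, seed=0)
        assert imp.basis["Z1"] == "imputed" and imp.basis["Z2"] == "imputed"
        zi = imp.admin2.index("Z1")
        assert np.all(imp.u[:, zi] == 0.0)

    def test_country_without_admin2_data_falls_back_to_admin1(self):
        h = w.AdminHierarchy(
            countries=["P", "Q"],
            admin1_of={"PA": "P", "QA": "Q"},
            admin2_of={"N0": "PA", "N2": "PA", "N4": "PA",
                       "Q1": "QA", "Q2": "QA"},
            adjacency={("Q1", "Q2")},
        )
        draws = self.fake_draws([0.1, 0.0, -0.1], n=20, countries=("P", "Q"))
        imp = impute_unsampled_effects(draws, h, seed=0)
        assert imp.basis["Q1"] == "admin1-level"
        # and prediction then omits the spatial effect for those areas
        pred = predict_coverage(draws, h, year=2012, seed=0)
        qi = pred.admin2.index("Q1")
        assert np.all(np.abs(pred.p["rural"][:, qi] - 0.5) < 0.4)

    def test_predict_all_zero_parameters_give_half(self):
        h = path_hierarchy(5)
        draws = self.fake_draws([0.0, 0.0, 0.0], sigma_u=1e-12, n=30)
        pred = predict_coverage(draws, h, year=2012, seed=0)
        for stratum in ("rural", "urban"):
            assert np.allclose(pred.p[stratum], 0.5, atol=1e-9)

    def test_predict_alpha_two_gives_0_8808(self):
        h = path_hierarchy(5)
        draws = self.fake_draws([0.0, 0.0, 0.0], sigma_u=1e-12, n=30)
        draws.params["alpha"][..., :] = 2.0
        pred = predict_coverage(draws, h, year=2012, seed=0)
        assert np.allclose(np.round(pred.p["rural"], 4), 0.8808)

    def test_time_trend_applied_for_other_years(self):
        h = path_hierarchy(5)
        draws = self.fake_draws([0.0, 0.0, 0.0], sigma_u=1e-12, n=30)
        draws.params["beta"][..., :] = 0.1
        pred = predict_coverage(draws, h, year=2002, seed=0)
        assert np.allclose(pred.p["rural"][:, 0], expit(-1.0), atol=1e-9)


class TestAggregation:
    def pred(self, p_urban, p_rural, admin2, country="P"):
        from wssmap.predict import PredictedCoverage

        return PredictedCoverage(
            admin2=admin2, country_of=[country] * len(admin2),
            p={"urban": np.asarray(p_urban, float),
               "rural": np.asarray(p_rural, float)},
            basis={a: "sampled" for a in admin2}, year=2012,
        )

    def test_overall_weighted_mean_example(self):
        # urban 1000 at 0.9, rural 3000 at 0.5 -> overall 0.6
        pred = self.pred([[0.9]], [[0.5]], ["A"])
        pop = w.PopulationTable(p_urban={"A": 1000}, p_rural={"A": 3000})
        overall, national = aggregate_population(pred, pop)
        assert overall[0, 0] == pytest.approx(0.6, abs=1e-15)

    def test_equal_coverage_is_conserved_nationally(self):
        pred = self.pred([[0.37, 0.37]], [[0.37, 0.37]], ["A", "B"])
        pop = w.PopulationTable(p_urban={"A": 10, "B": 999},
                                p_rural={"A": 55, "B": 1})
        _, national = aggregate_population(pred, pop)
        assert national["P"]["overall"][0] == pytest.approx(0.37, abs=1e-15)

    def test_two_area_hand_computation(self):
        # (P=1, p=0) and (P=3, p=1) -> national 0.75
        pred = self.pred([[0.0, 1.0]], [[0.0, 1.0]], ["A", "B"])
        pop = w.PopulationTable(p_urban={"A": 0.5, "B": 1.5},
                                p_rural={"A": 0.5, "B": 1.5})
        _, national = aggregate_population(pred, pop)
        assert national["P"]["overall"][0] == pytest.approx(0.75, abs=1e-15)

    def test_zero_population_admin2_excluded(self, caplog):
        pred = self.pred([[0.2, 0.8]], [[0.2, 0.8]], ["A", "B"])
        pop = w.PopulationTable(p_urban={"A": 0, "B": 100},
                                p_rural={"A": 0, "B": 100})
        with caplog.at_level("WARNING"):
            overall, national = aggregate_population(pred, pop)
        assert np.isnan(overall[0, 0])
        assert national["P"]["overall"][0] == pytest.approx(0.8)

    def test_national_is_population_weighted_mean_per_draw(self, rng):
        n_draw, n_area = 50, 7
        pu = rng.uniform(0.1, 0.9, (n_draw, n_area))
        pr = rng.uniform(0.1, 0.9, (n_draw, n_area))
        admin2 = [f"A{i}" for i in range(n_area)]
        pops_u = rng.uniform(100, 1000, n_area)
        pops_r = rng.uniform(100, 1000, n_area)
        pred = self.pred(pu, pr, admin2)
        pop = w.PopulationTable(p_urban=dict(zip(admin2, pops_u)),
                                p_rural=dict(zip(admin2, pops_r)))
        overall, national = aggregate_population(pred, pop)
        tot = pops_u + pops_r
        expect = (overall * tot).sum(axis=1) / tot.sum()
        assert np.max(np.abs(national["P"]["overall"] - expect)) < 1e-12


class TestFlags:
    def test_identical_draws_not_flagged(self, rng):
        nat = rng.uniform(0.2, 0.8, 100)
        flags = flag_significant_areas(nat[:, None], nat)
        assert flags == ["none"]

    def test_all_negative_difference_flags_low(self, rng):
        nat = rng.uniform(0.4, 0.6, 200)
        area = nat - 0.1
        flags = flag_significant_areas(area[:, None], nat)
        assert flags == ["low"]

    def test_all_positive_difference_flags_high(self, rng):
        nat = rng.uniform(0.4, 0.6, 200)
        flags = flag_significant_areas(nat[:, None] + 0.2, nat)
        assert flags == ["high"]

    def test_draw_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="draw counts"):
            flag_significant_areas(np.zeros((10, 2)), np.zeros(9))


class TestEndToEnd:
    def test_coverage_table_shape_and_invariants(self, demo, fitted):
        hierarchy, populations, *_ = demo
        tab = fitted.coverage_table(populations, year=2012, seed=4)
        assert set(tab["stratum"]) == {"rural", "urban", "overall"}
        assert set(tab["flag"]) <= {"low", "high", "none"}
        assert set(tab["basis"]) <= {"sampled", "imputed", "admin1-level"}
        ok = tab.dropna(subset=["median"])
        assert ((ok["lower"] <= ok["median"]) & (ok["median"] <= ok["upper"])).all()
        assert ((ok["lower"] >= 0) & (ok["upper"] <= 1)).all()
        assert len(tab) == 54 * 3

    def test_imputed_area_interval_not_narrower_than_sampled_twin(self):
        # one country, flat truth, symmetric lattice: drop all sites of one
        # corner admin2 and compare its predicted interval with the
        # mirror-image corner that kept its data
        from tests.test_synthetic import flat_truth

        cfg = w.SimulationConfig(n_countries=1, admin1_per_country=2,
                                 lattice_rows=3, lattice_cols=3,
                                 sites_per_admin2_per_year=2)
        h = w.build_admin_hierarchy(cfg)
        admin2 = h.admin2_ids
        pop = w.PopulationTable(p_urban={a: 1000 for a in admin2},
                                p_rural={a: 1000 for a in admin2})
        truth = flat_truth(h, mu_alpha=0.5)
        recs = w.simulate_survey(h, pop, {"improved_water": truth}, cfg, seed=3)
        dropped = "C0A0D00"
        twin = "C0A1D08"
        kept = [r for r in recs if r.admin2 != dropped]
        model = w.CoverageModel.from_records(kept, h)
        res = model.fit(n_chains=2, n_iter=1500, n_warmup=700, seed=6)
        tab = res.coverage_table(pop, seed=2)
        ov = tab[tab["stratum"] == "overall"].set_index("admin2")
        assert ov.loc[dropped, "basis"] == "imputed"
        assert ov.loc[twin, "basis"] == "sampled"
        w_drop = ov.loc[dropped, "upper"] - ov.loc[dropped, "lower"]
        w_twin = ov.loc[twin, "upper"] - ov.loc[twin, "lower"]
        assert w_drop > w_twin
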