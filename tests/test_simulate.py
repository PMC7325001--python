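import numpy as np
import networkx as nx
import pytest

from rdsmm.data import SiteMeta
from rdsmm.program import count_unique_attenders
from rdsmm.rds import rds2_proportion
from rdsmm.diagnostics import recruitment_homophily
from rdsmm.simulate import (
    SimConfig,
    SimTruth,
    simulate_population,
    simulate_program_log,
    simulate_rds,
    simulate_study,
)

import datetime as dt


class TestSimConfig:
    def test_target_sample_cannot_exceed_population(self):
        with pytest.raises(ValueError):
            SimConfig(n_true=100, target_sample=200)

    def test_unknown_seed_policy_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed_policy="oldest_first")


class TestSimulatePopulation:
    def test_no_attenders_when_prevalence_zero(self):
        _, truth = simulate_population(SimConfig(n_true=200, p_true=0.0, target_sample=50, rng_seed=1))
        assert truth.n_attenders == 0

    def test_mean_realized_degree_near_target(self):
        # config-model wiring loses a little degree to removed self-loops and
        # parallel edges; the realized mean must stay within 5% of nominal
        means = []
        for rep in range(50):
            _, truth = simulate_population(
                SimConfig(n_true=1000, mean_degree=10.0, target_sample=200, rng_seed=rep)
            )
            means.append(truth.degrees.mean())
        assert np.mean(means) == pytest.approx(10.0, rel=0.05)

    def test_null_homophily_balances_cross_group_density(self):
        # With the homophily dial at zero, edges between the attender and
        # non-attender groups occur at the rate expected from the margins.
        obs_frac, exp_frac = [], []
        for rep in range(30):
            graph, truth = simulate_population(
                SimConfig(n_true=400, p_true=0.4, target_sample=100, rng_seed=100 + rep)
            )
            t = truth.attendance
            cross = sum(1 for u, v in graph.edges if t[u] != t[v])
            obs_frac.append(cross / graph.number_of_edges())
            q = t.mean()
            exp_frac.append(2 * q * (1 - q))
        assert np.mean(obs_frac) == pytest.approx(np.mean(exp_frac), abs=0.01)

    def test_homophily_rewiring_reduces_cross_edges_but_keeps_degrees(self):
        base_cfg = SimConfig(n_true=400, p_true=0.4, target_sample=100, rng_seed=5)
        hom_cfg = SimConfig(
            n_true=400, p_true=0.4, target_sample=100, rng_seed=5, trait_homophily=1.0
        )
        g0, t0 = simulate_population(base_cfg)
        g1, t1 = simulate_population(hom_cfg)
        assert np.array_equal(t0.attendance, t1.attendance)
        cross0 = sum(1 for u, v in g0.edges if t0.attendance[u] != t0.attendance[v])
        cross1 = sum(1 for u, v in g1.edges if t1.attendance[u] != t1.attendance[v])
        assert cross1 < cross0
        assert g1.number_of_edges() == g0.number_of_edges()


class TestSimulateRDS:
    def test_chain_network_with_certain_coupons_gives_path(self):
        # On a path graph with one seed at the end and certain coupon return,
        # recruitment is forced into a single chain with waves 0..target-1.
        config = SimConfig(
            n_true=30, target_sample=10, n_seeds=1, coupon_return_prob=1.0,
            max_waves=100, rng_seed=0,
        )
        graph = nx.path_graph(30)
        truth = SimTruth(
            config=config,
            degrees=np.array([graph.degree(i) for i in range(30)]),
            attendance=np.zeros(30, dtype=bool),
            largest_cc_frac=1.0,
        )
        rng = np.random.default_rng(0)
        # force the seed to node 0 (an endpoint) by drawing until we get it
        forest = None
        for trial in range(200):
            f = simulate_rds(graph, truth, config, rng=np.random.default_rng(trial))
            if f.seeds()[0].degree == 1:
                forest = f
                break
        assert forest is not None
        waves = sorted(r.wave for r in forest)
        assert waves == list(range(len(forest)))

    def test_same_seed_reproduces_identical_forest(self):
        config = SimConfig(n_true=300, target_sample=100, rng_seed=42)
        graph, truth = simulate_population(config)
        f1 = simulate_rds(graph, truth, config)
        f2 = simulate_rds(graph, truth, config)
        assert [(r.respondent_id, r.recruiter_id, r.degree) for r in f1] == [
            (r.respondent_id, r.recruiter_id, r.degree) for r in f2
        ]

    def test_degrees_are_true_network_degrees(self):
        config = SimConfig(n_true=300, target_sample=100, rng_seed=7)
        graph, truth = simulate_population(config)
        forest = simulate_rds(graph, truth, config)
        degs = sorted(r.degree for r in forest)
        assert degs[0] >= 1
        assert max(degs) <= max(dict(graph.degree()).values())

    def test_sparse_network_returns_partial_forest_with_warning(self):
        config = SimConfig(
            n_true=50, target_sample=40, n_seeds=1, max_waves=100, rng_seed=0,
            coupon_return_prob=1.0,
        )
        graph = nx.empty_graph(50)  # nobody can recruit
        truth = SimTruth(config, np.zeros(50, int), np.zeros(50, bool), 1 / 50)
        with pytest.warns(UserWarning, match="partial"):
            forest = simulate_rds(graph, truth, config)
        assert len(forest) == 1

    def test_wave_cap_respected(self):
        config = SimConfig(n_true=500, target_sample=499, max_waves=3, rng_seed=2)
        graph, truth = simulate_population(config)
        with pytest.warns(UserWarning):
            forest = simulate_rds(graph, truth, config)
        assert max(r.wave for r in forest) <= 3


class TestSimulateProgramLog:
    @pytest.fixture
    def meta(self):
        return SiteMeta("sim", dt.date(2013, 11, 1), 6)

    def test_count_closure_recovers_attenders_exactly(self, meta):
        config = SimConfig(n_true=300, p_true=0.3, target_sample=100, rng_seed=3)
        _, truth = simulate_population(config)
        visits = simulate_program_log(truth, config, meta)
        count = count_unique_attenders(visits, meta)
        assert count.m == truth.n_attenders

    def test_underage_injection_excluded_by_dedup(self, meta):
        config = SimConfig(
            n_true=300, p_true=0.3, target_sample=100, rng_seed=3, underage_frac=0.2
        )
        _, truth = simulate_population(config)
        visits = simulate_program_log(truth, config, meta)
        count = count_unique_attenders(visits, meta)
        assert count.m == truth.n_attenders
        assert count.n_dropped_underage > 0
        n_under_clients = len({v.client_id for v in visits if v.client_id.startswith("U")})
        assert n_under_clients == round(0.2 * truth.n_attenders)

    def test_visits_per_attender_tracks_rate_for_large_rate(self, meta):
        config = SimConfig(n_true=400, p_true=0.5, target_sample=100, visit_rate=20.0, rng_seed=4)
        _, truth = simulate_population(config)
        visits = simulate_program_log(truth, config, meta)
        per_head = len(visits) / truth.n_attenders
        assert per_head == pytest.approx(20.0, rel=0.05)

    def test_all_visit_dates_inside_window(self, meta):
        config = SimConfig(n_true=200, p_true=0.4, target_sample=50, rng_seed=6)
        _, truth = simulate_population(config)
        visits = simulate_program_log(truth, config, meta)
        start, end = meta.window
        assert all(start <= v.visit_date < end for v in visits)


class TestRegimes:
    def test_ideal_regime_recovers_prevalence(self):
        # degree-proportional sampling corrected by inverse-degree weights:
        # mean p_hat over replicates stays within Monte-Carlo error of truth
        phats, truths = [], []
        for rep in range(30):
            config = SimConfig(n_true=500, p_true=0.3, max_waves=100, rng_seed=700 + rep)
            forest, _, _, truth = simulate_study(config)
            phats.append(rds2_proportion(forest, "attended_program").p_hat)
            truths.append(truth.realized_prevalence)
        err = np.mean(phats) - np.mean(truths)
        mc_se = np.std(np.array(phats) - np.array(truths), ddof=1) / np.sqrt(len(phats))
        assert abs(err) < 3 * mc_se + 0.005

    def test_homophily_dial_is_monotone(self):
        means = []
        for h in (0.0, 0.5, 1.0):
            vals = []
            for rep in range(25):
                config = SimConfig(
                    n_true=400, p_true=0.3, target_sample=150, max_waves=100,
                    trait_homophily=h, rng_seed=900 + rep,
                )
                forest, _, _, _ = simulate_study(config)
                vals.append(recruitment_homophily(forest, "attended_program").h)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
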