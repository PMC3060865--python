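"""Distances, random/minimal networks, essentiality and the closed forms."""

import numpy as np
import pytest

from genospace.fba import Genotype, get_model
from genospace.genotype_space import (Demand, distance, essential_reactions,
                                      fit_essential_decline, minimal_network,
                                      predicted_dmax, predicted_robustness,
                                      random_demand, random_viable_network,
                                      robustness, superessential_reactions)

from conftest import enumerate_minimal_sets


class TestDistance:
    def test_identical_networks_have_distance_zero(self, unique_case):
        u = unique_case.universe
        g = Genotype.from_ids(u, u.reaction_ids[:4])
        assert distance(g, g) == 0.0

    def test_one_substitution_among_three(self, unique_case):
        u = unique_case.universe
        ids = u.reaction_ids
        g1 = Genotype.from_ids(u, ids[:3])            # {A, B, C}
        g2 = Genotype.from_ids(u, ids[:2] + ids[3:4])  # {A, B, D}
        assert distance(g1, g2) == pytest.approx(1.0 / 3.0)

    def test_disjoint_networks_have_distance_one(self, decoy_case):
        u = decoy_case.universe
        g1 = Genotype.from_ids(u, u.reaction_ids[:4])
        g2 = Genotype.from_ids(u, u.reaction_ids[4:10])
        assert distance(g1, g2) == 1.0

    def test_symmetry_and_size_normalization(self, decoy_case):
        u = decoy_case.universe
        rng = np.random.default_rng(0)
        for _ in range(20):
            g1 = Genotype(rng.random(u.size) < 0.5, u.key)
            g2 = Genotype(rng.random(u.size) < 0.3, u.key)
            d = distance(g1, g2)
            assert d == distance(g2, g1)
            assert 0.0 <= d <= 1.0
            assert (d == 0.0) == (g1 == g2)

    def test_cross_universe_comparison_rejected(self, unique_case, decoy_case):
        g1 = Genotype.empty(unique_case.universe)
        g2 = Genotype.empty(decoy_case.universe)
        with pytest.raises(ValueError, match="different universes"):
            distance(g1, g2)


class TestRandomViableNetwork:
    def test_target_size_equal_to_universe_keeps_everything(self, unique_case):
        u = unique_case.universe
        demand = Demand(unique_case.demand)
        g = random_viable_network(u, demand, u.size, np.random.default_rng(0))
        assert g == Genotype.full(u)

    def test_reaches_exact_size_and_meets_demand(self, shared_trunk_case):
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        model = get_model(u)
        for seed in range(5):
            g = random_viable_network(u, demand, 9, np.random.default_rng(seed))
            assert g.size == 9
            assert model.meets_demand(g, demand)

    def test_seed_determinism(self, shared_trunk_case):
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        g1 = random_viable_network(u, demand, 8, np.random.default_rng(5))
        g2 = random_viable_network(u, demand, 8, np.random.default_rng(5))
        assert g1 == g2

    def test_target_below_minimal_regime_fails(self, unique_case):
        u = unique_case.universe
        demand = Demand(unique_case.demand)
        n_min = unique_case.expected_n_min
        with pytest.raises(ValueError, match="minimal regime"):
            random_viable_network(u, demand, n_min - 1,
                                  np.random.default_rng(0))

    def test_often_viable_beyond_the_demand(self, shared_trunk_case):
        # networks required on one source usually gain others for free
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        model = get_model(u)
        extra = [int(model.phenotype(random_viable_network(
            u, demand, 12, np.random.default_rng(s))).sum())
            for s in range(8)]
        assert np.mean(extra) > len(demand)


class TestMinimalNetwork:
    def test_unique_minimal_network_found_for_any_seed(self, unique_case):
        u = unique_case.universe
        demand = Demand(unique_case.demand)
        (expected,) = unique_case.expected_minimal_sets
        for seed in range(6):
            g = minimal_network(u, demand, np.random.default_rng(seed))
            assert frozenset(g.ids(u)) == expected

    def test_single_deletions_all_break_viability(self, shared_trunk_case):
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        model = get_model(u)
        g = minimal_network(u, demand, np.random.default_rng(1), verify=False)
        for idx in np.flatnonzero(g.bits):
            assert not model.meets_demand(g.with_bit(idx, False), demand)

    def test_all_and_only_true_minimal_sets_discovered(self, parallel_case):
        u = parallel_case.universe
        demand = Demand(parallel_case.demand)
        truth_sets = enumerate_minimal_sets(u, demand)
        found = {frozenset(minimal_network(
            u, demand, np.random.default_rng(seed)).ids(u))
            for seed in range(60)}
        assert found == truth_sets
        assert truth_sets == parallel_case.expected_minimal_sets


class TestEssentialityAndRobustness:
    def test_every_reaction_of_a_minimal_network_is_essential(
            self, shared_trunk_case):
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        g = minimal_network(u, demand, np.random.default_rng(2))
        assert essential_reactions(g, u, demand) == frozenset(g.ids(u))
        assert robustness(g, u, demand) == 0.0

    def test_adding_a_parallel_route_makes_the_partner_inessential(
            self, parallel_case):
        u = parallel_case.universe
        truth = parallel_case.truth
        demand = Demand(parallel_case.demand)
        g = minimal_network(u, demand, np.random.default_rng(0))
        present = set(g.ids(u))
        # find a redundant step and add the alternative route's reaction
        for eid in truth.demand_edges(demand.sources):
            routes = truth.edges[eid]
            if len(routes) < 2:
                continue
            (used,) = [r for r in routes if set(r) <= present]
            (alt,) = [r for r in routes if r != used][:1]
            bigger = g
            for rid in alt:
                bigger = bigger.with_bit(u.index_of(rid), True)
            ess = essential_reactions(bigger, u, demand)
            assert not (set(used) & ess)
            return
        pytest.fail("no redundant step found")

    def test_robustness_counts_inessential_fraction(self, decoy_case):
        u = decoy_case.universe
        demand = Demand(decoy_case.demand)
        g = random_viable_network(u, demand, 10, np.random.default_rng(4))
        ess = essential_reactions(g, u, demand)
        assert robustness(g, u, demand) == pytest.approx(1 - len(ess) / 10)

    def test_full_phenotype_flag_protects_undemanded_sources(
            self, shared_trunk_case):
        u = shared_trunk_case.universe
        truth = shared_trunk_case.truth
        both = Demand(tuple(truth.leaf_sources))
        one = Demand((truth.leaf_sources[0],))
        g = minimal_network(u, both, np.random.default_rng(3))
        ess_demand = essential_reactions(g, u, one)
        ess_full = essential_reactions(g, u, one, full_phenotype=True)
        # the second leaf's pathway only matters under the literal definition
        assert ess_demand < ess_full
        assert ess_full == frozenset(g.ids(u))


class TestSuperessential:
    def test_unique_minimal_network_is_all_superessential(self, unique_case):
        u = unique_case.universe
        demand = Demand(unique_case.demand)
        stats = superessential_reactions(u, demand, 10,
                                         np.random.default_rng(0))
        assert stats.r_se == stats.n_min == unique_case.expected_n_min
        assert stats.superessential == unique_case.expected_superessential

    def test_disjoint_routes_empty_the_intersection(self, parallel_case):
        u = parallel_case.universe
        demand = Demand(parallel_case.demand)
        stats = superessential_reactions(u, demand, 60,
                                         np.random.default_rng(1))
        assert stats.r_se == 0

    def test_estimate_non_increasing_in_replicates(self, shared_trunk_case):
        u = shared_trunk_case.universe
        demand = Demand(shared_trunk_case.demand)
        rng = np.random.default_rng(2)
        stats = superessential_reactions(u, demand, 40, rng)
        sizes = []
        common = stats.networks[0].bits.copy()
        for k, g in enumerate(stats.networks):
            common &= g.bits
            sizes.append(int(common.sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == stats.r_se
        assert stats.r_se <= min(stats.sizes) and stats.n_min >= stats.r_se

    def test_matches_constructive_truth(self, shared_trunk_case):
        stats = superessential_reactions(
            shared_trunk_case.universe, Demand(shared_trunk_case.demand),
            50, np.random.default_rng(3))
        assert stats.superessential == shared_trunk_case.expected_superessential


class TestClosedForms:
    def test_noiseless_linear_decline_recovered_exactly(self):
        samples = [(n, 20 - 0.05 * n) for n in (20, 60, 100, 140)]
        fit = fit_essential_decline(samples)
        assert fit.m == pytest.approx(0.05)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_essential_count_gives_zero_slope(self):
        fit = fit_essential_decline([(20, 7.0), (40, 7.0), (60, 7.0)])
        assert fit.m == pytest.approx(0.0)

    def test_identical_sizes_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_essential_decline([(50, 4.0), (50, 6.0)])

    def test_negative_slope_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            fit_essential_decline([(20, 5.0), (40, 8.0), (60, 11.0)])

    def test_predicted_robustness_anchors(self):
        assert predicted_robustness(14, 14, 0.3) == pytest.approx(0.0)
        assert predicted_robustness(28, 14, 0.0) == pytest.approx(0.5)
        with pytest.warns(UserWarning, match="model domain"):
            predicted_robustness(10, 14, 0.1)

    def test_predicted_dmax_anchors(self):
        assert predicted_dmax(100, 0) == 1.0
        assert predicted_dmax(100, 25) == pytest.approx(0.75)

    def test_slope_recovery_from_noisy_simulation(self):
        rng = np.random.default_rng(8)
        m_true, n_min = 0.08, 14.0
        n_vals = np.repeat([20, 60, 100, 140, 180], 20)
        r_vals = n_min * (1 + m_true) - m_true * n_vals + rng.normal(0, 1.0, n_vals.size)
        fit = fit_essential_decline(list(zip(n_vals, r_vals)))
        lo, hi = fit.ci95
        assert lo <= m_true <= hi


class TestDemand:
    def test_random_demand_distinct_and_sized(self, shared_trunk_case):
        u = shared_trunk_case.universe
        d = random_demand(u, 3, np.random.default_rng(0))
        assert d.S == 3 and len(set(d.sources)) == 3
        assert all(s in u.sources for s in d)

    def test_out_of_range_demand_size(self, shared_trunk_case):
        u = shared_trunk_case.universe
        with pytest.raises(ValueError):
            random_demand(u, 0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            random_demand(u, len(u.sources) + 1, np.random.default_rng(0))
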