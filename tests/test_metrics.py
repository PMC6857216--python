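"""Network statistics against their definitions, closed forms, and oracles."""

import itertools
import random

import networkx as nx
import pytest

import egonet.metrics as m
from egonet.metrics import (
    NA,
    HOMOPHILIC,
    NOT_HOMOPHILIC,
    HomophilySummary,
)
from egonet.model import UnknownActorError

from conftest import (
    brute_force_betweenness,
    complete_network,
    complete_pairs,
    make_network,
    path_network,
    random_network,
    star_network,
)


def to_nx(net):
    g = nx.Graph()
    g.add_nodes_from(net.actor_ids)
    g.add_edges_from(net.ties)
    return g


class TestDensity:
    def test_84_directed_ties_give_0_76(self):
        ids = ["ego"] + [f"a{i}" for i in range(1, 11)]
        net = make_network(10, complete_pairs(ids)[:42])
        assert m.round2(m.density(net)) == 0.76

    def test_complete_network_density_1(self):
        assert m.density(complete_network(10)) == 1.0

    def test_56_directed_ties_give_0_51(self):
        ids = ["ego"] + [f"a{i}" for i in range(1, 11)]
        net = make_network(10, complete_pairs(ids)[:28])
        assert net.directed_tie_count == 56
        assert m.round2(m.density(net)) == 0.51

    def test_edgeless_density_0(self):
        assert m.density(make_network(10, [])) == 0.0

    def test_density_requires_two_actors(self):
        with pytest.raises(ValueError):
            m.density(make_network(0, []))


class TestDegree:
    def test_ego_tied_to_all_alters_has_degree_10(self):
        assert m.actor_degree(complete_network(10), "ego") == 10

    def test_isolated_actor_degree_0(self):
        assert m.actor_degree(make_network(5, [("a1", "a2")]), "a3") == 0

    def test_star_center_degree(self):
        assert m.actor_degree(star_network(4), "ego") == 4

    def test_unknown_actor_rejected(self):
        with pytest.raises(UnknownActorError):
            m.actor_degree(star_network(3), "nobody")

    def test_average_degree_84_ties_11_actors(self):
        ids = ["ego"] + [f"a{i}" for i in range(1, 11)]
        net = make_network(10, complete_pairs(ids)[:42])
        assert m.round2(m.average_degree(net)) == 7.64

    def test_average_degree_complete_is_10(self):
        assert m.average_degree(complete_network(10)) == 10.0

    def test_average_degree_edgeless_is_0(self):
        assert m.average_degree(make_network(10, [])) == 0.0


class TestBetweenness:
    def test_complete_graph_all_zero(self):
        assert all(v == 0.0 for v in m.betweenness_raw(complete_network(10)).values())

    def test_three_node_path_middle_is_1(self):
        bw = m.betweenness_raw(path_network(2))
        assert bw["a1"] == 1.0 and bw["ego"] == 0.0 and bw["a2"] == 0.0

    def test_star_center_closed_form(self):
        # centre of an 11-node star mediates all (n-1)(n-2)/2 = 45 pairs
        assert m.betweenness_raw(star_network(10))["ego"] == 45.0

    def test_normalized_star_center_is_100(self):
        for n_alters in (4, 7, 10):
            assert m.betweenness_normalized(star_network(n_alters))["ego"] == 100.0

    def test_normalized_three_node_path_middle_is_100(self):
        assert m.betweenness_normalized(path_network(2))["a1"] == 100.0

    def test_normalized_needs_three_actors(self):
        with pytest.raises(ValueError):
            m.betweenness_normalized(make_network(1, [("ego", "a1")]))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        """Brandes accumulation == brute-force geodesic enumeration, n <= 8."""
        rng = random.Random(seed)
        net = random_network(seed, rng.randint(3, 8), rng.choice([0.15, 0.3, 0.6, 0.9]))
        ours = m.betweenness_raw(net)
        oracle = brute_force_betweenness(net)
        for v in net.actor_ids:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_cross_check(self, seed):
        net = random_network(1000 + seed, 8, 0.4)
        ref = nx.betweenness_centrality(to_nx(net), normalized=False)
        ours = m.betweenness_raw(net)
        for v in net.actor_ids:
            assert ours[v] == pytest.approx(ref[v], abs=1e-9)


class TestCentralization:
    def test_star_is_100(self):
        assert m.degree_centralization(star_network(10)) == 100.0

    def test_complete_is_0(self):
        for n_alters in (2, 5, 10):
            assert m.degree_centralization(complete_network(n_alters)) == 0.0

    def test_four_node_path_hand_value(self):
        # degrees 1,2,2,1; sum(cmax - c) = 2; denominator (n-1)(n-2) = 6
        assert m.degree_centralization(path_network(3)) == pytest.approx(100 * 2 / 6)

    def test_needs_three_actors(self):
        with pytest.raises(ValueError):
            m.degree_centralization(make_network(1, [("ego", "a1")]))


class TestEIIndex:
    def _mixed_network(self):
        """5 actors: ego,a1,a2 Hausa; a3,a4 Others; E=3, I=1 for Hausa."""
        return make_network(
            4,
            [("ego", "a1"), ("ego", "a3"), ("a1", "a4"), ("a2", "a3")],
            alter_overrides={"a3": {"ethnicity": "Others"}, "a4": {"ethnicity": "Others"}},
        )

    def test_direct_count_fixture_gives_half(self):
        res = m.group_ei_index(self._mixed_network(), "ethnicity", "Hausa")
        assert (res.external, res.internal) == (3, 1)
        assert res.ei_index == 0.5

    def test_all_external_ties_give_plus_1(self):
        net = make_network(
            2,
            [("ego", "a1"), ("ego", "a2")],
            alter_overrides={"a1": {"ethnicity": "Others"}, "a2": {"ethnicity": "Others"}},
        )
        assert m.group_ei_index(net, "ethnicity", "Hausa").ei_index == 1.0

    def test_all_internal_ties_give_minus_1(self):
        net = make_network(2, [("ego", "a1"), ("a1", "a2")])
        assert m.group_ei_index(net, "ethnicity", "Hausa").ei_index == -1.0

    def test_empty_group_is_na_rendered_as_dash(self):
        net = make_network(2, [("ego", "a1")])
        res = m.group_ei_index(net, "ethnicity", "Others")
        assert res.is_na and res.render() == "–"

    def test_ties_touching_na_actors_are_excluded(self):
        net = make_network(
            3,
            [("ego", "a1"), ("a1", "a2"), ("a2", "a3")],
            alter_overrides={"a2": {"marital_status": "single"}},
        )
        res = m.group_ei_index(net, "marriage_type", "monogamy")
        # only ego-a1 counted: both monogamous -> internal
        assert (res.external, res.internal) == (0, 1)
        assert res.ei_index == -1.0

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            m.group_ei_index(make_network(1, []), "ethnicity", "Yoruba")

    @pytest.mark.parametrize("seed", range(20))
    def test_defined_index_always_within_bounds(self, seed):
        rng = random.Random(seed)
        overrides = {
            f"a{i}": {"ethnicity": rng.choice(["Hausa", "Others"])} for i in range(1, 8)
        }
        net = random_network(seed, 8, 0.4)
        net = make_network(7, net.ties, alter_overrides=overrides)
        for group in ("Hausa", "Others"):
            res = m.group_ei_index(net, "ethnicity", group)
            if not res.is_na:
                assert -1.0 <= res.ei_index <= 1.0


class TestActorHomophily:
    def test_majority_same_category_is_homophilic(self):
        overrides = {f"a{i}": {"ethnicity": "Others"} for i in (8, 9, 10)}
        net = make_network(
            10, [("ego", f"a{i}") for i in range(1, 11)], alter_overrides=overrides
        )
        # 7 of ego's 10 ties are to fellow Hausas
        assert m.actor_homophily(net, "ego", "ethnicity") == HOMOPHILIC

    def test_exactly_half_is_not_homophilic(self):
        overrides = {"a3": {"ethnicity": "Others"}, "a4": {"ethnicity": "Others"}}
        net = make_network(
            4, [("ego", f"a{i}") for i in range(1, 5)], alter_overrides=overrides
        )
        assert m.actor_homophily(net, "ego", "ethnicity") == NOT_HOMOPHILIC

    def test_isolated_actor_is_na(self):
        assert m.actor_homophily(make_network(3, []), "a1", "ethnicity") == NA

    def test_na_attribute_is_na(self):
        net = make_network(
            3,
            [("a1", "a2")],
            alter_overrides={"a1": {"marital_status": "single"}},
        )
        assert m.actor_homophily(net, "a1", "marriage_type") == NA

    def test_threshold_parameter_shifts_the_rule(self):
        overrides = {"a3": {"ethnicity": "Others"}, "a4": {"ethnicity": "Others"}}
        net = make_network(
            4, [("ego", f"a{i}") for i in range(1, 5)], alter_overrides=overrides
        )
        # ties split 2/2: E-I = 0, homophilic only under a lenient threshold
        assert m.actor_homophily(net, "ego", "ethnicity", threshold=0.1) == HOMOPHILIC


class TestHomophilySummary:
    def test_aggregation_arithmetic_from_counts(self):
        s = HomophilySummary("ethnicity", 20, 175, 20, 200)
        assert s.total_count == 195
        assert (s.ego_pct, s.alter_pct, s.total_pct) == (100.0, 87.5, 88.6)
        s2 = HomophilySummary("cbdic_use", 17, 162, 20, 200)
        assert (s2.total_count, s2.total_pct) == (179, 81.4)

    def test_no_homophilic_actors(self, small_collection):
        from egonet.model import StudyCollection

        # edgeless networks: everyone NA -> zero counts, zero percent
        nets = [make_network(3, [], label=f"N{i}") for i in range(3)]
        s = m.homophily_summary(StudyCollection(networks=nets), "ethnicity")
        assert s.total_count == 0 and s.total_pct == 0.0

    def test_counts_computed_from_collection(self):
        from egonet.model import StudyCollection

        overrides = {"a2": {"ethnicity": "Others"}}
        net = make_network(2, [("ego", "a1"), ("ego", "a2")], alter_overrides=overrides)
        s = m.homophily_summary(StudyCollection(networks=[net]), "ethnicity")
        # ego: 1 internal 1 external -> not homophilic; a1: 1/1 internal ->
        # homophilic; a2: its only tie is external -> not
        assert (s.ego_count, s.alter_count) == (0, 1)
        assert s.n_egos == 1 and s.n_alters == 2


class TestNetworkSummary:
    def test_dense_row_matches_printed_identities(self):
        ids = ["ego"] + [f"a{i}" for i in range(1, 11)]
        net = make_network(10, complete_pairs(ids)[:42])
        row = m.network_summary(net).rounded()
        assert row["ties"] == 84
        assert row["density"] == 0.76
        assert row["average_degree"] == 7.64

    def test_complete_network_row(self):
        row = m.network_summary(complete_network(10)).rounded()
        assert row["density"] == 1.0
        assert row["ego_degree"] == 10
        assert row["average_degree"] == 10.0
        assert row["ego_nbetweenness"] == 0.0
        assert row["average_nbetweenness"] == 0.0
        assert row["centralization_pct"] == 0.0
        assert row["cbdic_users"] == 11

    def test_two_actor_network_centralization_is_na(self):
        row = m.network_summary(make_network(1, [("ego", "a1")]))
        assert row.density == 1.0
        assert row.degree_centralization is None


class TestInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_relabelling_leaves_metrics_invariant(self, seed):
        net = random_network(seed, 8, 0.45)
        ids = net.actor_ids
        mapping = {i: f"x{k}" for k, i in enumerate(reversed(ids))}
        relabelled = net.relabelled(mapping)
        assert m.density(net) == pytest.approx(m.density(relabelled))
        assert m.average_degree(net) == pytest.approx(m.average_degree(relabelled))
        assert m.degree_centralization(net) == pytest.approx(
            m.degree_centralization(relabelled)
        )
        bw, bw2 = m.betweenness_raw(net), m.betweenness_raw(relabelled)
        for old, new in mapping.items():
            assert bw[old] == pytest.approx(bw2[new])

    @pytest.mark.parametrize("n_alters", [2, 4, 7, 10])
    def test_complete_graph_limits(self, n_alters):
        net = complete_network(n_alters)
        assert m.density(net) == 1.0
        assert m.degree_centralization(net) == 0.0
        assert all(v == 0.0 for v in m.betweenness_raw(net).values())

    @pytest.mark.parametrize("seed", range(10))
    def test_denominator_identity(self, seed):
        net = random_network(seed + 500, 11, 0.6)
        assert m.average_degree(net) * 11 == pytest.approx(net.directed_tie_count)
        assert 110 * m.density(net) == pytest.approx(net.directed_tie_count)

    def test_rounding_is_half_away_from_zero(self):
        assert m.round2(0.455) == 0.46
        assert m.round2(0.8545) == 0.85
        assert m.round2(-0.125) == -0.13
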