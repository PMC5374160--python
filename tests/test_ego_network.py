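import json
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egodyn import (
    Alter,
    CultureLabel,
    EgoNetwork,
    NetworkValidationError,
    RelationalDomain,
    generate_network,
    group_size,
    interclass_tie_weight,
    read_network,
    same_culture_degree,
    write_edge_list,
    write_network,
)

A = CultureLabel.CULTURE_A
B = CultureLabel.CULTURE_B


class TestEgoNetworkInvariants:
    def test_self_tie_rejected(self):
        with pytest.raises(NetworkValidationError, match="self-tie"):
            EgoNetwork(alters=(Alter(0, A), Alter(1, A)), ties=frozenset({(1, 1)}))

    def test_out_of_range_tie_rejected(self):
        with pytest.raises(NetworkValidationError, match="unknown alter"):
            EgoNetwork(alters=(Alter(0, A), Alter(1, A)), ties=frozenset({(0, 5)}))

    def test_ties_normalized_smaller_first(self):
        net = EgoNetwork(alters=(Alter(0, A), Alter(1, B)), ties=frozenset({(1, 0)}))
        assert net.sorted_ties() == [(0, 1)]

    def test_non_contiguous_ids_rejected(self):
        with pytest.raises(NetworkValidationError, match="roster order"):
            EgoNetwork(alters=(Alter(0, A), Alter(2, A)), ties=frozenset())


class TestGenerateNetwork:
    def test_complete_graph_same_culture_degree(self):
        net = generate_network(8, 4, 28, rng=np.random.default_rng(7))
        assert net.n_ties == 28
        # complete graph forces same-culture degree = group size - 1
        for alter in net.alters:
            assert same_culture_degree(net, alter.id) == 3

    def test_degenerate_empty(self):
        net = generate_network(8, 0, 0, rng=np.random.default_rng(7))
        assert net.n_ties == 0
        assert all(a.culture is B for a in net.alters)

    def test_requested_counts_by_enumeration(self):
        net = generate_network(8, 2, 12, rng=np.random.default_rng(11))
        assert len(set(net.ties)) == 12
        assert all(i < j and i != j for i, j in net.ties)
        assert group_size(net, A) == 2
        assert group_size(net, B) == 6

    @pytest.mark.parametrize("seed", range(100))
    def test_exact_counts_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(0, 9))
        n_ties = int(rng.integers(0, 29))
        net = generate_network(8, n_a, n_ties, rng=rng)
        assert net.n_ties == n_ties
        assert group_size(net, A) == n_a
        assert group_size(net, B) == 8 - n_a

    def test_deterministic_given_seed(self):
        net1 = generate_network(8, 3, 14, rng=np.random.default_rng(99))
        net2 = generate_network(8, 3, 14, rng=np.random.default_rng(99))
        assert net1 == net2

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(n_alters=8, n_culture_a=9, n_ties=0), "n_culture_a"),
            (dict(n_alters=8, n_culture_a=0, n_ties=29), "n_ties"),
            (dict(n_alters=0, n_culture_a=0, n_ties=0), "n_alters"),
            (dict(n_alters=8, n_culture_a=-1, n_ties=0), "n_culture_a"),
        ],
    )
    def test_bounds_errors_name_parameter(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            generate_network(rng=np.random.default_rng(0), **kwargs)

    def test_domain_assignment_halves(self):
        net = generate_network(8, 4, 0, domains=True, rng=np.random.default_rng(1))
        assert [a.domain for a in net.alters[:4]] == [RelationalDomain.FRIEND] * 4
        assert [a.domain for a in net.alters[4:]] == [RelationalDomain.COLLEAGUE] * 4

    def test_tie_placement_covers_pair_space(self):
        # over many draws every one of the 28 pairs appears
        seen = set()
        for seed in range(200):
            net = generate_network(8, 4, 4, rng=np.random.default_rng(seed))
            seen |= set(net.ties)
        assert seen == set(combinations(range(8), 2))


class TestSameCultureDegree:
    def test_tie_free_is_zero(self, tie_free_all_a):
        for alter in tie_free_all_a.alters:
            assert same_culture_degree(tie_free_all_a, alter.id) == 0

    def test_manual_count(self, tiny_triangle):
        assert same_culture_degree(tiny_triangle, 0) == 1
        assert same_culture_degree(tiny_triangle, 1) == 1
        assert same_culture_degree(tiny_triangle, 2) == 0

    def test_unknown_id(self, tiny_triangle):
        with pytest.raises(KeyError):
            same_culture_degree(tiny_triangle, 42)

    @pytest.mark.parametrize("seed", range(20))
    def test_degree_sum_twice_within_culture_ties(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_network(8, int(rng.integers(0, 9)), int(rng.integers(0, 29)), rng=rng)
        within = sum(
            1
            for i, j in net.ties
            if net.alters[i].culture is net.alters[j].culture
        )
        total = sum(same_culture_degree(net, a.id) for a in net.alters)
        assert total == 2 * within


class TestGroupSize:
    def test_four_a(self, complete_half_half):
        assert group_size(complete_half_half, A) == 4

    def test_all_b(self):
        net = generate_network(8, 0, 0, rng=np.random.default_rng(0))
        assert group_size(net, A) == 0

    @pytest.mark.parametrize("n_a", range(9))
    def test_range_and_complement(self, n_a):
        net = generate_network(8, n_a, 0, rng=np.random.default_rng(0))
        assert 0 <= group_size(net, A) <= 8
        assert group_size(net, A) + group_size(net, B) == 8


class TestInterclassTieWeight:
    def test_no_cross_ties_zero(self, tie_free_all_a):
        assert interclass_tie_weight(tie_free_all_a, {0, 1}, {2, 3}) == 0.0

    def test_complete_bipartite_saturates(self):
        ties = {(0, 2), (0, 3), (1, 2), (1, 3)}
        net = EgoNetwork(
            alters=tuple(Alter(i, A) for i in range(4)), ties=frozenset(ties)
        )
        assert interclass_tie_weight(net, {0, 1}, {2, 3}) == 1.0

    def test_printed_formula(self):
        # |F|=3, |C|=2, e=3 -> 3/6 = 0.5
        ties = {(0, 3), (1, 4), (2, 3)}
        net = EgoNetwork(
            alters=tuple(Alter(i, A) for i in range(5)), ties=frozenset(ties)
        )
        assert interclass_tie_weight(net, {0, 1, 2}, {3, 4}) == pytest.approx(0.5)

    def test_overlap_raises(self, complete_half_half):
        with pytest.raises(ValueError, match="disjoint"):
            interclass_tie_weight(complete_half_half, {0, 1}, {1, 2})

    def test_empty_group_is_nan_sentinel(self, complete_half_half):
        assert math.isnan(interclass_tie_weight(complete_half_half, set(), {1, 2}))

    @pytest.mark.parametrize("seed", range(30))
    def test_bounds_and_saturation_iff_complete(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_network(8, 4, int(rng.integers(0, 29)), rng=rng)
        f, c = {0, 1, 2}, {3, 4}
        w = interclass_tie_weight(net, f, c)
        assert 0.0 <= w <= 1.0
        cross = {
            t
            for t in net.ties
            if (t[0] in f and t[1] in c) or (t[0] in c and t[1] in f)
        }
        assert (w == 0.0) == (len(cross) == 0)
        assert (w == 1.0) == (len(cross) == len(f) * len(c))


class TestSerialization:
    def test_round_trip_complete(self, complete_half_half, tmp_path):
        path = tmp_path / "net.json"
        write_network(path, complete_half_half)
        assert read_network(path) == complete_half_half

    def test_round_trip_with_domains(self, tmp_path):
        net = generate_network(8, 3, 9, domains=True, rng=np.random.default_rng(5))
        path = tmp_path / "net.json"
        write_network(path, net)
        assert read_network(path) == net

    def test_self_tie_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps(
                {
                    "alters": [{"id": i, "culture": "A"} for i in range(8)],
                    "ties": [[3, 3]],
                }
            )
        )
        with pytest.raises(NetworkValidationError, match="self-tie"):
            read_network(path)

    def test_too_many_ties_rejected(self, tmp_path):
        # 29 distinct "ties" on 8 alters can only exist with an invalid pair
        ties = list(map(list, combinations(range(8), 2))) + [[0, 8]]
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps(
                {
                    "alters": [{"id": i, "culture": "B"} for i in range(8)],
                    "ties": ties,
                }
            )
        )
        with pytest.raises(NetworkValidationError):
            read_network(path)

    def test_duplicate_tie_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps(
                {
                    "alters": [{"id": i, "culture": "A"} for i in range(3)],
                    "ties": [[0, 1], [1, 0]],
                }
            )
        )
        with pytest.raises(NetworkValidationError, match="duplicate"):
            read_network(path)

    def test_bad_culture_label(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps({"alters": [{"id": 0, "culture": "Z"}], "ties": []})
        )
        with pytest.raises(NetworkValidationError, match="culture"):
            read_network(path)

    def test_ties_written_sorted(self, tmp_path):
        net = generate_network(8, 4, 15, rng=np.random.default_rng(3))
        path = tmp_path / "net.json"
        write_network(path, net)
        payload = json.loads(path.read_text())
        assert payload["ties"] == sorted(payload["ties"])

    def test_edge_list_export(self, tmp_path, tiny_triangle):
        edges, alters = tmp_path / "edges.csv", tmp_path / "alters.csv"
        write_edge_list(tiny_triangle, edges, alters)
        assert edges.read_text().splitlines() == ["source,target", "0,1", "0,2"]
        assert alters.read_text().splitlines()[0] == "id,culture,domain"


@given(
    n_a=st.integers(min_value=0, max_value=8),
    n_ties=st.integers(min_value=0, max_value=28),
    seed=st.integers(min_value=0, max_value=2**32 - 1),
)
@settings(max_examples=60, deadline=None)
def test_generated_network_always_valid(n_a, n_ties, seed):
    net = generate_network(8, n_a, n_ties, rng=np.random.default_rng(seed))
    assert net.n_ties == n_ties
    assert group_size(net, A) == n_a
    assert all(0 <= same_culture_degree(net, a.id) <= 7 for a in net.alters)
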