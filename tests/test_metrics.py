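import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taskcomm as tc
from conftest import random_filtered_matrix


def brute_force_z(W, labels):
    z = np.zeros(len(labels))
    for m in set(labels):
        members = [i for i in range(len(labels)) if labels[i] == m]
        k = [sum(W[i][j] for j in members) for i in members]
        mu = sum(k) / len(k)
        sigma = (sum((v - mu) ** 2 for v in k) / len(k)) ** 0.5
        for i, v in zip(members, k):
            z[i] = (v - mu) / sigma if sigma > 0 else 0.0
    return z


def brute_force_pc(W, labels):
    pc = np.zeros(len(labels))
    for i in range(len(labels)):
        k_i = sum(W[i])
        if k_i == 0:
            continue
        acc = 0.0
        for m in set(labels):
            k_im = sum(W[i][j] for j in range(len(labels)) if labels[j] == m)
            acc += (k_im / k_i) ** 2
        pc[i] = 1.0 - acc
    return pc


class TestWithinModuleZ:
    def test_uniform_clique_degenerates_to_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        z = tc.within_module_z(w, np.ones(5, dtype=int))
        np.testing.assert_array_equal(z, 0.0)

    def test_hand_standardization(self):
        w = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
        z = tc.within_module_z(w, np.array([1, 1, 1]))
        # within-degrees {1, 2, 3}: population sd sqrt(2/3), z = (d - 2)/sd
        np.testing.assert_allclose(z, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2 / 3), atol=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            net = random_filtered_matrix(20, seed=seed)
            labels = rng.integers(1, 5, 20)
            z = tc.within_module_z(net, labels)
            np.testing.assert_allclose(z, brute_force_z(net.weights, labels), atol=1e-12)

    def test_zero_mean_unit_sd_within_modules(self):
        net = random_filtered_matrix(30, seed=1)
        labels = np.repeat([1, 2, 3], 10)
        z = tc.within_module_z(net, labels)
        for m in (1, 2, 3):
            zm = z[labels == m]
            assert abs(zm.mean()) < 1e-10 and abs(zm.std() - 1.0) < 1e-10


class TestParticipation:
    def test_all_weight_in_own_module_gives_zero(self):
        w = np.ones((4, 4)) - np.eye(4)
        pc, _ = tc.participation(w, np.ones(4, dtype=int))
        np.testing.assert_array_equal(pc, 0.0)

    def test_even_split_closed_form(self):
        for m in range(2, 7):
            n = m + 1
            w = np.zeros((n, n))
            w[0, 1:] = w[1:, 0] = 1.0  # hub splits evenly over m other modules
            labels = np.arange(n)
            labels[0] = 1
            pc, _ = tc.participation(w, labels + 1)
            assert pc[0] == pytest.approx(1 - 1 / m, abs=1e-12)
            np.testing.assert_allclose(
                pc, brute_force_pc(w, (labels + 1).tolist()), atol=1e-12
            )

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            net = random_filtered_matrix(20, seed=100 + seed)
            labels = rng.integers(1, 4, 20)
            pc, pc_z = tc.participation(net, labels)
            np.testing.assert_allclose(pc, brute_force_pc(net.weights, labels.tolist()), atol=1e-12)
            assert np.all(pc >= 0) and np.all(pc <= 1)
            assert abs(pc_z.mean()) < 1e-10

    def test_isolated_node_gets_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        pc, _ = tc.participation(w, np.array([1, 1, 2]))
        assert pc[2] == 0.0


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "z,pc,expected",
        [
            (0.5, 0.5, "connector"),
            (0.0, -0.2, "provincial"),
            (0.0, 0.0, "connector"),
            (-0.1, 0.3, "satellite"),
            (-0.1, -0.1, "peripheral"),
        ],
    )
    def test_sign_quadrants(self, z, pc, expected):
        assert tc.classify_roles(np.array([z]), np.array([pc]))[0] == expected

    @given(
        st.lists(
            st.tuples(
                st.floats(-3, 3, allow_nan=False), st.floats(-3, 3, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_every_node_gets_exactly_one_identity(self, pairs):
        z = np.array([p[0] for p in pairs])
        pc = np.array([p[1] for p in pairs])
        roles = tc.classify_roles(z, pc)
        assert all(r in ("connector", "provincial", "satellite", "peripheral") for r in roles)


def rsn_table(labels):
    n = len(labels)
    return pd.DataFrame(
        {
            "node_id": np.arange(n),
            "x_mm": np.zeros(n),
            "y_mm": np.zeros(n),
            "z_mm": np.zeros(n),
            "rsn_label": labels,
        }
    )


class TestFragmentation:
    def test_eight_two_split_is_twenty_percent(self):
        nodes = rsn_table(["X"] * 10 + ["other"] * 2)
        partition = np.array([1] * 8 + [2] * 2 + [1, 2])
        res = tc.fragmentation(partition, nodes, "X")
        assert res.fragmentation == pytest.approx(0.20)
        assert (res.largest_block, res.total_nodes) == (8, 10)

    def test_intact_subnetwork_is_zero(self):
        nodes = rsn_table(["X"] * 6 + ["Y"] * 3)
        partition = np.array([1] * 6 + [2] * 3)
        assert tc.fragmentation(partition, nodes, "X").fragmentation == 0.0

    def test_four_way_split(self):
        nodes = rsn_table(["X"] * 12)
        partition = np.repeat([1, 2, 3, 4], 3)
        assert tc.fragmentation(partition, nodes, "X").fragmentation == pytest.approx(0.75)

    def test_unknown_label_rejected(self):
        nodes = rsn_table(["X"] * 4)
        with pytest.raises(ValueError):
            tc.fragmentation(np.ones(4, dtype=int), nodes, "Z")

    def test_invariant_to_module_relabeling(self):
        nodes = rsn_table(["X"] * 7 + ["Y"] * 5)
        rng = np.random.default_rng(3)
        partition = rng.integers(1, 4, 12)
        perm = np.array([0, 3, 1, 2])  # relabel modules
        relabeled = perm[partition]
        a = tc.fragmentation(tc.Partition.from_labels(partition), nodes, "X")
        b = tc.fragmentation(tc.Partition.from_labels(relabeled), nodes, "X")
        assert a.fragmentation == b.fragmentation


class TestNmi:
    def test_identical_partitions_give_one(self):
        lab = np.repeat([1, 2, 3], 4)
        assert tc.nmi(lab, lab) == pytest.approx(1.0)

    def test_single_cluster_vs_multi_gives_zero(self):
        assert tc.nmi(np.array([1, 1, 1, 2, 2, 2]), np.ones(6, dtype=int)) == 0.0

    def test_both_single_cluster_gives_one(self):
        assert tc.nmi(np.ones(5, dtype=int), np.ones(5, dtype=int)) == 1.0

    def test_hand_contingency_oracle(self):
        a = np.array([1, 1, 1, 2, 2, 2])  # AAABBB
        b = np.array([1, 1, 2, 2, 2, 2])  # AABBBB
        # contingency: [[2,1],[0,3]] / 6
        pa = np.array([0.5, 0.5])
        pb = np.array([2 / 6, 4 / 6])
        pj = np.array([[2 / 6, 1 / 6], [0.0, 3 / 6]])
        mi = sum(
            pj[i, j] * np.log(pj[i, j] / (pa[i] * pb[j]))
            for i in range(2)
            for j in range(2)
            if pj[i, j] > 0
        )
        ha = -(pa * np.log(pa)).sum()
        hb = -(pb * np.log(pb)).sum()
        assert tc.nmi(a, b) == pytest.approx(2 * mi / (ha + hb), abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 5, 40)
        b = rng.integers(1, 4, 40)
        assert tc.nmi(a, b) == pytest.approx(tc.nmi(b, a), abs=1e-12)
        perm = np.array([0, 4, 2, 3, 1])
        assert tc.nmi(perm[a], b) == pytest.approx(tc.nmi(a, b), abs=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            tc.nmi(np.ones(3, dtype=int), np.ones(4, dtype=int))


class TestNmiCostCurve:
    def test_auc_normalization_conventions(self):
        from taskcomm.metrics import normalized_auc

        assert normalized_auc([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.5)
        assert normalized_auc([0.1, 0.5, 0.9], [0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_stable_cliques_give_unit_auc(self):
        import itertools

        w = np.zeros((10, 10))
        rng = np.random.default_rng(5)
        for block in (range(5), range(5, 10)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0 + 0.1 * rng.random()
        net = tc.ConnectivityMatrix(weights=w, node_ids=tuple(range(10)))
        reference = tc.Partition.from_labels(np.repeat([1, 2], 5))
        cfg = tc.CommunityConfig(cost_grid=(0.01, 0.11), n_iterations=10, seed=6)
        costs, values, auc = tc.nmi_cost_curve_auc(net, reference, cfg)
        np.testing.assert_allclose(values, 1.0)
        assert auc == pytest.approx(1.0)

    def test_single_point_grid_rejected(self, planted_network):
        cfg = tc.CommunityConfig(cost_grid=(0.11,))
        with pytest.raises(ValueError):
            tc.nmi_cost_curve_auc(planted_network, np.ones(100, dtype=int), cfg)


class TestNetworkSimilarity:
    def test_self_similarity_is_one(self):
        net = random_filtered_matrix(8, seed=7)
        assert tc.network_similarity(net, net).similarity_r == pytest.approx(1.0)

    def test_negated_matrix_gives_minus_one(self):
        rng = np.random.default_rng(8)
        w = rng.normal(0, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        assert tc.network_similarity(w, -w).similarity_r == pytest.approx(-1.0)

    def test_hand_computed_upper_triangle(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        va = [0.1, 0.4, 0.2, 0.9, 0.3, 0.6]
        vb = [0.2, 0.1, 0.5, 0.8, 0.4, 0.5]
        iu = np.triu_indices(4, k=1)
        a[iu] = va
        b[iu] = vb
        a, b = a + a.T, b + b.T
        res = tc.network_similarity(a, b)
        assert res.n_edges_compared == 6
        assert res.similarity_r == pytest.approx(np.corrcoef(va, vb)[0, 1], abs=1e-12)

    def test_node_subset_selector(self):
        net_a = random_filtered_matrix(10, seed=9)
        net_b = random_filtered_matrix(10, seed=10)
        subset = [0, 2, 5, 7]
        res = tc.network_similarity(net_a, net_b, node_subset=subset)
        wa = net_a.weights[np.ix_(subset, subset)]
        wb = net_b.weights[np.ix_(subset, subset)]
        iu = np.triu_indices(4, k=1)
        assert res.similarity_r == pytest.approx(np.corrcoef(wa[iu], wb[iu])[0, 1], abs=1e-12)

    def test_invariant_to_simultaneous_reordering(self):
        net_a = random_filtered_matrix(9, seed=11)
        net_b = random_filtered_matrix(9, seed=12)
        perm = np.random.default_rng(13).permutation(9)
        ra = net_a.weights[np.ix_(perm, perm)]
        rb = net_b.weights[np.ix_(perm, perm)]
        assert tc.network_similarity(ra, rb).similarity_r == pytest.approx(
            tc.network_similarity(net_a, net_b).similarity_r, abs=1e-12
        )

    def test_degenerate_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tc.network_similarity(np.ones((4, 4)) - np.eye(4), np.ones((4, 4)) - np.eye(4))
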