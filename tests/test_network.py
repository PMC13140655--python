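"""Network construction, centrality, rankings and similarity indices."""

import numpy as np
import pytest

from breathnet.network import (TEMatrix, group_median_network, jsi,
                               participant_network, rank_nodes, total_te,
                               weighted_degrees, wjsi)
from breathnet.series import CHANNELS
from breathnet.synthetic import (CouplingSpec, Edge,
                                 generate_participant_recording)
from breathnet.te import TEConfig

from conftest import stream


def toy(weights, nodes=("A", "B", "C"), **meta):
    return TEMatrix(weights=np.asarray(weights, float), nodes=nodes,
                    metadata=meta)


def mat7(rng=None, density=0.3):
    rng = rng or stream(80)
    w = rng.random((7, 7)) * (rng.random((7, 7)) < density)
    np.fill_diagonal(w, 0.0)
    return TEMatrix(weights=w, metadata={"condition": "CTR", "phase": "rest"})


class TestTEMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            TEMatrix(weights=np.zeros((6, 7)))
        with pytest.raises(ValueError, match="non-negative"):
            toy([[0, -1, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            toy([[1, 0, 0], [0, 0, 0], [0, 0, 0]])


class TestDegrees:
    def test_three_node_cycle(self):
        m = toy([[0, 0.2, 0], [0, 0, 0.3], [0.5, 0, 0]])
        prof = weighted_degrees(m)
        assert prof.outdegree == pytest.approx([0.2, 0.3, 0.5])
        assert prof.indegree == pytest.approx([0.5, 0.2, 0.3])
        assert prof.total_te == pytest.approx(1.0)
        assert total_te(m) == pytest.approx(1.0)

    def test_zero_matrix(self):
        prof = weighted_degrees(toy(np.zeros((3, 3))))
        assert prof.total_te == 0.0
        assert not prof.indegree.any() and not prof.outdegree.any()

    def test_degree_conservation_property(self):
        for s in range(100):
            m = mat7(stream(81, s))
            prof = weighted_degrees(m)
            assert prof.indegree.sum() == pytest.approx(prof.outdegree.sum())
            assert prof.indegree.sum() == pytest.approx(prof.total_te)


class TestRankNodes:
    def test_descending_with_toy(self):
        prof = weighted_degrees(toy([[0, 0, 0.2], [0.5, 0, 0.1],
                                     [0, 0, 0]]))
        # indegrees: A=0.5, B=0, C=0.3
        assert rank_nodes(prof, "ID") == ["A", "C", "B"]

    def test_ties_keep_fixed_channel_order(self):
        prof = weighted_degrees(TEMatrix(weights=np.zeros((7, 7))))
        assert rank_nodes(prof, "ID") == list(CHANNELS)
        assert rank_nodes(prof, "OD") == list(CHANNELS)

    def test_ranking_is_permutation(self):
        prof = weighted_degrees(mat7(stream(82)))
        assert sorted(rank_nodes(prof, "OD")) == sorted(CHANNELS)


class TestGroupMedian:
    def test_identical_matrices_returned(self):
        m = mat7(stream(83))
        out = group_median_network([m, m, m])
        assert np.allclose(out.weights, m.weights)
        assert out.metadata["participant_id"] == "group"

    def test_majority_zeros_erase_edge(self):
        base = np.zeros((3, 3))
        w = base.copy()
        w[0, 1] = 0.4
        ms = [toy(base, condition="CTR", phase="rest"),
              toy(base, condition="CTR", phase="rest"),
              toy(w, condition="CTR", phase="rest")]
        assert group_median_network(ms).weights[0, 1] == 0.0

    def test_even_count_uses_midpoint(self):
        ms = []
        for v in (0.1, 0.2, 0.7, 0.8):
            w = np.zeros((3, 3))
            w[0, 1] = v
            ms.append(toy(w, condition="CTR", phase="rest"))
        assert group_median_network(ms).weights[0, 1] == pytest.approx(0.45)

    def test_bounded_by_elementwise_extremes(self):
        ms = [mat7(stream(84, s)) for s in range(5)]
        med = group_median_network(ms).weights
        stack = np.stack([m.weights for m in ms])
        assert (med >= stack.min(0) - 1e-15).all()
        assert (med <= stack.max(0) + 1e-15).all()

    def test_mixed_condition_rejected(self):
        a = toy(np.zeros((3, 3)), condition="CTR", phase="rest")
        b = toy(np.zeros((3, 3)), condition="HY1", phase="rest")
        with pytest.raises(ValueError, match="mixed"):
            group_median_network([a, b])


class TestSimilarity:
    def test_jsi_set_arithmetic(self):
        a = toy([[0, 1, 0], [0, 0, 1], [0, 0, 0]])      # edges e1, e2
        b = toy([[0, 0, 0], [0, 0, 1], [1, 0, 0]])      # edges e2, e3
        assert jsi(a, b) == pytest.approx(1 / 3)
        assert jsi(a, a) == 1.0

    def test_disjoint_edges_give_zero(self):
        a = toy([[0, 1, 0], [0, 0, 0], [0, 0, 0]])
        b = toy([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
        assert jsi(a, b) == 0.0
        assert wjsi(a, b) == 0.0

    def test_wjsi_direct_evaluation(self):
        a = toy([[0, 0.2, 0.5], [0, 0, 0], [0, 0, 0]])
        b = toy([[0, 0.4, 0.1], [0, 0, 0], [0, 0, 0]])
        # sum(min) / sum(max) = (0.2 + 0.1) / (0.4 + 0.5)
        assert wjsi(a, b) == pytest.approx(1 / 3)
        assert wjsi(a, a) == 1.0

    def test_both_empty_identical_by_convention(self):
        z = toy(np.zeros((3, 3)))
        assert jsi(z, z) == 1.0 and wjsi(z, z) == 1.0

    def test_symmetry(self):
        for s in range(20):
            a, b = mat7(stream(85, s)), mat7(stream(86, s))
            assert wjsi(a, b) == pytest.approx(wjsi(b, a))
            assert jsi(a, b) == pytest.approx(jsi(b, a))

    def test_scaling_law(self):
        a = mat7(stream(87))
        for c in (0.3, 1.0, 2.5):
            scaled = TEMatrix(weights=c * a.weights, metadata=a.metadata)
            assert wjsi(a, scaled) == pytest.approx(min(c, 1) / max(c, 1))
            assert wjsi(scaled, scaled) == 1.0

    def test_wjsi_equals_jsi_on_binary_weights(self):
        for s in range(20):
            rng = stream(88, s)
            w1 = (rng.random((7, 7)) < 0.3).astype(float)
            w2 = (rng.random((7, 7)) < 0.3).astype(float)
            np.fill_diagonal(w1, 0)
            np.fill_diagonal(w2, 0)
            a, b = TEMatrix(weights=w1), TEMatrix(weights=w2)
            assert wjsi(a, b) == pytest.approx(jsi(a, b))

    def test_removing_shared_edge_decreases_wjsi(self):
        a = mat7(stream(89), density=0.5)
        b = TEMatrix(weights=a.weights * 0.8, metadata=a.metadata)
        shared = list(zip(*np.nonzero(a.weights)))
        i, j = shared[0]
        w2 = a.weights.copy()
        w2[i, j] = 0.0
        a2 = TEMatrix(weights=w2, metadata=a.metadata)
        assert wjsi(a2, b) < wjsi(a, b)

    def test_node_order_mismatch_rejected(self):
        a = toy(np.zeros((3, 3)), nodes=("A", "B", "C"))
        b = toy(np.zeros((3, 3)), nodes=("A", "C", "B"))
        with pytest.raises(ValueError, match="node order"):
            wjsi(a, b)


class TestParticipantNetwork:
    def test_shape_and_diagonal_contract(self):
        rec = generate_participant_recording(CouplingSpec(), 15, 5, stream(90))
        net = participant_network(rec, TEConfig(lag=5), seed=1)
        assert net.weights.shape == (7, 7)
        assert not np.diag(net.weights).any()
        assert (net.weights >= 0).all()
        assert net.metadata["participant_id"] == rec.participant_id

    def test_strong_single_link_detected_and_dominant(self):
        """A lone strong HR->RF link is recovered in >= 95 of 100 seeds
        and, when recovered, ranks among the largest entries (top 3 of
        42; the echo of the coupling can appear on adjacent pairs)."""
        spec = CouplingSpec(edges=(Edge("HR", "RF", 5, 1.0),
                                   Edge("HR", "RF", 4, 1.0)))
        i, j = CHANNELS.index("HR"), CHANNELS.index("RF")
        hits = dominant = 0
        for s in range(100):
            rec = generate_participant_recording(spec, 20, 5, stream(91, s))
            net = participant_network(rec, TEConfig(lag=5), seed=stream(92, s))
            if net.weights[i, j] > 0:
                hits += 1
                top3 = np.sort(net.weights.ravel())[-3:]
                dominant += net.weights[i, j] >= top3[0]
        assert hits >= 95
        assert dominant >= 0.9 * hits

    def test_null_recording_matches_nominal_false_positive_rate(self):
        """With no couplings, the expected significant-edge count per
        42-pair network is about 5% of 42 (the strict 95th-order-statistic
        rule gives 6/101 per pair); 100 seeds."""
        spec = CouplingSpec(edges=())
        counts = []
        for s in range(100):
            rec = generate_participant_recording(spec, 20, 5, stream(93, s))
            net = participant_network(rec, TEConfig(lag=5), seed=stream(94, s))
            counts.append((net.weights > 0).sum())
        rate = np.mean(counts) / 42
        assert 0.035 <= rate <= 0.075
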