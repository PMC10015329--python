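import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netews import (
    Network,
    NodeSetSpec,
    correlation_scores,
    input_scores,
    select_node_set,
)
from conftest import LOWER_THRESHOLD, make_block


def block_from_states(base_states, jitter=0.01, m=20, seed=0, state_at_relax=None):
    rng = np.random.default_rng(seed)
    base = np.asarray(base_states, dtype=float)
    samples = base + jitter * rng.standard_normal((m, base.size))
    return make_block(samples, state_at_relax=base if state_at_relax is None else state_at_relax)


class TestInputScores:
    def test_star_center_sums_leaves(self, star5):
        scores = input_scores(star5, np.ones(5))
        assert scores[0] == pytest.approx(4.0)
        assert np.allclose(scores[1:], 1.0)

    def test_isolated_node_scores_zero(self):
        net = Network(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]))
        assert input_scores(net, np.ones(3))[2] == 0

    def test_path_hand_values(self, path3):
        assert np.allclose(input_scores(path3, np.array([1.0, 1.0, 7.0])), [1.0, 8.0, 1.0])


class TestCorrelationScores:
    def test_all_constant_series_score_zero(self):
        block = make_block(np.full((10, 3), 4.2))
        assert np.allclose(correlation_scores(block), 0.0)

    def test_duplicated_node_contributes_its_mean(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        c = 3.0
        samples = np.column_stack([x + c, x + c])  # identical series, mean c
        scores = correlation_scores(make_block(samples))
        assert scores[0] == pytest.approx(c + np.mean(x), abs=1e-9)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(size=(5000, 3))
        scores = correlation_scores(make_block(samples))
        assert np.all(np.abs(scores) < 0.1)


class TestSelectNodeSet:
    def test_all_and_state_sets(self, path3):
        block = block_from_states([1.0, 1.0, 7.0])
        assert select_node_set(NodeSetSpec("all"), block).tolist() == [0, 1, 2]
        assert select_node_set(NodeSetSpec("lower_state"), block).tolist() == [0, 1]
        assert select_node_set(NodeSetSpec("upper_state"), block).tolist() == [2]

    def test_upper_state_empty_at_lower_start(self):
        block = block_from_states([1.0, 1.0])
        assert select_node_set(NodeSetSpec("upper_state"), block).size == 0

    def test_high_input_skips_transitioned_node(self, path3):
        # x̄ = (1, 1, 7): R = (1, 8, 1) but node 2 is already upper → {1}
        block = block_from_states([1.0, 1.0, 7.0])
        picked = select_node_set(NodeSetSpec("high_input", n=1), block, net=path3)
        assert picked.tolist() == [1]

    def test_truncation_when_few_candidates(self, path3):
        block = block_from_states([1.0, 1.0, 7.0])
        picked = select_node_set(NodeSetSpec("high_input", n=10), block, net=path3)
        assert picked.tolist() == [0, 1]

    def test_high_and_low_input_disjoint(self):
        rng = np.random.default_rng(6)
        n = 12
        a = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        net = Network(a)
        block = block_from_states(np.ones(n), seed=7)
        hi = select_node_set(NodeSetSpec("high_input", n=3), block, net=net)
        lo = select_node_set(NodeSetSpec("low_input", n=3), block, net=net)
        assert len(set(hi) & set(lo)) == 0

    def test_input_ranking_matches_degree_at_uniform_means(self, star5):
        """With x̄ constant, R_i ∝ degree, so the star center ranks first."""
        block = block_from_states(np.ones(5), jitter=0.0)
        picked = select_node_set(NodeSetSpec("high_input", n=1), block, net=star5)
        assert picked.tolist() == [0]

    def test_lower_half_strict_median(self, star5):
        block = block_from_states(np.ones(5), jitter=0.0)
        picked = select_node_set(NodeSetSpec("lower_half"), block, net=star5)
        # R = (4, 1, 1, 1, 1); median over available lower nodes is 1 → strictly below: none
        assert picked.size == 0

    def test_random_is_seeded_and_without_replacement(self):
        block = block_from_states(np.ones(6))
        a = select_node_set(NodeSetSpec("random", n=4), block,
                            rng=np.random.default_rng(9))
        b = select_node_set(NodeSetSpec("random", n=4), block,
                            rng=np.random.default_rng(9))
        assert a.tolist() == b.tolist()
        assert len(set(a)) == 4

    def test_large_sd_picks_noisiest_available(self):
        rng = np.random.default_rng(10)
        samples = np.column_stack(
            [0.01 * rng.normal(size=30), 0.5 * rng.normal(size=30), 0.01 * rng.normal(size=30)]
        ) + 1.0
        block = make_block(samples, state_at_relax=np.ones(3))
        picked = select_node_set(NodeSetSpec("large_sd", n=1), block)
        assert picked.tolist() == [1]

    def test_tie_break_lowest_index(self, path3):
        block = block_from_states(np.ones(3), jitter=0.0)
        picked = select_node_set(NodeSetSpec("low_input", n=1), block, net=path3)
        # R = (1, 2, 1): nodes 0 and 2 tie at the bottom; lowest index wins
        assert picked.tolist() == [0]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            NodeSetSpec("mystery")

    def test_network_required_for_structural_kinds(self):
        block = block_from_states(np.ones(3))
        with pytest.raises(ValueError):
            select_node_set(NodeSetSpec("high_input"), block, net=None)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_fixed_size_sets_valid_members(self, seed):
        rng = np.random.default_rng(seed)
        base = np.where(rng.uniform(size=8) < 0.3, 7.0, 1.0)
        block = block_from_states(base, seed=seed)
        for kind in ("large_sd", "large_correlation", "random"):
            picked = select_node_set(
                NodeSetSpec(kind, n=3), block, rng=np.random.default_rng(seed)
            )
            assert len(set(picked.tolist())) == picked.size
            assert np.all((0 <= picked) & (picked < 8))
            if kind == "random":
                assert picked.size == 3
            else:
                assert picked.size == min(3, int((base < LOWER_THRESHOLD).sum()))
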