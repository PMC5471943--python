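"""Jaccard matching, greedy vs optimal tracking, links, colors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

import cortexflow as cf
from cortexflow.tracking import (
    greedy_match,
    matching_objective,
    optimal_match,
    overlap_matrix,
    similarity_matrix,
    transition_links,
)

from conftest import clustering_from_labels, dcs_from_label_matrix, random_partition

# the two-timestep worked example: 2x2 overlap counts, row = source cluster
WORKED_OVERLAPS = np.array([[11, 11], [10, 2]])


class TestJaccard:
    def test_identity(self):
        assert cf.jaccard({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint(self):
        assert cf.jaccard({1, 2}, {3, 4}) == 0.0

    def test_partial_overlap_exact(self):
        a = set(range(1, 16))  # 1..15
        b = set(range(5, 21))  # 5..20
        assert len(a & b) == 11 and len(a | b) == 20
        assert cf.jaccard(a, b) == 11 / 20 == 0.55

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cf.jaccard(set(), {1})

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_bounds_and_symmetry(self, a, b):
        s = cf.jaccard(a, b)
        assert 0.0 <= s <= 1.0
        assert s == cf.jaccard(b, a)


class TestGreedyMatch:
    def test_worked_example_first_pair_overlap_eleven(self):
        m = greedy_match([], [], overlaps=WORKED_OVERLAPS)
        assert m.pairs[0] == (0, 0)
        assert WORKED_OVERLAPS[m.pairs[0]] == 11
        assert m.pairs[1] == (1, 1)
        assert WORKED_OVERLAPS[m.pairs[1]] == 2

    def test_identical_partitions_identity_matching(self):
        parts = [{"a", "b"}, {"c"}, {"d", "e", "f"}]
        m = greedy_match(parts, parts)
        assert sorted(m.pairs) == [(0, 0), (1, 1), (2, 2)]
        for i, j in m.pairs:
            assert len(parts[i]) == overlap_matrix(parts, parts)[i, j]

    def test_single_shared_node_matched(self):
        m = greedy_match([{"a"}], [{"a", "b"}])
        assert m.pairs == [(0, 0)]

    def test_no_overlap_leaves_unmatched(self):
        m = greedy_match([{"a"}], [{"b"}])
        assert m.pairs == []
        assert m.unmatched_sources == [0] and m.unmatched_sinks == [0]


class TestOptimalMatch:
    def test_worked_example_crossed_pairing_total_21(self):
        m = optimal_match([], [], theta=0.0, similarities=WORKED_OVERLAPS.astype(float))
        assert sorted(m.pairs) == [(0, 1), (1, 0)]
        assert WORKED_OVERLAPS[0, 1] + WORKED_OVERLAPS[1, 0] == 21

    def test_all_below_threshold_empty_matching(self):
        sims = np.full((3, 3), 0.05)
        m = optimal_match([], [], theta=0.1, similarities=sims)
        assert m.pairs == []
        assert m.unmatched_sources == [0, 1, 2]

    def test_equals_assignment_solver_on_seeded_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sims = rng.uniform(0, 1, size=(6, 6))
            sims[sims < 0.1] = 0.0
            m = optimal_match([], [], theta=0.1, similarities=sims)
            ri, ci = linear_sum_assignment(-np.where(sims < 0.1, 0.0, sims))
            oracle = float(sum(sims[i, j] for i, j in zip(ri, ci) if sims[i, j] >= 0.1))
            mine = float(sum(sims[i, j] for i, j in m.pairs))
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_rectangular_partial_matching(self):
        sims = np.array([[0.9, 0.0], [0.8, 0.7], [0.0, 0.6]])
        m = optimal_match([], [], theta=0.1, similarities=sims)
        assert sorted(m.pairs) == [(0, 0), (1, 1)] or sorted(m.pairs) == [(0, 0), (2, 1)]
        total = sum(sims[i, j] for i, j in m.pairs)
        assert total == pytest.approx(1.6)

    def test_enumeration_limit_advises_solver(self):
        sims = np.eye(11)
        with pytest.raises(ValueError, match="solver"):
            optimal_match([], [], similarities=sims, engine="enumerate")
        m = optimal_match([], [], similarities=sims, engine="solver")
        assert len(m.pairs) == 11

    def test_theta_compliance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p1 = random_partition(rng, [f"e{i}" for i in range(10)], 3)
            p2 = random_partition(rng, [f"e{i}" for i in range(10)], 3)
            m = optimal_match(p1, p2, theta=0.3)
            sims = similarity_matrix(p1, p2)
            for i, j in m.pairs:
                assert sims[i, j] >= 0.3

    def test_optimal_never_below_greedy(self):
        rng = np.random.default_rng(1)
        ids = [f"e{i}" for i in range(14)]
        for _ in range(200):
            p1 = random_partition(rng, ids, 4)
            p2 = random_partition(rng, ids, 4)
            sims = similarity_matrix(p1, p2)
            g = greedy_match(p1, p2)
            o = optimal_match(p1, p2, theta=0.1)
            assert matching_objective(o, sims, 0.1) >= matching_objective(g, sims, 0.1) - 1e-12


class TestTransitionLinks:
    def test_identical_partitions_diagonal_links(self):
        parts = [{"a", "b"}, {"c", "d", "e"}]
        links = transition_links(parts, parts)
        assert [(lk.source, lk.sink, lk.count) for lk in links] == [(0, 0, 2), (1, 1, 3)]
        assert all(lk.similarity == 1.0 for lk in links)

    def test_split_conserves_counts(self):
        src = [{"a", "b", "c", "d", "e", "f", "g"}]
        snk = [{"a", "b", "c"}, {"d", "e", "f", "g"}]
        links = transition_links(src, snk)
        assert sorted(lk.count for lk in links) == [3, 4]
        assert sum(lk.count for lk in links) == 7

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(2)
        ids = [f"e{i}" for i in range(20)]
        for _ in range(30):
            p1 = random_partition(rng, ids, 4)
            p2 = random_partition(rng, ids, 4)
            links = transition_links(p1, p2)
            got = {(lk.source, lk.sink): lk.count for lk in links}
            for i, a in enumerate(p1):
                for j, b in enumerate(p2):
                    inter = len(a & b)
                    if inter:
                        assert got[(i, j)] == inter
                        assert links[0].t == 0
                    else:
                        assert (i, j) not in got

    def test_flow_conservation(self):
        rng = np.random.default_rng(3)
        ids = [f"e{i}" for i in range(16)]
        for _ in range(30):
            p1 = random_partition(rng, ids, 5)
            p2 = random_partition(rng, ids, 5)
            links = transition_links(p1, p2)
            assert sum(lk.count for lk in links) == len(ids)
            for i, a in enumerate(p1):
                assert sum(lk.count for lk in links if lk.source == i) == len(a)
            for j, b in enumerate(p2):
                assert sum(lk.count for lk in links if lk.sink == j) == len(b)


class TestTrackCommunities:
    def test_identical_partitions_keep_persistent_ids(self):
        labels = np.tile(np.array([0, 0, 1, 1, 2, 2])[:, None], (1, 5))
        dcs = dcs_from_label_matrix(labels)
        assert dcs.persistent_ids() == ["dc0", "dc1", "dc2"]
        for t in range(5):
            assert sorted(b.persistent_id for b in dcs.blocks[t]) == ["dc0", "dc1", "dc2"]

    def test_low_similarity_triggers_birth(self):
        # complete relabelling: every new cluster overlaps each old one too little
        labels = np.array(
            [
                [0, 0, 0, 1, 1, 1, 2, 2, 2],
                [0, 1, 2, 0, 1, 2, 0, 1, 2],
            ]
        ).T
        dcs = dcs_from_label_matrix(labels, theta=0.5)
        t0 = {b.persistent_id for b in dcs.blocks[0]}
        t1 = {b.persistent_id for b in dcs.blocks[1]}
        assert t0 == {"dc0", "dc1", "dc2"}
        assert t0 & t1 == set()  # all births

    def test_block_cover_and_disjointness(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, size=(15, 6))
        labels[:4, :] = np.arange(4)[:, None]  # keep all 4 labels present
        dcs = dcs_from_label_matrix(labels)
        dcs.validate()  # raises on overlap/cover violations
        for t in range(6):
            assert sum(len(b.members) for b in dcs.blocks[t]) == 15

    def test_greedy_and_optimal_diverge_on_worked_example(self):
        # build partitions realizing the worked overlap matrix
        src_a = set(range(22))          # 22 electrodes
        src_b = set(range(22, 34))      # 12 electrodes
        snk_a = set(range(11)) | set(range(22, 32))   # 11 from a, 10 from b
        snk_b = set(range(11, 22)) | set(range(32, 34))  # 11 from a, 2 from b
        assert overlap_matrix([src_a, src_b], [snk_a, snk_b]).tolist() == [
            [11, 11],
            [10, 2],
        ]
        g = greedy_match([src_a, src_b], [snk_a, snk_b])
        o = optimal_match([src_a, src_b], [snk_a, snk_b], theta=0.0)
        assert g.pairs != o.pairs


class TestAssignColors:
    def test_three_ids_three_distinct_colors(self):
        labels = np.tile(np.array([0, 0, 1, 1, 2, 2])[:, None], (1, 3))
        dcs = dcs_from_label_matrix(labels)
        colors = cf.assign_colors(dcs, "Dark2")
        assert len(set(colors.values())) == 3

    def test_color_stable_over_lifetime(self):
        labels = np.tile(np.array([0, 0, 1, 1])[:, None], (1, 7))
        dcs = dcs_from_label_matrix(labels)
        colors = cf.assign_colors(dcs, "Set1")
        for t in range(7):
            for b in dcs.blocks[t]:
                assert colors[b.persistent_id] == colors[dcs.blocks[0][b.i].persistent_id]

    def test_palette_recycling_warns(self, caplog):
        rng = np.random.default_rng(6)
        # force many births with disjoint relabellings over 30 nodes
        labels = np.empty((30, 4), dtype=int)
        for t in range(4):
            labels[:, t] = (np.arange(30) // 10 + 3 * t) % 9 if t == 0 else rng.permutation(30) % 3
        dcs = dcs_from_label_matrix(labels, theta=0.9)
        assert len(dcs.persistent_ids()) > 8
        with caplog.at_level("WARNING"):
            colors = cf.assign_colors(dcs, "Dark2")
        assert "recycle" in caplog.text
        ids = dcs.persistent_ids()
        assert colors[ids[8]] == colors[ids[0]]

    def test_unknown_palette_rejected(self, small_tracked):
        dcs, _, _, _ = small_tracked
        with pytest.raises(KeyError):
            cf.assign_colors(dcs, "nope")
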