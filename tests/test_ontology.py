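import math
import random
from collections import deque

import numpy as np
import pytest

from complexkit.ontology import (
    CycleError,
    TermGraph,
    compare_distributions,
    consistency_index,
    enrichment_test,
    normalize_to_depth,
    random_control_indexes,
    read_annotations,
    term_depths,
)


def chain_graph(n):
    g = TermGraph()
    g.add_term("t0")
    for i in range(1, n + 1):
        g.add_edge(f"t{i}", f"t{i-1}")
    return g


def bfs_depth_oracle(graph):
    children = graph.children_index()
    depths = {}
    q = deque((r, 0) for r in graph.roots)
    while q:
        t, d = q.popleft()
        if t in depths:
            continue
        depths[t] = d
        for c in children[t]:
            q.append((c, d + 1))
    return depths


class TestTermDepths:
    def test_root_depth_zero(self):
        g = chain_graph(0)
        assert term_depths(g) == {"t0": 0}

    def test_chain(self):
        g = chain_graph(2)
        assert term_depths(g)["t2"] == 2

    def test_diamond_shortest_path(self):
        g = TermGraph()
        # two routes to "leaf": length 3 and length 5
        g.add_term("root")
        for i, (child, parent) in enumerate(
            [("a1", "root"), ("a2", "a1"), ("leaf", "a2"),
             ("b1", "root"), ("b2", "b1"), ("b3", "b2"), ("b4", "b3"), ("leaf", "b4")]
        ):
            g.add_edge(child, parent)
        depths = term_depths(g)
        assert depths["leaf"] == 3
        assert depths == bfs_depth_oracle(g)

    def test_cycle_detected(self):
        g = TermGraph()
        g.add_edge("a", "b")
        g.add_edge("b", "a")
        with pytest.raises(CycleError):
            term_depths(g)

    def test_unreachable_cycle_component(self):
        g = chain_graph(1)
        g.add_edge("x", "y")
        g.add_edge("y", "x")
        with pytest.raises(CycleError):
            term_depths(g)


class TestNormalizeToDepth:
    def graph(self):
        # chain t0..t7 plus a second depth-5 parent of t6
        g = chain_graph(7)
        g.add_edge("alt5", "t4")  # alt5 at depth 5
        g.add_edge("t6", "alt5")  # t6 now has two depth-5 ancestors
        return g

    def test_depth_five_kept(self):
        norm = normalize_to_depth({"p": {"t5"}}, self.graph(), 5)
        assert norm["p"] == {"t5"}

    def test_shallow_dropped(self):
        norm = normalize_to_depth({"p": {"t3"}}, self.graph(), 5)
        assert "p" not in norm

    def test_deep_term_maps_to_all_depth5_ancestors(self):
        norm = normalize_to_depth({"p": {"t7"}}, self.graph(), 5)
        assert norm["p"] == {"t5", "alt5"}

    def test_unknown_term_dropped_with_warning(self, caplog):
        norm = normalize_to_depth({"p": {"nope", "t5"}}, self.graph(), 5)
        assert norm["p"] == {"t5"}

    def test_idempotent(self):
        g = self.graph()
        once = normalize_to_depth({"p": {"t7", "t5", "t2"}}, g, 5)
        twice = normalize_to_depth(once, g, 5)
        assert once == twice


def hypergeom_tail_oracle(a, n_draws, K, N):
    """Exact P(X >= a) by integer-arithmetic summation."""
    total = 0
    denom = math.comb(N, n_draws)
    for x in range(a, min(n_draws, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n_draws - x)
    return total / denom


class TestEnrichment:
    def universe(self, n, k_with_term):
        ann = {f"g{i}": {"T"} if i < k_with_term else {"U"} for i in range(n)}
        return ann, {f"g{i}" for i in range(n)}

    def test_matches_hypergeometric_tail(self):
        ann, proteome = self.universe(1000, 10)
        members = {f"g{i}" for i in range(4)}  # all 4 carry T
        results = {e.term: e for e in enrichment_test("c", members, ann, proteome)}
        expected = hypergeom_tail_oracle(4, 4, 10, 1000)
        assert results["T"].p_value == pytest.approx(expected, abs=1e-12)

    def test_universal_term_p_one(self):
        ann = {f"g{i}": {"T"} for i in range(50)}
        proteome = set(ann)
        members = {"g0", "g1", "g2"}
        (res,) = enrichment_test("c", members, ann, proteome)
        assert res.p_value == pytest.approx(1.0)

    def test_only_terms_hitting_a_subunit(self):
        ann, proteome = self.universe(100, 10)
        members = {"g50", "g51"}  # only carry U
        terms = {e.term for e in enrichment_test("c", members, ann, proteome)}
        assert terms == {"U"}

    def test_empty_proteome_raises(self):
        with pytest.raises(ValueError):
            enrichment_test("c", {"a", "b"}, {}, set())

    def test_cells_consistent(self):
        ann, proteome = self.universe(200, 30)
        members = {f"g{i}" for i in range(6)}
        for e in enrichment_test("c", members, ann, proteome):
            assert e.a + e.b == 6
            assert e.c + e.d == 200  # members inside the proteome: no inflation
            assert 0 < e.p_value <= 1


class TestConsistencyIndex:
    def test_all_share(self):
        ann = {p: {"T"} for p in "abc"}
        score = consistency_index("c", set("abc"), ann)
        assert score.index == 1.0
        assert score.n_all == 3

    def test_one_pair_shares(self):
        ann = {"p1": {"T"}, "p2": {"T"}, "p3": {"U"}}
        score = consistency_index("c", {"p1", "p2", "p3"}, ann)
        assert score.index == pytest.approx(1 / 3)

    def test_matches_bruteforce_pair_scan(self):
        rng = random.Random(13)
        members = [f"m{i}" for i in range(6)]
        ann = {m: {f"T{rng.randrange(4)}" for _ in range(2)} for m in members}
        score = consistency_index("c", members, ann)
        brute = sum(
            1
            for i in range(6)
            for j in range(i + 1, 6)
            if ann[members[i]] & ann[members[j]]
        )
        assert score.n_cons == brute
        assert score.n_all == 15

    def test_unannotated_members_count_in_denominator(self):
        ann = {"p1": {"T"}, "p2": {"T"}}
        score = consistency_index("c", {"p1", "p2", "p3"}, ann)
        assert score.n_all == 3 and score.n_cons == 1

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            consistency_index("c", {"p1"}, {})

    def test_removing_annotations_never_increases_index(self):
        rng = random.Random(3)
        members = [f"m{i}" for i in range(8)]
        ann = {m: {f"T{rng.randrange(5)}"} for m in members}
        full = consistency_index("c", members, ann).index
        reduced_ann = dict(ann)
        reduced_ann[members[0]] = set()
        reduced = consistency_index("c", members, reduced_ann).index
        assert reduced <= full


class TestRandomControls:
    def test_no_shared_terms_all_zero(self):
        ann = {f"g{i}": {f"T{i}"} for i in range(20)}
        sets = random_control_indexes(ann, [3, 4], n_sets=5, seed=1)
        assert all(x == 0.0 for s in sets for x in s)

    def test_all_share_one_term_all_one(self):
        ann = {f"g{i}": {"T"} for i in range(20)}
        sets = random_control_indexes(ann, [3, 5], n_sets=5, seed=1)
        assert all(x == 1.0 for s in sets for x in s)

    def test_reproducible_under_seed(self):
        ann = {f"g{i}": {f"T{i % 3}"} for i in range(30)}
        a = random_control_indexes(ann, [4, 4, 5], n_sets=10, seed=42)
        b = random_control_indexes(ann, [4, 4, 5], n_sets=10, seed=42)
        assert a == b

    def test_size_exceeding_universe_raises(self):
        ann = {"g0": {"T"}, "g1": {"T"}}
        with pytest.raises(ValueError):
            random_control_indexes(ann, [3], n_sets=1, seed=0)

    def test_mean_matches_closed_form_pair_sharing(self):
        # calibrated universe: term T assigned to m of G genes, one term per gene
        G, m = 40, 10
        ann = {f"g{i}": {"T"} if i < m else {f"U{i}"} for i in range(G)}
        p_share = (m * (m - 1)) / (G * (G - 1))
        sets = random_control_indexes(ann, [4] * 50, n_sets=20, seed=7)
        flat = np.array([x for s in sets for x in s])
        se = flat.std(ddof=1) / np.sqrt(flat.size)
        assert abs(flat.mean() - p_share) <= 3 * se


class TestCompareDistributions:
    def test_identical_sets(self):
        out = compare_distributions([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        assert out["p_value"] == pytest.approx(1.0)
        assert out["statistic"] == pytest.approx(0.0)

    def test_extreme_separation(self):
        out = compare_distributions([0, 0, 0, 0], [1, 1, 1, 1])
        assert out["mean_b"] - out["mean_a"] == 1.0
        assert out["p_value"] < 0.01

    def test_bonferroni_scaling(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.2, 0.05, 50)
        b = rng.normal(0.25, 0.05, 50)
        raw = compare_distributions(a, b)["p_value"]
        adj = compare_distributions(a, b, n_comparisons=3)["p_value"]
        assert adj == pytest.approx(min(raw * 3, 1.0))

    def test_null_calibration(self):
        # p roughly uniform when both samples share a distribution
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            ps.append(compare_distributions(a, b)["p_value"])
        ps = np.array(ps)
        assert 0.35 < (ps < 0.5).mean() < 0.65

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            compare_distributions([0.1], [0.2, 0.3])


class TestIO:
    def test_tsv_term_graph(self, tmp_path):
        path = tmp_path / "terms.tsv"
        path.write_text("b\ta\nc\tb\n")
        g = TermGraph.from_tsv(path)
        assert g.roots == {"a"}
        assert term_depths(g)["c"] == 2

    def test_obo_reader(self, tmp_path):
        path = tmp_path / "mini.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0001\nname: root\n\n"
            "[Term]\nid: GO:0002\nis_a: GO:0001 ! root\n\n"
            "[Term]\nid: GO:0003\nis_a: GO:0002\nis_obsolete: true\n\n"
            "[Typedef]\nid: part_of\n"
        )
        g = TermGraph.from_obo(path)
        assert g.terms == {"GO:0001", "GO:0002"}
        assert g.parents["GO:0002"] == {"GO:0001"}

    def test_annotation_reader(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("p1\tT1\np1\tT2\np2\tT1\n")
        assert read_annotations(path) == {"p1": {"T1", "T2"}, "p2": {"T1"}}
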