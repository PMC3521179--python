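import numpy as np
import pytest

from complexkit.clustering import density
from complexkit.expression import collapse_tags, complex_coherence, profile_entropy
from complexkit.ontology import consistency_index, normalize_to_depth, term_depths
from complexkit.paralogs import complex_paralog_pairs
from complexkit.synthetic import (
    SyntheticTruth,
    gen_expression,
    gen_go,
    gen_homology,
    gen_network,
    gen_reference,
    powerlaw_sizes,
)


class TestGenNetwork:
    def test_pure_cliques_are_components(self):
        import networkx as nx

        net, truth = gen_network(0, [4, 5, 6], p_in=1.0, p_out=0.0, seed=0)
        comps = [frozenset(c) for c in nx.connected_components(net.graph) if len(c) > 1]
        assert sorted(comps, key=sorted) == sorted(truth.planted_complexes, key=sorted)

    def test_intra_density_matches_p_in(self):
        net, truth = gen_network(100, [6] * 10, p_in=0.9, p_out=0.02, seed=7)
        densities = [density(net, m) for m in truth.planted_complexes]
        n_pairs = sum(len(m) * (len(m) - 1) // 2 for m in truth.planted_complexes)
        se = np.sqrt(0.9 * 0.1 / n_pairs)
        assert abs(np.mean(densities) - 0.9) <= 3 * se

    def test_shared_subunits(self):
        net, truth = gen_network(0, [5, 5, 5], p_in=1.0, p_out=0.0, n_shared=2, seed=1)
        counts = {}
        for members in truth.planted_complexes:
            for p in members:
                counts[p] = counts.get(p, 0) + 1
        assert sum(1 for v in counts.values() if v == 2) == 2
        assert len(truth.shared_subunits) == 2

    def test_reproducible(self):
        a, _ = gen_network(30, [5] * 3, seed=5)
        b, _ = gen_network(30, [5] * 3, seed=5)
        assert a.edges() == b.edges()

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_network(10, [2], seed=0)
        with pytest.raises(ValueError):
            gen_network(10, [4], p_in=0.1, p_out=0.5, seed=0)

    def test_truth_roundtrip(self, tmp_path):
        _, truth = gen_network(10, [4, 5], n_shared=1, seed=2)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.planted_complexes == truth.planted_complexes
        assert back.shared_subunits == truth.shared_subunits


class TestGenGo:
    def test_fully_consistent(self):
        _, truth = gen_network(0, [4, 4], p_in=1.0, p_out=0.0, seed=0)
        graph, ann = gen_go(truth, f_consistent=1.0, noise_terms_per_protein=0, seed=0)
        norm = normalize_to_depth(ann, graph, 5)
        for members in truth.planted_complexes:
            assert consistency_index("c", members, norm).index == 1.0

    def test_dedicated_terms_at_requested_depth(self):
        _, truth = gen_network(0, [4], p_in=1.0, p_out=0.0, seed=0)
        graph, _ = gen_go(truth, depth=5, seed=0)
        depths = term_depths(graph)
        for t in truth.complex_terms.values():
            assert depths[t] == 5

    def test_zero_consistency_no_planted_term(self):
        _, truth = gen_network(0, [4, 4], p_in=1.0, p_out=0.0, seed=0)
        _, ann = gen_go(truth, f_consistent=0.0, noise_terms_per_protein=0, seed=0)
        planted_terms = set(truth.complex_terms.values())
        assert all(not (terms & planted_terms) for terms in ann.values())

    def test_half_consistency_matches_pair_combinatorics(self):
        # f=0.5 on 4-mers: 2 of 4 members share the planted term, so
        # C(2,2)/C(4,2) = 1/6 of pairs share it
        _, truth = gen_network(0, [4] * 200, p_in=1.0, p_out=0.0, seed=0)
        graph, ann = gen_go(truth, f_consistent=0.5, noise_terms_per_protein=0, seed=3)
        norm = normalize_to_depth(ann, graph, 5)
        idx = [
            consistency_index("c", m, norm).index for m in truth.planted_complexes
        ]
        expected = 1 / 6
        se = np.std(idx, ddof=1) / np.sqrt(len(idx))
        assert abs(np.mean(idx) - expected) <= 3 * se + 1e-9


class TestGenExpression:
    def test_full_coherence_gives_cosine_one(self):
        _, truth = gen_network(0, [4, 5], p_in=1.0, p_out=0.0, seed=0)
        matrix = gen_expression(truth, coherence=1.0, noise_sd=0.0, tags_per_locus=3, seed=1)
        profiles = collapse_tags(matrix)
        for members in truth.planted_complexes:
            avg, _ = complex_coherence(members, profiles)
            assert avg == pytest.approx(1.0)

    def test_tag_averaging_preserves_direction(self):
        _, truth = gen_network(0, [3], p_in=1.0, p_out=0.0, seed=0)
        m1 = gen_expression(truth, tags_per_locus=1, seed=5)
        m4 = gen_expression(truth, tags_per_locus=4, seed=5)
        p1, p4 = collapse_tags(m1), collapse_tags(m4)
        for locus in p1:
            c = np.dot(p1[locus], p4[locus]) / (
                np.linalg.norm(p1[locus]) * np.linalg.norm(p4[locus])
            )
            assert c == pytest.approx(1.0)

    def test_tissue_specific_lowers_entropy(self):
        _, truth = gen_network(0, [5] * 4, p_in=1.0, p_out=0.0, seed=0)
        matrix = gen_expression(truth, tissue_specific=True, seed=2)
        profiles = collapse_tags(matrix)
        ents = [profile_entropy(v) for v in profiles.values()]
        assert max(ents) < np.log2(10)

    def test_zero_coherence_profiles_independent_of_latent(self):
        _, truth = gen_network(0, [4] * 30, p_in=1.0, p_out=0.0, seed=0)
        matrix = gen_expression(truth, coherence=0.0, seed=3)
        profiles = collapse_tags(matrix)
        avgs = [complex_coherence(m, profiles)[0] for m in truth.planted_complexes]
        assert np.mean(avgs) < 0.99  # far from forced coherence


class TestGenHomology:
    def test_core_vs_peripheral_tiers(self):
        _, truth = gen_network(0, [5], p_in=1.0, p_out=0.0, seed=0)
        genes = sorted(truth.planted_complexes[0])
        table = gen_homology(truth, [(genes, 3)], e_value_strong=1e-5, e_value_weak=1e-2, seed=0)
        members = set(genes)
        strict = complex_paralog_pairs(members, table, threshold=1e-5)
        loose = complex_paralog_pairs(members, table, threshold=1e-2)
        assert {g for p in strict for g in p} == set(genes[:3])
        assert {g for p in loose for g in p} == set(genes)

    def test_no_families_empty_only_when_no_complexes(self):
        truth = SyntheticTruth(planted_complexes=[])
        table = gen_homology(truth, [], seed=0)
        assert table.pairs == {}

    def test_no_cross_family_pairs(self):
        truth = SyntheticTruth(planted_complexes=[])
        table = gen_homology(truth, [(["a", "b"], 2), (["x", "y"], 2)], seed=0)
        assert table.e_value("a", "x") is None
        assert table.e_value("a", "b") is not None


class TestGenReference:
    def test_unperturbed_reference_self_matches(self):
        from complexkit.benchmark import match_complexes

        _, truth = gen_network(0, [5, 5], p_in=1.0, p_out=0.0, seed=0)
        reference = gen_reference(truth)
        predicted = {f"p{i}": m for i, m in enumerate(truth.planted_complexes)}
        matches = match_complexes(predicted, reference)
        perfect = [m for m in matches if m.recall == 1.0 and m.precision == 1.0]
        assert len(perfect) == 2

    def test_dropped_member_bounds_precision(self):
        from complexkit.benchmark import match_complexes

        _, truth = gen_network(0, [5, 5], p_in=1.0, p_out=0.0, seed=0)
        reference = gen_reference(truth, drop_per_complex=1, seed=1)
        predicted = {f"p{i}": m for i, m in enumerate(truth.planted_complexes)}
        for m in match_complexes(predicted, reference):
            assert m.precision == pytest.approx(4 / 5)
            assert m.recall == 1.0

    def test_added_foreign_member_bounds_recall(self):
        from complexkit.benchmark import match_complexes

        _, truth = gen_network(0, [5], p_in=1.0, p_out=0.0, seed=0)
        reference = gen_reference(truth, add_per_complex=1, seed=1)
        (m,) = match_complexes({"p": truth.planted_complexes[0]}, reference)
        assert m.recall == pytest.approx(5 / 6)
        assert m.precision == 1.0


def test_powerlaw_sizes_within_range():
    sizes = powerlaw_sizes(500, exponent=2.0, size_range=(3, 25), seed=0)
    assert min(sizes) >= 3 and max(sizes) <= 25
    # heavier mass at small sizes
    assert sizes.count(3) > sizes.count(25)
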