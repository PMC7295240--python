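import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from miningd import (
    GenerativeModel,
    PipelineConfig,
    build_similarity_graph,
    classify_by_position,
    filter_unidirectional,
    merge_across_datasets,
    merge_cliques,
    relative_position,
    similarity_distance,
    simulate_cdr3s,
)
from miningd.core import Extension
from miningd.filtering import (
    PositionedExtension,
    longest_common_substring,
    mean_relative_position,
)
from miningd.pipeline import infer_genes

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


def _ext(seq, left=1, right=1):
    seed = seq[left : len(seq) - right] if len(seq) - left - right >= 1 else seq
    if seed not in seq or len(seq) - len(seed) != left + right:
        seed = seq
        left = right = 0
    return Extension(sequence=seq, seed=seed, left_steps=left, right_steps=right)


class TestRelativePosition:
    def test_identity_case(self):
        assert relative_position("ACGT", "ACGT") == 0.0

    def test_prefix_is_zero(self):
        c = "ACGTACGTACGTACGTACGT"
        assert relative_position(c[:10], c) == 0.0

    def test_last_window(self):
        c = "A" * 10 + "CCGGCCGGTT"
        assert relative_position("CCGGCCGGTT", c) == pytest.approx(10 / 11)

    def test_absent_substring_rejected(self):
        with pytest.raises(ValueError):
            relative_position("TTT", "ACACAC")

    @given(dna, dna)
    def test_range(self, sub, c):
        if sub in c:
            rp = relative_position(sub, c)
            assert 0.0 <= rp < 1.0

    def test_mean_over_dataset(self):
        rp, n = mean_relative_position("AC", ["ACGG", "GACG", "TTTT"])
        assert n == 2
        assert rp == pytest.approx((0.0 + 1 / 3) / 2)


class TestClassifyByPosition:
    def test_three_cluster_example(self):
        rps = [0.10, 0.12, 0.48, 0.50, 0.52, 0.90]
        exts = [
            PositionedExtension(_ext("ACGTACGTACGT"), rp, 10) for rp in rps
        ]
        classify_by_position(exts)
        assert [e.segment_class for e in exts] == ["V", "V", "D", "D", "D", "J"]

    def test_degenerate_identical_positions(self):
        exts = [PositionedExtension(_ext("ACGTACGTACGT"), 0.5, 5) for _ in range(4)]
        classify_by_position(exts)
        assert all(e.segment_class == "D" for e in exts)

    def test_fewer_than_three_all_d(self):
        exts = [PositionedExtension(_ext("ACGTACGTACGT"), 0.1, 5)]
        classify_by_position(exts)
        assert exts[0].segment_class == "D"

    def test_planted_v_and_j_extensions_separated(self):
        # long V suffixes / J prefixes put V- and J-derived extensions in the
        # outer relative-position clusters; planted genes stay central
        hits = 0
        runs = 6
        for seed in range(runs):
            model = GenerativeModel.default(100 + seed, n_genes=4,
                                            gene_length_range=(16, 26))
            v_base = "GTCGTGTCGAGGTGACGTAT"
            j_base = "CTCGAACCAGTTATCGCCTG"
            model.v_suffixes = [(f"V.{L}", v_base[-L:], 1.0) for L in range(10, 16)]
            model.j_prefixes = [(f"J.{L}", j_base[:L], 1.0) for L in range(10, 16)]
            cdr3s, _ = simulate_cdr3s(model, 20_000, rng_seed=200 + seed)
            res = infer_genes(cdr3s, PipelineConfig(num_seeds=200, min_dataset_size=0))
            classes = {
                p.extension.sequence: p.segment_class for p in res.positioned
            }
            v_ok = all(
                cls == "V" for s, cls in classes.items()
                if longest_common_substring(s, v_base) == s
            )
            j_ok = all(
                cls == "J" for s, cls in classes.items()
                if longest_common_substring(s, j_base) == s
            )
            d_ok = all(
                any(
                    cls == "D"
                    for s, cls in classes.items()
                    if gene in s or s in gene
                )
                for _, gene, _ in [(n, g, w) for n, g, w in model.seeds]
            )
            hits += v_ok and j_ok and d_ok
        assert hits >= runs - 1


class TestUnidirectionalFilter:
    def test_one_sided_removed(self):
        ext = Extension("ACGTACGTACGTACGTA", "ACGTACGTAC", 0, 7)
        assert filter_unidirectional([ext]) == []

    def test_two_sided_kept(self):
        ext = Extension("AACGTACGTACGTACGT", "CGTACGTACG", 3, 4)
        assert filter_unidirectional([ext]) == [ext]

    def test_configurable_off(self):
        ext = Extension("ACGTACGTACGTACGTA", "ACGTACGTAC", 0, 7)
        assert filter_unidirectional([ext], keep_unidirectional=True) == [ext]


class TestSimilarityDistance:
    def test_identical_strings(self):
        assert similarity_distance("ACGTACGT", "ACGTACGT") == 0

    def test_substring_distance_zero(self):
        assert similarity_distance("CGTAC", "ACGTACGT") == 0

    def test_edge_difference_example(self):
        # LCS("ACGTACGT", "TTACGTAA") = "ACGTA": 8 - 5 = 3
        assert similarity_distance("ACGTACGT", "TTACGTAA") == 3

    @given(dna, dna)
    def test_symmetric_nonnegative(self, a, b):
        d = similarity_distance(a, b)
        assert d == similarity_distance(b, a)
        assert d >= 0
        assert (d == 0) == (a in b or b in a)


class TestCliqueMerging:
    def test_clique_collapses_to_common_substring(self):
        seqs = ["ACGTACGTACGT", "CGTACGTACGTA", "ACGTACGTACG"]
        graph = build_similarity_graph(seqs, max_dist=1)
        assert graph.graph.number_of_edges() == 3
        merged = merge_cliques(graph, engine=None)
        assert merged == ["CGTACGTACG"]

    def test_no_edges_passthrough(self):
        seqs = ["AAAAAAAAAA", "CCCCCCCCCC", "GGTTGGTTGG"]
        graph = build_similarity_graph(seqs, max_dist=2)
        assert graph.graph.number_of_edges() == 0
        assert sorted(merge_cliques(graph, engine=None)) == sorted(seqs)

    def test_short_common_substring_passes_members_through(self):
        # high overlap in the middle but a short overall common core
        seqs = ["AAAAA", "AAAAT"]
        graph = build_similarity_graph(seqs, max_dist=2)
        merged = merge_cliques(graph, engine=None, min_core=6)
        assert sorted(merged) == sorted(seqs)

    def test_reextension_recovers_planted_gene(self):
        model = GenerativeModel.default(41, n_genes=1, gene_length_range=(24, 24))
        gene = model.seeds[0][1]
        cdr3s, _ = simulate_cdr3s(model, 30_000, rng_seed=41)
        # truncated reconstructions of the same gene
        seqs = [gene[1:], gene[:-1], gene[2:]]
        graph = build_similarity_graph(seqs, max_dist=2)
        merged = merge_cliques(graph, engine=cdr3s)
        assert len(merged) == 1
        assert gene in merged[0] and len(merged[0]) <= len(gene) + 2


class TestCrossDatasetMerge:
    def test_substring_removed(self):
        out = merge_across_datasets([["ACGTACGTAC"], ["GTACGTAC"]])
        assert out == ["ACGTACGTAC"]

    def test_disjoint_union(self):
        out = merge_across_datasets([["AAAAAAAAAA"], ["CCGGCCGGTT"]])
        assert sorted(out) == ["AAAAAAAAAA", "CCGGCCGGTT"]

    def test_two_simulated_datasets_consolidate_to_planted_genes(self):
        model = GenerativeModel.default(51, n_genes=6, gene_length_range=(14, 30))
        cfg = PipelineConfig(num_seeds=300, min_dataset_size=0)
        lists = []
        for rep in range(2):
            cdr3s, _ = simulate_cdr3s(model, 20_000, rng_seed=60 + rep)
            lists.append(infer_genes(cdr3s, cfg).candidates)
        merged = merge_across_datasets(lists)
        genes = [g for _, g, _ in model.seeds]

        def recovered(g):
            return any(
                len(g) - len(longest_common_substring(g, c)) <= 3
                and len(c) - len(longest_common_substring(g, c)) <= 3
                for c in merged
            )

        assert len(merged) <= len(genes) + 1
        assert sum(recovered(g) for g in genes) >= 5
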