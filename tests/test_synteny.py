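"""Chaining correctness, depth semantics, and microsynteny clustering."""

import numpy as np
import pytest

from paleosynteny.io import AnchorPair
from paleosynteny.synteny import (ChainParams, build_clusters, chain_anchors,
                                  phylogenomic_profile, shared_cluster_counts,
                                  syntenic_depth, syntenic_gene_pairs)

from conftest import make_annotation
from oracles import union_find_components


def _pair_setup(n_q=20, n_t=20):
    q = make_annotation("q", {"c1": [f"q{i}" for i in range(n_q)]})
    t = make_annotation("t", {"c1": [f"t{i}" for i in range(n_t)]})
    return q, t


class TestChainAnchors:
    def test_perfect_minimum_block(self):
        q, t = _pair_setup()
        anchors = [AnchorPair(f"q{i}", f"t{10 + i}") for i in range(5)]
        blocks = chain_anchors(anchors, q, t)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.orientation, b.n_anchors) == ("+", 5)
        assert (b.q_start, b.q_end, b.t_start, b.t_end) == (0, 4, 10, 14)

    def test_below_block_size_discarded(self):
        q, t = _pair_setup()
        anchors = [AnchorPair(f"q{i}", f"t{i}") for i in range(4)]
        assert chain_anchors(anchors, q, t) == []

    def test_gap_size_limits_chain(self):
        q, t = _pair_setup()
        # a 7-rank hole on the target side breaks the chain at gap_size 5
        anchors = [AnchorPair(f"q{i}", f"t{i}") for i in range(5)]
        anchors += [AnchorPair(f"q{5 + i}", f"t{12 + i}") for i in range(5)]
        blocks = chain_anchors(anchors, q, t, ChainParams(block_size=5, gap_size=5))
        assert [b.n_anchors for b in blocks] == [5, 5]
        one = chain_anchors(anchors, q, t, ChainParams(block_size=5, gap_size=7))
        assert [b.n_anchors for b in one] == [10]

    def test_inversion_robustness(self):
        """Reversing a target segment turns + blocks into - with identical anchors."""
        q, t = _pair_setup()
        fwd = [AnchorPair(f"q{i}", f"t{i}") for i in range(8)]
        rev = [AnchorPair(f"q{i}", f"t{7 - i}") for i in range(8)]
        bf = chain_anchors(fwd, q, t)
        br = chain_anchors(rev, q, t)
        assert [b.orientation for b in bf] == ["+"]
        assert [b.orientation for b in br] == ["-"]
        assert {h.gene_a for h in bf[0].anchors} == {h.gene_a for h in br[0].anchors}

    def test_anchor_partition_and_gap_invariant(self):
        """No anchor lands in two blocks; internal gaps respect gap_size."""
        rng = np.random.default_rng(42)
        q = make_annotation("q", {"c1": [f"q{i}" for i in range(120)]})
        t = make_annotation("t", {"c1": [f"t{i}" for i in range(120)]})
        idx = rng.permutation(120)
        anchors = [AnchorPair(f"q{i}", f"t{idx[i]}") for i in range(120)]
        params = ChainParams(block_size=3, gap_size=4)
        blocks = chain_anchors(anchors, q, t, params)
        seen = set()
        for b in blocks:
            qs = [h.q_rank for h in b.anchors]
            ts = [h.t_rank for h in b.anchors]
            for h in b.anchors:
                assert (h.gene_a, h.gene_b) not in seen
                seen.add((h.gene_a, h.gene_b))
            assert all(1 <= y - x <= params.gap_size + 1 for x, y in zip(qs, qs[1:]))
            dts = [y - x for x, y in zip(ts, ts[1:])]
            sign = 1 if b.orientation == "+" else -1
            assert all(1 <= sign * d <= params.gap_size + 1 for d in dts)

    def test_tandem_array_does_not_inflate_blocks(self):
        """Two anchors per query gene into one local region yield one block."""
        q, t = _pair_setup()
        anchors = [AnchorPair(f"q{i}", f"t{i}") for i in range(6)]
        anchors += [AnchorPair(f"q{i}", f"t{i + 1}") for i in range(6)]
        blocks = chain_anchors(anchors, q, t, ChainParams(block_size=5, gap_size=5,
                                                          exact_limit=0))
        assert len(blocks) == 1


class TestSyntenicDepth:
    def test_no_blocks_all_zero(self):
        q, t = _pair_setup()
        d = syntenic_depth([], q)
        assert (d == 0).all() and len(d) == 20

    def test_span_coverage_includes_non_anchor_genes(self):
        q, t = _pair_setup()
        anchors = [AnchorPair(f"q{r}", f"t{r}") for r in (2, 3, 5, 6, 7)]
        blocks = chain_anchors(anchors, q, t)
        d = syntenic_depth(blocks, q)
        assert d.loc[[f"q{i}" for i in range(2, 8)]].eq(1).all()  # q4 covered by span
        assert d.sum() == 6

    def test_depth_conservation(self, lossfree_sim):
        from paleosynteny.synteny import chain_anchors as ca

        og, sp1 = lossfree_sim.genomes["og"], lossfree_sim.genomes["sp1"]
        blocks = ca(lossfree_sim.anchors[("og", "sp1")], og, sp1, ChainParams())
        d = syntenic_depth(blocks, og)
        assert d.sum() == sum(b.q_end - b.q_start + 1 for b in blocks)


class TestSyntenicGenePairs:
    def test_union_and_dedup(self):
        q, t = _pair_setup()
        anchors = [AnchorPair(f"q{i}", f"t{i}") for i in range(5)]
        anchors += [AnchorPair(f"q{10 + i}", f"t{10 + i}") for i in range(5)]
        blocks = chain_anchors(anchors, q, t)
        assert len(syntenic_gene_pairs(blocks)) == 10
        assert syntenic_gene_pairs([]) == []
        assert len(syntenic_gene_pairs(blocks + blocks)) == 10  # dedup


class TestClusters:
    def test_chain_across_three_species(self):
        species_of = {"g1": "spA", "g2": "spB", "g3": "spC"}
        clusters = build_clusters(
            [AnchorPair("g1", "g2"), AnchorPair("g2", "g3")], species_of)
        assert len(clusters) == 1
        assert clusters[0].copy_number == {"spA": 1, "spB": 1, "spC": 1}

    def test_single_species_component_dropped(self):
        species_of = {"g1": "spA", "g2": "spA", "g3": "spB", "g4": "spC"}
        clusters = build_clusters(
            [AnchorPair("g1", "g2"), AnchorPair("g3", "g4")], species_of)
        assert len(clusters) == 1 and clusters[0].species == {"spB", "spC"}

    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        edges = [(f"g{int(rng.integers(n))}", f"g{int(rng.integers(n))}")
                 for _ in range(int(rng.integers(3, 60)))]
        edges = [(a, b) for a, b in edges if a != b]
        species_of = {f"g{i}": f"sp{i % 3}" for i in range(n)}
        clusters = build_clusters([AnchorPair(a, b) for a, b in edges],
                                  species_of, min_species=1)
        got = {frozenset(g for _, g in c.members) for c in clusters}
        assert got == set(union_find_components(edges))


class TestProfileAndSharedCounts:
    def _clusters(self, pattern):
        species_of = {}
        pairs = []
        for ci, members in enumerate(pattern):
            genes = []
            for sp, k in members.items():
                for j in range(k):
                    g = f"c{ci}_{sp}_{j}"
                    species_of[g] = sp
                    genes.append(g)
            pairs += [AnchorPair(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
        return build_clusters(pairs, species_of)

    def test_single_cluster_profile(self):
        clusters = self._clusters([{"A": 1, "B": 2}])
        mat, order = phylogenomic_profile(clusters, ["A", "B"])
        assert mat.shape == (2, 1)
        assert mat.iloc[:, 0].tolist() == [1, 2]

    def test_identical_columns_adjacent(self):
        pattern = [{"A": 1, "B": 1}, {"A": 3, "B": 3, "C": 3},
                   {"A": 1, "B": 1}, {"A": 3, "B": 3, "C": 3}, {"A": 9, "C": 9}]
        clusters = self._clusters(pattern)
        mat, order = phylogenomic_profile(clusters, ["A", "B", "C"])
        cols = [tuple(mat[c]) for c in mat.columns]
        for i, c in enumerate(cols):
            if cols.count(c) == 2:
                assert c in (cols[max(0, i - 1)], cols[min(len(cols) - 1, i + 1)])

    def test_shared_counts_exact_span(self):
        clusters = self._clusters([{"A": 1, "B": 1, "C": 1}, {"A": 1, "B": 1},
                                   {"C": 1, "D": 1}])
        clade_of = {"A": "x", "B": "x", "C": "y", "D": "y"}
        counts = shared_cluster_counts(clusters, clade_of)
        assert counts == {("x", "y"): 1, ("x",): 1, ("y",): 1}

    def test_unknown_species_rejected(self):
        clusters = self._clusters([{"A": 1, "B": 1}])
        with pytest.raises(Exception, match="clade"):
            shared_cluster_counts(clusters, {"A": "x"})
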