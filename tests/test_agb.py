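"""Level 2-4 block reconstruction, region definition, and model-genome mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from paleosynteny.agb import (assign_homoeologs, build_model_genome, define_regions,
                              lift_anchors, map_to_agbs, merge_level2, order_level4)
from paleosynteny.evaluation import agb_recovery, set_accuracy, slot_ari, truth_labels
from paleosynteny.io import AnchorPair, ValidationError
from paleosynteny.simulate import SimulationConfig, simulate_clade
from paleosynteny.synteny import AnchorHit, ChainParams, SyntenyBlock, chain_anchors

from conftest import make_annotation


def _block(bid, qc, q0, q1, tc, t0, t1, orient="+"):
    n = q1 - q0 + 1
    if orient == "+":
        hits = [AnchorHit(f"{qc}_g{q0 + i}", f"{tc}_g{t0 + i}", q0 + i, t0 + i)
                for i in range(n)]
    else:
        hits = [AnchorHit(f"{qc}_g{q0 + i}", f"{tc}_g{t1 - i}", q0 + i, t1 - i)
                for i in range(n)]
    return SyntenyBlock(bid, qc, tc, orient, hits, q0, q1, t0, t1)


def _build_model(sim, sp="sp1", merge_tol=15):
    og = sim.genomes["og"]
    ing = sim.genomes[sp]
    anchors = [AnchorPair(a.gene_b, a.gene_a) for a in sim.anchors[("og", sp)]]
    blocks = chain_anchors(anchors, ing, og, ChainParams())
    l2 = merge_level2(blocks, ing, og, tol=merge_tol)
    regions = define_regions(og, l2, 16)
    sets, conflicts = assign_homoeologs(l2, regions, ing)
    sets = order_level4(sets, og)
    return build_model_genome(sets, ing), l2, regions, sets, conflicts


class TestMergeLevel2:
    def test_adjacent_spans_merge(self):
        ing = make_annotation("i", {"c1": [f"c1_g{i}" for i in range(40)]})
        outg = make_annotation("o", {"o1": [f"o1_g{i}" for i in range(40)]})
        b1 = _block("b1", "c1", 0, 9, "o1", 0, 9)
        b2 = _block("b2", "c1", 10, 19, "o1", 10, 19)
        merged = merge_level2([b1, b2], ing, outg, tol=5)
        assert len(merged) == 1
        assert (merged[0].outgroup_start, merged[0].outgroup_end) == (0, 19)
        assert merged[0].members == ["b1", "b2"]

    def test_different_outgroup_chroms_do_not_merge(self):
        ing = make_annotation("i", {"c1": [f"c1_g{i}" for i in range(40)]})
        outg = make_annotation("o", {"o1": [f"o1_g{i}" for i in range(20)],
                                     "o2": [f"o2_g{i}" for i in range(20)]})
        b1 = _block("b1", "c1", 0, 9, "o1", 0, 9)
        b2 = _block("b2", "c1", 10, 19, "o2", 10, 19)
        assert len(merge_level2([b1, b2], ing, outg)) == 2

    def test_gap_beyond_tolerance_blocks_merge(self):
        ing = make_annotation("i", {"c1": [f"c1_g{i}" for i in range(60)]})
        outg = make_annotation("o", {"o1": [f"o1_g{i}" for i in range(60)]})
        b1 = _block("b1", "c1", 0, 9, "o1", 0, 9)
        b2 = _block("b2", "c1", 10, 19, "o1", 30, 39)
        assert len(merge_level2([b1, b2], ing, outg, tol=5)) == 2
        assert len(merge_level2([b1, b2], ing, outg, tol=25)) == 1

    def test_conservation_on_simulation(self, default_sim):
        sim = default_sim
        anchors = [AnchorPair(a.gene_b, a.gene_a) for a in sim.anchors[("og", "sp1")]]
        blocks = chain_anchors(anchors, sim.genomes["sp1"], sim.genomes["og"], ChainParams())
        merged = merge_level2(blocks, sim.genomes["sp1"], sim.genomes["og"])
        assert len(merged) <= len(blocks)
        # merging never loses anchors beyond those dropped for ingroup-span
        # overlap, and never reduces outgroup anchor coverage
        kept_members = {m for b in merged for m in b.members}
        kept_blocks = [b for b in blocks if b.block_id in kept_members]
        anchors_before = {(h.gene_a, h.gene_b) for b in kept_blocks for h in b.anchors}
        anchors_after = {(h.gene_a, h.gene_b) for b in merged for h in b.anchors}
        assert anchors_after == anchors_before
        cov_before = {(b.target_chrom, r) for b in kept_blocks
                      for r in range(b.t_start, b.t_end + 1)}
        cov_after = {(b.outgroup_chrom, r) for b in merged
                     for r in range(b.outgroup_start, b.outgroup_end + 1)}
        assert cov_before <= cov_after


class TestDefineRegions:
    def test_n_regions_equals_n_chrom(self, small_lossfree_sim):
        og = small_lossfree_sim.genomes["og"]
        regions = define_regions(og, [], n_regions=2)
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr01", 0, 59), ("chr02", 0, 59)]

    def test_sixteen_regions_one_cut_per_chromosome(self, default_sim):
        og = default_sim.genomes["og"]
        regions = define_regions(og, [], n_regions=16)
        assert len(regions) == 16
        per_chrom = pd.Series([r.chrom for r in regions]).value_counts()
        assert (per_chrom == 2).all()

    def test_no_boundaries_fall_back_to_midpoints(self, small_lossfree_sim):
        og = small_lossfree_sim.genomes["og"]
        regions = define_regions(og, [], n_regions=4)
        assert [(r.start, r.end) for r in regions] == [(0, 29), (30, 59)] * 2

    def test_too_few_regions_rejected(self, small_lossfree_sim):
        with pytest.raises(ValidationError):
            define_regions(small_lossfree_sim.genomes["og"], [], n_regions=1)


class TestAssignAndOrder:
    def test_lossfree_recovery_is_perfect(self, lossfree_sim):
        model, l2, regions, sets, conflicts = _build_model(lossfree_sim)
        acc, ari, n = agb_recovery(model, lossfree_sim.truth)
        assert conflicts.empty
        assert acc == 1.0 and ari == 1.0
        assert n == lossfree_sim.genomes["sp1"].n_genes

    def test_fractionated_recovery(self, default_sim):
        model, *_ = _build_model(default_sim)
        acc, ari, n = agb_recovery(model, default_sim.truth)
        assert acc >= 0.95 and ari >= 0.9

    def test_slot_tiling_invariant(self, default_sim):
        """Within a set, one slot never covers the same outgroup rank twice."""
        model, l2, regions, sets, conflicts = _build_model(default_sim)
        assert conflicts.empty
        for agb in sets:
            for slot, blocks in agb.slots.items():
                spans = sorted((b.outgroup_start, b.outgroup_end) for b in blocks)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 < s2

    def test_input_order_invariance(self, default_sim):
        sim = default_sim
        og, ing = sim.genomes["og"], sim.genomes["sp1"]
        anchors = [AnchorPair(a.gene_b, a.gene_a) for a in sim.anchors[("og", "sp1")]]
        blocks = chain_anchors(anchors, ing, og, ChainParams())
        l2 = merge_level2(blocks, ing, og)
        regions = define_regions(og, l2, 16)
        s1, _ = assign_homoeologs(l2, regions, ing)
        s2, _ = assign_homoeologs(list(reversed(l2)), regions, ing)
        for a, b in zip(s1, s2):
            assert {k: [x.block_id for x in v] for k, v in a.slots.items()} == \
                   {k: [x.block_id for x in v] for k, v in b.slots.items()}

    def test_order_level4_flips_inverted_block_and_improves_collinearity(self, default_sim):
        sim = default_sim
        model, l2, regions, sets, _ = _build_model(sim)
        og_rank = {g: sim.genomes["og"].rank_of(g) for g in sim.genomes["og"].df.gene_id}
        # after ordering, Kendall tau between slot gene order and outgroup order
        # must be >= the unordered value for every set/slot
        raw_sets, _ = assign_homoeologs(l2, regions, sim.genomes["sp1"])
        ordered = order_level4(raw_sets, sim.genomes["og"])

        def tau_of(agb_sets):
            taus = []
            for agb in agb_sets:
                for slot, blocks in agb.slots.items():
                    ts = [h.t_rank for b in blocks
                          for h in (b.anchors if b.orientation == "+" else b.anchors[::-1])]
                    if len(ts) > 2:
                        t, _ = kendalltau(ts, range(len(ts)))
                        taus.append(t)
            return float(np.mean(taus))

        assert tau_of(ordered) >= tau_of(raw_sets) - 1e-9


class TestModelGenomeAndMapping:
    def test_48_pseudochromosomes_and_conservation(self, default_sim):
        model, *_ = _build_model(default_sim)
        assert model.n_agbs == 48
        placed = sum(model.slot_totals.values())
        assert placed == len(model.provenance) <= default_sim.genomes["sp1"].n_genes

    def test_lossfree_slot_totals_equal_ancestral_count(self, lossfree_sim):
        model, *_ = _build_model(lossfree_sim)
        assert model.slot_totals == {"a": 4000, "b": 4000, "c": 4000}

    def test_self_mapping_is_consistent(self, default_sim):
        model, *_ = _build_model(default_sim)
        sp1 = default_sim.genomes["sp1"]
        ident = [AnchorPair(g, g) for g in sorted(model.source_of)]
        blocks = chain_anchors(lift_anchors(ident, model), sp1, model.annotation,
                               ChainParams())
        labels = map_to_agbs(sp1, blocks, model)
        placed = labels.index.intersection(model.source_of)
        own = sum(model.source_of[g].startswith(labels.loc[g, "agb"]) for g in placed)
        assert own / len(placed) >= 0.99

    def test_sibling_mapping_matches_truth(self, default_sim):
        sim = default_sim
        model, *_ = _build_model(sim)
        sp2 = sim.genomes["sp2"]
        pairs = [AnchorPair(a.gene_b, a.gene_a) for a in sim.anchors[("sp1", "sp2")]]
        blocks = chain_anchors(lift_anchors(pairs, model), sp2, model.annotation,
                               ChainParams())
        labels = map_to_agbs(sp2, blocks, model).dropna()
        tr = truth_labels(labels.index, sim.truth)
        assert set_accuracy(labels["set_index"], tr["set_index"]) >= 0.95
        assert slot_ari(labels[["set_index", "slot"]], tr) >= 0.9

    def test_zero_anchors_empty_mapping(self, default_sim):
        model, *_ = _build_model(default_sim)
        labels = map_to_agbs(default_sim.genomes["sp2"], [], model)
        assert labels.empty
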