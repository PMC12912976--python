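"""RTG calling, hotspot calibration, over-representation and tau."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from paleosynteny.io import ValidationError
from paleosynteny.rtg import (build_copy_matrix, call_rtgs, overrepresentation,
                              rtg_hotspots, tau, tau_contrast, tau_matrix)

from conftest import make_annotation


def _matrix(ref, presence):
    return build_copy_matrix(presence, ref)


class TestCopyMatrix:
    def test_lossfree_matrix_is_all_ones(self, small_lossfree_sim):
        sim = small_lossfree_sim
        og = sim.genomes["og"]
        presence = {sp: sim.truth.presence_matrix(sp, og) for sp in sim.descendants}
        m = _matrix(og, presence)
        assert m.to_numpy().all()
        assert m.shape == (120, 6)  # 120 genes x (2 species x 3 slots)

    def test_single_missing_copy_is_a_single_zero(self, small_lossfree_sim):
        sim = small_lossfree_sim
        og = sim.genomes["og"]
        presence = {sp: sim.truth.presence_matrix(sp, og).copy()
                    for sp in sim.descendants}
        victim = og.genes_on("chr01")[3]
        presence["sp1"].loc[victim, "b"] = False
        m = _matrix(og, presence)
        assert m.loc[victim].sum() == 5
        assert m.drop(index=victim).to_numpy().all()

    def test_column_sums_match_retention_counts(self, default_sim):
        """Cross-module consistency with the retention presence calls."""
        sim = default_sim
        og = sim.genomes["og"]
        presence = {sp: sim.truth.presence_matrix(sp, og) for sp in sim.descendants}
        m = _matrix(og, presence)
        for sp in sim.descendants:
            for slot in "abc":
                assert m[(sp, slot)].sum() == presence[sp][slot].sum()

    def test_missing_slot_filled_with_zeros(self, small_lossfree_sim):
        sim = small_lossfree_sim
        og = sim.genomes["og"]
        presence = {sp: sim.truth.presence_matrix(sp, og) for sp in sim.descendants}
        presence["sp1"] = presence["sp1"][["a", "b"]]
        m = _matrix(og, presence)
        assert (m[("sp1", "c")] == 0).all()


class TestCallRtgs:
    def _toy_matrix(self, rows, n_species=4):
        cols = pd.MultiIndex.from_product(
            [[f"sp{i}" for i in range(1, n_species + 1)], list("abc")],
            names=["species", "slot"])
        return pd.DataFrame(rows, columns=cols,
                            index=[f"g{i}" for i in range(len(rows))])

    def test_all_ones_all_rtg(self):
        m = self._toy_matrix([[1] * 12] * 3)
        assert call_rtgs(m)["rtg"].all()

    def test_strict_threshold_rejects_single_missing_copy(self):
        row = [1] * 12
        row[4] = 0
        m = self._toy_matrix([row, [1] * 12])
        calls = call_rtgs(m, species_fraction=1.0)
        assert calls["rtg"].tolist() == [False, True]

    def test_monotone_in_species_fraction(self):
        rng = np.random.default_rng(0)
        m = self._toy_matrix((rng.random((300, 12)) < 0.75).astype(int))
        counts = [call_rtgs(m, f)["rtg"].sum() for f in (0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_validation(self):
        m = self._toy_matrix([[1] * 12])
        with pytest.raises(ValidationError):
            call_rtgs(m, species_fraction=0.0)


class TestHotspots:
    def _ann(self, n=2000):
        return make_annotation("m", {f"c{i // 500}": [f"g{j}" for j in
                                                      range(i, min(i + 500, n))]
                                     for i in range(0, n, 500)})

    def test_concentrated_rtgs_flagged(self):
        ann = self._ann()
        flags = pd.Series(False, index=[f"g{i}" for i in range(2000)])
        flags.iloc[100:130] = True  # all in one window
        hs = rtg_hotspots(flags, ann, window=50, n_perm=300, seed=0)
        hot = hs[hs["hotspot"]]
        assert len(hot) == 1 and hot["count"].iloc[0] == 30

    def test_zero_rtgs_no_hotspots(self):
        ann = self._ann()
        flags = pd.Series(False, index=[f"g{i}" for i in range(2000)])
        hs = rtg_hotspots(flags, ann, window=50, n_perm=100, seed=0)
        assert not hs["hotspot"].any()

    def test_null_calibration_near_alpha(self):
        """Uniform placement flags ~5% of windows (mean over 20 seeds)."""
        ann = self._ann()
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            flags = pd.Series(rng.random(2000) < 0.02,
                              index=[f"g{i}" for i in range(2000)])
            hs = rtg_hotspots(flags, ann, window=50, n_perm=200, seed=seed)
            fracs.append(hs["hotspot"].mean())
        assert 0.03 <= float(np.mean(fracs)) <= 0.07


class TestOverrepresentation:
    def test_no_association(self):
        background = {f"g{i}" for i in range(40)}
        target = {f"g{i}" for i in range(20)}
        labels = {f"g{i}": {"TF"} for i in list(range(10)) + list(range(20, 30))}
        df = overrepresentation(target, labels, background)
        row = df.iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_enriched_label_or_and_hypergeometric_p(self):
        # target: 8 with label, 2 without; rest: 12 with, 78 without
        background = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(10)}
        labelled = set(list(target)[:8]) | {f"g{i}" for i in range(50, 62)}
        labels = {g: {"TF"} for g in labelled}
        df = overrepresentation(target, labels, background)
        row = df.iloc[0]
        assert row["odds_ratio"] == pytest.approx(26.0)
        # two-sided Fisher p from first principles: sum hypergeometric
        # probabilities of tables at most as likely as the observed one
        N, K, n = 100, 20, 10
        probs = {a: comb(K, a) * comb(N - K, n - a) / comb(N, n)
                 for a in range(max(0, n + K - N), min(K, n) + 1)}
        p_expect = sum(p for p in probs.values() if p <= probs[8] * (1 + 1e-9))
        assert row["p"] == pytest.approx(p_expect, rel=1e-6)

    def test_label_missing_from_background_skipped(self):
        df = overrepresentation({"g1"}, {"g9": {"X"}}, {"g1", "g2"})
        assert df.empty

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation(set(), {}, set())


class TestTau:
    @pytest.mark.parametrize("vec,expect", [
        ((10, 0, 0, 0), 1.0),
        ((5, 5, 5, 5), 0.0),
        ((8, 4, 0, 0), 2.5 / 3),
    ])
    def test_known_values(self, vec, expect):
        assert tau(vec) == pytest.approx(expect)

    def test_all_zero_undefined(self):
        assert math.isnan(tau((0.0, 0.0, 0.0)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.random(int(rng.integers(2, 15))) * 10
            c = float(rng.uniform(0.01, 100))
            assert tau(c * x) == pytest.approx(tau(x), abs=1e-12)

    def test_single_tissue_rejected(self):
        with pytest.raises(ValidationError):
            tau([5.0])
        with pytest.raises(ValidationError):
            tau_matrix(pd.DataFrame({"t1": [1.0, 2.0]}))


class TestTauContrast:
    def test_planted_specialization_detected(self, default_sim):
        sim = default_sim
        t = sim.truth
        expr = sim.expression
        rtg_genes = [g for g in expr.index if t.ancestral_gene_of.get(g) in t.rtg_set]
        controls = [g for g in expr.index
                    if t.ancestral_gene_of.get(g) not in t.rtg_set][:3 * len(rtg_genes)]
        res = tau_contrast(rtg_genes, controls, expr)
        assert res.tau_a.median() > res.tau_b.median()
        assert res.p_value < 0.01

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.lognormal(1, 0.3, (60, 6)),
                            index=[f"g{i}" for i in range(60)],
                            columns=[f"t{i}" for i in range(6)])
        res = tau_contrast([f"g{i}" for i in range(30)],
                           [f"g{i}" for i in range(30, 60)], expr)
        assert res.p_value > 0.05

    def test_empty_group_rejected(self):
        expr = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                            columns=["t1", "t2", "t3"])
        with pytest.raises(ValidationError):
            tau_contrast(["a"], ["zzz"], expr)
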