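"""Lineage aggregation, Kruskal-Wallis screen, and LDA effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, rankdata

from assemblage import (CountTable, GroupDesign, LefseScreen,
                        aggregate_lineages, kw_screen)

from conftest import random_table


def taxonomy_for(table, n_phyla=3):
    return {t: f"Phylum{i % n_phyla};Class{i % n_phyla}_{i % 2}"
            for i, t in enumerate(table.taxon_ids)}


class TestAggregation:
    def test_single_phylum_sums_to_scale(self, small_table):
        tax = {t: "PhylumA;ClassB" for t in small_table.taxon_ids}
        feats = aggregate_lineages(small_table, tax)
        np.testing.assert_allclose(feats.loc["PhylumA"], 1e6)
        np.testing.assert_allclose(feats.loc["PhylumA|ClassB"], 1e6)

    def test_children_sum_to_parent(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_taxa=20, n_samples=5)
        feats = aggregate_lineages(t, taxonomy_for(t))
        for parent in [f for f in feats.index if "|" not in f]:
            children = [f for f in feats.index
                        if f.startswith(parent + "|") and f.count("|") == 1]
            np.testing.assert_allclose(feats.loc[children].sum(axis=0),
                                       feats.loc[parent], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_groupby(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_taxa=15, n_samples=4)
        tax = taxonomy_for(t)
        feats = aggregate_lineages(t, tax)
        df = t.to_dataframe()
        phylum = pd.Series({otu: tax[otu].split(";")[0] for otu in t.taxon_ids})
        brute = df.groupby(phylum).sum() / df.sum(axis=0) * 1e6
        for ph in brute.index:
            np.testing.assert_allclose(feats.loc[ph], brute.loc[ph])

    def test_missing_taxa_fall_back_to_unclassified(self, small_table):
        feats = aggregate_lineages(small_table, {})
        assert "unclassified" in feats.index


class TestKruskalWallis:
    def _design(self, n=10):
        return GroupDesign({f"s{j}": ("A" if j < n // 2 else "B")
                            for j in range(n)})

    def test_identical_distributions_fail(self):
        feats = pd.DataFrame([[5.0] * 10], index=["flat"],
                             columns=[f"s{j}" for j in range(10)])
        out = kw_screen(feats, self._design())
        assert out.loc["flat", "kw_p"] == 1.0
        assert not out.loc["flat", "passed"]

    def test_one_class_shift_passes(self):
        vals = [0.0] * 5 + [100.0, 110.0, 90.0, 105.0, 95.0]
        feats = pd.DataFrame([vals], index=["shift"],
                             columns=[f"s{j}" for j in range(10)])
        out = kw_screen(feats, self._design())
        assert out.loc["shift", "passed"]

    def test_h_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 4, size=12).astype(float)  # heavy ties
        cols = [f"s{j}" for j in range(12)]
        design = GroupDesign({c: ("A" if j < 4 else "B" if j < 8 else "C")
                              for j, c in enumerate(cols)})
        feats = pd.DataFrame([vals], index=["x"], columns=cols)
        out = kw_screen(feats, design)
        # independent oracle: H from midranks with tie correction
        ranks = rankdata(vals)
        groups = [ranks[:4], ranks[4:8], ranks[8:]]
        n = 12
        h = 12 / (n * (n + 1)) * sum(len(g) * g.mean() ** 2 for g in groups) \
            - 3 * (n + 1)
        _, counts = np.unique(vals, return_counts=True)
        h /= 1 - (counts**3 - counts).sum() / (n**3 - n)
        assert out.loc["x", "kw_h"] == pytest.approx(h)
        assert out.loc["x", "kw_h"] == pytest.approx(
            kruskal(vals[:4], vals[4:8], vals[8:]).statistic)


class TestLdaEffectSize:
    def _planted_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_taxa=30, n_samples=12, lam=20)
        # plant a 100-fold enrichment of taxon o0 in category A
        counts = t.counts.copy()
        counts[0, :6] = 100 * (counts[0, :6] + 1)
        t = CountTable(t.taxon_ids, t.sample_ids, counts)
        design = GroupDesign({f"s{j}": ("A" if j < 6 else "B")
                              for j in range(12)})
        tax = {otu: f"P{i}" for i, otu in enumerate(t.taxon_ids)}
        return t, design, tax

    def test_planted_biomarker_recovered_for_its_class(self):
        t, design, tax = self._planted_setup()
        feats = aggregate_lineages(t, tax)
        df = LefseScreen(feats, design).fit(n_boot=20, seed=1)
        hit = df[df["feature"] == "P0"]
        assert len(hit) == 1
        assert hit.iloc[0]["enriched_class"] == "A"
        assert hit.iloc[0]["passed"]

    def test_enriched_class_is_argmax_of_class_means(self):
        t, design, tax = self._planted_setup(seed=2)
        feats = aggregate_lineages(t, tax)
        df = LefseScreen(feats, design).fit(n_boot=10, seed=3)
        for _, row in df.iterrows():
            means = feats.loc[row["feature"]].groupby(
                pd.Series(design.for_table(t), index=feats.columns)).mean()
            assert row["enriched_class"] == means.idxmax()

    def test_deterministic_and_single_class_per_feature(self):
        t, design, tax = self._planted_setup(seed=4)
        feats = aggregate_lineages(t, tax)
        a = LefseScreen(feats, design).fit(n_boot=15, seed=5)
        b = LefseScreen(feats, design).fit(n_boot=15, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a["feature"].is_unique

    def test_zero_separation_below_threshold(self):
        cols = [f"s{j}" for j in range(12)]
        design = GroupDesign({c: ("A" if j < 6 else "B")
                              for j, c in enumerate(cols)})
        rng = np.random.default_rng(6)
        flat = pd.DataFrame(rng.normal(1000, 1, size=(3, 12)),
                            index=["f1", "f2", "f3"], columns=cols)
        df = LefseScreen(flat, design, alpha=1.0).fit(n_boot=10, seed=7)
        assert not df["passed"].any()
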