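"""Synthetic-community generator: ground truth, reproducibility, and the
statistical properties downstream stages rely on."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from assemblage import (GroupDesign, SimSpec, blomberg_k, make_host_tree,
                        make_metacommunity, plant_niche_otus,
                        simulate_community, simulate_host_traits,
                        simulate_neutral, simulate_niche)
from assemblage.neutral import _beta_occupancy
from assemblage.simulate import tree_vcv


class TestMetacommunity:
    def test_zero_variance_is_uniform(self):
        meta = make_metacommunity(4, sigma=0.0, seed=0)
        np.testing.assert_allclose(meta.p, 0.25)

    def test_normalized_and_positive(self):
        meta = make_metacommunity(500, sigma=2.0, seed=1)
        assert meta.p.sum() == pytest.approx(1.0)
        assert meta.p.min() > 0

    def test_evenness_decreases_with_sigma(self):
        def gini(p):
            p = np.sort(p)
            n = p.size
            return float((2 * np.arange(1, n + 1) - n - 1) @ p / (n * p.sum()))

        sigmas = [0.5, 1.0, 1.5, 2.0, 3.0]
        ginis = [np.mean([gini(make_metacommunity(200, s, seed=r).p)
                          for r in range(5)]) for s in sigmas]
        assert spearmanr(sigmas, ginis).statistic > 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            make_metacommunity(1)


class TestNeutral:
    def test_reproducible(self):
        meta = make_metacommunity(40, 1.5, seed=0)
        a = simulate_neutral(meta, 6, 300, 0.2, seed=5)
        b = simulate_neutral(meta, 6, 300, 0.2, seed=5)
        assert a == b

    def test_high_m_low_variance(self):
        meta = make_metacommunity(20, 1.0, seed=2)
        t = simulate_neutral(meta, 30, 20000, 1.0, seed=3)
        rel = t.counts / t.counts.sum(axis=0)
        # composition hugs the metacommunity when N*m is huge
        assert np.abs(rel.mean(axis=1) - meta.p).max() < 0.02

    def test_abundant_taxon_always_occurs(self):
        meta = make_metacommunity(30, 2.0, seed=4)
        t = simulate_neutral(meta, 20, 5000, 0.5, seed=5)
        top = int(np.argmax(meta.p))
        assert (t.counts[top] > 0).all()

    def test_marginal_occupancy_matches_model(self):
        # occurrence frequency over many samples matches the neutral-model
        # prediction with exact read-sampling detection, within 3 SE
        meta = make_metacommunity(60, 1.5, seed=6)
        N, m, n = 800, 0.3, 500
        t = simulate_neutral(meta, n, N, m, seed=7)
        f = (t.counts > 0).mean(axis=1)
        pred = _beta_occupancy(meta.p, m, N, 1 / N, detection="exact")
        se = np.sqrt(pred * (1 - pred) / n)
        assert (np.abs(f - pred) <= 3 * se + 0.01).all()

    def test_invalid_m(self):
        meta = make_metacommunity(10, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_neutral(meta, 5, 100, 0.0)


class TestNiche:
    @staticmethod
    def _design(n_cat=2, reps=4):
        return GroupDesign({f"c{c}_s{r}": f"c{c}"
                            for c in range(n_cat) for r in range(reps)})

    def test_sigma_zero_no_category_structure(self):
        meta = make_metacommunity(100, 1.5, seed=8)
        design = self._design()
        t = simulate_niche(meta, design, 0.0, 2000, seed=9)
        d = squareform(pdist(t.counts.T.astype(float), "braycurtis"))
        labels = design.for_table(t)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(8, 1)
        within = d[iu][same[iu]].mean()
        between = d[iu][~same[iu]].mean()
        assert abs(within - between) < 0.05

    def test_strong_selection_separates_categories(self):
        meta = make_metacommunity(100, 1.5, seed=10)
        design = self._design()
        t = simulate_niche(meta, design, 3.0, 2000, seed=11)
        d = squareform(pdist(t.counts.T.astype(float), "braycurtis"))
        labels = design.for_table(t)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(8, 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean() - 0.2


class TestPlanting:
    def test_planted_breadths_and_truth(self):
        spec = SimSpec(S=120, n_categories=3, n_samples_per_category=4,
                       depth=2000, regime="niche", sigma_sel=0.0,
                       n_generalist=5, n_specialist=5, seed=12)
        table, design, truth = simulate_community(spec)
        from assemblage import levins_b
        b = levins_b(table)
        labels = design.for_table(table)
        for otu, lab in truth.items():
            i = table.taxon_ids.index(otu)
            if lab == "generalist":
                assert b[otu] > 0.9 * table.n_samples
            else:
                cat_sizes = 4
                assert b[otu] <= cat_sizes + 1e-9
                cats = {labels[j] for j in np.flatnonzero(table.counts[i] > 0)}
                assert len(cats) == 1

    def test_row_totals_preserved(self):
        spec = SimSpec(S=80, n_categories=2, n_samples_per_category=4,
                       depth=1000, regime="niche", sigma_sel=0.0, seed=13)
        table, design, _ = simulate_community(spec)
        planted, truth = plant_niche_otus(table, design, 3, 3, seed=14)
        np.testing.assert_array_equal(planted.taxon_sums, table.taxon_sums)

    def test_too_many_planted(self):
        spec = SimSpec(S=30, n_categories=2, n_samples_per_category=3,
                       depth=500, seed=15)
        table, design, _ = simulate_community(spec)
        with pytest.raises(ValueError):
            plant_niche_otus(table, design, 40, 0, seed=0)


class TestHostTraits:
    def test_vcv_is_valid_covariance(self):
        tree = make_host_tree(8, seed=0)
        labels, V = tree_vcv(tree)
        assert len(labels) == 8
        np.testing.assert_allclose(V, V.T)
        assert (np.linalg.eigvalsh(V) > -1e-9).all()

    def test_brownian_reproducible_and_replicated(self):
        tree = make_host_tree(4, seed=1)
        tr1, xt1 = simulate_host_traits(tree, "brownian", 1.0, reps_per_tip=3,
                                        seed=2)
        tr2, _ = simulate_host_traits(tree, "brownian", 1.0, reps_per_tip=3,
                                      seed=2)
        assert tr1 == tr2
        assert len(tr1) == 12
        # replicates of one species stay close (1% noise)
        vals = [tr1[f"sp1_r{r}"] for r in (1, 2, 3)]
        spread = np.ptp(vals)
        assert spread < 0.2 * np.std(list(tr1.values()))

    def test_negative_sigma_rejected(self):
        tree = make_host_tree(4, seed=1)
        with pytest.raises(ValueError):
            simulate_host_traits(tree, "brownian", -1.0)

    def test_constant_trait_flagged_downstream(self):
        tree = make_host_tree(4, seed=3)
        traits = {lf.taxon.label: 1.0 for lf in tree.leaf_node_iter()}
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(tree, traits)
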