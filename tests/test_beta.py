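"""Bray-Curtis and permutation group tests, with exhaustive and scikit-bio
cross-checks."""

from itertools import permutations

import numpy as np
import pytest
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from assemblage import Anosim, CountTable, GroupDesign, Permanova, bray_curtis

from conftest import random_table


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = CountTable(["a", "b"], ["s1", "s2"], np.array([[3, 3], [2, 2]]))
        assert bray_curtis(t)["s1", "s2"] == 0.0

    def test_disjoint_supports_one(self):
        t = CountTable(["a", "b"], ["s1", "s2"], np.array([[4, 0], [0, 6]]))
        assert bray_curtis(t)["s1", "s2"] == 1.0

    def test_hand_value(self):
        t = CountTable(["a", "b"], ["s1", "s2"], np.array([[2, 1], [2, 3]]))
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(0.25)

    def test_zero_sum_sample_rejected(self):
        t = CountTable(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="zero-sum"):
            bray_curtis(t)


def _brute_permanova(d, codes):
    n = len(codes)
    a = len(set(codes))
    d2 = d**2
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in set(codes):
        idx = np.flatnonzero(codes == g)
        ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a)), ss_a / ss_t


class TestPermanova:
    def test_matches_brute_force_and_exhaustive_p(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, n_taxa=10, n_samples=6)
        design = GroupDesign({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
        dm = bray_curtis(t)
        res = Permanova(dm, design).fit(n_permutations=999, seed=0)
        f, r2 = _brute_permanova(np.asarray(dm.data),
                                 np.array([0, 0, 0, 1, 1, 1]))
        assert res.statistic == pytest.approx(f)
        assert res.r_squared == pytest.approx(r2)
        # exhaustive p over all 6! label orders
        codes = np.array([0, 0, 0, 1, 1, 1])
        f_all = [_brute_permanova(np.asarray(dm.data), codes[list(p)])[0]
                 for p in permutations(range(6))]
        exact_p = np.mean([fp >= f - 1e-12 for fp in f_all])
        assert abs(res.p_value - exact_p) < 0.1

    def test_statistic_agrees_with_skbio(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_taxa=15, n_samples=9)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        design = GroupDesign(dict(zip(t.sample_ids, labels)))
        dm = bray_curtis(t)
        ours = Permanova(dm, design).fit(99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=0)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_separated_clusters_minimal_p(self):
        counts = np.zeros((4, 8), dtype=int)
        counts[:2, :4] = 50
        counts[2:, 4:] = 50
        t = CountTable(list("abcd"), [f"s{j}" for j in range(8)], counts)
        design = GroupDesign({f"s{j}": ("A" if j < 4 else "B") for j in range(8)})
        res = Permanova(bray_curtis(t), design).fit(99, seed=1)
        # permutations that reproduce the same 4|4 split tie with the observed
        # F (probability 2/70 each), so p sits just above 1/(n_perm+1)
        assert res.p_value <= 0.1
        assert res.statistic > 100

    def test_r2_identity(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, n_taxa=12, n_samples=8)
        design = GroupDesign({f"s{j}": ("A" if j % 2 else "B") for j in range(8)})
        dm = bray_curtis(t)
        res = Permanova(dm, design).fit(49, seed=0)
        d2 = np.asarray(dm.data) ** 2
        n = 8
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        codes = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        _, r2 = _brute_permanova(np.asarray(dm.data), codes)
        # R^2 + SS_W/SS_T = 1 exactly
        assert res.r_squared == pytest.approx(r2)
        assert 0 < res.p_value <= 1


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        counts = np.zeros((4, 6), dtype=int)
        counts[:2, :3] = np.array([[9, 8, 9], [5, 6, 5]])
        counts[2:, 3:] = np.array([[7, 7, 8], [4, 5, 4]])
        t = CountTable(list("abcd"), [f"s{j}" for j in range(6)], counts)
        design = GroupDesign({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
        res = Anosim(bray_curtis(t), design).fit(99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_agrees_with_skbio(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n_taxa=15, n_samples=8)
        labels = ["A"] * 4 + ["B"] * 4
        design = GroupDesign(dict(zip(t.sample_ids, labels)))
        dm = bray_curtis(t)
        ours = Anosim(dm, design).fit(9, seed=0)
        ref = skbio_anosim(dm, grouping=labels, permutations=0)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_null_mean_r_near_zero_and_bounds_with_ties(self):
        rng = np.random.default_rng(8)
        rs = []
        for s in range(60):
            counts = rng.integers(0, 3, size=(6, 8))  # many tied distances
            counts[0] += 1
            t = CountTable([f"o{i}" for i in range(6)],
                           [f"s{j}" for j in range(8)], counts)
            design = GroupDesign({f"s{j}": ("A" if j < 4 else "B")
                                  for j in range(8)})
            r = Anosim(bray_curtis(t), design).fit(9, seed=s).statistic
            assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
            rs.append(r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) <= 3 * se + 0.05
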