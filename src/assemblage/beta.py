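"""Bray-Curtis dissimilarity and permutation group tests (PERMANOVA, ANOSIM).

Both tests are one-way: they ask whether community composition differs among
the categories of a :class:`~assemblage.tables.GroupDesign`.  Permutation
p-values follow the ``(1 + more-extreme) / (n_perm + 1)`` convention and are
therefore never zero.  Dissimilarities are computed on (rarefied) counts, not
relative abundances, so library normalization must happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .tables import CountTable, GroupDesign

__all__ = ["bray_curtis", "Permanova", "Anosim", "GroupTestResult",
           "permanova", "anosim"]


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d_ij = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, table.sample_sums) if t == 0]
        raise ValueError(f"zero-sum samples: {bad}")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class GroupTestResult:
    """Outcome of a permutation group test on a distance matrix."""

    method: str
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_categories: int
    r_squared: float | None = None  # PERMANOVA only

    def summary(self) -> str:
        lines = [
            f"{self.method} ({self.n_samples} samples, "
            f"{self.n_categories} categories, {self.n_permutations} permutations)",
            f"  {self.statistic_name:10s} {self.statistic:.4f}",
        ]
        if self.r_squared is not None:
            lines.append(f"  {'R^2':10s} {self.r_squared:.4f}")
        lines.append(f"  {'p-value':10s} {self.p_value:.4g}")
        return "\n".join(lines)


def _group_codes(dm: DistanceMatrix, design: GroupDesign) -> tuple[np.ndarray, int]:
    missing = [s for s in dm.ids if s not in design.labels]
    if missing:
        raise ValueError(f"samples without a category label: {missing}")
    labels = [design.labels[s] for s in dm.ids]
    cats = [c for c in design.categories if c in labels]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    codes = np.array([cats.index(l) for l in labels])
    counts = np.bincount(codes, minlength=len(cats))
    if (counts < 2).any():
        small = [c for c, n in zip(cats, counts) if n < 2]
        raise ValueError(f"categories with fewer than 2 samples: {small}")
    return codes, len(cats)


class Permanova:
    """One-way permutational multivariate analysis of variance (adonis-style).

    Partitions the sum of squared dissimilarities into among- and
    within-category components; the pseudo-F statistic is compared against
    label permutations.
    """

    def __init__(self, dm: DistanceMatrix, design: GroupDesign):
        self.dm = dm
        self.design = design
        self._codes, self._n_cats = _group_codes(dm, design)

    def _f_and_r2(self, codes: np.ndarray, d2: np.ndarray,
                  ss_t: float) -> tuple[float, float]:
        n = codes.size
        a = self._n_cats
        ss_w = 0.0
        for g in range(a):
            mask = codes == g
            ng = int(mask.sum())
            ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
        ss_a = ss_t - ss_w
        f = (ss_a / (a - 1)) / (ss_w / (n - a))
        return f, ss_a / ss_t

    def fit(self, n_permutations: int = 999, seed: int = 0) -> GroupTestResult:
        d2 = np.asarray(self.dm.data) ** 2
        n = d2.shape[0]
        ss_t = d2.sum() / (2.0 * n)
        f_obs, r2 = self._f_and_r2(self._codes, d2, ss_t)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            f_perm, _ = self._f_and_r2(rng.permutation(self._codes), d2, ss_t)
            if f_perm >= f_obs:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
        return GroupTestResult(
            method="PERMANOVA", statistic_name="pseudo-F", statistic=float(f_obs),
            p_value=float(p), n_permutations=n_permutations, seed=seed,
            n_samples=n, n_categories=self._n_cats, r_squared=float(r2),
        )


class Anosim:
    """Analysis of similarity on midranked dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = N(N-1)/2; R near 1 means all between-group dissimilarities exceed the
    within-group ones, R near 0 means no separation.
    """

    def __init__(self, dm: DistanceMatrix, design: GroupDesign):
        self.dm = dm
        self.design = design
        self._codes, self._n_cats = _group_codes(dm, design)

    @staticmethod
    def _r_stat(within: np.ndarray, ranks: np.ndarray) -> float:
        m = ranks.size
        return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))

    def fit(self, n_permutations: int = 999, seed: int = 0) -> GroupTestResult:
        d = np.asarray(self.dm.data)
        n = d.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        ranks = rankdata(d[iu, ju])  # midranks over the condensed vector
        codes = self._codes
        r_obs = self._r_stat(codes[iu] == codes[ju], ranks)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            if self._r_stat(perm[iu] == perm[ju], ranks) >= r_obs:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
        return GroupTestResult(
            method="ANOSIM", statistic_name="R", statistic=float(r_obs),
            p_value=float(p), n_permutations=n_permutations, seed=seed,
            n_samples=n, n_categories=self._n_cats,
        )


def permanova(dm: DistanceMatrix, design: GroupDesign,
              n_permutations: int = 999, seed: int = 0) -> GroupTestResult:
    return Permanova(dm, design).fit(n_permutations, seed)


def anosim(dm: DistanceMatrix, design: GroupDesign,
           n_permutations: int = 999, seed: int = 0) -> GroupTestResult:
    return Anosim(dm, design).fit(n_permutations, seed)
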