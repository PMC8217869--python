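"""Modified stochasticity ratio (MST): deterministic vs stochastic assembly.

For every within-category pair of samples the observed Bray-Curtis
dissimilarity ``D`` is compared with its expectation ``E`` under a null model
of stochastic assembly.  The pairwise ratio

    MST = D / E              if D <= E
    MST = (D_max - D) / (D_max - E)   if D > E        (D_max = 1)

equals 1 when the observation coincides with the null and falls toward 0 as
the community departs from it in either direction (toward determinism via
selection, D < E, or toward determinism via divergent selection, D > E).
Category means below 0.5 are called deterministic-dominated, above 0.5
stochastic-dominated.

The default null model redraws each sample's taxon set at its observed
richness, selecting taxa with probability proportional to their occurrence
frequency in the regional pool (the other samples of the same category, or
all samples with ``pool="global"``), and then refills the sample's original
depth multinomially in proportion to regional mean relative abundance.  A
fixed-fixed alternative reuses the quasiswap randomization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .niche import quasiswap_random
from .tables import CountTable, GroupDesign

__all__ = ["null_communities", "mst_pairwise", "StochasticityRatio", "MSTResults"]


def _null_counts_occurrence(counts: np.ndarray, pool_counts: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """One null draw for every column of ``counts`` given a regional pool."""
    S, n = counts.shape
    occ = (pool_counts > 0).mean(axis=1)
    rel = pool_counts / pool_counts.sum(axis=0, keepdims=True)
    mean_rel = rel.mean(axis=1)
    candidates = np.flatnonzero(occ > 0)
    w = occ[candidates]
    logw = np.log(w)
    out = np.zeros_like(counts)
    for j in range(n):
        richness = int((counts[:, j] > 0).sum())
        depth = int(counts[:, j].sum())
        # Efraimidis-Spirakis via Gumbel keys: top-k of log(w) + Gumbel is a
        # weighted sample without replacement proportional to w
        keys = logw + rng.gumbel(size=candidates.size)
        k = min(richness, candidates.size)
        chosen = candidates[np.argpartition(-keys, k - 1)[:k]]
        p = mean_rel[chosen]
        tot = p.sum()
        p = np.full(k, 1.0 / k) if tot <= 0 else p / tot
        filled = rng.multinomial(depth - k, p) + 1 if depth >= k else \
            rng.multinomial(depth, p)
        out[chosen, j] = filled
    return out


def null_communities(table: CountTable, design: GroupDesign,
                     null_model: str = "occurrence_abundance",
                     n_null: int = 1000, seed: int = 0,
                     pool: str = "category") -> Iterator[CountTable]:
    """Stream of randomized tables under the chosen null model.

    Each null sample keeps its observed richness and depth; every drawn taxon
    receives at least one read so the richness constraint holds exactly.
    """
    labels, members = _category_members(table, design)
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        yield _one_null(table, labels, members, null_model, rng, pool)


def _one_null(table: CountTable, labels: np.ndarray, members: dict,
              null_model: str, rng: np.random.Generator,
              pool: str) -> CountTable:
    counts = np.zeros_like(table.counts)
    if null_model == "occurrence_abundance":
        for cat, idx in members.items():
            pool_counts = table.counts if pool == "global" else table.counts[:, idx]
            counts[:, idx] = _null_counts_occurrence(
                table.counts[:, idx], pool_counts, rng)
    elif null_model == "fixed_fixed":
        for cat, idx in members.items():
            sub = CountTable(list(table.taxon_ids),
                             [table.sample_ids[i] for i in idx],
                             table.counts[:, idx])
            counts[:, idx] = quasiswap_random(
                sub, seed=int(rng.integers(2**31))).counts
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    return CountTable(list(table.taxon_ids), list(table.sample_ids), counts)


def mst_pairwise(d_obs: np.ndarray, e_null: np.ndarray,
                 d_max: float = 1.0) -> np.ndarray:
    """Two-branch normalized stochasticity ratio per pair (NaN when E is
    degenerate, i.e. 0 or D_max)."""
    d = np.asarray(d_obs, dtype=float)
    e = np.asarray(e_null, dtype=float)
    out = np.where(d <= e, d / np.where(e == 0, np.nan, e),
                   (d_max - d) / np.where(e == d_max, np.nan, d_max - e))
    out = np.where((e <= 0) | (e >= d_max), np.nan, out)
    return out


def _category_members(table: CountTable,
                      design: GroupDesign) -> tuple[np.ndarray, dict]:
    labels = design.for_table(table)
    members = {}
    for cat in design.categories:
        idx = np.flatnonzero(labels == cat)
        if idx.size == 0:
            continue
        if idx.size == 1:
            warnings.warn(f"category {cat!r} has a single sample; excluded from MST")
            continue
        members[cat] = idx
    if not members:
        raise ValueError("no category has at least 2 samples")
    return labels, members


@dataclass
class MSTResults:
    """Pairwise and per-category modified stochasticity ratios."""

    pairwise: pd.DataFrame       # sample_i, sample_j, category, d_obs, e_null, mst
    per_category: pd.DataFrame   # mean_mst, regime
    null_model: str
    n_null: int
    seed: int

    @property
    def mean_mst(self) -> float:
        return float(self.pairwise["mst"].mean())

    def summary(self) -> str:
        lines = [
            f"Modified stochasticity ratio ({self.null_model} null, "
            f"{self.n_null} randomizations; boundary 0.5)",
        ]
        for cat, row in self.per_category.iterrows():
            lines.append(f"  {cat:12s} MST = {row['mean_mst']:.3f}  -> {row['regime']}")
        return "\n".join(lines)


class StochasticityRatio:
    """Estimate per-category MST from a count table and a design."""

    def __init__(self, table: CountTable, design: GroupDesign,
                 null_model: str = "occurrence_abundance",
                 pool: str = "category"):
        self.table = table
        self.design = design
        self.null_model = null_model
        self.pool = pool
        self._labels, self._members = _category_members(table, design)

    def fit(self, n_null: int = 1000, seed: int = 0) -> MSTResults:
        table = self.table
        d_full = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
        rng = np.random.default_rng(seed)
        e_sum = {cat: np.zeros((idx.size, idx.size))
                 for cat, idx in self._members.items()}
        for _ in range(n_null):
            null = _one_null(table, self._labels, self._members,
                             self.null_model, rng, self.pool)
            for cat, idx in self._members.items():
                sub = null.counts[:, idx].T.astype(float)
                e_sum[cat] += squareform(pdist(sub, metric="braycurtis"))
        rows = []
        for cat, idx in self._members.items():
            e_mean = e_sum[cat] / n_null
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    d = d_full[idx[a], idx[b]]
                    e = e_mean[a, b]
                    rows.append({
                        "sample_i": table.sample_ids[idx[a]],
                        "sample_j": table.sample_ids[idx[b]],
                        "category": cat,
                        "d_obs": d,
                        "e_null": e,
                        "mst": float(mst_pairwise(d, e)),
                    })
        pairwise = pd.DataFrame(rows)
        dropped = int(pairwise["mst"].isna().sum())
        if dropped:
            warnings.warn(f"{dropped} pair(s) with degenerate null expectation excluded")
        per_cat = (
            pairwise.dropna(subset=["mst"]).groupby("category")["mst"].mean()
            .rename("mean_mst").to_frame()
        )
        per_cat["regime"] = np.where(per_cat["mean_mst"] < 0.5,
                                     "deterministic", "stochastic")
        per_cat = per_cat.reindex([c for c in self.design.categories
                                   if c in per_cat.index])
        return MSTResults(pairwise, per_cat, self.null_model, n_null, seed)
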