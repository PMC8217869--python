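"""Discriminative-lineage screen (LEfSe-style biomarker discovery).

Two stages, mirroring the classic effect-size workflow: a Kruskal-Wallis
filter keeps lineage features whose abundance distributions differ among
categories (alpha = 0.05), then a bootstrapped one-vs-all linear discriminant
scores the surviving features.  Scores are log10 of an effect size expressed
in per-million abundance units, so the conventional reporting threshold is
2.0 and stringent display cutoffs (e.g. 4.5) can be applied downstream.

The per-feature effect is a documented simplification of the original tool:
half the sum of the raw between-class mean difference and the
discriminant-weighted mean difference, both on the per-million scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, GroupDesign

__all__ = ["aggregate_lineages", "kw_screen", "LefseScreen", "BiomarkerResult",
           "lda_effect_size"]

SCALE = 1e6  # per-million normalization of lineage abundances
RIDGE_EPS = 1e-6  # ridge added to the pooled within-class covariance


def aggregate_lineages(table: CountTable, taxonomy: dict[str, str],
                       include_otus: bool = False) -> pd.DataFrame:
    """Rank-aggregated feature table (features x samples, per-million units).

    Lineages are ';'-separated rank strings; each OTU contributes its counts
    to every prefix of its lineage ('|'-joined feature IDs, one feature per
    rank).  Missing taxa are treated as fully unclassified.  Each sample is
    normalized so that every rank level sums to 1e6.
    """
    sums = table.sample_sums.astype(float)
    if (sums == 0).any():
        raise ValueError("zero-sum sample(s)")
    features: dict[str, np.ndarray] = {}
    for i, otu in enumerate(table.taxon_ids):
        lineage = taxonomy.get(otu, "unclassified")
        ranks = [r.strip() for r in lineage.split(";") if r.strip()]
        if not ranks:
            ranks = ["unclassified"]
        for depth in range(1, len(ranks) + 1):
            key = "|".join(ranks[:depth])
            if key not in features:
                features[key] = np.zeros(table.n_samples)
            features[key] += table.counts[i]
        if include_otus:
            key = "|".join(ranks) + f"|{otu}"
            features[key] = features.get(key, np.zeros(table.n_samples)) \
                + table.counts[i]
    df = pd.DataFrame(features, index=table.sample_ids).T
    return df / sums * SCALE


def kw_screen(features: pd.DataFrame, design: GroupDesign,
              alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis H per feature (midranks, tie-corrected); pass iff p <= alpha."""
    labels = np.array([design.labels[s] for s in features.columns])
    cats = [c for c in design.categories if c in labels]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    groups_idx = [labels == c for c in cats]
    pvals = np.ones(len(features))
    hstats = np.zeros(len(features))
    for r, (_, row) in enumerate(features.iterrows()):
        vals = row.to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            continue  # constant feature: H undefined, keep p = 1
        h, p = stats.kruskal(*[vals[g] for g in groups_idx])
        hstats[r], pvals[r] = h, p
    out = pd.DataFrame({"kw_h": hstats, "kw_p": pvals}, index=features.index)
    out["passed"] = out["kw_p"] <= alpha
    return out


def _lda_axis(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction for a binary split, ridge-regularized."""
    X0, X1 = X[~y], X[y]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    C = np.cov(X0, rowvar=False) * (len(X0) - 1) + \
        np.cov(X1, rowvar=False) * (len(X1) - 1)
    C = np.atleast_2d(C) / max(len(X) - 2, 1)
    C[np.diag_indices_from(C)] += RIDGE_EPS
    return np.linalg.solve(C, mu1 - mu0)


@dataclass
class BiomarkerResult:
    feature: str
    rank_depth: int
    enriched_class: str
    kw_p: float
    lda_score: float
    passed: bool  # lda_score >= threshold


class LefseScreen:
    """Kruskal-Wallis filter followed by bootstrapped LDA effect sizes."""

    def __init__(self, features: pd.DataFrame, design: GroupDesign,
                 alpha: float = 0.05):
        self.features = features
        self.design = design
        self.alpha = alpha
        self.labels = np.array([design.labels[s] for s in features.columns])
        self.categories = [c for c in design.categories if c in self.labels]

    def fit(self, n_boot: int = 30, subsample: float = 2 / 3, seed: int = 0,
            threshold: float = 2.0) -> pd.DataFrame:
        kw = kw_screen(self.features, self.design, self.alpha)
        passing = kw.index[kw["passed"]]
        rng = np.random.default_rng(seed)
        rows: list[BiomarkerResult] = []
        if len(passing):
            sub = self.features.loc[passing]
            X_full = sub.to_numpy(dtype=float).T  # samples x features
            # standardized copy for the discriminant direction
            sd = X_full.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Z_full = (X_full - X_full.mean(axis=0)) / sd
            class_means = {c: X_full[self.labels == c].mean(axis=0)
                           for c in self.categories}
            enriched = np.array(self.categories)[
                np.argmax(np.stack([class_means[c] for c in self.categories]), axis=0)
            ]
            effects = np.zeros((n_boot, len(passing)))
            for b in range(n_boot):
                keep = self._subsample(rng, subsample)
                Xb, Zb, yb = X_full[keep], Z_full[keep], self.labels[keep]
                for c in self.categories:
                    is_c = yb == c
                    sel = enriched == c
                    if not sel.any():
                        continue
                    w = np.abs(_lda_axis(Zb, is_c))
                    w = w / w.max() if w.max() > 0 else w
                    raw_diff = np.abs(Xb[is_c].mean(axis=0) - Xb[~is_c].mean(axis=0))
                    effects[b, sel] = 0.5 * (raw_diff[sel] + (w * raw_diff)[sel])
            mean_effect = effects.mean(axis=0)
            with np.errstate(divide="ignore"):
                scores = np.log10(np.where(mean_effect > 0, mean_effect, np.nan))
            for k, feat in enumerate(passing):
                score = float(scores[k]) if np.isfinite(scores[k]) else -np.inf
                rows.append(BiomarkerResult(
                    feature=feat, rank_depth=feat.count("|") + 1,
                    enriched_class=str(enriched[k]),
                    kw_p=float(kw.loc[feat, "kw_p"]),
                    lda_score=score, passed=bool(score >= threshold),
                ))
        df = pd.DataFrame([r.__dict__ for r in rows],
                          columns=["feature", "rank_depth", "enriched_class",
                                   "kw_p", "lda_score", "passed"])
        return df.sort_values("lda_score", ascending=False).reset_index(drop=True)

    def _subsample(self, rng: np.random.Generator, frac: float) -> np.ndarray:
        keep: list[int] = []
        for c in self.categories:
            idx = np.flatnonzero(self.labels == c)
            k = max(int(round(frac * idx.size)), 1)
            if k < 3:
                raise ValueError(
                    f"category {c!r} retains {k} sample(s) after subsampling; "
                    "need at least 3 per class")
            keep.extend(rng.choice(idx, size=k, replace=False))
        return np.array(sorted(keep))


def lda_effect_size(features: pd.DataFrame, design: GroupDesign,
                    n_boot: int = 30, subsample: float = 2 / 3, seed: int = 0,
                    threshold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    return LefseScreen(features, design, alpha).fit(
        n_boot=n_boot, subsample=subsample, seed=seed, threshold=threshold)
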