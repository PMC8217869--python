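"""Alpha diversity: richness (observed, Chao1, ACE), diversity (Shannon H',
inverse Simpson D2), evenness (Pielou's J), and rarefaction curves.

Conventions: Shannon uses the natural logarithm; Pielou's denominator is
``ln(observed richness)``; Chao1 is the bias-corrected estimator
``S_obs + F1(F1-1)/(2(F2+1))``; ACE uses the standard rare/abundant threshold
of 10 reads.  Chao1 and ACE are delegated to scikit-bio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .tables import CountTable, GroupDesign

__all__ = [
    "observed_richness",
    "chao1",
    "ace",
    "shannon",
    "inv_simpson",
    "pielou",
    "AlphaResult",
    "alpha_diversity",
    "rarefaction_curve",
]

METRICS = ["observed_otus", "chao1", "ace", "shannon", "inv_simpson", "pielou"]


def _as_counts(sample_counts) -> np.ndarray:
    x = np.asarray(sample_counts)
    if (x < 0).any():
        raise ValueError("negative counts")
    return x.astype(np.int64)


def observed_richness(sample_counts) -> int:
    x = _as_counts(sample_counts)
    s = int((x > 0).sum())
    if s == 0:
        warnings.warn("all-zero sample: observed richness is 0")
    return s


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness estimator."""
    x = _as_counts(sample_counts)
    return float(_skbio_chao1(x, bias_corrected=True))


def ace(sample_counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (falls back to Chao1 when the
    sample coverage of the rare class is undefined, i.e. all rare taxa are
    singletons)."""
    x = _as_counts(sample_counts)
    x = x[x > 0]
    rare = x[x <= rare_threshold]
    if rare.size == 0:
        return float((x > 0).sum())
    if (rare == 1).all():
        warnings.warn("all rare taxa are singletons; ACE undefined, using Chao1")
        return chao1(x)
    return float(_skbio_ace(x, rare_threshold=rare_threshold))


def shannon(sample_counts) -> float:
    """Shannon entropy H' in nats."""
    x = _as_counts(sample_counts)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(sample_counts) -> float:
    """Inverse Simpson diversity D2 = 1 / sum(p^2)."""
    x = _as_counts(sample_counts)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    p = x / x.sum()
    return float(1.0 / (p**2).sum())


def pielou(sample_counts) -> float:
    """Pielou's evenness J = H' / ln(S_obs); 0 (flagged) for single-taxon samples."""
    x = _as_counts(sample_counts)
    s = int((x > 0).sum())
    if s == 0:
        raise ValueError("empty sample")
    if s == 1:
        warnings.warn("single-taxon sample: Pielou's evenness undefined, reporting 0")
        return 0.0
    return shannon(x) / float(np.log(s))


@dataclass
class AlphaResult:
    """Per-sample index values and per-category mean +/- dispersion."""

    per_sample: pd.DataFrame
    per_category: pd.DataFrame | None = None
    dispersion: str = "se"

    def summary(self) -> str:
        out = ["Alpha diversity (per sample)", self.per_sample.round(4).to_string()]
        if self.per_category is not None:
            out += [
                f"\nPer-category mean +/- {self.dispersion.upper()}",
                self.per_category.round(4).to_string(),
            ]
        return "\n".join(out)


def alpha_diversity(table: CountTable, design: GroupDesign | None = None,
                    dispersion: str = "se") -> AlphaResult:
    """All six indices for every sample, optionally summarised by category.

    ``dispersion`` selects the +/- column of the category summary: standard
    error (``"se"``, default) or standard deviation (``"sd"``).
    """
    if dispersion not in ("se", "sd"):
        raise ValueError("dispersion must be 'se' or 'sd'")
    rows = {}
    for j, s in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows[s] = [
            observed_richness(col), chao1(col), ace(col),
            shannon(col), inv_simpson(col), pielou(col),
        ]
    per_sample = pd.DataFrame.from_dict(rows, orient="index", columns=METRICS)
    per_category = None
    if design is not None:
        labels = design.for_table(table)
        grouped = per_sample.groupby(pd.Series(labels, index=per_sample.index))
        mean = grouped.mean()
        sd = grouped.std(ddof=1)
        disp = sd / np.sqrt(grouped.size().to_numpy()[:, None]) if dispersion == "se" else sd
        per_category = pd.concat(
            {"mean": mean, dispersion: disp}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1)
        per_category = per_category.reindex(design.categories)
    return AlphaResult(per_sample, per_category, dispersion)


def rarefaction_curve(table: CountTable, depths, n_reps: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean observed richness per sample over ``n_reps`` random subsamples at
    each depth.  Depths exceeding a sample's total are reported as NaN."""
    depths = list(depths)
    if sorted(depths) != depths:
        raise ValueError("depths must be ascending")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums
    out = np.full((len(depths), table.n_samples), np.nan)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        for k, d in enumerate(depths):
            if d > sums[j]:
                continue
            if d == sums[j]:
                out[k, j] = (col > 0).sum()
                continue
            rich = [
                (rng.multivariate_hypergeometric(col, d) > 0).sum()
                for _ in range(n_reps)
            ]
            out[k, j] = float(np.mean(rich))
    return pd.DataFrame(out, index=pd.Index(depths, name="depth"),
                        columns=table.sample_ids)
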