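"""Shared / exclusive / core OTU set algebra across categories.

A category "detects" an OTU when the OTU is present (>= 1 read) in at least
``min_reps`` of the category's replicate samples.  The core is the set of
OTUs detected in every category -- present in all categories, though not
necessarily in all replicates.  Venn regions are the disjoint cells of the
detection sets; headline percentages follow the field's reporting style
(percent of a category's community specific to it, and a subset's share of
the whole dataset), rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np

from .tables import CountTable, GroupDesign

__all__ = ["detect_sets", "venn_regions", "headline_fractions",
           "percent", "PartitionSummary"]


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (reporting convention)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator set")
    val = Decimal(numerator) / Decimal(denominator) * 100
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def detect_sets(table: CountTable, design: GroupDesign,
                min_reps: int = 1) -> dict[str, set[str]]:
    """Per-category OTU detection sets (present in >= min_reps replicates)."""
    labels = design.for_table(table)
    present = table.counts >= 1
    sets = {}
    for cat in design.categories:
        idx = np.flatnonzero(labels == cat)
        if idx.size == 0:
            continue
        hits = present[:, idx].sum(axis=1) >= min_reps
        sets[cat] = {t for t, h in zip(table.taxon_ids, hits) if h}
    return sets


@dataclass
class PartitionSummary:
    """Region sizes of the detection-set Venn partition."""

    sets: dict[str, set[str]]
    regions: dict[frozenset, int] | None  # None when k > 6 (not enumerated)
    core: set[str]
    exclusives: dict[str, set[str]]
    pairwise: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return len(out)

    def summary(self) -> str:
        lines = [f"OTU partition over {len(self.sets)} categories "
                 f"({self.union_size} detected OTUs)"]
        for c, s in self.sets.items():
            lines.append(f"  {c:12s} detected {len(s):6d}  exclusive {len(self.exclusives[c]):6d}")
        lines.append(f"  core (all categories): {len(self.core)}")
        return "\n".join(lines)


def venn_regions(sets: dict[str, set[str]]) -> PartitionSummary:
    """All 2^k - 1 disjoint region sizes, plus core and exclusives.

    For more than 6 categories the full enumeration is refused and only
    pairwise intersections, exclusives, and the core are reported.
    """
    cats = list(sets)
    if len(cats) < 2:
        raise ValueError("need at least 2 sets")
    core = set.intersection(*sets.values())
    exclusives = {
        c: sets[c] - set.union(*(sets[o] for o in cats if o != c))
        for c in cats
    }
    pairwise = {
        frozenset((a, b)): len(sets[a] & sets[b])
        for a, b in combinations(cats, 2)
    }
    regions = None
    if len(cats) <= 6:
        regions = {}
        for r in range(1, len(cats) + 1):
            for inside in combinations(cats, r):
                cell = set.intersection(*(sets[c] for c in inside))
                for c in cats:
                    if c not in inside:
                        cell = cell - sets[c]
                regions[frozenset(inside)] = len(cell)
    return PartitionSummary(sets=dict(sets), regions=regions, core=core,
                            exclusives=exclusives, pairwise=pairwise)


def headline_fractions(summary: PartitionSummary,
                       total_otus: int | None = None,
                       subset: list[str] | None = None) -> dict[str, float]:
    """Reporting percentages.

    ``percent_specific_<cat>``: share of the category's detected community
    that is exclusive to it.  ``subset_share``: share of the whole dataset
    (``total_otus``, default = union of all detection sets) detected in at
    least one category of ``subset``.
    """
    out = {}
    for c, s in summary.sets.items():
        if not s:
            out[f"percent_specific_{c}"] = float("nan")
            continue
        out[f"percent_specific_{c}"] = percent(len(summary.exclusives[c]), len(s))
    if total_otus is None:
        total_otus = summary.union_size
    if subset is not None:
        union: set[str] = set()
        for c in subset:
            union |= summary.sets[c]
        out["subset_share"] = percent(len(union), total_otus)
    out["core_share"] = percent(len(summary.core), total_otus)
    return out
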