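"""OTU count tables, sample designs, taxonomy maps, host trees, and rarefaction.

The central container is :class:`CountTable`, a taxa x samples matrix of
non-negative integer read counts.  Everything downstream (diversity indices,
dissimilarity, null models, the neutral model) consumes it.  Two text dialects
are supported: ``tsv_wide`` (rows = taxa, first column the taxon ID, optional
trailing ``taxonomy`` column) and ``shared`` (rows = samples with leading
``label``/``Group``/``numOtus`` columns, the common amplicon-pipeline export;
transposed on load so taxa are rows internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "GroupDesign",
    "TableParseError",
    "read_count_table",
    "write_count_table",
    "read_design",
    "write_design",
    "read_taxonomy",
    "read_tree",
    "rarefy",
]


class TableParseError(ValueError):
    """Raised when an on-disk table violates the count-table contract."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts with unique IDs."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t).strip() for t in self.taxon_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableParseError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableParseError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.taxon_ids) < 1 or len(self.sample_ids) < 1:
            raise TableParseError("need at least 1 taxon and 1 sample")
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise TableParseError(f"duplicate {name} IDs: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flt = np.asarray(self.counts, dtype=float)
            if not np.allclose(flt, np.round(flt)):
                bad = np.argwhere(flt != np.round(flt))[0]
                raise TableParseError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = np.round(flt).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise TableParseError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.taxon_sums > 0
        return CountTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            list(self.sample_ids),
            self.counts[keep],
        )

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.sample_sums
        if (sums == 0).any():
            raise ValueError("zero-sum sample(s); cannot form relative abundances")
        return self.counts / sums

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class GroupDesign:
    """Mapping of sample IDs onto categories (host species / environment)."""

    labels: dict[str, str]
    category_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = {str(k).strip(): str(v).strip() for k, v in self.labels.items()}
        seen: list[str] = []
        for c in self.labels.values():
            if c not in seen:
                seen.append(c)
        if not self.category_order:
            self.category_order = seen
        else:
            missing = [c for c in seen if c not in self.category_order]
            if missing:
                raise ValueError(f"categories missing from category_order: {missing}")

    @property
    def categories(self) -> list[str]:
        return list(self.category_order)

    def for_table(self, table: CountTable) -> np.ndarray:
        """Category label per table column; every sample must be labelled."""
        missing = [s for s in table.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a category label: {missing}")
        return np.array([self.labels[s] for s in table.sample_ids])

    def samples_in(self, category: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == category]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(
    path, dialect: str = "tsv_wide", orientation: str = "taxa_rows"
) -> tuple[CountTable, dict[str, str] | None]:
    """Read a count table; returns ``(table, taxonomy_or_None)``.

    ``orientation`` applies to ``tsv_wide`` only: ``taxa_rows`` (default) or
    ``samples_rows`` (transposed on load).  The ``shared`` dialect is always
    samples-as-rows on disk.
    """
    if dialect == "tsv_wide":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise TableParseError(f"{path}: expected >=2 tab-separated columns")
        df = df.set_index(df.columns[0])
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = {str(t).strip(): str(v) for t, v in df["taxonomy"].items()}
            df = df.drop(columns=["taxonomy"])
        mat = _parse_int_block(df, path)
        if orientation == "samples_rows":
            mat = mat.T
        table = CountTable(list(mat.index), list(mat.columns), mat.to_numpy())
        return table, taxonomy
    if dialect == "shared":
        df = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["label", "Group", "numOtus"]
        if list(df.columns[:3]) != expected:
            raise TableParseError(
                f"{path}: shared dialect requires leading columns {expected}, "
                f"got {list(df.columns[:3])}"
            )
        df = df.set_index("Group").drop(columns=["label", "numOtus"])
        mat = _parse_int_block(df, path)
        table = CountTable(list(mat.columns), list(mat.index), mat.to_numpy().T)
        return table, None
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_int_block(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        out = df.astype(np.int64)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for col in df.columns:
            for row, val in df[col].items():
                try:
                    int(val)
                except (TypeError, ValueError):
                    raise TableParseError(
                        f"{path}: non-integer cell {val!r} at row {row!r}, column {col!r}"
                    ) from exc
        raise TableParseError(f"{path}: {exc}") from exc
    neg = out.lt(0)
    if neg.to_numpy().any():
        row = neg.any(axis=1).idxmax()
        col = neg.loc[row].idxmax()
        raise TableParseError(f"{path}: negative count at row {row!r}, column {col!r}")
    return out


def write_count_table(table: CountTable, path, dialect: str = "tsv_wide",
                      taxonomy: dict[str, str] | None = None) -> None:
    if table.n_taxa == 0:
        raise ValueError("refusing to write a table with zero taxa")
    if dialect == "tsv_wide":
        df = table.to_dataframe()
        df.index.name = "otu_id"
        if taxonomy is not None:
            df = df.assign(taxonomy=[taxonomy.get(t, "unclassified") for t in table.taxon_ids])
        df.to_csv(path, sep="\t")
    elif dialect == "shared":
        df = table.to_dataframe().T
        out = pd.DataFrame(
            {"label": "0.03", "Group": df.index, "numOtus": table.n_taxa}
        ).reset_index(drop=True)
        out = pd.concat([out, df.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_design(path) -> GroupDesign:
    """Two-column TSV ``sample_id<TAB>category`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0] in ("sample_id", "sample", "Group"):
        df = df.iloc[1:]
    return GroupDesign(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_design(design: GroupDesign, path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.labels), "category": list(design.labels.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_taxonomy(path) -> dict[str, str]:
    """Two-column TSV ``otu_id<TAB>lineage`` with ';'-separated ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1]))


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int,
           drop_below: bool = True) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single random draw per sample (not an average over draws).  Samples with
    fewer than ``depth`` reads are dropped with a warning when ``drop_below``
    (the default), otherwise an error is raised.  Taxa left with zero total
    are retained; use :meth:`CountTable.drop_empty_taxa` to prune them.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}; largest is {sums.max()}")
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        if not drop_below:
            raise ValueError(f"samples below depth {depth}: {dropped}")
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}")
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if sums[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    return CountTable(
        list(table.taxon_ids),
        [s for s, k in zip(table.sample_ids, keep) if k],
        np.column_stack(cols),
    )
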