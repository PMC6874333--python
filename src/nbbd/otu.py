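"""OTU table container and I/O.

The central data structure is :class:`OTUTable`, a samples-by-taxa abundance
matrix (counts or relative abundances) with optional binary phenotype labels.
Tables are read from and written to delimited text (TSV by default) with the
header row holding taxon IDs and the first column holding sample IDs;
metadata is a two-column ``sample_id``/``label`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OTUTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "to_relative_abundance",
    "prevalence_filter",
    "split_by_phenotype",
    "nested_subsets",
]


@dataclass
class OTUTable:
    """Samples x taxa abundance matrix with optional per-sample labels.

    Parameters
    ----------
    data
        DataFrame with sample IDs as the index and taxon IDs as columns.
        Values must be nonnegative (counts or fractions).
    labels
        Optional per-sample phenotype labels aligned with ``data.index``.
    normalized
        True if every row sums to 1 (relative abundances).
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance matrix contains negative values")
        if self.labels is not None:
            self.labels = pd.Series(self.labels)
            if not self.labels.index.equals(self.data.index):
                self.labels = self.labels.reindex(self.data.index)
                if self.labels.isna().any():
                    missing = self.labels[self.labels.isna()].index.tolist()
                    raise ValueError(f"labels missing for samples: {missing}")
        if self.normalized:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized table has rows not summing to 1")

    # -- lightweight accessors -------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict_taxa(self, taxa: Sequence[str]) -> "OTUTable":
        """Return the table restricted to the given taxa (order preserved)."""
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        return OTUTable(self.data.loc[:, list(taxa)].copy(), labels=self.labels,
                        normalized=False)

    def restrict_samples(self, samples: Sequence[str]) -> "OTUTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        labels = self.labels.loc[list(samples)] if self.labels is not None else None
        return OTUTable(self.data.loc[list(samples)].copy(), labels=labels,
                        normalized=self.normalized)

    def with_labels(self, labels: pd.Series) -> "OTUTable":
        return OTUTable(self.data.copy(), labels=labels, normalized=self.normalized)


def read_otu_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    sep: str = "\t",
    metadata: str | Path | None = None,
    label_column: str = "label",
) -> OTUTable:
    """Read a delimited OTU table.

    The first row holds IDs for the columns and the first column holds IDs for
    the rows. ``orientation`` declares whether rows are samples or taxa; the
    returned table is always samples-as-rows. Optionally attach labels from a
    metadata table with columns ``sample_id`` and ``label_column``.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate IDs in header of {path}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(
                f"malformed numeric cell at row {bad!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if orientation == "taxa_as_rows":
        df = df.T
    labels = None
    if metadata is not None:
        labels = read_metadata(metadata, label_column=label_column, sep=sep)
    return OTUTable(df, labels=labels)


def write_otu_table(table: OTUTable, path: str | Path, sep: str = "\t") -> None:
    """Write the table as delimited text, samples as rows."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_metadata(path: str | Path, label_column: str = "label",
                  sep: str = "\t") -> pd.Series:
    """Read a sample metadata table; returns labels indexed by sample ID."""
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'sample_id' column")
    if label_column not in meta.columns:
        raise ValueError(f"metadata {path} lacks column {label_column!r}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    return pd.Series(meta[label_column].to_numpy(), index=meta["sample_id"].astype(str))


def write_metadata(table: OTUTable, path: str | Path, sep: str = "\t") -> None:
    if table.labels is None:
        raise ValueError("table carries no labels")
    pd.DataFrame({"sample_id": table.sample_ids,
                  "label": table.labels.to_numpy()}).to_csv(path, sep=sep, index=False)


def to_relative_abundance(table: OTUTable) -> OTUTable:
    """Normalize each sample row to sum to one."""
    sums = table.values.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total abundance: {[table.sample_ids[i] for i in zero]}"
        )
    data = table.data.div(pd.Series(sums, index=table.data.index), axis=0)
    return OTUTable(data, labels=table.labels, normalized=True)


def prevalence_filter(table: OTUTable, min_fraction: float) -> OTUTable:
    """Retain taxa with nonzero abundance in at least
    ``ceil(min_fraction * n_samples)`` samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    needed = math.ceil(min_fraction * table.n_samples)
    counts = (table.values > 0).sum(axis=0)
    keep = [t for t, c in zip(table.taxon_ids, counts) if c >= needed]
    if not keep:
        raise ValueError("prevalence filter removed every taxon")
    return OTUTable(table.data.loc[:, keep].copy(), labels=table.labels,
                    normalized=False)


def split_by_phenotype(table: OTUTable) -> tuple[OTUTable, OTUTable]:
    """Partition samples by binary label; label order is lexicographic."""
    if table.labels is None:
        raise ValueError("table carries no labels")
    groups = sorted(table.labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 label values, got {groups}")
    out = []
    for g in groups:
        samples = table.labels.index[table.labels == g].tolist()
        out.append(table.restrict_samples(samples))
    return out[0], out[1]


def nested_subsets(table: OTUTable, sizes: Sequence[int], seed: int) -> list[OTUTable]:
    """Draw class-balanced nested sample subsets.

    ``sizes`` are per-group sample counts, strictly increasing. The subsets
    form a chain: every sample in subset i is in subset i+1. Determinism: a
    single seeded shuffle per class is drawn and each subset takes prefixes.
    """
    if table.labels is None:
        raise ValueError("table carries no labels")
    sizes = list(sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly increasing, got {sizes}")
    groups = sorted(table.labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 label values, got {groups}")
    per_class: dict[str, list[str]] = {}
    rng = np.random.default_rng(seed)
    for g in groups:
        members = sorted(table.labels.index[table.labels == g].tolist())
        if len(members) < sizes[-1]:
            raise ValueError(
                f"group {g!r} has {len(members)} samples; need {sizes[-1]}"
            )
        order = rng.permutation(len(members))
        per_class[g] = [members[i] for i in order]
    subsets = []
    for n in sizes:
        chosen: list[str] = []
        for g in groups:
            chosen.extend(per_class[g][:n])
        # keep the original table's sample order for determinism of output
        chosen_set = set(chosen)
        ordered = [s for s in table.sample_ids if s in chosen_set]
        subsets.append(table.restrict_samples(ordered))
    return subsets
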