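"""Core record types and I/O for expression matrices, sample metadata and gene sets.

The central container is :class:`Dataset`: a real-valued expression matrix
(features in rows, samples in columns, log2 scale) together with per-sample
metadata — the brain region (or, generically, the source sub-dataset), a
binary disease class, and optionally the donating individual.  Regions act as
the "colours" of the combinatorial feature-set problems and individuals link
samples across regions for the generalised variant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "Dataset",
    "GeneSetCollection",
    "DataError",
    "read_dataset",
    "write_dataset",
    "split_by_region",
    "combine_datasets",
    "read_gene_sets",
    "read_mapping",
    "read_series_matrix",
]

#: expression values above this are assumed to be on a linear scale and are
#: log2(x+1)-transformed at load time
LOG2_HEURISTIC_MAX = 50.0


class DataError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one sample: identity, region (colour), class and donor."""

    sample_id: str
    region: str
    klass: int
    individual: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DataError("sample_id must be non-empty")
        if not self.region:
            raise DataError(f"sample {self.sample_id!r} has no region")
        if self.klass not in (0, 1):
            raise DataError(
                f"sample {self.sample_id!r}: klass must be 0 (control) or 1 "
                f"(affected), got {self.klass!r}"
            )


@dataclass
class Dataset:
    """Expression matrix (features x samples) plus aligned sample metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by feature id, one column per sample, log2-scale
        values, no missing entries.
    samples
        One :class:`SampleMeta` per column, in column order.
    log2_transformed
        True when the loader applied the log2(x+1) transform.
    """

    matrix: pd.DataFrame
    samples: list[SampleMeta]
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        idx = self.matrix.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicated feature ids: {dupes[:5]}")
        if len(self.samples) != self.matrix.shape[1]:
            raise DataError(
                f"{len(self.samples)} sample records for "
                f"{self.matrix.shape[1]} matrix columns"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataError("duplicated sample ids in metadata")
        if list(self.matrix.columns) != ids:
            raise DataError("matrix columns do not match metadata sample order")
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix must be numeric")
        if np.isnan(values).any():
            rows = self.matrix.index[np.isnan(values).any(axis=1)].tolist()
            raise DataError(f"missing values in features {rows[:5]}")
        by_indiv: dict[str, int] = {}
        for s in self.samples:
            if s.individual is None:
                continue
            prev = by_indiv.setdefault(s.individual, s.klass)
            if prev != s.klass:
                raise DataError(
                    f"individual {s.individual!r} appears with both classes"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def regions(self) -> list[str]:
        """Distinct region labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.region, None)
        return list(seen)

    @property
    def klasses(self) -> np.ndarray:
        return np.array([s.klass for s in self.samples], dtype=int)

    def region_labels(self) -> np.ndarray:
        return np.array([s.region for s in self.samples], dtype=object)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def select_features(self, feature_ids: Sequence[str]) -> "Dataset":
        """Restrict to the given features, in the given order."""
        missing = [f for f in feature_ids if f not in self.matrix.index]
        if missing:
            raise DataError(f"unknown feature ids: {missing[:5]}")
        return replace(self, matrix=self.matrix.loc[list(feature_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "Dataset":
        by_id = {s.sample_id: s for s in self.samples}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        return replace(
            self,
            matrix=self.matrix[list(sample_ids)],
            samples=[by_id[s] for s in sample_ids],
        )


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene/feature identifiers."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# -- readers / writers ---------------------------------------------------------


def _read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_dataset(expr_path: Path | str, meta_path: Path | str) -> Dataset:
    """Load an expression table plus metadata table into a :class:`Dataset`.

    The expression table has feature ids in the first column and sample ids in
    the header; the metadata table has columns ``sample_id``, ``region``,
    ``klass`` and optionally ``individual``.  Values are log2(x+1)-transformed
    when the matrix maximum exceeds ``LOG2_HEURISTIC_MAX`` (linear-scale
    input), and the transform is recorded on the Dataset.
    """
    expr = _read_table(expr_path)
    meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "region", "klass"}
    if not required.issubset(meta.columns):
        raise DataError(
            f"metadata must have columns {sorted(required)}, got "
            f"{list(meta.columns)}"
        )
    samples = []
    for _, row in meta.iterrows():
        indiv = row.get("individual")
        if indiv is not None and (pd.isna(indiv) or indiv == ""):
            indiv = None
        samples.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                region=str(row["region"]),
                klass=int(row["klass"]),
                individual=indiv,
            )
        )
    unknown = [s.sample_id for s in samples if s.sample_id not in expr.columns]
    if unknown:
        raise DataError(f"metadata samples absent from expression header: {unknown}")
    expr = expr[[s.sample_id for s in samples]]
    expr.index = expr.index.astype(str)
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = expr.index[np.isnan(values).any(axis=1)].tolist()
        raise DataError(f"missing values in features {bad[:5]}")
    transformed = False
    if np.nanmax(values) > LOG2_HEURISTIC_MAX:
        expr = np.log2(expr + 1.0)
        transformed = True
    return Dataset(matrix=expr, samples=samples, log2_transformed=transformed)


def write_dataset(ds: Dataset, expr_path: Path | str, meta_path: Path | str) -> None:
    """Write the TSV pair that :func:`read_dataset` consumes (6-decimal values)."""
    ds.matrix.to_csv(expr_path, sep="\t", float_format="%.6f", index_label="feature_id")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in ds.samples],
            "region": [s.region for s in ds.samples],
            "klass": [s.klass for s in ds.samples],
            "individual": [s.individual or "" for s in ds.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def split_by_region(ds: Dataset) -> dict[str, Dataset]:
    """One Dataset per region, feature order preserved, sample order preserved."""
    out: dict[str, Dataset] = {}
    for region in ds.regions:
        ids = [s.sample_id for s in ds.samples if s.region == region]
        out[region] = ds.select_samples(ids)
    return out


def combine_datasets(
    parts: Sequence[Dataset], feature_rule: str = "intersection"
) -> Dataset:
    """Concatenate samples of several region datasets over their common features.

    Features are restricted to those present in every part (order taken from
    the first part); sample ids must be globally unique, though individuals may
    repeat across parts.
    """
    if feature_rule != "intersection":
        raise ValueError(f"unsupported feature_rule {feature_rule!r}")
    if len(parts) < 2:
        raise DataError("combine_datasets needs at least two parts")
    common = set(parts[0].feature_ids)
    for p in parts[1:]:
        common &= set(p.feature_ids)
    if not common:
        raise DataError("no features common to all parts")
    order = [f for f in parts[0].feature_ids if f in common]
    seen: set[str] = set()
    for p in parts:
        dup = seen.intersection(p.sample_ids)
        if dup:
            raise DataError(f"duplicate sample ids across parts: {sorted(dup)[:5]}")
        seen.update(p.sample_ids)
    matrix = pd.concat([p.matrix.loc[order] for p in parts], axis=1)
    samples = [s for p in parts for s in p.samples]
    return Dataset(
        matrix=matrix,
        samples=samples,
        log2_transformed=any(p.log2_transformed for p in parts),
    )


def read_gene_sets(gmt_path: Path | str) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members per line)."""
    sets: dict[str, frozenset[str]] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{gmt_path}: line {lineno} has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{gmt_path}: duplicate set name {name!r} at line {lineno}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise DataError(f"{gmt_path}: line {lineno} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def read_mapping(path: Path | str) -> dict[str, str]:
    """Two-column TSV (probe id -> gene symbol), used as a plain table join."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if table.shape[1] < 2:
        raise DataError("mapping table must have two columns")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def read_series_matrix(path: Path | str) -> pd.DataFrame:
    """Read the data block of a GEO series-matrix file (convenience only).

    Returns the expression table (probe x sample) between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers;
    metadata lines are ignored and must be supplied separately.
    """
    lines: list[str] = []
    inside = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise DataError(f"{path}: no series-matrix table block found")
    table = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [str(c).strip('"') for c in table.columns]
    return table
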