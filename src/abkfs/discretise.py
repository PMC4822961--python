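"""Entropy-based (Fayyad–Irani MDLP) discretisation and uninformative-feature filter.

Each continuous feature is recursively split at class-boundary midpoints
maximising information gain; a split is kept only when the gain exceeds the
minimum-description-length cost of encoding it.  Features for which even the
first split is rejected carry no class information at the resolution of the
data and are dropped.  Applied per region, this both filters the feature space
and produces the integer-coded matrix consumed by the combinatorial
feature-set problems.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import DataError, Dataset, combine_datasets, split_by_region

__all__ = [
    "CutPointModel",
    "DiscretisedMatrix",
    "FilterResult",
    "class_entropy",
    "mdlp_threshold",
    "mdlp_accept",
    "discretise_feature",
    "assign_bins",
    "filter_dataset",
    "filter_regions",
]


def class_entropy(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (bits) of a class-count vector, with 0*log(0)=0."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative class counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero class counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mdlp_threshold(
    n: int,
    parent_entropy: float,
    left_entropy: float,
    right_entropy: float,
    k: int,
    k1: int,
    k2: int,
) -> float:
    """Minimum gain (bits) a binary split must exceed to be accepted.

    ``(log2(n-1) + log2(3^k - 2) - [k*E - k1*E1 - k2*E2]) / n`` where k, k1, k2
    count the classes present in the parent and the two children.
    """
    delta = math.log2(3**k - 2) - (
        k * parent_entropy - k1 * left_entropy - k2 * right_entropy
    )
    return (math.log2(n - 1) + delta) / n


def mdlp_accept(
    gain: float,
    n: int,
    parent_entropy: float,
    left_entropy: float,
    right_entropy: float,
    k: int,
    k1: int,
    k2: int,
) -> bool:
    """True when the split's information gain beats the MDL coding cost."""
    if n < 2:
        return False
    return gain > mdlp_threshold(n, parent_entropy, left_entropy, right_entropy, k, k1, k2)


def _best_boundary_split(values: np.ndarray, klass: np.ndarray):
    """Best midpoint cut on a (sub)sample, or None if no boundary exists.

    Candidate cuts lie between adjacent distinct values whose adjacent groups
    are not the same pure class (restricting to class boundaries is lossless
    for entropy minimisation).  Ties on gain resolve to the smallest cut.
    Returns (threshold, gain, stats needed by the MDL criterion).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = klass[order]
    n = len(v)
    # group equal values; per-group class counts
    boundaries = np.flatnonzero(np.diff(v) > 0) + 1  # split positions between groups
    if boundaries.size == 0:
        return None
    ones = np.cumsum(y)
    total_ones = int(ones[-1])
    parent_counts = np.array([n - total_ones, total_ones], dtype=float)
    parent_entropy = class_entropy(parent_counts)
    best = None
    prev_group_pure: int | None = None
    for pos in boundaries:
        left_ones = int(ones[pos - 1])
        left = np.array([pos - left_ones, left_ones], dtype=float)
        right = parent_counts - left
        # class-boundary restriction: skip cuts between two groups that are
        # pure and of the same class on both flanks
        lo = pos - 1
        while lo > 0 and v[lo - 1] == v[pos - 1]:
            lo -= 1
        hi = pos
        while hi + 1 < n and v[hi + 1] == v[pos]:
            hi += 1
        flank = y[lo : hi + 1]
        if flank.min() == flank.max():
            continue
        e_left = class_entropy(left)
        e_right = class_entropy(right)
        gain = parent_entropy - (pos / n) * e_left - ((n - pos) / n) * e_right
        if best is None or gain > best[1] + 1e-12:
            threshold = (v[pos - 1] + v[pos]) / 2.0
            k1 = int((left > 0).sum())
            k2 = int((right > 0).sum())
            best = (threshold, gain, parent_entropy, e_left, e_right,
                    int((parent_counts > 0).sum()), k1, k2, pos)
    return best


def discretise_feature(
    values: Sequence[float] | np.ndarray, klass: Sequence[int] | np.ndarray
) -> tuple[list[float], np.ndarray]:
    """Recursive MDLP discretisation of one feature.

    Returns the sorted accepted thresholds (possibly empty) and the integer bin
    codes (count of thresholds strictly below each value, i.e. the
    ``value > threshold`` convention — thresholds sit at midpoints so ties
    cannot straddle a cut).
    """
    values = np.asarray(values, dtype=float)
    klass = np.asarray(klass, dtype=int)
    if values.shape != klass.shape:
        raise ValueError("values and klass must have equal length")
    thresholds: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        v = values[mask]
        y = klass[mask]
        n = len(v)
        if n < 2 or y.min() == y.max():
            return
        best = _best_boundary_split(v, y)
        if best is None:
            return
        thr, gain, e_p, e_l, e_r, k, k1, k2, _ = best
        if not mdlp_accept(gain, n, e_p, e_l, e_r, k, k1, k2):
            return
        thresholds.append(thr)
        recurse(mask & (values <= thr))
        recurse(mask & (values > thr))

    recurse(np.ones(len(values), dtype=bool))
    thresholds.sort()
    return thresholds, assign_bins(values, thresholds)


def assign_bins(values: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Integer codes 0..B-1: number of thresholds strictly below the value."""
    values = np.asarray(values, dtype=float)
    if not thresholds:
        return np.zeros(len(values), dtype=np.int16)
    codes = np.zeros(len(values), dtype=np.int16)
    for t in thresholds:
        codes += (values > t).astype(np.int16)
    return codes


@dataclass
class CutPointModel:
    """Accepted MDLP thresholds per feature (empty list = feature rejected)."""

    thresholds: dict[str, list[float]]
    #: information gain of the first accepted split, per accepted feature
    first_gain: dict[str, float] = field(default_factory=dict)

    def accepted(self) -> list[str]:
        return [f for f, t in self.thresholds.items() if t]


@dataclass
class DiscretisedMatrix:
    """Integer-coded matrix (features x samples) with its cut-point provenance.

    For combined multi-region matrices ``cuts`` maps region -> CutPointModel
    and each region's samples are coded with that region's thresholds; for a
    single-region matrix there is one entry.
    """

    codes: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    cuts: dict[str, CutPointModel]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("codes shape does not match ids")


@dataclass
class FilterResult:
    dataset: Dataset
    discretised: DiscretisedMatrix
    cuts: CutPointModel


def filter_dataset(ds: Dataset, region_label: str | None = None) -> FilterResult:
    """Drop features without an accepted MDLP split; code the survivors.

    The dataset must contain both classes.  Surviving features keep their
    input order.  An all-rejected matrix yields an empty (but valid) result
    with a warning.
    """
    y = ds.klasses
    if len(np.unique(y)) < 2:
        raise DataError("filter_dataset requires both classes present")
    values = ds.values()
    thresholds: dict[str, list[float]] = {}
    gains: dict[str, float] = {}
    codes_rows: list[np.ndarray] = []
    kept: list[str] = []
    for row, fid in zip(values, ds.feature_ids):
        thr, codes = discretise_feature(row, y)
        thresholds[fid] = thr
        if thr:
            best = _best_boundary_split(row, y)
            gains[fid] = best[1] if best else 0.0
            kept.append(fid)
            codes_rows.append(codes)
    if not kept:
        warnings.warn("entropy filter removed every feature", stacklevel=2)
    label = region_label or (ds.regions[0] if len(ds.regions) == 1 else "all")
    cuts = CutPointModel(thresholds=thresholds, first_gain=gains)
    dm = DiscretisedMatrix(
        codes=np.array(codes_rows, dtype=np.int16).reshape(len(kept), ds.n_samples),
        feature_ids=kept,
        sample_ids=ds.sample_ids,
        cuts={label: cuts},
    )
    return FilterResult(dataset=ds.select_features(kept), discretised=dm, cuts=cuts)


@dataclass
class CombinedFilterResult:
    """Per-region filtering joined over the common surviving features."""

    dataset: Dataset  # continuous, restricted to the common feature universe
    discretised: DiscretisedMatrix  # region-wise codes, same feature order
    per_region: dict[str, FilterResult]


def filter_regions(ds: Dataset) -> CombinedFilterResult:
    """Filter each region separately, keep features accepted in every region.

    The combined integer matrix codes each region's samples with that region's
    own cut points (regions have distinct expression profiles, so cuts are not
    transferable); the feature universe is the intersection of the per-region
    survivor lists, in input feature order.
    """
    regions = split_by_region(ds)
    if len(regions) < 1:
        raise DataError("dataset has no regions")
    per_region = {r: filter_dataset(sub, region_label=r) for r, sub in regions.items()}
    common = set(ds.feature_ids)
    for res in per_region.values():
        common &= set(res.discretised.feature_ids)
    universe = [f for f in ds.feature_ids if f in common]
    if not universe:
        warnings.warn("no feature passed the entropy filter in every region", stacklevel=2)
    sample_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for r, res in per_region.items():
        pos = {f: i for i, f in enumerate(res.discretised.feature_ids)}
        rows = [pos[f] for f in universe]
        blocks.append(res.discretised.codes[rows, :])
        sample_ids.extend(res.discretised.sample_ids)
    codes = (
        np.concatenate(blocks, axis=1)
        if universe
        else np.zeros((0, len(sample_ids)), dtype=np.int16)
    )
    combined = ds.select_samples(sample_ids).select_features(universe)
    dm = DiscretisedMatrix(
        codes=codes,
        feature_ids=universe,
        sample_ids=sample_ids,
        cuts={r: res.cuts for r, res in per_region.items()},
    )
    return CombinedFilterResult(dataset=combined, discretised=dm, per_region=per_region)
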