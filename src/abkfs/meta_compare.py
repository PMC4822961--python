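"""Comparison and post-hoc statistics: fold change, rank product, effect-size
meta-analysis, Welch/Bonferroni testing, and EASE enrichment.

These re-implement the benchmark statistics the combinatorial signature is
compared against, all seeded and permutation-based where significance is
estimated:

rank product
    per region, features are ranked by log2 fold change (rank 1 = most
    extreme in the chosen direction); a feature's statistic is the geometric
    mean of its rank ratios across the K regions, RP_g = (Π_i r_gi)^(1/K),
    and its pfp (percentage of false positives) is estimated from
    within-region class-label permutations.
effect-size meta-analysis
    per region a Hedges-corrected standardised mean difference d with
    sampling variance 1/n_t + 1/n_c + d²/(2(n_t+n_c)); regions are combined
    by inverse-variance weighting (the random model adds a
    DerSimonian–Laird between-region variance), and the FDR at each
    |z| threshold is the permutation-expected count of null exceedances over
    the observed count.
EASE score
    a conservative variant of the one-tailed Fisher exact enrichment
    p-value: the upper hypergeometric tail starting one hit earlier
    (equivalently, the list-hit count reduced by one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, Dataset, GeneSetCollection, split_by_region

__all__ = [
    "RankProductResult",
    "EffectSizeResult",
    "DEGTestResult",
    "EnrichmentResult",
    "fold_change",
    "rank_product",
    "hedges_d",
    "effect_size_meta",
    "welch_bonferroni",
    "ease_enrichment",
]


def fold_change(ds: Dataset, per_region: bool = False) -> pd.Series | pd.DataFrame:
    """Per-feature log2 fold change, affected minus control mean (log2 scale).

    With ``per_region`` the result is a DataFrame feature x region; each
    region must then contain both classes.
    """
    if per_region:
        cols = {}
        for region, sub in split_by_region(ds).items():
            cols[region] = fold_change(sub, per_region=False)
        return pd.DataFrame(cols, index=ds.feature_ids)
    y = ds.klasses
    if (y == 0).sum() == 0:
        raise DataError("no control samples for fold change")
    if (y == 1).sum() == 0:
        raise DataError("no affected samples for fold change")
    v = ds.values()
    fc = v[:, y == 1].mean(axis=1) - v[:, y == 0].mean(axis=1)
    return pd.Series(fc, index=ds.feature_ids, name="log2fc")


# -- rank product --------------------------------------------------------------


@dataclass
class RankProductResult:
    """Rank products with permutation pfp, one direction per run."""

    table: pd.DataFrame  # columns: rp, rank, pfp
    rank_ratios: pd.DataFrame  # feature x region
    direction: Literal["up", "down"]
    K: int
    B: int

    def significant(self, cutoff: float = 0.05) -> list[str]:
        return self.table.index[self.table["pfp"] < cutoff].tolist()


def _rank_ratios(fc: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Rank 1 = most extreme in the direction; ratio = rank / n_features."""
    n = fc.shape[0]
    signed = -fc if direction == "up" else fc
    ranks = signed.rank(axis=0, method="average")
    return ranks / n


def _rp_from_fc(fc: pd.DataFrame, direction: str) -> np.ndarray:
    rr = _rank_ratios(fc, direction)
    return np.exp(np.log(rr.to_numpy()).mean(axis=1))


def rank_product(
    ds: Dataset,
    direction: Literal["up", "down"] = "up",
    B_perm: int = 100,
    seed: int | None = None,
) -> RankProductResult:
    """Rank-product meta-analysis over regions with permutation pfp.

    pfp(g) = E_perm[#null RP ≤ RP_g] / rank(RP_g), the expected number of
    null features at least as extreme divided by the feature's position in
    the observed RP ordering.  Permutations shuffle class labels within each
    region.
    """
    if B_perm < 1:
        raise ValueError("B_perm must be >= 1")
    rng = np.random.default_rng(seed)
    regions = split_by_region(ds)
    fc = fold_change(ds, per_region=True)
    rr = _rank_ratios(fc, direction)
    rp = _rp_from_fc(fc, direction)
    order_rank = stats.rankdata(rp, method="average")
    # permutation null: within-region label shuffles, full RP recomputed
    region_values = {r: sub.values() for r, sub in regions.items()}
    region_y = {r: sub.klasses for r, sub in regions.items()}
    exceed = np.zeros(len(rp))
    for _ in range(B_perm):
        cols = {}
        for r in regions:
            y = rng.permutation(region_y[r])
            v = region_values[r]
            cols[r] = v[:, y == 1].mean(axis=1) - v[:, y == 0].mean(axis=1)
        null_fc = pd.DataFrame(cols, index=ds.feature_ids)
        null_rp = np.sort(_rp_from_fc(null_fc, direction))
        exceed += np.searchsorted(null_rp, rp, side="right")
    expected_false = exceed / B_perm
    pfp = expected_false / order_rank
    table = pd.DataFrame(
        {"rp": rp, "rank": order_rank, "pfp": pfp}, index=ds.feature_ids
    )
    return RankProductResult(
        table=table, rank_ratios=rr, direction=direction, K=len(regions), B=B_perm
    )


# -- effect-size meta-analysis -------------------------------------------------


def hedges_d(
    mean_t: np.ndarray,
    mean_c: np.ndarray,
    sd_pooled: np.ndarray,
    n_t: int,
    n_c: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Small-sample-corrected standardised mean difference and its variance.

    d = J * (mean_t - mean_c) / sd_pooled with J = 1 - 3/(4(n_t+n_c) - 9);
    var(d) = 1/n_t + 1/n_c + d^2 / (2 (n_t + n_c)).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        d_raw = (mean_t - mean_c) / sd_pooled
    correction = 1.0 - 3.0 / (4.0 * (n_t + n_c) - 9.0)
    d = correction * d_raw
    var = 1.0 / n_t + 1.0 / n_c + d**2 / (2.0 * (n_t + n_c))
    return d, var


@dataclass
class EffectSizeResult:
    """Combined effect sizes with a permutation FDR curve on |z| thresholds."""

    table: pd.DataFrame  # columns: mu, se, z, fdr
    d: pd.DataFrame  # feature x region effect sizes
    var: pd.DataFrame  # feature x region variances
    z_grid: np.ndarray  # ascending |z| thresholds
    fdr_curve: np.ndarray  # FDR estimate per grid point (monotone, clipped)
    model: Literal["fixed", "random"]
    B: int
    excluded: list[str] = field(default_factory=list)

    def significant(self, cutoff: float = 0.05) -> list[str]:
        return self.table.index[self.table["fdr"] < cutoff].tolist()


def _region_effects(values: np.ndarray, y: np.ndarray):
    """Per-feature Hedges d and variance for one region's label vector."""
    t = values[:, y == 1]
    c = values[:, y == 0]
    n_t, n_c = t.shape[1], c.shape[1]
    if n_t < 2 or n_c < 2:
        raise DataError("each region needs >= 2 samples per class")
    var_t = t.var(axis=1, ddof=1)
    var_c = c.var(axis=1, ddof=1)
    sp = np.sqrt(((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2))
    return hedges_d(t.mean(axis=1), c.mean(axis=1), sp, n_t, n_c)


def _combine(d: np.ndarray, var: np.ndarray, model: str):
    """Inverse-variance combination across regions (columns); returns mu, se, z."""
    w = 1.0 / var
    mu_fixed = (w * d).sum(axis=1) / w.sum(axis=1)
    if model == "random":
        K = d.shape[1]
        q = (w * (d - mu_fixed[:, None]) ** 2).sum(axis=1)
        denom = w.sum(axis=1) - (w**2).sum(axis=1) / w.sum(axis=1)
        tau2 = np.clip((q - (K - 1)) / denom, 0.0, None)
        w = 1.0 / (var + tau2[:, None])
    mu = (w * d).sum(axis=1) / w.sum(axis=1)
    se = np.sqrt(1.0 / w.sum(axis=1))
    return mu, se, mu / se


def effect_size_meta(
    ds: Dataset,
    model: Literal["fixed", "random"] = "fixed",
    B_perm: int = 100,
    seed: int | None = None,
) -> EffectSizeResult:
    """Effect-size meta-analysis across regions with a permutation FDR.

    FDR(z_th) = (1/B) Σ_b Σ_j I(|Z*_jb| ≥ z_th) / Σ_j I(|z_j| ≥ z_th),
    evaluated two-sidedly on the grid of observed |z| values, monotonised by
    cumulative minimum (in increasing z_th) and clipped to 1.  Features with a
    degenerate pooled SD in any region are excluded from the combination and
    reported separately.
    """
    if B_perm < 1:
        raise ValueError("B_perm must be >= 1")
    rng = np.random.default_rng(seed)
    regions = split_by_region(ds)
    feats = ds.feature_ids
    d_cols, v_cols = {}, {}
    for r, sub in regions.items():
        d_cols[r], v_cols[r] = _region_effects(sub.values(), sub.klasses)
    d = pd.DataFrame(d_cols, index=feats)
    var = pd.DataFrame(v_cols, index=feats)
    ok = np.isfinite(d.to_numpy()).all(axis=1)
    excluded = [f for f, good in zip(feats, ok) if not good]
    d_ok = d.loc[ok]
    var_ok = var.loc[ok]
    mu, se, z = _combine(d_ok.to_numpy(), var_ok.to_numpy(), model)
    abs_z = np.abs(z)
    z_grid = np.unique(abs_z)
    obs_counts = (abs_z[None, :] >= z_grid[:, None]).sum(axis=1).astype(float)
    null_counts = np.zeros_like(obs_counts)
    region_values = {r: sub.values()[ok] for r, sub in regions.items()}
    region_y = {r: sub.klasses for r, sub in regions.items()}
    for _ in range(B_perm):
        d_b, v_b = [], []
        for r in regions:
            y = rng.permutation(region_y[r])
            db, vb = _region_effects(region_values[r], y)
            d_b.append(db)
            v_b.append(vb)
        db = np.column_stack(d_b)
        vb = np.column_stack(v_b)
        good = np.isfinite(db).all(axis=1)
        _, _, zb = _combine(db[good], vb[good], model)
        zb_sorted = np.sort(np.abs(zb))
        null_counts += len(zb_sorted) - np.searchsorted(zb_sorted, z_grid, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (null_counts / B_perm) / obs_counts
    raw = np.where(obs_counts > 0, raw, np.nan)
    fdr_curve = np.minimum.accumulate(np.nan_to_num(raw, nan=np.inf))
    fdr_curve = np.clip(fdr_curve, 0.0, 1.0)
    per_feature_fdr = fdr_curve[np.searchsorted(z_grid, abs_z)]
    table = pd.DataFrame(
        {"mu": mu, "se": se, "z": z, "fdr": per_feature_fdr}, index=d_ok.index
    )
    return EffectSizeResult(
        table=table, d=d_ok, var=var_ok, z_grid=z_grid, fdr_curve=fdr_curve,
        model=model, B=B_perm, excluded=excluded,
    )


# -- Welch t / Bonferroni ------------------------------------------------------


@dataclass
class DEGTestResult:
    """Per-feature Welch t statistics with Bonferroni-corrected p (BF-value)."""

    table: pd.DataFrame  # columns: t, p, bf

    def significant(self, cutoff: float = 1e-4) -> list[str]:
        return self.table.index[self.table["bf"] < cutoff].tolist()

    def bf_values(self) -> pd.Series:
        return self.table["bf"]


def welch_bonferroni(ds: Dataset, center_by_region: bool = False) -> DEGTestResult:
    """Two-sided Welch t-test per feature with Bonferroni correction.

    With ``center_by_region`` each region's per-feature mean is subtracted
    first, removing region-level expression offsets before pooling samples.
    """
    v = ds.values().copy()
    y = ds.klasses
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise DataError("Welch test needs >= 2 samples per class")
    if center_by_region:
        labels = ds.region_labels()
        for r in ds.regions:
            cols = labels == r
            v[:, cols] -= v[:, cols].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(v[:, y == 1], v[:, y == 0], axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    bf = np.minimum(1.0, p * ds.n_features)
    return DEGTestResult(
        table=pd.DataFrame({"t": t, "p": p, "bf": bf}, index=ds.feature_ids)
    )


# -- EASE enrichment -----------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per gene set: 2x2 table counts, Fisher one-tailed p, EASE score."""

    table: pd.DataFrame
    # columns: list_hits, list_misses, bg_hits, bg_misses, p_fisher, ease

    def significant(self, cutoff: float = 0.06) -> list[str]:
        return self.table.index[self.table["ease"] < cutoff].tolist()


def ease_enrichment(
    list_ids: Iterable[str],
    background_ids: Iterable[str],
    sets: GeneSetCollection,
) -> EnrichmentResult:
    """One-tailed Fisher exact enrichment plus the EASE score per gene set.

    For a set with ``a`` hits in the candidate list, the Fisher p is the
    hypergeometric upper tail P(X >= a); the EASE score is the tail started
    one hit earlier, P(X >= a-1) — i.e. the penalised p after discounting a
    single supporting gene, which is 1 whenever a <= 1.
    """
    lst = set(list_ids)
    bg = set(background_ids)
    if not lst:
        raise DataError("candidate list is empty")
    if not lst <= bg:
        raise DataError("candidate list must be a subset of the background")
    M = len(bg)
    N = len(lst)
    rows = {}
    for name, members in sets.items():
        hits_bg = members & bg
        K = len(hits_bg)
        a = len(hits_bg & lst)
        p = float(stats.hypergeom.sf(a - 1, M, K, N)) if K else 1.0
        ease = float(stats.hypergeom.sf(a - 2, M, K, N)) if K else 1.0
        rows[name] = {
            "list_hits": a,
            "list_misses": N - a,
            "bg_hits": K - a,
            "bg_misses": M - N - (K - a),
            "p_fisher": min(p, 1.0),
            "ease": min(ease, 1.0),
        }
    return EnrichmentResult(table=pd.DataFrame.from_dict(rows, orient="index"))
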