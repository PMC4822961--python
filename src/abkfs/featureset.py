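"""The (α,β)-k feature-set problems: pair constraints, maxima, and solvers.

Given a discretised matrix and binary class labels, every admissible sample
pair generates a covering constraint: an inter-class pair (i, j) must be
*discriminated* by at least α selected features (features where the two bin
codes differ), and an intra-class pair must be *agreed on* by at least β
selected features (codes equal).  Which pairs are admissible defines the
variant:

plain
    all pairs (one colour);
coloured
    only pairs within the same region/colour — the multi-dataset integration
    setting, where bin codes are only comparable within a region;
generalised
    pairs admitted by an arbitrary predicate g(i, j); the default predicate
    admits same-region pairs plus cross-region pairs of the same individual.

Minimising the number of selected features subject to these quotas is a set
multicover problem (NP-hard).  Two solvers are provided behind one interface:
an exact 0/1 integer program (HiGHS via scipy) that can prove optimality, and
a deterministic greedy cover with a reverse redundancy-elimination pass for
large instances.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .data_model import DataError, Dataset, SampleMeta
from .discretise import DiscretisedMatrix, filter_dataset, filter_regions

__all__ = [
    "PairUniverse",
    "FeatureSetSolution",
    "SignatureReport",
    "InfeasibleError",
    "build_pairs",
    "alpha_beta_max",
    "verify_solution",
    "solve_min_k",
    "run_signature",
]

Mode = Literal["plain", "coloured", "generalised"]


class InfeasibleError(ValueError):
    """Raised when the requested (α, β) quotas cannot be met."""


@dataclass
class PairUniverse:
    """All admissible sample pairs with their per-pair feature masks.

    ``inter_masks[p, f]`` is True when feature f discriminates inter-class pair
    p (bin codes differ); ``intra_masks[p, f]`` is True when f agrees on
    intra-class pair p.  For every pair the two mask rows are complementary:
    a feature either differs or agrees.
    """

    inter_pairs: np.ndarray  # (P_inter, 2) sample indices, i < j, lexicographic
    intra_pairs: np.ndarray  # (P_intra, 2)
    inter_masks: np.ndarray  # (P_inter, n_features) bool
    intra_masks: np.ndarray  # (P_intra, n_features) bool
    feature_ids: list[str]
    sample_ids: list[str]
    mode: Mode

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def pair_label(self, kind: str, index: int) -> str:
        pairs = self.inter_pairs if kind == "inter" else self.intra_pairs
        i, j = pairs[index]
        return f"({self.sample_ids[i]}, {self.sample_ids[j]})"


@dataclass
class FeatureSetSolution:
    """A feasible feature set with the quotas it satisfies and its provenance."""

    selected: list[str]
    alpha: int
    beta: int
    method: Literal["greedy", "exact"]
    optimal: bool

    @property
    def k(self) -> int:
        return len(self.selected)


def default_g_rule(a: SampleMeta, b: SampleMeta) -> bool:
    """Generalised-variant predicate: same region, or same individual."""
    if a.region == b.region:
        return True
    return a.individual is not None and a.individual == b.individual


def build_pairs(
    dm: DiscretisedMatrix,
    meta: Sequence[SampleMeta],
    mode: Mode = "plain",
    g_rule: Callable[[SampleMeta, SampleMeta], bool] | None = None,
    on_indistinguishable: Literal["error", "drop"] = "error",
) -> PairUniverse:
    """Enumerate admissible sample pairs and their feature masks.

    Pairs are ordered lexicographically by (i, j) sample index, inter- and
    intra-class pairs listed separately.  Raises if no inter-class pair exists
    anywhere (α would be undefined).

    ``on_indistinguishable`` sets the policy for inter-class pairs with an
    empty discriminating set (identical discretised profiles): "error" keeps
    them, so α* = 0 and solving at α ≥ 1 fails naming the pair; "drop"
    removes them with a warning, letting the remaining pairs define α*.
    """
    meta = list(meta)
    m = len(meta)
    if m < 2:
        raise DataError("need at least two samples to build pairs")
    if [s.sample_id for s in meta] != dm.sample_ids:
        raise DataError("metadata order does not match discretised matrix")
    if mode == "generalised" and g_rule is None:
        g_rule = default_g_rule

    def admissible(i: int, j: int) -> bool:
        if mode == "plain":
            return True
        if mode == "coloured":
            return meta[i].region == meta[j].region
        return bool(g_rule(meta[i], meta[j]))

    inter: list[tuple[int, int]] = []
    intra: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(i + 1, m):
            if not admissible(i, j):
                continue
            (inter if meta[i].klass != meta[j].klass else intra).append((i, j))
    if not inter:
        raise DataError("no admissible inter-class pair: alpha is undefined")
    codes = dm.codes
    n = codes.shape[0]

    def masks(pairs: list[tuple[int, int]], agree: bool) -> np.ndarray:
        if not pairs:
            return np.zeros((0, n), dtype=bool)
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        diff = codes[:, ii] != codes[:, jj]  # (n_features, P)
        return (~diff).T if agree else diff.T

    inter_pairs = np.array(inter, dtype=int).reshape(-1, 2)
    inter_masks = masks(inter, agree=False)
    if on_indistinguishable == "drop":
        keep = inter_masks.sum(axis=1) > 0
        if not keep.all():
            bad = [
                f"({dm.sample_ids[i]}, {dm.sample_ids[j]})"
                for i, j in inter_pairs[~keep]
            ]
            warnings.warn(
                f"dropping {len(bad)} indistinguishable inter-class pair(s): "
                f"{bad[:5]}",
                stacklevel=2,
            )
            inter_pairs = inter_pairs[keep]
            inter_masks = inter_masks[keep]
        if inter_pairs.shape[0] == 0:
            raise DataError("all inter-class pairs were indistinguishable")
    return PairUniverse(
        inter_pairs=inter_pairs,
        intra_pairs=np.array(intra, dtype=int).reshape(-1, 2),
        inter_masks=inter_masks,
        intra_masks=masks(intra, agree=True),
        feature_ids=list(dm.feature_ids),
        sample_ids=list(dm.sample_ids),
        mode=mode,
    )


def alpha_beta_max(pu: PairUniverse) -> tuple[int, int]:
    """Largest feasible quotas: the worst pair coverage on each side.

    α* = min over inter pairs of |D(i,j)| and β* = min over intra pairs of
    |A(i,j)| (0 with no intra pairs); the full feature set witnesses both.
    α* = 0 flags an indistinguishable inter-class pair — reported, not raised.
    """
    if pu.inter_pairs.shape[0] == 0:
        raise DataError("alpha undefined without inter-class pairs")
    alpha_star = int(pu.inter_masks.sum(axis=1).min())
    beta_star = (
        int(pu.intra_masks.sum(axis=1).min()) if pu.intra_pairs.shape[0] else 0
    )
    return alpha_star, beta_star


def verify_solution(
    pu: PairUniverse, selected: Sequence[str], alpha: int, beta: int
) -> bool:
    """Check every inter-pair α quota and intra-pair β quota against a set."""
    idx = _selected_indices(pu, selected)
    mask = np.zeros(pu.n_features, dtype=bool)
    mask[idx] = True
    if pu.inter_masks.shape[0] and (pu.inter_masks[:, mask].sum(axis=1) < alpha).any():
        return False
    if beta > 0 and pu.intra_masks.shape[0]:
        if (pu.intra_masks[:, mask].sum(axis=1) < beta).any():
            return False
    return True


def _selected_indices(pu: PairUniverse, selected: Sequence[str]) -> np.ndarray:
    pos = {f: i for i, f in enumerate(pu.feature_ids)}
    try:
        return np.array([pos[f] for f in selected], dtype=int)
    except KeyError as e:
        raise DataError(f"selected feature {e.args[0]!r} not in universe") from None


def _constraint_rows(pu: PairUniverse, alpha: int, beta: int):
    """(masks, quotas) of all binding covering constraints."""
    rows = []
    quotas = []
    if alpha > 0:
        rows.append(pu.inter_masks)
        quotas.append(np.full(pu.inter_masks.shape[0], alpha))
    if beta > 0 and pu.intra_masks.shape[0]:
        rows.append(pu.intra_masks)
        quotas.append(np.full(pu.intra_masks.shape[0], beta))
    if not rows:
        return np.zeros((0, pu.n_features), dtype=bool), np.zeros(0, dtype=int)
    return np.concatenate(rows, axis=0), np.concatenate(quotas)


def _check_feasible(pu: PairUniverse, alpha: int, beta: int) -> None:
    if alpha < 1:
        raise InfeasibleError("alpha must be a positive integer")
    if beta < 0:
        raise InfeasibleError("beta must be non-negative")
    cover = pu.inter_masks.sum(axis=1)
    if cover.size and cover.min() < alpha:
        p = int(cover.argmin())
        raise InfeasibleError(
            f"inter pair {pu.pair_label('inter', p)} has only {int(cover.min())} "
            f"discriminating features < alpha={alpha}"
        )
    if beta > 0 and pu.intra_masks.shape[0]:
        cover = pu.intra_masks.sum(axis=1)
        if cover.min() < beta:
            p = int(cover.argmin())
            raise InfeasibleError(
                f"intra pair {pu.pair_label('intra', p)} has only "
                f"{int(cover.min())} agreeing features < beta={beta}"
            )


def solve_min_k(
    pu: PairUniverse,
    alpha: int,
    beta: int,
    method: Literal["greedy", "exact"] = "greedy",
    time_limit: float | None = None,
) -> FeatureSetSolution:
    """Minimum-cardinality feature set meeting every pair quota.

    exact
        0/1 integer program  min Σ_f z_f  s.t.  Σ_{f∈D(i,j)} z_f ≥ α (inter),
        Σ_{f∈A(i,j)} z_f ≥ β (intra); solved by HiGHS, ``optimal`` is True only
        when optimality was proved within ``time_limit``.
    greedy
        repeatedly add the feature covering the most pairs whose quota is
        still unmet (ties: lower index), then walk the additions in reverse
        and drop any feature whose removal keeps all quotas satisfied.
    """
    _check_feasible(pu, alpha, beta)
    masks, quotas = _constraint_rows(pu, alpha, beta)
    if method == "exact":
        return _solve_exact(pu, masks, quotas, alpha, beta, time_limit)
    if method == "greedy":
        return _solve_greedy(pu, masks, quotas, alpha, beta)
    raise ValueError(f"unknown method {method!r}")


def _solve_exact(pu, masks, quotas, alpha, beta, time_limit) -> FeatureSetSolution:
    n = pu.n_features
    if masks.shape[0] == 0:
        return FeatureSetSolution([], alpha, beta, "exact", True)
    A = sp.csr_matrix(masks.astype(np.int8))
    constraint = LinearConstraint(A, lb=quotas, ub=np.inf)
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=np.ones(n),
        integrality=np.ones(n),
        bounds=(0, 1),
        constraints=[constraint],
        options=options,
    )
    if res.x is None:
        raise InfeasibleError(f"exact solver found no solution: {res.message}")
    chosen = np.flatnonzero(res.x > 0.5)
    selected = [pu.feature_ids[i] for i in chosen]
    # guard against tolerance artefacts from the MILP relaxation
    if not verify_solution(pu, selected, alpha, beta):  # pragma: no cover
        raise RuntimeError("exact solver returned an infeasible set")
    return FeatureSetSolution(selected, alpha, beta, "exact", optimal=res.status == 0)


def _solve_greedy(pu, masks, quotas, alpha, beta) -> FeatureSetSolution:
    n = pu.n_features
    remaining = quotas.astype(int).copy()
    chosen: list[int] = []
    chosen_mask = np.zeros(n, dtype=bool)
    while True:
        active = remaining > 0
        if not active.any():
            break
        scores = masks[active].sum(axis=0)
        scores[chosen_mask] = -1
        f = int(scores.argmax())  # argmax takes the lowest index on ties
        if scores[f] <= 0:  # pragma: no cover - prevented by _check_feasible
            raise InfeasibleError("greedy cannot cover remaining quotas")
        chosen.append(f)
        chosen_mask[f] = True
        remaining -= masks[:, f].astype(int)
    # reverse-order redundancy elimination
    coverage = masks[:, chosen_mask].sum(axis=1) if chosen else np.zeros(0, dtype=int)
    for f in reversed(chosen.copy()):
        col = masks[:, f]
        if np.all(coverage[col] - 1 >= quotas[col]):
            coverage = coverage - col.astype(int)
            chosen.remove(f)
            chosen_mask[f] = False
    chosen.sort()
    return FeatureSetSolution(
        [pu.feature_ids[i] for i in chosen], alpha, beta, "greedy", optimal=False
    )


# -- end-to-end signature run --------------------------------------------------


@dataclass
class SignatureReport:
    """Outcome of a full filter → pairs → solve run, with annotations."""

    solution: FeatureSetSolution | None
    alpha_star: int
    beta_star: int
    mode: Mode
    solver: str
    universe: list[str]
    #: per-region mean log2 fold change (AD − control) of the universe features
    fold_changes: pd.DataFrame | None = None
    infeasible_reason: str | None = None
    elapsed_s: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.solution is not None

    def signature_table(self) -> pd.DataFrame:
        """TSV-ready table: selected features with per-region log2FC."""
        if self.solution is None:
            raise InfeasibleError(self.infeasible_reason or "no signature produced")
        table = self.fold_changes.loc[self.solution.selected].copy()
        table.insert(0, "selected_by", self.mode)
        return table

    def manifest(self) -> dict:
        return {
            "mode": self.mode,
            "solver": self.solver,
            "alpha_star": self.alpha_star,
            "beta_star": self.beta_star,
            "alpha": self.solution.alpha if self.solution else None,
            "beta": self.solution.beta if self.solution else None,
            "k": self.solution.k if self.solution else None,
            "optimal": self.solution.optimal if self.solution else None,
            "universe_size": len(self.universe),
            "feasible": self.feasible,
            "infeasible_reason": self.infeasible_reason,
            "elapsed_s": round(self.elapsed_s, 3),
        }


def run_signature(
    ds: Dataset,
    mode: Mode = "coloured",
    solver: Literal["greedy", "exact"] = "greedy",
    alpha: int | None = None,
    beta: int | None = None,
    time_limit: float | None = None,
    g_rule: Callable[[SampleMeta, SampleMeta], bool] | None = None,
) -> SignatureReport:
    """Full pipeline on a raw dataset: filter, build pairs, solve at (α*, β*).

    In plain mode the whole dataset is discretised as one block; in coloured /
    generalised mode each region is filtered separately and the universe is the
    intersection of per-region survivors, each region keeping its own cut
    points.  With ``alpha``/``beta`` unset the maximal feasible quotas are
    used.  An instance with an indistinguishable inter-class pair (α* = 0)
    yields a report with no solution rather than an exception.
    """
    from .meta_compare import fold_change  # local import: avoid cycle

    t0 = time.perf_counter()
    if mode == "plain":
        fr = filter_dataset(ds)
        filtered_ds, dm = fr.dataset, fr.discretised
    else:
        cr = filter_regions(ds)
        filtered_ds, dm = cr.dataset, cr.discretised
    meta = [s for sid in dm.sample_ids for s in ds.samples if s.sample_id == sid]
    if not dm.feature_ids:
        return SignatureReport(
            solution=None, alpha_star=0, beta_star=0, mode=mode, solver=solver,
            universe=[], infeasible_reason="entropy filter left no features",
            elapsed_s=time.perf_counter() - t0,
        )
    pu = build_pairs(dm, meta, mode=mode, g_rule=g_rule)
    alpha_star, beta_star = alpha_beta_max(pu)
    fc = fold_change(filtered_ds, per_region=True)
    if alpha_star == 0 and alpha is None:
        worst = int(pu.inter_masks.sum(axis=1).argmin())
        return SignatureReport(
            solution=None, alpha_star=0, beta_star=beta_star, mode=mode,
            solver=solver, universe=dm.feature_ids, fold_changes=fc,
            infeasible_reason=(
                f"inter pair {pu.pair_label('inter', worst)} is indistinguishable "
                "(alpha* = 0); no signature produced"
            ),
            elapsed_s=time.perf_counter() - t0,
        )
    a = alpha if alpha is not None else alpha_star
    b = beta if beta is not None else beta_star
    solution = solve_min_k(pu, a, b, method=solver, time_limit=time_limit)
    return SignatureReport(
        solution=solution, alpha_star=alpha_star, beta_star=beta_star,
        mode=mode, solver=solver, universe=dm.feature_ids, fold_changes=fc,
        elapsed_s=time.perf_counter() - t0,
    )
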