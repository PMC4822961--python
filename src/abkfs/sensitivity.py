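"""Leave-region(s)-out robustness analysis and signature overlap reporting.

Removing a region relaxes the pair-constraint system (fewer pairs can only
raise the worst-pair coverage), so the maximal quotas (α*, β*) never decrease;
the question the analysis answers is how much of the full-data signature each
reduced run retains, overall and within strata of increasingly significant
features (by Bonferroni-corrected p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import DataError, Dataset
from .featureset import FeatureSetSolution, SignatureReport, run_signature
from .meta_compare import DEGTestResult

__all__ = ["OverlapReport", "leave_regions_out", "overlap_report"]


def leave_regions_out(
    combined: Dataset, drop: Iterable[str], **pipeline_options
) -> SignatureReport:
    """Re-run the full coloured pipeline with the given regions removed.

    The reduced run re-derives its own feature universe and (α*, β*); all
    other options are passed through unchanged.  At least two regions must
    remain.
    """
    drop = set(drop)
    unknown = drop - set(combined.regions)
    if unknown:
        raise DataError(f"unknown regions to drop: {sorted(unknown)}")
    keep = [r for r in combined.regions if r not in drop]
    if len(keep) < 2:
        raise DataError(
            f"only {len(keep)} region(s) would remain; need at least 2"
        )
    ids = [s.sample_id for s in combined.samples if s.region not in drop]
    reduced = combined.select_samples(ids)
    pipeline_options.setdefault("mode", "coloured")
    return run_signature(reduced, **pipeline_options)


@dataclass
class OverlapReport:
    """Pairwise agreement between a reference signature and alternatives."""

    pairs: pd.DataFrame
    # index: comparison name; columns: shared, ref_size, other_size,
    #   frac_of_ref, frac_of_other, jaccard
    strata: pd.DataFrame | None = None
    # index: (comparison, bf_cutoff); columns: ref_in_stratum, shared, frac_shared


def _features(sig) -> set[str]:
    if isinstance(sig, SignatureReport):
        if sig.solution is None:
            return set()
        return set(sig.solution.selected)
    if isinstance(sig, FeatureSetSolution):
        return set(sig.selected)
    return set(sig)


def overlap_report(
    reference,
    others: Mapping[str, object],
    deg: DEGTestResult | None = None,
    strata: Sequence[float] = (),
) -> OverlapReport:
    """Shared counts, both-direction fractions and Jaccard per comparison.

    With a :class:`DEGTestResult` and BF-value cutoffs, additionally reports —
    per cutoff — the fraction of the reference features below the cutoff that
    each alternative retains.  Both sharing denominators are emitted because
    "agreement" is directional.
    """
    ref = _features(reference)
    rows = {}
    strata_rows = {}
    for name, other_sig in others.items():
        other = _features(other_sig)
        shared = ref & other
        union = ref | other
        rows[name] = {
            "shared": len(shared),
            "ref_size": len(ref),
            "other_size": len(other),
            "frac_of_ref": len(shared) / len(ref) if ref else 0.0,
            "frac_of_other": len(shared) / len(other) if other else 0.0,
            "jaccard": len(shared) / len(union) if union else 1.0,
        }
        if deg is not None:
            bf = deg.bf_values()
            for cutoff in strata:
                in_stratum = {f for f in ref if f in bf.index and bf[f] < cutoff}
                kept = in_stratum & other
                strata_rows[(name, cutoff)] = {
                    "ref_in_stratum": len(in_stratum),
                    "shared": len(kept),
                    "frac_shared": len(kept) / len(in_stratum) if in_stratum else 0.0,
                }
    strata_df = (
        pd.DataFrame.from_dict(strata_rows, orient="index") if strata_rows else None
    )
    return OverlapReport(
        pairs=pd.DataFrame.from_dict(rows, orient="index"), strata=strata_df
    )
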