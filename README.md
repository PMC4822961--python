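# abkfs — Coloured (α,β)-k feature-set analysis for multi-region expression studies

`abkfs` is an integrated differential-expression pipeline for case/control
expression studies measured in several related sub-datasets — typically the
same disease sampled in multiple brain regions or cohorts on one platform.
Instead of ranking features one at a time, it selects a *minimum* feature set
that collectively guarantees pairwise evidence, and surrounds that core with
the standard pre-filtering, benchmark meta-analysis, enrichment and
robustness machinery.

## The model

Expression values are first discretised per region with Fayyad–Irani MDLP
splitting: each feature gets the entropy-optimal threshold(s) accepted under
a minimum-description-length stopping rule, and features with no accepted
split are dropped as uninformative. On the discretised matrix X with binary
classes y, the **(α,β)-k feature set problem** asks for the smallest feature
set I such that

- every inter-class sample pair (y_i ≠ y_j) is *discriminated* by at least α
  selected features (bin codes differ), and
- every intra-class pair (y_i = y_j) *agrees* on at least β selected features,

for all admissible pairs. In the **Coloured** variant each sample carries a
colour c(i) (its region) and only same-coloured pairs generate constraints,
which is how heterogeneous regions are integrated without cross-region value
comparison. The **Generalised** variant admits pairs through an arbitrary
predicate g(i,j) — by default, same region *or* same donating individual, so
repeated donors link regions. The maximal feasible quotas (α\*, β\*) are the
worst-pair coverages; signatures are solved at those maxima, either exactly
(0/1 integer programming, optimality proven) or by a deterministic greedy
multicover with redundancy elimination.

Around the core:

- **Rank product**: RP_g = (Π_i r_gi)^(1/K) over per-region fold-change rank
  ratios, with a permutation pfp (percentage of false positives) estimate.
- **Effect-size meta-analysis**: Hedges-corrected standardised mean
  differences combined by inverse-variance weighting (fixed or
  DerSimonian–Laird random effects), with a permutation FDR over |z|
  thresholds.
- **Welch t / Bonferroni** BF-values for stratifying signatures.
- **EASE enrichment**: the one-tailed Fisher exact p penalised by one
  supporting gene, against user-supplied GMT gene sets.
- **Sensitivity analysis**: leave-region(s)-out re-runs and overlap reports.
- **Synthetic generator**: multi-region datasets with planted shared and
  region-specific differential features, shared donors and known truth.

## Worked example

```sh
python examples/02_feature_selection.py
```

```
worked instance: alpha*=2, beta*=2, min k=2, I=['f1', 'f3'], proven optimal=True
coloured signature: k=30 of 30-feature universe at (alpha*=23, beta*=23)
shared planted recall 1.00, precision 1.00
```

The first line solves a 4-sample, 3-feature instance to proven optimality:
two features suffice to give every inter-class pair two discriminating
features and every intra-class pair two agreeing ones. The second runs the
full pipeline on a five-region synthetic study (30 planted shared features,
effect 3 log2-units, 10+10 samples per region): after per-region filtering
the combined universe is exactly the planted shared set, the worst inter-class
pair is separated by 23 features (α\* = 23), and the minimal signature at the
maximal quotas recovers every planted feature with no false positives.

The other `examples/` scripts walk the filter, the benchmark meta-analysis
statistics, EASE enrichment and the leave-region-out analysis; each prints a
few numbers and says what they mean. A thin CLI (`abkfs simulate|filter|
select|meta|enrich|sensitivity`) wraps the same calls for shell use.

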