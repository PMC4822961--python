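# Methods

## Data model

A study is a features × samples matrix of log2-scale expression values plus
per-sample metadata: a region label (the "colour"), a binary class (0 =
control, 1 = affected) and optionally a donating individual. Individuals must
be class-consistent across their samples; this invariant is enforced at
construction, which is why inter-class same-individual pairs cannot arise in
the generalised variant. Loaders reject missing values, duplicated feature
ids and metadata/matrix mismatches outright rather than imputing. Input on a
linear scale (matrix maximum above 50) is log2(x+1)-transformed at load time
and the transform is recorded; the threshold is a heuristic for telling
linear-scale matrices from already-logged ones, and callers handling unusual
data should transform explicitly.

Multi-region matrices are combined over the *intersection* of per-part
features. The alternative (union with missing blocks) would leave regions
undiscretisable on features they never passed; the intersection keeps every
downstream constraint well defined. The reported combined-universe size under
the intersection rule is therefore the operative one, and per-region survivor
counts let a user recompute the union if wanted.

## Entropy filtering and discretisation

Each feature is discretised per region by recursive binary splitting:
candidate cuts are midpoints between adjacent distinct values whose flanking
value-groups are not one pure class (the class-boundary restriction, which is
lossless for entropy optimisation), the best cut maximises information gain,
and a cut is accepted only when

    gain > [log2(n−1) + log2(3^k − 2) − (k·E − k1·E1 − k2·E2)] / n

with E, E1, E2 the parent/child entropies and k, k1, k2 the class counts
present in each. Equal-gain ties resolve to the smallest threshold, making
the procedure deterministic. Bin codes count thresholds strictly below the
value; since thresholds sit at midpoints of observed values, the ≤ vs <
choice cannot affect observed data. Features whose root split is rejected are
dropped — this is the uninformative-feature filter.

Two properties are worth knowing. First, the partition of samples is
invariant under any strictly increasing transform of a feature (cut
*positions* move, bins do not), so the filter is insensitive to monotone
normalisation choices. Second, the criterion's null false-positive rate is a
function of sample size: on pure-noise features it admits roughly 2% at 20
samples per class, dropping below 1% only around 50 per class. The
implementation was checked against a brute-force reference discretiser (all
cuts, no shortcuts) on hundreds of random inputs including ties.

For combined runs, each region keeps its own cut points — regions have
distinct expression profiles and thresholds are not transferable — and the
combined universe is the set of features accepted in *every* included
region. Bin codes are therefore comparable only within a region, which is
exactly the comparison scope of the coloured variant. The generalised
variant's cross-region same-individual pairs do compare codes produced by
different cut-point sets; that is inherent to the construction and the reason
its β\* can differ from the coloured value in either direction.

## The (α,β)-k problems and solvers

All variants reduce to a covering system over sample pairs: inter-class pair
(i,j) carries the discriminating set D(i,j) = {f : bin_f(i) ≠ bin_f(j)} and
quota α; intra-class pairs carry the complementary agreeing set A(i,j) and
quota β. |D| + |A| = n for every pair. α\* = min |D| over admissible
inter-class pairs and β\* = min |A| over intra-class pairs are the largest
feasible quotas (the full feature set is always a witness). α\* = 0 means
some inter-class pair is indistinguishable after discretisation; the solver
refuses such instances by default (α > 0 is part of the problem statement)
and the pipeline-level runner instead reports the offending pair and
declines to produce a signature — the observed behaviour on null data, where
the filter also empties the universe.

Minimising |I| subject to the quotas is a set multicover problem, NP-hard in
general, so two solvers sit behind one interface:

- **exact** — min Σ z_f subject to Σ_{f∈D(i,j)} z_f ≥ α and
  Σ_{f∈A(i,j)} z_f ≥ β, z binary, solved by HiGHS branch-and-cut through
  scipy; `optimal=True` only when optimality was proven within the time
  limit. Validated against exhaustive subset enumeration on hundreds of
  random instances up to 15 features.
- **greedy** — repeatedly add the feature contained in the most
  quota-unsatisfied pairs (ties to the lower feature index, making runs
  deterministic), then traverse the additions in reverse and drop any
  feature whose removal keeps all quotas met. Feasible by construction,
  k ≥ the optimum, and fast enough for thousands of pairs.

Pair masks are dense boolean matrices (pairs × features); at the scales this
package targets (hundreds of pairs, tens to thousands of features) that
representation is both the fastest to reduce over and trivially correct.

Signature runs default to the greedy solver and to (α\*, β\*) — maximising
the per-pair evidence the minimal set must carry, which is the study design
this pipeline implements; both quota values and the solver are overridable.

## Benchmark statistics

**Fold change** is the difference of class means on the log2 scale, per
region or pooled.

**Rank product.** One comparison per region: features are ranked by
per-region fold change (rank 1 = most extreme in the chosen direction;
up- and down-regulation are two separate runs), r_gi = rank/n, and
RP_g = (Π r_gi)^(1/K). The region-level formulation (rather than the
all-sample-pairs product) matches one comparison per dataset and keeps
permutations within regions. pfp(g) = E_perm[# null RP ≤ RP_g] / rank(RP_g),
estimated from B within-region class-label permutations with the full RP
vector recomputed per permutation.

**Effect-size meta-analysis.** Per region, d = J·(mean_t − mean_c)/s_pooled
with the small-sample factor J = 1 − 3/(4(n_t+n_c) − 9), and variance
σ² = 1/n_t + 1/n_c + d²/(2(n_t+n_c)). Regions combine by inverse-variance
weighting; the random model adds the DerSimonian–Laird moment estimate of
between-region variance (clipped at 0). Reported z = μ̂/se(μ̂). The FDR at
threshold z_th is the permutation-expected count of |Z\*| ≥ z_th over the
observed count, evaluated two-sidedly on the grid of observed |z| values;
since the threshold set is otherwise arbitrary, the observed values are the
natural grid. The raw curve is monotonised by cumulative minimum in
increasing z_th and clipped to 1. Features with zero pooled SD in any region
are excluded from combination and listed separately. With B = 1 and an
identity permutation the estimate is identically 1, a useful smoke check.

**Welch/Bonferroni.** Two-sided Welch t per feature, BF = min(1, p·n).
Combined runs centre each region's per-feature mean first so that region
offsets do not masquerade as class signal; per-region runs skip centering.
Welch was chosen over pooled-variance t because expression variances are
routinely unequal between classes; the test is a stratification device here,
not the selection method, and is easily swapped.

**EASE score.** For a gene set with a hits in the candidate list, the Fisher
exact one-tailed p is the hypergeometric upper tail P(X ≥ a) on the observed
margins; the EASE score is the tail started one hit earlier, P(X ≥ a−1) on
the same margins — equivalently the p-value after discounting a single
supporting gene, hence always ≥ the Fisher p and exactly 1 when a ≤ 1.
EASE conventions differ in whether the margins are recomputed; this package
keeps them fixed, which reproduces the conservative single-gene-discount
behaviour with a closed hypergeometric form.

## Sensitivity analysis

Leave-region(s)-out re-runs the *entire* pipeline (per-region filter,
intersection universe, pair construction, fresh (α\*, β\*), solve) on the
reduced region set. Removing a region only removes constraints and can only
grow the universe, so α\* and β\* never decrease — asserted end-to-end in the
tests. Overlap reports give shared counts, the fraction of each side shared
(agreement is directional, so both denominators are emitted) and the Jaccard
index, plus per-stratum retention for BF-value cutoffs.

## Synthetic generator

The generator emulates a multi-region case/control microarray study on the
log2 scale: value = baseline_f + class·effect + individual effect + noise,
with per-feature baselines N(8, 2²), planted effects ±δ (direction random
per feature, as real signatures mix up- and down-regulation), Gaussian noise,
and additive per-individual, per-feature effects N(0, individual_sd²) shared
across a donor's samples. A configured fraction of samples is drawn from
returning donors (class preserved), giving the generalised variant its
cross-region pairs. Defaults are the reference simulation conditions: 200
features, 30 shared + 10 per-region planted at δ = 3 with σ = 1, five
regions at 10+10 samples, 30% donor overlap with individual SD 0.3 — chosen
as a realistic strong-effect microarray regime where the combined universe
should essentially coincide with the planted shared set.

What the generator does *not* model: probe-level cross-hybridisation, batch
and array effects, heavy-tailed or heteroscedastic noise, missing data, and
correlation between features beyond the shared individual effect. Passing
recovery tests therefore demonstrate the machinery is correct and calibrated
under an idealised additive-Gaussian regime, not that real studies of this
size would behave as cleanly.

## Numerical and edge-case choices

- Entropies use log2 with 0·log 0 = 0; all-zero count vectors are errors.
- Equal-gain discretisation cuts take the smallest threshold; greedy ties
  take the lowest feature index; pair enumeration is lexicographic — every
  run is reproducible bit-for-bit given the seed.
- Permutation seeds are explicit arguments everywhere; the CLI logs them in
  run manifests together with input digests.
- Constant features discretise to no thresholds (never an error); one-class
  datasets are errors.
- MILP solutions are re-verified against the quota system before being
  returned, guarding against solver tolerance artefacts.

## Known limitations

- Exactly two classes; multi-class labels are out of scope.
- The exact solver's practical range is instance-dependent; large combined
  instances should use greedy (the default) and treat reported k as an upper
  bound (`optimal` is always explicit in the result).
- Per-run recovery on borderline instances is limited by the filter: a
  planted feature whose worst-region split narrowly misses the MDL bar
  leaves the universe before selection begins, and minimal-cover solving may
  drop a feature whose quotas are covered elsewhere. At the default
  simulation conditions this caps occasional runs at 28/30 planted features
  recovered even though the aggregate recall stays above 95%.
- The pfp and FDR estimators are permutation-based and share the usual
  granularity limits at small B; they are calibrated (conservative-to-
  nominal) under the generator's null, as the tests measure.
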