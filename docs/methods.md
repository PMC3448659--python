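# Methods

## Scope and model

`mstknn` clusters the rows (features) of a strictly positive
expression matrix by recursive partitioning of an annotated minimum
spanning tree, after optionally expanding the matrix with all pairwise
metafeatures and appending disease-progression marker vectors as
ordinary nodes.  The sections below record the exact procedure, the
parameters that matter, and the design choices made where the method
left room.

## Distance and neighbour ranks

Similarity between features is the absolute Spearman rank correlation;
the distance is `d(i,j) = 1 − |ρ(i,j)| ∈ [0,1]`.  Two properties drive
this choice:

- *sign-blindness*: a marker's cluster should admit both strongly
  positively and strongly negatively correlated features, since both
  are informative biomarkers;
- *monotone invariance*: Spearman depends only on ranks, so the
  clustering is unchanged under any per-feature strictly increasing
  transform of the data (tested as a property).

Constant features have no defined rank correlation and are dropped
with a warning before clustering.

For each node *a* every other node is totally ordered by
`(d(a,·), node index)` — ties break toward the smaller index so all
downstream steps are deterministic — and `f(a,b)` denotes b's 1-based
position in that order.  Ranks are computed **once** from the full
distance matrix and reused at every recursion level; only the
elimination threshold adapts to the component size.

## Graph construction

A complete graph over n features is quadratic in memory; instead the
method uses the symmetrized q-nearest-neighbour graph (edge {a,b} iff
`f(a,b) ≤ q` or `f(b,a) ≤ q`) with entry point `q₀ = ⌊ln n⌋ + 1`,
motivated by the inclusion relationship between the MST and the family
of k-NN graphs with `k > ln n`.  A q-NN graph need not be connected;
`q` is escalated by +1 until it is (`q = n−1` is complete, so this
terminates).  The spanning tree is then the Kruskal MST with edges
considered in ascending `(weight, smaller endpoint, larger endpoint)`
order, making tie-breaks — and therefore the whole pipeline —
deterministic.

## Edge annotation and partition criteria

Each tree edge (a,b) carries `p = min(f(a,b), f(b,a))`.  The defining
identity, verified by brute force in the test suite, is:

> `p > k` holds exactly when neither endpoint lies within the other's
> k nearest neighbours,

i.e. removing edges with `p > k` is the classical MST-kNN elimination
rule.  Each component of size `n_c` is processed with threshold
`t = ⌊ln n_c⌋` (natural log; `t = 2` at the canonical 10-node worked
example):

| case | condition | action |
|------|-----------|--------|
| MINSIZE | `n_c ≤ min_size` (default 3) | terminal cluster |
| C1 | `p_max > t` | remove every edge with `p > t` |
| C3 | `p_max = 1` or `p_max = t` | terminal cluster |
| C2 | `1 < p_max < t` | remove every edge with `p = p_max` |

The cases are exhaustive and mutually exclusive; every non-terminal
step removes at least one edge, so the recursion terminates after at
most n−1 removals.  Components are processed in a deterministic
(smallest-node-first, depth-first) order and final cluster ids are
renumbered by each cluster's lexicographically smallest member, so
repeated runs are byte-identical.

Two genuinely open points are resolved as follows and exposed as
switches rather than hard-coded:

- **C2 target.** The criterion is stated ambiguously in the method's
  source descriptions; removing the edges with the *weakest* mutual
  support (`p = p_max`) is the reading under which C2 always splits
  the component and the recursion terminates, and is the default.
  `c2_policy="pmax-1"` selects the alternative reading (remove
  `p = p_max − 1`, falling back to `p_max` when no such edge exists —
  without the fallback the step could remove nothing).
- **Rank scope.** Neighbour ranks come from the full distance matrix,
  not per-component recomputation: the method re-adjusts only the
  threshold with component size.

## Jensen–Shannon progression scores

A sample's profile is its expression vector over the signature
features normalized to unit sum (well-defined because intensities are
strictly positive).  A group's characteristic profile is the
arithmetic mean of its members' profiles — mean-of-profiles rather
than profile-of-means, so each member weighs equally regardless of
overall intensity.  The divergence of sample s from group G is

    JSD(P_s, P_G) = H((P_s + P_G)/2) − (H(P_s) + H(P_G))/2,

with Shannon entropy H in nats, so JSD ∈ [0, ln 2].  The natural-log
convention is stated everywhere it matters; downstream clustering uses
ranks of the scores, which are base-invariant.  Symmetry,
boundedness, identity of indiscernibles and monotonicity along linear
interpolation are property-tested; the implementation is additionally
cross-checked against an independent library evaluation of the same
divergence.

## Metafeatures

All unordered feature pairs under the chosen operator set, oriented
first-over-second in the matrix's feature order (one orientation per
pair; downstream |Spearman| is orientation-invariant).  Ratios require
strict positivity, enforced at the point of use; no log-transform is
applied to ratios since rank correlation is invariant to monotone
transforms.  Generation streams in blocks of at most `block_size` rows
so the full expansion (millions of rows at signature scale) never has
to be materialized; the materializing wrapper is intended for desk
scale.  Marker vectors are appended as rows named `MARKER:<name>` so
they participate in clustering as ordinary nodes.

## Cluster quality and FDR

Homogeneity is the mean Pearson correlation of each feature with its
cluster centroid (cluster mean including the member; a singleton
therefore contributes exactly 1 — `include_singletons=False` covers
the stricter reading).  Separation is the size-weighted mean Pearson
correlation between centroid pairs.  Both are invariant to cluster
relabeling.

The permutation FDR shuffles the marker uniformly across samples
(seeded generator, permutations sampled with replacement over
orderings), recomputes all |Spearman| values per permutation
(vectorized as Pearson on ranks), and reports
`fdr = min(1, mean_null_count / max(observed_count, 1))` per
threshold.  1,000 permutations is the conventional depth; tests use
200, which is enough for the ~±10% Monte-Carlo accuracy they assert.

## Synthetic data

The generator emulates the target regime: a few hundred strictly
positive features over a small cohort, organized in correlation
blocks.  Block k has a latent `z_k ~ N(0, I)` over samples; feature i
of block k is `exp(a·z_k + ε_i)` with `ε ~ N(0, noise_sd²)` and
`a = noise_sd · sqrt(rho_within / (1 − rho_within))`, which makes the
population correlation of log-values within a block exactly
`rho_within`; distinct blocks are independent.  `noise_sd = 0` is
handled as the exact limit (features are noiseless monotone transforms
of the latent).  Defaults — 5 blocks × 30 features, 17 samples,
`rho_within = 0.9`, `noise_sd = 0.3` — mirror the cohort size and
signal strength of the motivating application.

Markers are blends `α·z_k + sqrt(1 − α²)·η` with
`α = min(1, rho_target / sqrt(rho_within))`, so the expected
correlation with block members is `rho_target` (attainable maximum
`sqrt(rho_within)`); `rho_target = 1` returns the latent itself, and a
separate null generator gives markers independent of every block.

What the generator does **not** model: probe-affinity effects, batch
effects, heteroskedastic array noise, correlated noise between blocks,
or missing values.  Passing the planted-recovery tests therefore shows
the algorithm recovers clean latent-factor structure at realistic
cohort size and noise — not that it is robust to array artefacts.

On planted data the method recovers blocks but also shaves weakly
attached members into small satellite clusters (that is what C2 is
for), so recovery is scored by adjusted Rand index rather than exact
equality; under the default conditions ARI is ≈ 0.8 (the two-block
easy case is recovered exactly).  This matches the method's character
on real data, where it yields many small clusters rather than a few
big ones.

## Numerical choices and degenerate inputs

- Full double precision throughout; no internal rounding.  Reports
  print correlations and divergences with 6 decimals.
- Distance values are clipped to [0,1] and symmetrized to remove
  floating-point asymmetry before ranking.
- JSD values are floored at 0 to absorb rounding noise at P = Q.
- Spearman on fewer than 3 observations, constant vectors in a
  pairwise call, empty groups, components of size < 2, single-cluster
  separation: all raise with informative messages.  Constant features
  in batch screening (`correlate_all`) are flagged NaN and logged
  instead, so one dead probe cannot abort a million-row screen.
- Writers sort rows lexicographically and use fixed float formats;
  outputs carry no timestamps, so identical inputs give identical
  bytes.

## Problem sizes

The default test and example configurations run at desk scale — up to
~500 features, 17 samples, 200 permutations, thousand-fold brute-force
oracle comparisons on graphs of ≤ 6 nodes — chosen so the full suite
completes in well under a minute while still exercising every code
path at the cohort size the method targets.  The streaming metafeature
contract is what would carry the same code to signature scale
(millions of pairs); the external-memory and GPU engineering that a
full-scale run would additionally want is deliberately out of scope.

## Known limitations

- The q-escalation rule (+1 until connected) is one reasonable
  realization of the method's connectivity requirement; very sparse
  data could in principle escalate far.
- Homogeneity/separation use Pearson on raw rows (the convention of
  the classic microarray evaluation tools); rank-based variants are
  not provided.
- The robust-marker intersection counts probe identifiers, not genes;
  multiple probes of one gene count separately.
- `stratified_recluster` re-runs the full pipeline on the stratum; it
  does not test the significance of membership changes.
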