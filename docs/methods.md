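# Methods

This note documents the models and procedures implemented in `domarchnet`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Entities and classification

An architecture is an ordered, N→C list of SCOP FSF tokens joined by `|`.
A trailing `&` marks a collapsed tandem repeat and creates a *distinct*
token: `c.43.1&` never matches `c.43.1`, and both can coexist as network
nodes.  Classification is purely combinatorial: one block → domain; a
multi-block entity whose token sequence occurs contiguously inside at
least one other entity → supradomain; the rest → multidomain.  Matching is
order-sensitive and contiguous because domain adjacency encodes chain
topology; reversed or gapped matches never count.  An entity can be both a
standalone protein and a reused building block; classification then picks
supradomain.  Overlapping occurrences of the same component are all
reported; each network criterion decides how to use them.

## Ages and the timeline

Relative age `nd` of a leaf is its root-to-leaf internal-node count,
min-max rescaled to [0, 1], so the shallowest leaf is exactly 0 (this is
what makes the oldest domain's printed age 0.0000000) and only tree
imbalance — not branch lengths, not node density — carries signal.
Whether the root itself is counted is unobservable after min-max scaling.
`nd` values are rounded to 7 decimals before forming time events, which
prevents float noise from splitting one age sliver into two; distinct
values, ascending, get 1-based event ordinals.

The molecular clock `t = −3.831·nd + 3.628` (Gy per nd unit; Gya at
nd = 0) is affine, so differences are exact: Δnd = 0.11 is 0.42 Gy.  Two
caveats are deliberate: at nd = 1 the published clock overshoots the
present (−0.203 Gya), and values are returned unclamped; and absolute ages
published alongside this clock elsewhere (e.g. ~3.54 Gya at nd = 0.069)
differ from the printed equation by ~0.18 Gy, while all Δ arithmetic is
consistent — this package trusts the printed equation and treats only
differences as exact.

## Network construction

All five criteria emit arcs directed old → new whose age is the *younger*
endpoint's `nd`; equal-age links are retained but flagged contemporary
(they are excluded from "first event" queries and typically from
renderings).  Weights are multiplicities.  Decisions worth knowing:

- **CX** uses every multi-block entity as a container and every entity
  occurring as a contiguous proper sub-sequence as a component; weight =
  number of distinct occurrences.  In-weights therefore conserve the
  occurrence count of the container.
- **PX/PAX/SPX/SPAX** decompose *multidomain-classified* entities only.
  Decomposing supradomains as well would double-count every pair that a
  containing multidomain already induces (the worked toy enumeration pins
  this down).  Weight = number of distinct inducing multidomains, keeping
  weights comparable across criteria.
- **PX/PAX pairs require disjoint occurrences** — a domain does not pair
  with a supradomain that covers it.  "Decomposed into pairs" is read as a
  partition-like split; this is the main construction ambiguity and is the
  first thing to revisit if replication against a published census
  deviates.
- **Self-pairs** (the same token twice in one protein) are dropped;
  repeat-marked tokens are nodes in their own right.
- Spliced-token ages are first appearances: the minimum `nd` over all
  entities carrying the token.  This is why domain-only networks can have
  fewer time events than the full entity set.
- Snapshots are cumulative: event *e* holds nodes with `nd ≤ nd_e` and
  arcs with age `≤ nd_e`.  Modularity and clustering consume an undirected
  view (weights summed over the two directions; unweighted for C).

## Scale-free statistics

P(k) is computed from raw, unbinned frequencies of observed positive
degrees (no binning rule is imposed); γ and R² come from least squares of
log10 P(k) on log10 k and need ≥ 3 distinct degree values, otherwise the
event records a gap rather than an error.  Weighted indegree is the
primary fitted quantity (outdegree is reported alongside), matching the
convention that cumulative weighted connectivity is what evolves.

The discrete power-law fit maximises the exact zeta-normalised likelihood
on a 400-point exponent grid over [1.05, 6] with one parabolic refinement
(precision ~10⁻³, well below the estimator's standard error
(α−1)/√n), scanning xmin over up to 75 quantile-spaced unique values and
choosing the KS-minimising cutoff.  The KS p-value uses the
semi-parametric bootstrap (body resampled empirically, tail from the
fitted law, full refit per replicate); the default is 100 replicates for a
single fit and 25 per event in chronological series, a cost/precision
trade-off that still resolves the 0.05 decision line.  For growth-model
*controls* the attachment exponent is measured with a fixed deep-tail
cutoff (k ≥ 8, roughly the top 5% at n = 5000) averaged over replicate
graphs, because the stationary Barabási law 1/(k(k+1)(k+2)) approaches its
asymptotic slope 3 only in the tail and KS-chosen cutoffs absorb that
pre-asymptotic curvature into the estimate (the exact-law MLE at xmin = 3
is ~2.65 even with infinite data).

## Randomness

The Bartels rank version of von Neumann's ratio uses midranks for ties;
RVN = Σ(R_i − R_{i+1})² / Σ(R_i − (n+1)/2)², E[RVN] = 2 under randomness,
σ² = 4(n−2)(5n²−2n−9)/[5n(n+1)(n−1)²], and the two-sided p-value comes
from the symmetric beta approximation of RVN/4 with shape 2/σ² − 1/2.
The input series is a genuinely open choice (no published statement pins
it down): this package uses the **weighted total degree sequence ordered
by node age** (ties by label) per event — the only age-indexed scalar
series the chronological analyses share.  This is the major interpretive
decision in the statistics module.

## Modularity

- **VQ** implements the printed community-pair formula
  Σ_{i<j}(e_ij − a_i²) literally, with e_ij the fraction of total edge
  weight crossing i and j.  This differs from standard modularity (it is
  negative for well-separated communities); standard Newman–Girvan Q is
  always reported alongside and verified against a brute-force double
  loop.
- **Community detection**: "VOS-style" clustering is seeded,
  resolution-parameterized local moving (Louvain); the original tool's
  internals are unpublished, so cluster *counts* are indicative only.
  Fast-greedy uses CNM agglomeration, and a best cut with Q ≤ 0 collapses
  to a single community (Q = 0).
- **NG_age** uses 10 equal-width age bins over [0, 1] (right-closed last
  bin), the same granularity as the age color-coding convention; the bin
  id is kept even when bins are empty.
- **C** is computed on the simplified (undirected, unweighted) graph,
  contemporary links included, degree-<2 nodes contributing 0.
- **Heatmaps**: B = A − k kᵀ/2m (rows sum to 0 exactly); the published
  scaling phrase "log10 of network-wide modularity" is ambiguous, so B is
  multiplied by sign(Q)·log10(1 + |Q|·scale) (scale = 10), an
  order-preserving transform, and the raw B is kept alongside.  Distances
  are squared Euclidean; linkage is Ward; leaves are age-sorted within the
  top 2-way split.

## Controls

Preferential attachment is generated directly: a connected seed clique of
m+1 nodes, then each new node attaches to m targets without replacement
with probability ∝ k^α (times bucket(l)^β for the age variant, where l
counts growth events since addition, bucketed into `aging_bins` classes,
default one bin per event; β > 0 favors older nodes).  Erdős–Rényi
controls are G(n, m).  Size matching per event copies node counts (and
edge counts for ER).

## Hubs

Combined degree = sum of weighted out- (or in-) degree over the five
networks at the latest event with `nd ≤` the requested time point; the
threshold is the linear-interpolation percentile of the combined-degree
vector *including* zero-degree nodes (interpolation is what makes
fractional thresholds possible).  Sum, not max, across networks.
Annotations are left joins (SCOP superfamily descriptions by sccs, GO term
names); composites and missing labels annotate as "N/A", never as errors.
Fusional/fissional flags are ingested, not inferred.

## Synthetic data

The generator emulates: a pool of `n_domains` single domains with ages on
an integer event grid weighted toward early events; `n_multidomains`
concatenations of 2..`max_blocks` tokens sampled ∝ (reuse count)^`pref_strength`
and biased toward older domains (rich-get-richer); a fraction
(`extend_prob` = 0.25) of multidomains extending existing ones, which is
what makes supradomains arise; optional `&` repeat markers
(`repeat_prob` = 0.05); and multidomain ages one grid step after their
youngest component.  Defaults (300 domains, 3000 multidomains, event-grid
target 169 yielding ~100 realised events) keep the same orders of
magnitude as a published census (1643 domains, 6162 entities, 169 events)
at a size every stage traverses in seconds.

It does **not** emulate: contemporary or age-inverted container/component
pairs (real tree-derived ages produce them; the pipeline tolerates them
via the contemporary flag), proteome abundances, domain-length effects, or
lineage structure.  Passing tests on synthetic data therefore validate the
combinatorics, the chronology mechanics and the statistical machinery —
not the biological conclusions one would draw from a real census.

Trees from `gen_tree` interpolate between a pure caterpillar
(imbalance = 1, maximal age spread) and a balanced tree (imbalance = 0,
all ages collapse to 0) by choosing the split rule per node.

## Problem sizes and determinism

The acceptance script runs the closed-form checks, the simulation
recoveries (10⁴-point MLE sample; ten n = 5000 preferential-attachment
replicates; twenty length-100 randomness series) and the full pipeline on
the default synthetic census (3300 entities, ~100 events), completing in
well under a minute on one core.  Every random quantity derives from the
`--seed` argument; per-event bootstrap seeds are offset by the event
ordinal so series are reproducible element-wise.

## Known limitations

- Replication against the published census requires the original data
  matrix/tree files; the loaders and the replication test exist, but the
  repository ships without the files.
- The PX/PAX disjointness rule and the RVN input series are interpretive
  choices (flagged above) that replication data could overturn.
- The KS bootstrap p-value is Monte-Carlo-discrete (resolution 1/replicates).
- Layout routines aim for deterministic, readable coordinates, not for
  reproducing any particular published drawing's energy minimisation.
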